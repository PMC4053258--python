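"""Control-derived SD thresholds and the m-of-n gene-level hit-calling rule.

Hit calling is anchored to the treated negative control: for each screen
batch, assay and condition, the mean mu and sample standard deviation sigma
of the siNeg fold changes define thresholds T_up(k) = mu + k*sigma and
T_down(k) = mu - k*sigma for k in {1, 2}.  An siRNA qualifies in a direction
at stringency k when its fold change lies strictly beyond the corresponding
threshold.  A gene is called when at least m of its n siRNAs qualify
(default m = 3 of n = 4), at one of two tiers:

* high ("+")  - at least m siRNAs beyond the 2-SD threshold;
* low ("(+)") - at least m beyond the 1-SD threshold (but not high);
* none ("-")  - otherwise.

A negative regulator of the death-ligand pathway is a gene whose silencing
*increases* treated caspase fold change (direction "up") and *decreases*
treated viability (direction "down"); the caller is direction-parameterised
so one code path serves both readouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ControlStats",
    "GeneCall",
    "CorroborationRecord",
    "TIER_SYMBOLS",
    "compute_control_stats",
    "compute_all_control_stats",
    "flag_sirnas",
    "call_gene",
    "call_screen",
    "corroborate_gene",
    "corroborate_screen",
    "rank_by_median",
    "secondary_matrix",
]

#: Table symbols for the two stringency tiers.
TIER_SYMBOLS = {"high": "+", "low": "(+)", "none": "-"}

_FLAG_COLS = ["flag_up_k1", "flag_up_k2", "flag_down_k1", "flag_down_k2"]


@dataclass(frozen=True)
class ControlStats:
    """siNeg fold-change statistics for one screen batch x assay x condition."""

    screen_batch: str
    assay: str
    condition: str
    mu: float
    sigma: float
    n: int

    def t_up(self, k: float) -> float:
        return self.mu + k * self.sigma

    def t_down(self, k: float) -> float:
        return self.mu - k * self.sigma

    def as_dict(self) -> dict:
        return {
            "screen_batch": self.screen_batch,
            "assay": self.assay,
            "condition": self.condition,
            "mu": self.mu,
            "sigma": self.sigma,
            "n": self.n,
            "t_up_k1": self.t_up(1),
            "t_up_k2": self.t_up(2),
            "t_down_k1": self.t_down(1),
            "t_down_k2": self.t_down(2),
        }


@dataclass(frozen=True)
class GeneCall:
    """Gene-level verdict under the m-of-n redundancy rule for one assay/direction."""

    gene_id: str
    assay: str
    direction: str  # "up" or "down"
    n: int
    n_flagged_k1: int
    n_flagged_k2: int
    tier: str  # "high" | "low" | "none"
    callable: bool
    gene_set: str = "unknown"

    @property
    def symbol(self) -> str:
        return TIER_SYMBOLS[self.tier]


@dataclass(frozen=True)
class CorroborationRecord:
    """Cross-assay support for a primary caspase-3/7 'up' call on one gene.

    Viability support is assessed in the 'down' direction at 2 SD (with the
    1-SD tier reported as a fallback); caspase-8 support in the 'up'
    direction at the relaxed 1-SD stringency.
    """

    gene_id: str
    primary_tier: str
    viability_support: str  # tier from viability-down calls
    caspase8_support: str  # "low"/"none": qualifies when >= m siRNAs beyond 1 SD
    n_assays_supporting: int
    complete: bool = True


def compute_control_stats(
    measurements: pd.DataFrame,
    screen_batch: str,
    assay: str,
    condition: str = "treated",
    control_role: str = "siNeg",
) -> ControlStats:
    """Pooled siNeg fold-change mean/SD for one batch x assay x condition.

    Control wells are pooled across all plates of the batch; sigma uses the
    n-1 denominator.  Requires at least two control wells.
    """
    if "fold_change" not in measurements.columns:
        raise ValueError("control stats require normalized measurements (fold_change)")
    sel = (
        (measurements["screen_batch"] == screen_batch)
        & (measurements["sample_role"] == control_role)
        & (measurements["assay"] == assay)
        & (measurements["condition"] == condition)
    )
    vals = measurements.loc[sel, "fold_change"].to_numpy(dtype=float)
    if vals.size < 2:
        raise ValueError(
            f"need >=2 {control_role} wells for {screen_batch}/{assay}/{condition}, "
            f"found {vals.size}"
        )
    mu = float(np.mean(vals))
    sigma = float(np.std(vals, ddof=1))
    return ControlStats(screen_batch, assay, condition, mu, sigma, int(vals.size))


def compute_all_control_stats(
    measurements: pd.DataFrame, condition: str = "treated"
) -> dict[tuple[str, str], ControlStats]:
    """ControlStats for every (screen_batch, assay) present in the data."""
    out: dict[tuple[str, str], ControlStats] = {}
    keys = (
        measurements.loc[measurements["sample_role"] == "siNeg", ["screen_batch", "assay"]]
        .drop_duplicates()
        .itertuples(index=False)
    )
    for batch, assay in keys:
        out[(batch, assay)] = compute_control_stats(measurements, batch, assay, condition)
    return out


def flag_sirnas(records: pd.DataFrame, stats: ControlStats) -> pd.DataFrame:
    """Flag per-siRNA fold changes against a batch's control thresholds.

    Inequalities are strict: a fold change exactly on a threshold does not
    qualify.  ``records`` must carry the same batch/assay/condition as
    ``stats``.
    """
    sel = records[
        (records["screen_batch"] == stats.screen_batch)
        & (records["assay"] == stats.assay)
        & (records["condition"] == stats.condition)
    ]
    if len(sel) < len(records):
        mismatched = records.index.difference(sel.index)
        raise ValueError(
            f"{len(mismatched)} records do not match ControlStats key "
            f"({stats.screen_batch}/{stats.assay}/{stats.condition})"
        )
    out = records.copy()
    f = out["fold_change"].to_numpy(dtype=float)
    for k in (1, 2):
        out[f"flag_up_k{k}"] = f > stats.t_up(k)
        out[f"flag_down_k{k}"] = f < stats.t_down(k)
    return out


def call_gene(
    flags: pd.DataFrame, direction: str, m: int = 3, gene_set: str = "unknown"
) -> GeneCall:
    """Apply the m-of-n redundancy rule to one gene's siRNA flags.

    ``flags`` holds one row per siRNA of a single gene x assay, with the
    boolean flag columns from :func:`flag_sirnas`.  Genes with fewer than m
    usable siRNAs are reported uncallable (tier forced to none).
    """
    if direction not in ("up", "down"):
        raise ValueError(f"direction must be 'up' or 'down', got {direction!r}")
    if flags.empty:
        raise ValueError("empty flag set")
    genes = flags["gene_id"].unique()
    assays = flags["assay"].unique()
    if len(genes) != 1 or len(assays) != 1:
        raise ValueError("call_gene expects flags for exactly one gene x assay")
    n = int(len(flags))
    n_k1 = int(flags[f"flag_{direction}_k1"].sum())
    n_k2 = int(flags[f"flag_{direction}_k2"].sum())
    is_callable = n >= m
    if not is_callable:
        tier = "none"
    elif n_k2 >= m:
        tier = "high"
    elif n_k1 >= m:
        tier = "low"
    else:
        tier = "none"
    return GeneCall(
        gene_id=str(genes[0]),
        assay=str(assays[0]),
        direction=direction,
        n=n,
        n_flagged_k1=n_k1,
        n_flagged_k2=n_k2,
        tier=tier,
        callable=is_callable,
        gene_set=gene_set,
    )


def call_screen(
    measurements: pd.DataFrame,
    annotation: pd.DataFrame | None,
    assay: str,
    direction: str,
    m: int = 3,
    condition: str = "treated",
) -> pd.DataFrame:
    """Gene-level calls for one assay/direction across all screen batches.

    Each batch is analysed under its own pooled siNeg ControlStats.  Returns
    one row per gene with flag counts, tier and tier symbol; unannotated
    genes are called with gene_set "unknown" and listed in
    ``result.attrs["unannotated_genes"]``.  Threshold statistics are kept in
    ``result.attrs["control_stats"]``.
    """
    from .screen_data import aggregate_sirna

    if "n_wells" not in measurements.columns:
        measurements = aggregate_sirna(measurements)
    exp = measurements[
        (measurements["sample_role"] == "experimental")
        & (measurements["assay"] == assay)
        & (measurements["condition"] == condition)
    ]
    gene_sets = {} if annotation is None else dict(
        zip(annotation["gene_id"], annotation["gene_set"])
    )

    rows = []
    stats_used: list[ControlStats] = []
    for batch, batch_df in exp.groupby("screen_batch", sort=True):
        stats = compute_control_stats(measurements, batch, assay, condition)
        stats_used.append(stats)
        flagged = flag_sirnas(batch_df, stats)
        for gene, gf in flagged.groupby("gene_id", sort=True):
            call = call_gene(gf, direction, m=m, gene_set=gene_sets.get(gene, "unknown"))
            rows.append(
                {
                    "gene_id": call.gene_id,
                    "gene_set": call.gene_set,
                    "screen_batch": batch,
                    "assay": call.assay,
                    "direction": call.direction,
                    "n": call.n,
                    "n_k1": call.n_flagged_k1,
                    "n_k2": call.n_flagged_k2,
                    "tier": call.tier,
                    "symbol": call.symbol,
                    "callable": call.callable,
                }
            )
    out = pd.DataFrame(
        rows,
        columns=[
            "gene_id", "gene_set", "screen_batch", "assay", "direction",
            "n", "n_k1", "n_k2", "tier", "symbol", "callable",
        ],
    )
    unannotated = sorted(set(out["gene_id"]) - set(gene_sets)) if gene_sets else []
    if unannotated:
        warnings.warn(
            f"{len(unannotated)} genes missing from annotation (called with "
            f"gene_set='unknown'): {unannotated[:5]}...",
            stacklevel=2,
        )
    out.attrs["unannotated_genes"] = unannotated
    out.attrs["control_stats"] = [s.as_dict() for s in stats_used]
    return out


def corroborate_gene(
    primary: GeneCall | None,
    caspase8: GeneCall | None,
    viability: GeneCall | None,
    m: int = 3,
) -> CorroborationRecord:
    """Combine one gene's three assay calls into a corroboration record.

    ``primary`` is the caspase-3/7 'up' call; ``viability`` the viability
    'down' call; ``caspase8`` the caspase-8 'up' call.  Viability supports at
    its high (2-SD) tier, with the 1-SD tier reported as fallback; caspase-8
    supports at the relaxed 1-SD criterion (>= m siRNAs beyond 1 SD).
    """
    gene = next(c.gene_id for c in (primary, caspase8, viability) if c is not None)
    complete = all(c is not None for c in (primary, caspase8, viability))
    primary_tier = primary.tier if primary is not None else "none"
    viability_support = viability.tier if viability is not None else "none"
    if caspase8 is not None and caspase8.n_flagged_k1 >= m and caspase8.callable:
        caspase8_support = "low"
    else:
        caspase8_support = "none"
    n_sup = int(viability_support == "high") + int(caspase8_support != "none")
    return CorroborationRecord(
        gene_id=gene,
        primary_tier=primary_tier,
        viability_support=viability_support,
        caspase8_support=caspase8_support,
        n_assays_supporting=n_sup,
        complete=complete,
    )


def corroborate_screen(
    measurements: pd.DataFrame,
    annotation: pd.DataFrame | None = None,
    m: int = 3,
    condition: str = "treated",
) -> pd.DataFrame:
    """Corroboration records for every gene with a caspase-3/7 'up' call input.

    Genes present in batches lacking one of the assays (e.g. a batch screened
    without the caspase-8 endpoint) yield incomplete records, not errors.
    """
    calls = {}
    for assay, direction in (
        ("caspase3_7", "up"),
        ("caspase8", "up"),
        ("viability", "down"),
    ):
        try:
            df = call_screen(measurements, annotation, assay, direction, m=m, condition=condition)
        except ValueError:
            df = pd.DataFrame(columns=["gene_id", "tier", "n", "n_k1", "n_k2", "callable"])
        calls[assay] = df.set_index("gene_id") if len(df) else df

    def _get(assay: str, gene: str) -> GeneCall | None:
        df = calls[assay]
        if len(df) == 0 or gene not in df.index:
            return None
        r = df.loc[gene]
        return GeneCall(
            gene_id=gene, assay=assay, direction=str(r["direction"]),
            n=int(r["n"]), n_flagged_k1=int(r["n_k1"]), n_flagged_k2=int(r["n_k2"]),
            tier=str(r["tier"]), callable=bool(r["callable"]), gene_set=str(r["gene_set"]),
        )

    genes = sorted(calls["caspase3_7"].index) if len(calls["caspase3_7"]) else []
    rows = []
    for gene in genes:
        rec = corroborate_gene(_get("caspase3_7", gene), _get("caspase8", gene),
                               _get("viability", gene), m=m)
        rows.append(
            {
                "gene_id": rec.gene_id,
                "primary_tier": rec.primary_tier,
                "viability_support": rec.viability_support,
                "caspase8_support": rec.caspase8_support,
                "n_assays_supporting": rec.n_assays_supporting,
                "complete": rec.complete,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "primary_tier", "viability_support", "caspase8_support",
                 "n_assays_supporting", "complete"],
    )


def rank_by_median(
    measurements: pd.DataFrame,
    assay: str,
    condition: str = "treated",
    descending: bool = True,
) -> pd.DataFrame:
    """Rank genes by the median treated fold change of their siRNA set.

    The even-n median is the mean of the middle pair.  Ties are broken
    lexicographically by gene_id so the ordering is deterministic.
    """
    exp = measurements[
        (measurements["sample_role"] == "experimental")
        & (measurements["assay"] == assay)
        & (measurements["condition"] == condition)
    ]
    med = (
        exp.groupby("gene_id")["fold_change"]
        .agg(median_fold_change="median", n_sirnas="size")
        .reset_index()
    )
    med = med.sort_values(
        ["median_fold_change", "gene_id"], ascending=[not descending, True]
    ).reset_index(drop=True)
    med.insert(0, "rank", np.arange(1, len(med) + 1))
    return med


def secondary_matrix(calls_by_cell_line: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Assemble the gene x cell-line tier-symbol matrix of a secondary screen.

    Each cell line's calls must have been computed under that line's own
    siNeg ControlStats.  A gene absent from one cell line's calls is rendered
    as missing (empty string), not as "-".  Per-line "+" counts are stored in
    ``result.attrs["n_high_per_cell_line"]``.
    """
    cols = {}
    for line, calls in calls_by_cell_line.items():
        cols[line] = calls.set_index("gene_id")["symbol"]
    mat = pd.DataFrame(cols)
    mat = mat.reindex(sorted(mat.index))
    mat = mat.fillna("")
    mat.index.name = "gene_id"
    mat.attrs["n_high_per_cell_line"] = {
        line: int((col == "+").sum()) for line, col in mat.items()
    }
    return mat
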