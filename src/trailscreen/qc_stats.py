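"""Screen-quality metrics and statistical comparisons.

Covers the screening-window (Z-factor) coefficient, Welch's unequal-variance
t-test for control separation, pairwise Pearson correlation of the three
assay endpoints over shared siRNAs, and the excess-over-additivity test for
combination treatments (percent inhibition of the combination versus the sum
of the single-agent inhibitions).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "z_factor",
    "welch_t_test",
    "qc_report",
    "cross_screen_correlation",
    "CombinationResult",
    "combination_excess",
]


def z_factor(positive_values, negative_values) -> float:
    """Screening-window coefficient Z = 1 - 3(sigma_p + sigma_n)/|mu_p - mu_n|.

    Z <= 1 always; values near 1 indicate a wide assay window.  Standard
    deviations use the n-1 denominator.  Raises when the group means
    coincide (the separation band is undefined).
    """
    p = np.asarray(positive_values, dtype=float)
    n = np.asarray(negative_values, dtype=float)
    if p.size < 2 or n.size < 2:
        raise ValueError("z_factor needs >=2 values per control group")
    mu_p, mu_n = p.mean(), n.mean()
    if mu_p == mu_n:
        raise ValueError("z_factor undefined: control means are equal")
    return float(1.0 - 3.0 * (p.std(ddof=1) + n.std(ddof=1)) / abs(mu_p - mu_n))


def welch_t_test(group_a, group_b) -> tuple[float, float]:
    """Welch's unequal-variance t-test; returns (t, two-tailed p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("welch_t_test needs >=2 values per group")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        raise ValueError("welch_t_test undefined: both groups constant and equal")
    t, p = sps.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)


def qc_report(measurements: pd.DataFrame, per_plate: bool = True) -> dict:
    """Per batch x assay quality summary of the siNeg treatment window.

    The assay window is treated-siNeg versus vehicle-siNeg: Z-factor,
    Welch control-separation test, group summaries, and (optionally) the
    per-plate treated-siNeg means as a drift check.
    """
    if "fold_change" not in measurements.columns:
        raise ValueError("qc_report requires normalized measurements")
    neg = measurements[measurements["sample_role"] == "siNeg"]
    report: dict = {}
    for (batch, assay), grp in neg.groupby(["screen_batch", "assay"], sort=True):
        treated = grp.loc[grp["condition"] == "treated", "fold_change"].to_numpy(float)
        vehicle = grp.loc[grp["condition"] == "vehicle", "fold_change"].to_numpy(float)
        if treated.size < 2 or vehicle.size < 2:
            continue
        t, p = welch_t_test(treated, vehicle)
        entry = {
            "z_factor": z_factor(treated, vehicle),
            "t_statistic": t,
            "p_value": p,
            "treated": {"mean": float(treated.mean()), "sd": float(treated.std(ddof=1)),
                        "n": int(treated.size)},
            "vehicle": {"mean": float(vehicle.mean()), "sd": float(vehicle.std(ddof=1)),
                        "n": int(vehicle.size)},
        }
        if per_plate:
            drift = (
                grp[grp["condition"] == "treated"]
                .groupby("plate_id")["fold_change"].mean().sort_index()
            )
            entry["per_plate_treated_mean"] = {k: float(v) for k, v in drift.items()}
        report[f"{batch}/{assay}"] = entry
    return report


def cross_screen_correlation(
    measurements: pd.DataFrame, condition: str = "treated"
) -> pd.DataFrame:
    """Pairwise Pearson r between assay endpoints over shared siRNAs.

    Uses experimental siRNA fold changes only, matched on (gene, siRNA)
    within a condition; pairs with missing values are dropped listwise per
    assay pair.  Returns a symmetric DataFrame with unit diagonal; per-pair
    sample sizes are in ``result.attrs["n"]``.
    """
    exp = measurements[
        (measurements["sample_role"] == "experimental")
        & (measurements["condition"] == condition)
    ]
    wide = exp.pivot_table(
        index=["gene_id", "sirna_id"], columns="assay", values="fold_change",
        aggfunc="mean",
    )
    assays = sorted(wide.columns)
    mat = pd.DataFrame(np.eye(len(assays)), index=assays, columns=assays)
    n_pairs: dict[tuple[str, str], int] = {}
    for i, a in enumerate(assays):
        for b in assays[i + 1:]:
            sub = wide[[a, b]].dropna()
            if len(sub) < 3:
                raise ValueError(f"fewer than 3 shared siRNAs between {a} and {b}")
            for col in (a, b):
                if np.std(sub[col].to_numpy()) == 0:
                    raise ValueError(f"zero-variance fold changes in assay {col}")
            r = float(sps.pearsonr(sub[a], sub[b]).statistic)
            mat.loc[a, b] = mat.loc[b, a] = r
            n_pairs[(a, b)] = len(sub)
    mat.attrs["n"] = n_pairs
    return mat


@dataclass(frozen=True)
class CombinationResult:
    """Excess inhibition of a combination over single-agent additivity.

    Percent inhibition is I = 100 - viability%; the excess per replicate is
    E = I_combo - (I_A + I_B), compared to zero by a paired two-tailed t-test
    across replicate experiments.
    """

    inhibition_a: np.ndarray
    inhibition_b: np.ndarray
    inhibition_combo: np.ndarray
    excess: np.ndarray
    t_statistic: float
    p_value: float

    @property
    def mean_excess(self) -> float:
        return float(self.excess.mean())


def combination_excess(viability_a, viability_b, viability_combo) -> CombinationResult:
    """Compare combination inhibition with single-agent additivity.

    Inputs are viability percentages (0-100 scale) per replicate experiment
    for arm A alone, arm B alone and the combination; replicates must be
    matched (equal lengths, same experiment order).
    """
    va = np.asarray(viability_a, dtype=float)
    vb = np.asarray(viability_b, dtype=float)
    vc = np.asarray(viability_combo, dtype=float)
    if not (va.shape == vb.shape == vc.shape):
        raise ValueError("combination arms must have matched replicate counts")
    ia, ib, ic = 100.0 - va, 100.0 - vb, 100.0 - vc
    excess = ic - (ia + ib)
    if va.size >= 2 and np.ptp(excess) > 0:
        t, p = sps.ttest_rel(ic, ia + ib)
        t, p = float(t), float(p)
    elif va.size >= 2:
        # Constant excess: t-test degenerate; report exact outcome.
        t, p = (float("inf") if excess[0] != 0 else 0.0), (0.0 if excess[0] != 0 else 1.0)
    else:
        t, p = float("nan"), float("nan")
    return CombinationResult(ia, ib, ic, excess, t, p)
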