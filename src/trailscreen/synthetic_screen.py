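"""Synthetic arrayed RNAi screen generator with ground truth.

Emulates the structure of a paired (+/- death ligand) three-endpoint
arrayed siRNA screen in 384-well plates: four siRNAs per gene, one siRNA
per well; per-plate control wells (untransfected cells, siNeg, siCelldeath,
siCASP8, siFLIP); separate screen batches with their own plates and assay
panels; multiplicative log-normal well noise and per-plate scale factors;
per-siRNA knockdown efficacy including outright reagent failure; and
planted negative/positive pathway regulators whose effect sizes are
correlated across the caspase and viability endpoints (caspase-8 and
caspase-3/7 positively, both against viability negatively).

The signal model for a well is

    raw = vehicle_level(assay) * plate_scale(plate, assay)
          * condition_ratio * gene_effect * exp(sigma_log * N(0, 1))

where ``condition_ratio`` is 1 for vehicle wells and the configured treated
baseline (e.g. a 6.5-fold caspase-3/7 induction, a halving of viability)
for treated wells, and ``gene_effect`` for a treated experimental well is
``1 + eta_i * (e - 1)``: the siRNA's efficacy eta interpolates between no
effect and the gene's full effect size e.  Vehicle experimental wells have
unit effect (regulators here act on ligand-induced signalling only).
Everything is deterministic given (config, seed); each plate consumes its
own child random stream of the master seed, so generation is reproducible
plate by plate.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .screen_data import WELL_COLUMNS, format_well

__all__ = [
    "SimulationConfig",
    "SimulatedScreen",
    "RecoveryMetrics",
    "simulate_screen",
    "evaluate_recovery",
]

NEGATIVE = "negative_regulator"
POSITIVE = "positive_regulator"
NULL = "null"


class SimulationConfig(BaseModel):
    """Parameters of the synthetic screen.

    Defaults mirror the screen this generator emulates: 691 kinase, 206
    phosphatase and 238 additional genes (4,540 siRNAs); the kinase and
    additional sets share one batch screened with all three endpoints while
    the phosphatase set is a separate batch without the caspase-8 endpoint;
    treated/vehicle control baselines of ~6.5-fold (caspase-3/7), ~2.25-fold
    (caspase-8) and ~0.5 (viability).
    """

    model_config = ConfigDict(validate_assignment=True)

    n_genes: dict[str, int] = Field(
        default_factory=lambda: {"kinase": 691, "phosphatase": 206, "additional": 238}
    )
    batch_of_gene_set: dict[str, str] = Field(
        default_factory=lambda: {
            "kinase": "kinome_plus_additional",
            "additional": "kinome_plus_additional",
            "phosphatase": "phosphatase",
        }
    )
    assays_per_batch: dict[str, list[str]] = Field(
        default_factory=lambda: {
            "kinome_plus_additional": ["caspase8", "caspase3_7", "viability"],
            "phosphatase": ["caspase3_7", "viability"],
        }
    )
    n_sirnas: int = 4
    controls_per_plate: dict[str, int] = Field(
        default_factory=lambda: {
            "siNeg": 8, "cells_only": 30, "siCelldeath": 8, "siCASP8": 8, "siFLIP": 8
        }
    )

    # Raw vehicle-condition signal level per assay (arbitrary luminescence units).
    vehicle_signal: dict[str, float] = Field(
        default_factory=lambda: {"caspase8": 5e3, "caspase3_7": 1e4, "viability": 2e4}
    )
    # Treated/vehicle baseline ratio for control (siNeg-like) cells.
    treated_ratio: dict[str, float] = Field(
        default_factory=lambda: {"caspase8": 2.25, "caspase3_7": 6.5, "viability": 0.5}
    )

    # Planted regulators.
    frac_negative: float = 0.13
    frac_positive: float = 0.01
    negative_effect_median: float = 2.2  # median multiplicative caspase-3/7 effect
    positive_effect_median: float = 0.65
    effect_sigma: float = 0.3  # SD of log effect size across genes
    caspase8_effect_exponent: float = 0.5  # caspase-8 effect = c3/7 effect ** exponent
    viability_coupling: float = 1.0  # viability log-effect = -coupling * caspase log-effect
    endpoint_rho: float = 0.7  # cross-endpoint correlation of per-gene log effects

    # Per-siRNA efficacy. eta ~ Beta(alpha, beta), or exactly 1 when alpha is None;
    # a reagent fails outright (eta = 0) with probability p_fail.
    efficacy_alpha: float | None = 5.0
    efficacy_beta: float = 1.5
    p_fail: float = 0.25

    # Noise.
    sigma_log: dict[str, float] = Field(
        default_factory=lambda: {"caspase8": 0.2, "caspase3_7": 0.2, "viability": 0.1}
    )
    plate_scale_sigma: float = 0.15

    # Fixed control-well behaviours (multiplicative on the treated component).
    sicasp8_rescue: bool = True  # treated caspase and viability return to vehicle level
    siflip_caspase_effect: float = 1.6
    siflip_viability_effect: float = 0.64
    sicelldeath_viability_effect: float = 0.3  # applies in both conditions

    @model_validator(mode="after")
    def _check(self) -> "SimulationConfig":
        for name in ("frac_negative", "frac_positive", "p_fail"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.frac_negative + self.frac_positive > 1.0:
            raise ValueError("frac_negative + frac_positive must not exceed 1")
        if self.effect_sigma < 0 or any(s < 0 for s in self.sigma_log.values()):
            raise ValueError("noise SDs must be non-negative")
        if self.negative_effect_median <= 1.0:
            raise ValueError("negative_effect_median must exceed 1")
        if not 0.0 < self.positive_effect_median < 1.0:
            raise ValueError("positive_effect_median must lie in (0, 1)")
        if not 0.0 <= self.endpoint_rho <= 1.0:
            raise ValueError("endpoint_rho must be in [0, 1]")
        if self.n_sirnas < 1:
            raise ValueError("n_sirnas must be positive")
        missing = set(self.batch_of_gene_set.values()) - set(self.assays_per_batch)
        if missing:
            raise ValueError(f"batches without an assay panel: {sorted(missing)}")
        if self.genes_per_plate < 1:
            raise ValueError("control wells leave no room for experimental genes")
        return self

    @property
    def genes_per_plate(self) -> int:
        free = 384 - sum(self.controls_per_plate.values())
        return free // self.n_sirnas

    @property
    def sirna_labels(self) -> list[str]:
        return [chr(ord("A") + i) for i in range(self.n_sirnas)]


@dataclass
class SimulatedScreen:
    """Raw well table plus the generator's ground truth."""

    wells: pd.DataFrame
    gene_truth: pd.DataFrame  # gene_id, gene_set, screen_batch, truth_class, e_* per assay
    sirna_truth: pd.DataFrame  # gene_id, sirna_id, efficacy, failed

    @property
    def annotation(self) -> pd.DataFrame:
        """Gene -> gene-set annotation table derived from the truth."""
        ann = self.gene_truth[["gene_id", "gene_set"]].copy()
        ann["n_sirnas"] = (
            self.sirna_truth.groupby("gene_id")["sirna_id"].size()
            .reindex(ann["gene_id"]).to_numpy()
        )
        return ann

    def write(self, outdir: str | Path) -> dict[str, Path]:
        from .screen_data import write_screen_table

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "wells": outdir / "wells.csv",
            "gene_truth": outdir / "gene_truth.csv",
            "sirna_truth": outdir / "sirna_truth.csv",
            "annotation": outdir / "annotation.csv",
        }
        write_screen_table(self.wells, paths["wells"])
        self.gene_truth.to_csv(paths["gene_truth"], index=False)
        self.sirna_truth.to_csv(paths["sirna_truth"], index=False)
        self.annotation.to_csv(paths["annotation"], index=False)
        return paths


def _draw_gene_truth(config: SimulationConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Assign regulator classes and correlated per-assay effect sizes."""
    records = []
    rho = config.endpoint_rho
    cov = np.full((3, 3), rho)
    np.fill_diagonal(cov, 1.0)
    chol = np.linalg.cholesky(cov)
    for gene_set in sorted(config.n_genes):
        n = config.n_genes[gene_set]
        batch = config.batch_of_gene_set[gene_set]
        classes = rng.choice(
            [NEGATIVE, POSITIVE, NULL],
            size=n,
            p=[config.frac_negative, config.frac_positive,
               1.0 - config.frac_negative - config.frac_positive],
        )
        z = rng.standard_normal((n, 3)) @ chol.T
        for i in range(n):
            gene_id = f"{gene_set.upper()[:4]}{i + 1:04d}"
            cls = classes[i]
            if cls == NULL:
                e37 = e8 = ev = 1.0
            else:
                median = (config.negative_effect_median if cls == NEGATIVE
                          else config.positive_effect_median)
                log37 = np.log(median) + config.effect_sigma * z[i, 0]
                log8 = config.caspase8_effect_exponent * (
                    np.log(median) + config.effect_sigma * z[i, 1]
                )
                logv = -config.viability_coupling * (
                    np.log(median) + config.effect_sigma * z[i, 2]
                )
                # Keep planted effects on their own side of unity so the truth
                # class always has a definite direction.
                if cls == NEGATIVE:
                    e37, e8 = max(np.exp(log37), 1.05), max(np.exp(log8), 1.0)
                    ev = min(np.exp(logv), 0.95)
                else:
                    e37, e8 = min(np.exp(log37), 0.95), min(np.exp(log8), 1.0)
                    ev = max(np.exp(logv), 1.05)
            records.append(
                {
                    "gene_id": gene_id,
                    "gene_set": gene_set,
                    "screen_batch": batch,
                    "truth_class": cls,
                    "e_caspase3_7": float(e37),
                    "e_caspase8": float(e8),
                    "e_viability": float(ev),
                }
            )
    return pd.DataFrame(records)


def _draw_sirna_truth(
    config: SimulationConfig, gene_truth: pd.DataFrame, rng: np.random.Generator
) -> pd.DataFrame:
    genes = gene_truth["gene_id"].to_numpy()
    n = len(genes) * config.n_sirnas
    failed = rng.random(n) < config.p_fail
    if config.efficacy_alpha is None:
        eta = np.ones(n)
    else:
        eta = rng.beta(config.efficacy_alpha, config.efficacy_beta, size=n)
    eta = np.where(failed, 0.0, eta)
    return pd.DataFrame(
        {
            "gene_id": np.repeat(genes, config.n_sirnas),
            "sirna_id": np.tile(config.sirna_labels, len(genes)),
            "efficacy": eta,
            "failed": failed,
        }
    )


def _plate_layouts(config: SimulationConfig, gene_truth: pd.DataFrame) -> pd.DataFrame:
    """One row per physical well: plate_id, well, sample_role, gene_id, sirna_id."""
    frames = []
    for batch in sorted(config.assays_per_batch):
        genes = gene_truth.loc[gene_truth["screen_batch"] == batch, "gene_id"].to_numpy()
        if genes.size == 0:
            continue
        gpp = config.genes_per_plate
        n_plates = int(np.ceil(genes.size / gpp))
        for p in range(n_plates):
            plate_id = f"{batch}_p{p + 1:02d}"
            plate_genes = genes[p * gpp:(p + 1) * gpp]
            roles, gene_col, sirna_col = [], [], []
            for role, count in sorted(config.controls_per_plate.items()):
                roles += [role] * count
                gene_col += [""] * count
                sirna_col += [""] * count
            for g in plate_genes:
                for s in config.sirna_labels:
                    roles.append("experimental")
                    gene_col.append(g)
                    sirna_col.append(s)
            wells = [format_well(i // 24, i % 24 + 1) for i in range(len(roles))]
            frames.append(
                pd.DataFrame(
                    {
                        "screen_batch": batch,
                        "plate_id": plate_id,
                        "well": wells,
                        "sample_role": roles,
                        "gene_id": gene_col,
                        "sirna_id": sirna_col,
                    }
                )
            )
    return pd.concat(frames, ignore_index=True)


def _control_effect(config: SimulationConfig, role: str, assay: str, condition: str) -> float:
    """Fixed multiplicative behaviour of a control well."""
    treated = condition == "treated"
    if role in ("siNeg", "cells_only"):
        return 1.0
    if role == "siCelldeath":
        return config.sicelldeath_viability_effect if assay == "viability" else 1.0
    if role == "siCASP8":
        if treated and config.sicasp8_rescue:
            # Bring the treated signal back to the vehicle level.
            return 1.0 / config.treated_ratio[assay]
        return 1.0
    if role == "siFLIP":
        if treated:
            return (config.siflip_viability_effect if assay == "viability"
                    else config.siflip_caspase_effect)
        return 1.0
    raise ValueError(f"unknown control role: {role}")


def simulate_screen(config: SimulationConfig | None = None, seed: int = 0) -> SimulatedScreen:
    """Generate a raw well-level screen plus ground truth.

    Deterministic given (config, seed): the master seed spawns one child
    stream for the gene/siRNA truth and one per plate (in a fixed plate
    order), so the same plate always sees the same noise.
    """
    config = config or SimulationConfig()
    ss = np.random.SeedSequence(seed)
    truth_rng = np.random.default_rng(ss.spawn(1)[0])

    gene_truth = _draw_gene_truth(config, truth_rng)
    sirna_truth = _draw_sirna_truth(config, gene_truth, truth_rng)
    layout = _plate_layouts(config, gene_truth)

    effect_by_gene = gene_truth.set_index("gene_id")
    eta = sirna_truth.set_index(["gene_id", "sirna_id"])["efficacy"]

    plate_ids = list(dict.fromkeys(layout["plate_id"]))  # fixed generation order
    plate_streams = {pid: np.random.default_rng(child)
                     for pid, child in zip(plate_ids, ss.spawn(len(plate_ids)))}

    blocks = []
    for pid in plate_ids:
        lay = layout[layout["plate_id"] == pid]
        batch = lay["screen_batch"].iloc[0]
        assays = config.assays_per_batch[batch]
        rng = plate_streams[pid]
        for assay in assays:
            scale = float(np.exp(config.plate_scale_sigma * rng.standard_normal()))
            for condition in ("vehicle", "treated"):
                block = lay.copy()
                block["condition"] = condition
                block["assay"] = assay

                base = config.vehicle_signal[assay] * scale
                cond_ratio = config.treated_ratio[assay] if condition == "treated" else 1.0

                effect = np.ones(len(block))
                is_exp = (block["sample_role"] == "experimental").to_numpy()
                if condition == "treated" and is_exp.any():
                    genes = block.loc[is_exp, "gene_id"]
                    sirnas = block.loc[is_exp, "sirna_id"]
                    e = effect_by_gene.loc[genes, f"e_{assay}"].to_numpy()
                    h = eta.loc[list(zip(genes, sirnas))].to_numpy()
                    effect[is_exp] = 1.0 + h * (e - 1.0)
                ctrl_mask = ~is_exp
                if ctrl_mask.any():
                    roles = block.loc[ctrl_mask, "sample_role"]
                    effect[ctrl_mask] = [
                        _control_effect(config, r, assay, condition) for r in roles
                    ]

                noise = np.exp(config.sigma_log[assay] * rng.standard_normal(len(block)))
                block["raw_signal"] = base * cond_ratio * effect * noise
                blocks.append(block)

    wells = pd.concat(blocks, ignore_index=True).loc[:, WELL_COLUMNS]
    return SimulatedScreen(wells=wells, gene_truth=gene_truth, sirna_truth=sirna_truth)


@dataclass(frozen=True)
class RecoveryMetrics:
    """Confusion counts and derived rates of gene calls against planted truth."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if (self.tp + self.fn) else 1.0

    @property
    def precision(self) -> float:
        # Vacuously perfect when nothing is called.
        return self.tp / (self.tp + self.fp) if (self.tp + self.fp) else 1.0

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if (self.tn + self.fp) else 1.0


def evaluate_recovery(
    calls: pd.DataFrame,
    gene_truth: pd.DataFrame,
    truth_class: str = NEGATIVE,
    tier: str = "high",
) -> RecoveryMetrics:
    """Score gene calls against the simulator's planted regulators.

    A gene counts as predicted positive when its call tier qualifies at the
    requested stringency ("high" = high tier only; "low" = high or low).
    The call and truth tables must cover the same gene universe.
    """
    call_genes = set(calls["gene_id"])
    truth_genes = set(gene_truth["gene_id"])
    if call_genes != truth_genes:
        raise ValueError(
            f"gene universes differ: {len(call_genes - truth_genes)} only in calls, "
            f"{len(truth_genes - call_genes)} only in truth"
        )
    qualifying = {"high": {"high"}, "low": {"high", "low"}}[tier]
    pred = calls.set_index("gene_id")["tier"].isin(qualifying)
    truth = gene_truth.set_index("gene_id")["truth_class"] == truth_class
    truth = truth.reindex(pred.index)
    tp = int((pred & truth).sum())
    fp = int((pred & ~truth).sum())
    fn = int((~pred & truth).sum())
    tn = int((~pred & ~truth).sum())
    return RecoveryMetrics(tp=tp, fp=fp, fn=fn, tn=tn)
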