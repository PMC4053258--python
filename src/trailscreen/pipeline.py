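"""End-to-end pipeline: normalize -> QC -> thresholds -> calls -> corroboration -> network.

`run_pipeline` composes the stage functions exactly as a user would call
them individually, writes every stage table under an output directory and
records a JSON manifest with the parameter values, input checksums and the
control thresholds actually used.  Re-running with the same configuration
and inputs reproduces the tables byte for byte (timestamps are confined to
the log file).
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import hit_calling, network_analysis, qc_stats, screen_data

__all__ = ["RunConfig", "run_pipeline"]

logger = logging.getLogger(__name__)


class RunConfig(BaseModel):
    """Configuration of one pipeline run."""

    input: Path  # long-format well table (CSV/TSV)
    plate_map: Path | None = None
    annotation: Path | None = None
    edge_list: Path | None = None
    out: Path = Path("trailscreen_out")

    m: int = 3  # minimum qualifying siRNAs per gene
    n_sirnas: int = 4
    k_values: tuple[int, ...] = (1, 2)
    hub_degree: int = 7
    condition: str = "treated"
    primary_assay: str = "caspase3_7"

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        if self.m > self.n_sirnas:
            raise ValueError(
                f"m={self.m} qualifying siRNAs cannot exceed n_sirnas={self.n_sirnas}"
            )
        if self.m < 1:
            raise ValueError("m must be at least 1")
        if tuple(sorted(self.k_values)) != (1, 2):
            raise ValueError("k_values must be (1, 2): both stringency tiers are required")
        return self

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls(**yaml.safe_load(fh))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the report bundle.

    Returns the manifest dictionary (also written as ``manifest.json``).
    Stage errors propagate with the stage name prepended.
    """
    out = Path(config.out)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "parameters": json.loads(config.model_dump_json()),
        "inputs": {},
        "outputs": {},
        "thresholds": [],
    }
    for name in ("input", "plate_map", "annotation", "edge_list"):
        p = getattr(config, name)
        if p is not None:
            manifest["inputs"][name] = {"path": str(p), "sha256": _sha256(Path(p))}

    def _stage(name, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except Exception as exc:
            raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

    def _write(name: str, writer) -> None:
        path = out / name
        writer(path)
        manifest["outputs"][name] = str(path)

    records = _stage("read", screen_data.read_screen_table, config.input, config.plate_map)
    annotation = (
        _stage("annotation", screen_data.read_annotation, config.annotation)
        if config.annotation is not None
        else None
    )

    normalized = _stage("normalize", screen_data.normalize_to_plate_control, records)
    _write("normalized.csv", lambda p: screen_data.write_screen_table(normalized, p))

    qc = _stage("qc", qc_stats.qc_report, normalized)
    _write("qc.json", lambda p: p.write_text(json.dumps(qc, indent=2, sort_keys=True)))
    try:
        corr = qc_stats.cross_screen_correlation(normalized, condition=config.condition)
        _write("correlations.csv", lambda p: corr.to_csv(p))
    except ValueError as exc:  # fewer than two assays, or no shared siRNAs
        logger.info("skipping cross-screen correlation: %s", exc)

    aggregated = _stage("aggregate", screen_data.aggregate_sirna, normalized)

    calls = {}
    for assay, direction in (
        (config.primary_assay, "up"),
        (config.primary_assay, "down"),
        ("caspase8", "up"),
        ("viability", "down"),
    ):
        if assay not in set(aggregated["assay"]):
            continue
        key = f"{assay}_{direction}"
        if key in calls:
            continue
        df = _stage(
            f"call:{key}", hit_calling.call_screen,
            aggregated, annotation, assay, direction,
            m=config.m, condition=config.condition,
        )
        calls[key] = df
        manifest["thresholds"].extend(
            s for s in df.attrs["control_stats"] if s not in manifest["thresholds"]
        )
        _write(f"gene_calls_{key}.csv", lambda p, d=df: d.to_csv(p, index=False))

    corrob = _stage(
        "corroborate", hit_calling.corroborate_screen,
        aggregated, annotation, m=config.m, condition=config.condition,
    )
    _write("corroboration.csv", lambda p: corrob.to_csv(p, index=False))

    ranking = _stage(
        "rank", hit_calling.rank_by_median, aggregated, config.primary_assay,
        condition=config.condition,
    )
    _write("ranking.csv", lambda p: ranking.to_csv(p, index=False))

    if config.edge_list is not None:
        graph = _stage("network:read", network_analysis.read_edge_list, config.edge_list)
        primary_up = calls[f"{config.primary_assay}_up"]
        hits = primary_up.loc[primary_up["tier"] == "high", "gene_id"]
        sub, unmapped = _stage("network:subgraph", network_analysis.hit_subgraph, graph, hits)
        report = _stage(
            "network:hubs", network_analysis.hub_nodes, sub,
            min_degree=config.hub_degree,
            corroboration=corrob,
        )
        _write("network_nodes.csv", lambda p: report.to_csv(p, index=False))
        _write("hit_subgraph.sif", lambda p: network_analysis.write_sif(sub, p))
        manifest["network"] = {
            "n_hits": int(len(hits)),
            "n_mapped": sub.number_of_nodes(),
            "unmapped_genes": unmapped,
            "largest_component_size": (
                len(network_analysis.largest_component(sub)) if sub.number_of_nodes() else 0
            ),
            "n_hubs": int(report["is_hub"].sum()) if len(report) else 0,
        }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    logger.info("pipeline complete: %d output files in %s", len(manifest["outputs"]), out)
    return manifest
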