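import numpy as np
import pandas as pd
import pytest

import trailscreen as ts
from trailscreen.synthetic_screen import SimulationConfig, simulate_screen


def make_wells(rows: list[dict]) -> pd.DataFrame:
    """Build a well table from partial row dicts, filling common defaults."""
    defaults = {
        "screen_batch": "batch1",
        "plate_id": "p1",
        "well": None,
        "sample_role": "experimental",
        "gene_id": "",
        "sirna_id": "",
        "condition": "vehicle",
        "assay": "caspase3_7",
        "raw_signal": 1000.0,
    }
    filled = []
    for i, row in enumerate(rows):
        r = {**defaults, **row}
        if r["well"] is None:
            r["well"] = f"{chr(ord('A') + i // 24)}{i % 24 + 1:02d}"
        filled.append(r)
    return pd.DataFrame(filled)


def random_small_screen(rng: np.random.Generator, n_genes: int = 8) -> pd.DataFrame:
    """A random two-batch well table with controls, for oracle-equivalence tests."""
    rows = []
    for batch, plate in (("b1", "p1"), ("b2", "p2")):
        i = 0
        for _ in range(4):  # siNeg wells
            for cond in ("vehicle", "treated"):
                rows.append({"screen_batch": batch, "plate_id": plate,
                             "well": f"A{i % 24 + 1:02d}" if cond == "vehicle" else f"B{i % 24 + 1:02d}",
                             "sample_role": "siNeg", "condition": cond,
                             "assay": "caspase3_7",
                             "raw_signal": float(rng.uniform(500, 2000))})
            i += 1
        for g in range(n_genes):
            gene = f"{batch}G{g}"
            for s in "ABCD":
                for cond, row_letter in (("vehicle", "C"), ("treated", "D")):
                    idx = g * 4 + "ABCD".index(s)
                    rows.append({"screen_batch": batch, "plate_id": plate,
                                 "well": f"{chr(ord(row_letter) + idx // 24)}{idx % 24 + 1:02d}",
                                 "sample_role": "experimental", "gene_id": gene,
                                 "sirna_id": s, "condition": cond,
                                 "assay": "caspase3_7",
                                 "raw_signal": float(rng.uniform(200, 20000))})
    return pd.DataFrame(rows, columns=ts.screen_data.WELL_COLUMNS)


@pytest.fixture(scope="session")
def small_screen():
    """Default-parameter synthetic screen at reduced size, with derived tables."""
    cfg = SimulationConfig(n_genes={"kinase": 60, "phosphatase": 20, "additional": 20})
    sim = simulate_screen(cfg, seed=7)
    norm = ts.normalize_to_plate_control(sim.wells)
    agg = ts.aggregate_sirna(norm)
    return {"config": cfg, "sim": sim, "normalized": norm, "aggregated": agg}


@pytest.fixture(scope="session")
def study_scale_screen():
    """Full-size synthetic screen at the generator defaults (1,135 genes)."""
    cfg = SimulationConfig()
    sim = simulate_screen(cfg, seed=20140417)
    norm = ts.normalize_to_plate_control(sim.wells)
    agg = ts.aggregate_sirna(norm)
    return {"config": cfg, "sim": sim, "normalized": norm, "aggregated": agg}
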