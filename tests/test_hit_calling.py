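"""Control-threshold estimation and the m-of-n redundancy rule."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest

import trailscreen as ts
from trailscreen.hit_calling import (
    ControlStats,
    call_gene,
    call_screen,
    compute_control_stats,
    corroborate_gene,
    corroborate_screen,
    flag_sirnas,
    rank_by_median,
    secondary_matrix,
)
from trailscreen.screen_data import aggregate_sirna, normalize_to_plate_control

from conftest import make_wells, random_small_screen


def _flags_frame(pattern_k2, pattern_k1=None, direction="up", gene="G1"):
    """Build a flag table for one gene from boolean qualification patterns."""
    k2 = list(pattern_k2)
    k1 = list(pattern_k1) if pattern_k1 is not None else [a or b for a, b in zip(k2, k2)]
    rows = []
    for i, (f2, f1) in enumerate(zip(k2, k1)):
        rows.append({
            "gene_id": gene, "sirna_id": "ABCD"[i], "assay": "caspase3_7",
            "fold_change": 1.0,
            f"flag_{direction}_k1": bool(f1 or f2),
            f"flag_{direction}_k2": bool(f2),
            f"flag_{'down' if direction == 'up' else 'up'}_k1": False,
            f"flag_{'down' if direction == 'up' else 'up'}_k2": False,
        })
    return pd.DataFrame(rows)


def test_control_stats_hand_computed_sample_sd():
    df = make_wells([
        {"sample_role": "siNeg", "condition": "vehicle", "raw_signal": 1000.0},
        {"sample_role": "siNeg", "condition": "vehicle", "raw_signal": 1000.0},
        {"sample_role": "siNeg", "condition": "treated", "raw_signal": 8000.0},
        {"sample_role": "siNeg", "condition": "treated", "raw_signal": 10000.0},
        {"sample_role": "siNeg", "condition": "treated", "raw_signal": 12000.0},
    ])
    stats = compute_control_stats(normalize_to_plate_control(df), "batch1", "caspase3_7")
    assert stats.mu == pytest.approx(10.0)
    assert stats.sigma == pytest.approx(2.0)  # sample SD, n-1 denominator
    assert stats.t_up(2) == pytest.approx(14.0)
    assert stats.t_down(1) == pytest.approx(8.0)


def test_control_stats_zero_variance_degenerates_to_mu():
    stats = ControlStats("b", "caspase3_7", "treated", mu=5.0, sigma=0.0, n=3)
    assert stats.t_up(1) == stats.t_down(2) == 5.0


def test_control_stats_requires_two_wells():
    df = make_wells([
        {"sample_role": "siNeg", "condition": "vehicle", "raw_signal": 1000.0},
        {"sample_role": "siNeg", "condition": "treated", "raw_signal": 5000.0},
    ])
    with pytest.raises(ValueError, match=">=2"):
        compute_control_stats(normalize_to_plate_control(df), "batch1", "caspase3_7")


def test_threshold_symmetry_is_exact():
    rng = np.random.default_rng(5)
    for _ in range(100):
        mu, sigma = rng.uniform(-50, 50), rng.uniform(0, 10)
        s = ControlStats("b", "a", "treated", mu=mu, sigma=sigma, n=10)
        for k in (1, 2):
            # symmetric to within a rounding ulp of the float arithmetic
            assert s.t_up(k) - mu == pytest.approx(mu - s.t_down(k), rel=1e-12, abs=1e-12)
            assert s.t_up(k) + s.t_down(k) == pytest.approx(2 * mu, rel=1e-14)
        assert s.t_up(2) >= s.t_up(1) >= mu >= s.t_down(1) >= s.t_down(2)


def test_flag_boundary_is_strict():
    stats = ControlStats("b1", "caspase3_7", "treated", mu=6.0, sigma=2.14, n=10)
    records = pd.DataFrame({
        "screen_batch": ["b1"] * 3, "assay": ["caspase3_7"] * 3,
        "condition": ["treated"] * 3, "gene_id": ["G1"] * 3, "sirna_id": list("ABC"),
        "fold_change": [stats.t_up(2), np.nextafter(stats.t_up(2), np.inf), stats.t_down(2)],
    })
    flags = flag_sirnas(records, stats)
    assert flags["flag_up_k2"].tolist() == [False, True, False]
    assert flags["flag_down_k2"].tolist() == [False, False, False]


def test_flags_match_brute_force_comparison():
    rng = np.random.default_rng(9)
    stats = ControlStats("b1", "viability", "treated", mu=1.0, sigma=0.3, n=8)
    f = rng.uniform(0, 3, size=200)
    records = pd.DataFrame({
        "screen_batch": "b1", "assay": "viability", "condition": "treated",
        "gene_id": "G", "sirna_id": "A", "fold_change": f,
    })
    flags = flag_sirnas(records, stats)
    for _, row in flags.iterrows():
        for k in (1, 2):
            assert row[f"flag_up_k{k}"] == (row["fold_change"] > stats.mu + k * stats.sigma)
            assert row[f"flag_down_k{k}"] == (row["fold_change"] < stats.mu - k * stats.sigma)


def test_flag_rejects_mismatched_batch():
    stats = ControlStats("b1", "caspase3_7", "treated", mu=1, sigma=1, n=4)
    records = pd.DataFrame({
        "screen_batch": ["other"], "assay": ["caspase3_7"], "condition": ["treated"],
        "gene_id": ["G"], "sirna_id": ["A"], "fold_change": [2.0],
    })
    with pytest.raises(ValueError, match="do not match"):
        flag_sirnas(records, stats)


def test_redundancy_rule_exhaustive_over_all_flag_patterns():
    """Of the 2^4 qualification patterns, exactly C(4,3)+C(4,4)=5 call a gene."""
    n_called = 0
    for pattern in itertools.product([False, True], repeat=4):
        call = call_gene(_flags_frame(pattern), "up", m=3)
        assert (call.tier == "high") == (sum(pattern) >= 3)
        n_called += call.tier == "high"
    assert n_called == math.comb(4, 3) + math.comb(4, 4) == 5


def test_low_tier_requires_k1_quorum_without_k2_quorum():
    call = call_gene(_flags_frame([True, True, False, False], [True, True, True, False]), "up")
    assert call.tier == "low"
    assert call.n_flagged_k1 >= call.n_flagged_k2


def test_gene_with_too_few_sirnas_is_uncallable():
    flags = _flags_frame([True, True])
    call = call_gene(flags, "up", m=3)
    assert not call.callable and call.tier == "none" and call.n == 2


def test_call_gene_rejects_empty_and_mixed_input():
    with pytest.raises(ValueError, match="empty"):
        call_gene(_flags_frame([]).iloc[0:0], "up")
    mixed = pd.concat([_flags_frame([True]), _flags_frame([True], gene="G2")])
    with pytest.raises(ValueError, match="one gene"):
        call_gene(mixed, "up")


def _naive_call_screen(norm, assay, direction, m=3, condition="treated"):
    """Independent loop-based reimplementation used as the oracle."""
    out = {}
    for batch in sorted(norm["screen_batch"].unique()):
        ctl = [
            r["fold_change"] for _, r in norm.iterrows()
            if r["screen_batch"] == batch and r["sample_role"] == "siNeg"
            and r["assay"] == assay and r["condition"] == condition
        ]
        mu = sum(ctl) / len(ctl)
        sigma = math.sqrt(sum((x - mu) ** 2 for x in ctl) / (len(ctl) - 1))
        per_gene: dict[str, list[float]] = {}
        for _, r in norm.iterrows():
            if (r["screen_batch"] == batch and r["sample_role"] == "experimental"
                    and r["assay"] == assay and r["condition"] == condition):
                per_gene.setdefault(r["gene_id"], []).append(r["fold_change"])
        for gene, vals in per_gene.items():
            counts = {}
            for k in (1, 2):
                if direction == "up":
                    counts[k] = sum(v > mu + k * sigma for v in vals)
                else:
                    counts[k] = sum(v < mu - k * sigma for v in vals)
            if len(vals) < m:
                tier = "none"
            elif counts[2] >= m:
                tier = "high"
            elif counts[1] >= m:
                tier = "low"
            else:
                tier = "none"
            out[gene] = (tier, counts[1], counts[2], len(vals))
    return out


@pytest.mark.parametrize("direction", ["up", "down"])
def test_call_screen_matches_naive_reimplementation(direction):
    rng = np.random.default_rng(42)
    norm = normalize_to_plate_control(random_small_screen(rng))
    calls = call_screen(aggregate_sirna(norm), None, "caspase3_7", direction)
    oracle = _naive_call_screen(norm, "caspase3_7", direction)
    assert set(calls["gene_id"]) == set(oracle)
    for _, row in calls.iterrows():
        tier, n_k1, n_k2, n = oracle[row["gene_id"]]
        assert (row["tier"], row["n_k1"], row["n_k2"], row["n"]) == (tier, n_k1, n_k2, n)


def test_monotonicity_in_m_and_k(small_screen):
    """Raising the required quorum or stringency never yields more calls."""
    agg = small_screen["aggregated"]
    counts = []
    for m in (1, 2, 3, 4):
        calls = call_screen(agg, None, "caspase3_7", "up", m=m)
        counts.append((calls["tier"] != "none").sum())
        assert (calls["n_k2"] <= calls["n_k1"]).all()  # k2 flags are a subset of k1
        high = calls["tier"] == "high"
        assert (calls.loc[high, "n_k1"] >= 3).all() if m == 3 else True
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_corroboration_recomputes_from_flag_counts(small_screen):
    agg = small_screen["aggregated"]
    rec = corroborate_screen(agg, small_screen["sim"].annotation)
    primary = call_screen(agg, None, "caspase3_7", "up").set_index("gene_id")
    viab = call_screen(agg, None, "viability", "down").set_index("gene_id")
    c8 = call_screen(agg, None, "caspase8", "up").set_index("gene_id")
    assert len(rec) == len(primary)
    for _, row in rec.iterrows():
        g = row["gene_id"]
        assert row["primary_tier"] == primary.loc[g, "tier"]
        assert row["viability_support"] == viab.loc[g, "tier"]
        expected_c8 = "none"
        if g in c8.index and c8.loc[g, "n_k1"] >= 3 and c8.loc[g, "callable"]:
            expected_c8 = "low"
        assert row["caspase8_support"] == expected_c8
        expected_n = int(row["viability_support"] == "high") + int(row["caspase8_support"] != "none")
        assert row["n_assays_supporting"] == expected_n
        assert row["n_assays_supporting"] in (0, 1, 2)
        # Genes from the batch screened without a caspase-8 endpoint are incomplete.
        assert row["complete"] == (g in c8.index)


def test_corroborate_gene_null_case():
    none_call = ts.GeneCall("G", "caspase3_7", "up", 4, 0, 0, "none", True)
    rec = corroborate_gene(none_call,
                           ts.GeneCall("G", "caspase8", "up", 4, 0, 0, "none", True),
                           ts.GeneCall("G", "viability", "down", 4, 0, 0, "none", True))
    assert rec.n_assays_supporting == 0 and rec.complete


def test_corroborate_gene_missing_assay_marks_incomplete():
    primary = ts.GeneCall("G", "caspase3_7", "up", 4, 4, 4, "high", True)
    rec = corroborate_gene(primary, None, None)
    assert not rec.complete and rec.caspase8_support == "none"


def test_rank_by_median_ordering_and_even_n_convention():
    rows = [{"sample_role": "siNeg", "raw_signal": 1000.0}]
    gene_values = {"gA": [12000], "gB": [8000], "gC": [20000],
                   "gD": [2000, 4000, 6000, 8000]}
    for gene, vals in gene_values.items():
        for i, v in enumerate(vals):
            rows.append({"gene_id": gene, "sirna_id": "ABCD"[i], "condition": "treated",
                         "raw_signal": float(v)})
    # siNeg treated rows so normalization context is complete
    norm = normalize_to_plate_control(make_wells(rows))
    ranked = rank_by_median(norm, "caspase3_7")
    assert ranked["gene_id"].tolist() == ["gC", "gA", "gB", "gD"]
    assert ranked.set_index("gene_id").loc["gD", "median_fold_change"] == pytest.approx(5.0)


def test_rank_ties_break_lexicographically():
    rows = [{"sample_role": "siNeg", "raw_signal": 1000.0}]
    for gene in ("zz", "aa", "mm"):
        rows.append({"gene_id": gene, "sirna_id": "A", "condition": "treated",
                     "raw_signal": 5000.0})
    ranked = rank_by_median(normalize_to_plate_control(make_wells(rows)), "caspase3_7")
    assert ranked["gene_id"].tolist() == ["aa", "mm", "zz"]


def test_secondary_matrix_per_line_stats_and_missing_cells():
    def calls_df(tiers):
        return pd.DataFrame({
            "gene_id": list(tiers), "tier": list(tiers.values()),
            "symbol": [ts.hit_calling.TIER_SYMBOLS[t] for t in tiers.values()],
        })

    by_line = {
        "MB231": calls_df({"g1": "high", "g2": "low", "g3": "none"}),
        "MB468": calls_df({"g1": "high", "g2": "high", "g3": "high"}),
        "T47D": calls_df({"g1": "low", "g2": "none"}),  # g3 missing
    }
    mat = secondary_matrix(by_line)
    assert mat.loc["g1", "MB231"] == "+"
    assert mat.loc["g2", "MB231"] == "(+)"
    assert mat.loc["g3", "T47D"] == ""  # missing, not "-"
    assert mat.attrs["n_high_per_cell_line"] == {"MB231": 1, "MB468": 3, "T47D": 0}
    # Row-order permutation of the inputs leaves the matrix unchanged.
    shuffled = {k: v.sample(frac=1, random_state=1) for k, v in by_line.items()}
    pd.testing.assert_frame_equal(secondary_matrix(shuffled), mat)
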