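"""Scoring: frequencies, L2FC, rolling silent baseline, z-scores."""

import numpy as np
import pandas as pd
import pytest

from dmsfunc import (
    FunctionalScorer,
    aggregate_replicates,
    compute_l2fc,
    replicate_zscores,
    silent_baseline,
    to_frequencies,
)
from dmsfunc.scoring import CountsMatrix, SampleSpec
from dmsfunc.simulate import SimConfig, simulate_screen
from dmsfunc.variants import library_frame

from conftest import random_small_library, toy_counts


# --- frequencies and L2FC -------------------------------------------------

def test_to_frequencies_examples():
    np.testing.assert_allclose(to_frequencies([1, 1, 2], 0.0), [0.25, 0.25, 0.5])
    np.testing.assert_allclose(to_frequencies([0, 0, 0], 0.5), [1 / 3] * 3)
    np.testing.assert_allclose(
        to_frequencies([10, 30, 60], 0.5),
        [10.5 / 101.5, 30.5 / 101.5, 60.5 / 101.5])


def test_to_frequencies_degenerate_and_negative():
    with pytest.raises(ValueError):
        to_frequencies([0, 0, 0], 0.0)
    with pytest.raises(ValueError):
        to_frequencies([-1, 2], 0.5)


def test_compute_l2fc_examples():
    e = to_frequencies([100, 9900], 0.0)
    l = to_frequencies([25, 9975], 0.0)
    np.testing.assert_allclose(compute_l2fc(e, l)[0], -2.0)
    f = np.array([0.2, 0.8])
    np.testing.assert_allclose(compute_l2fc(f, f), [0.0, 0.0])
    np.testing.assert_allclose(compute_l2fc(f, 2 * f), [1.0, 1.0])
    with pytest.raises(ValueError):
        compute_l2fc(np.array([0.0, 1.0]), f)


# --- silent baseline ------------------------------------------------------

def _lib(rows):
    return pd.DataFrame(rows, columns=["variant_id", "position", "consequence"])


def test_silent_baseline_worked_example():
    """Silents at positions 1,2,3 with L2FC -1,-2,-3: window at position 2
    gives mean -2, sample SD 1."""
    lib = _lib([("s1", 1, "silent"), ("s2", 2, "silent"), ("s3", 3, "silent"),
                ("m2", 2, "missense")])
    l2fc = {"r": pd.Series([-1.0, -2.0, -3.0, 0.0],
                           index=["s1", "s2", "s3", "m2"])}
    base = silent_baseline(l2fc, lib, n_residues=3)
    row = base.at("r", 2)
    assert row["rolling_mean"] == pytest.approx(-2.0)
    assert row["rolling_sd"] == pytest.approx(1.0)
    assert row["n_silent"] == 3 and not row["sd_floored"]
    # z for the missense variant at position 2 with L2FC 0 is exactly 2
    z = replicate_zscores(l2fc, base, lib)
    assert z.loc["m2", "z_r"] == pytest.approx(2.0)
    assert z.loc["s2", "z_r"] == pytest.approx(0.0)


def test_silent_baseline_window_expands_until_min_silent():
    lib = _lib([("s1", 1, "silent"), ("s10", 10, "silent"), ("m5", 5, "missense")])
    l2fc = {"r": pd.Series([1.0, 3.0, 0.0], index=["s1", "s10", "m5"])}
    base = silent_baseline(l2fc, lib, n_residues=10, min_silent=2)
    row = base.at("r", 5)
    assert row["window_used"] > 2
    assert row["n_silent"] == 2
    assert row["rolling_mean"] == pytest.approx(2.0)


def test_silent_baseline_degenerate_spread_raises():
    lib = _lib([(f"s{p}", p, "silent") for p in range(1, 6)])
    l2fc = {"r": pd.Series([-2.0] * 5, index=lib["variant_id"])}
    with pytest.raises(ValueError, match="zero spread|unusable"):
        silent_baseline(l2fc, lib, n_residues=5)


def test_silent_baseline_sd_floor_uses_replicate_wide_sd():
    """A window whose silents are identical gets the replicate-wide SD."""
    lib = _lib([("s1", 1, "silent"), ("s2", 2, "silent"),
                ("s9", 9, "silent"), ("s10", 10, "silent"),
                ("s11", 11, "silent")])
    vals = pd.Series([1.0, 1.0, 0.0, 2.0, 4.0], index=lib["variant_id"])
    base = silent_baseline({"r": vals}, lib, n_residues=11, min_silent=2)
    row = base.at("r", 1)  # window captures s1, s2 only: SD 0 -> floored
    assert row["sd_floored"]
    assert row["rolling_sd"] == pytest.approx(vals.std(ddof=1))


def test_silent_baseline_requires_silents():
    lib = _lib([("m1", 1, "missense")])
    with pytest.raises(ValueError):
        silent_baseline({"r": pd.Series([0.0], index=["m1"])}, lib, n_residues=1)


def test_rolling_baseline_matches_brute_force_recollection():
    """Oracle equivalence on random small libraries: recollect silent L2FCs
    per expanding window by direct iteration."""
    rng = np.random.default_rng(42)
    for _ in range(25):
        lib, l2fc, n_res = random_small_library(rng)
        base = silent_baseline(l2fc, lib, n_residues=n_res,
                               half_width=2, min_silent=3)
        for rep, series in l2fc.items():
            sil = lib[lib["consequence"] == "silent"]
            tab = base.per_replicate[rep]
            for p in range(1, n_res + 1):
                h = 2
                while True:
                    vals = [series[v] for v, q in zip(sil["variant_id"], sil["position"])
                            if abs(q - p) <= h]
                    if len(vals) >= 3 or (p - h <= 1 and p + h >= n_res):
                        break
                    h += 1
                row = tab[tab["position"] == p].iloc[0]
                assert row["n_silent"] == len(vals)
                assert row["rolling_mean"] == pytest.approx(np.mean(vals), abs=1e-12)
                if len(vals) >= 2 and np.std(vals, ddof=1) > 0:
                    assert row["rolling_sd"] == pytest.approx(
                        np.std(vals, ddof=1), abs=1e-12)


# --- aggregation ----------------------------------------------------------

def test_aggregate_replicates_examples():
    z = pd.DataFrame({"z_a": [1.0, 2.0, 0.5], "z_b": [2.0, np.nan, np.nan],
                      "z_c": [3.0, np.nan, 1.5]},
                     index=["v1", "v2", "v3"])
    agg = aggregate_replicates(z)
    assert agg.loc["v1", "mean_z"] == pytest.approx(2.0)
    assert agg.loc["v1", "sd_z"] == pytest.approx(1.0)
    assert agg.loc["v1", "n_replicates"] == 3
    assert agg.loc["v2", "mean_z"] == pytest.approx(2.0)
    assert np.isnan(agg.loc["v2", "sd_z"]) and agg.loc["v2", "n_replicates"] == 1
    assert agg.loc["v3", "mean_z"] == pytest.approx(1.0)
    assert agg.loc["v3", "n_replicates"] == 2


# --- end-to-end scorer properties ----------------------------------------

def _small_screen(pseudocount_safe=True):
    rng = np.random.default_rng(0)
    lib = _lib(
        [(f"s{p}", p, "silent") for p in range(1, 11)]
        + [(f"m{p}", p, "missense") for p in range(1, 11)]
    )
    ids = list(lib["variant_id"])
    lo = 10 if pseudocount_safe else 0
    counts = {
        "e1": rng.integers(lo, 500, len(ids)),
        "l1": rng.integers(lo, 500, len(ids)),
    }
    cm = toy_counts(counts, ids, {"r1": ("e1", "l1")})
    return cm, lib


def test_depth_invariance_exact_with_zero_pseudocount():
    cm, lib = _small_screen()
    base = FunctionalScorer(pseudocount=0.0).fit_transform(cm, library=lib)
    scaled = cm.counts.copy()
    scaled["l1"] = scaled["l1"] * 7
    cm2 = CountsMatrix(counts=scaled, samples=cm.samples)
    other = FunctionalScorer(pseudocount=0.0).fit_transform(cm2, library=lib)
    np.testing.assert_allclose(base["mean_z"], other["mean_z"], atol=1e-12)


def test_depth_near_invariance_with_default_pseudocount():
    cm, lib = _small_screen()
    base = FunctionalScorer().fit_transform(cm, library=lib)
    scaled = cm.counts.copy()
    scaled["l1"] = scaled["l1"] * 2
    cm2 = CountsMatrix(counts=scaled, samples=cm.samples)
    other = FunctionalScorer().fit_transform(cm2, library=lib)
    assert np.nanmax(np.abs(base["mean_z"] - other["mean_z"])) < 1e-2


def test_z_strictly_increases_with_late_count():
    cm, lib = _small_screen()
    z0 = FunctionalScorer().fit_transform(cm, library=lib).loc["m5", "mean_z"]
    bumped = cm.counts.copy()
    bumped.loc["m5", "l1"] += 50
    z1 = FunctionalScorer().fit_transform(
        CountsMatrix(counts=bumped, samples=cm.samples), library=lib
    ).loc["m5", "mean_z"]
    assert z1 > z0


def test_location_shift_of_l2fc_leaves_z_unchanged():
    rng = np.random.default_rng(1)
    lib, l2fc, n_res = random_small_library(rng)
    base = silent_baseline(l2fc, lib, n_residues=n_res)
    z = replicate_zscores(l2fc, base, lib)
    shifted = {rep: s + 3.7 for rep, s in l2fc.items()}
    base2 = silent_baseline(shifted, lib, n_residues=n_res)
    z2 = replicate_zscores(shifted, base2, lib)
    np.testing.assert_allclose(z.to_numpy(), z2.to_numpy(), atol=1e-10)


def test_counts_matrix_validation():
    with pytest.raises(ValueError, match="negative"):
        toy_counts({"e": [-1, 2], "l": [1, 1]}, ["a", "b"], {"r": ("e", "l")})
    with pytest.raises(ValueError, match="zero total"):
        toy_counts({"e": [0, 0], "l": [1, 1]}, ["a", "b"], {"r": ("e", "l")})
    with pytest.raises(ValueError, match="duplicate variant"):
        toy_counts({"e": [1, 2], "l": [1, 1]}, ["a", "a"], {"r": ("e", "l")})
    cm = toy_counts({"e": [1, 2], "l": [1, 1]}, ["a", "b"], {"r": ("e", "l")})
    with pytest.raises(ValueError, match="exactly one"):
        cm.sample_for("r", "mid")


def test_scorer_output_schema(default_sim, default_sim_frame):
    scorer = FunctionalScorer().fit(default_sim.counts, library=default_sim_frame)
    scores = scorer.scores_
    assert {"position", "consequence", "mean_z", "sd_z", "n_replicates"} <= set(scores.columns)
    assert {"z_rep1", "z_rep2", "z_rep3"} <= set(scores.columns)
    assert (scores["n_replicates"] == 3).all()
    assert scores["mean_z"].notna().all()
    # sklearn param plumbing
    assert scorer.get_params()["pseudocount"] == 0.5
    clone_params = FunctionalScorer().set_params(half_width=4).get_params()
    assert clone_params["half_width"] == 4


def test_leave_one_out_mode_changes_only_silent_scores(default_sim, default_sim_frame):
    kept = FunctionalScorer().fit_transform(default_sim.counts, library=default_sim_frame)
    loo = FunctionalScorer(leave_one_out=True).fit_transform(
        default_sim.counts, library=default_sim_frame)
    nonsilent = kept["consequence"] != "silent"
    np.testing.assert_allclose(kept.loc[nonsilent, "mean_z"],
                               loo.loc[nonsilent, "mean_z"], atol=1e-12)
    silent = ~nonsilent
    assert not np.allclose(kept.loc[silent, "mean_z"], loo.loc[silent, "mean_z"])
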