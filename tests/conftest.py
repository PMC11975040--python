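import numpy as np
import pandas as pd
import pytest

from dmsfunc import CountsMatrix, SampleSpec, SimConfig, simulate_screen
from dmsfunc.variants import library_frame


@pytest.fixture(scope="session")
def default_sim():
    """One full-scale simulated screen (selection on, planted cluster)."""
    return simulate_screen(SimConfig(seed=7, lof_cluster=((50, 60),)))


@pytest.fixture(scope="session")
def default_sim_frame(default_sim):
    return library_frame(default_sim.library)


def toy_counts(counts_by_sample: dict[str, list[int]], variant_ids: list[str],
               replicates: dict[str, tuple[str, str]]) -> CountsMatrix:
    """Build a CountsMatrix from {sample_id: counts}; replicates maps
    replicate_id -> (early_sample, late_sample)."""
    samples = []
    for rep, (early, late) in replicates.items():
        samples.append(SampleSpec(early, rep, "early"))
        samples.append(SampleSpec(late, rep, "late"))
    counts = pd.DataFrame(counts_by_sample, index=variant_ids)
    counts.index.name = "variant_id"
    return CountsMatrix(counts=counts, samples=samples)


def random_small_library(rng: np.random.Generator, max_residues: int = 50):
    """A random small library table plus random per-replicate L2FC values.

    Used by the rolling-baseline oracle tests: positions, a random silent
    subset, and arbitrary L2FC values per variant.
    """
    n_res = int(rng.integers(5, max_residues + 1))
    rows = []
    for pos in range(1, n_res + 1):
        n_sil = int(rng.integers(0, 4))
        for j in range(n_sil):
            rows.append((f"S{pos}.{j}", pos, "silent"))
        for j in range(int(rng.integers(0, 3))):
            rows.append((f"M{pos}.{j}", pos, "missense"))
    lib = pd.DataFrame(rows, columns=["variant_id", "position", "consequence"])
    if (lib["consequence"] == "silent").sum() < 3:
        for pos in (1, 2, 3):
            lib.loc[len(lib)] = (f"Sx{pos}", min(pos, n_res), "silent")
    l2fc = {
        rep: pd.Series(rng.normal(0, 1, len(lib)), index=lib["variant_id"])
        for rep in ("r1", "r2")
    }
    return lib, l2fc, n_res
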