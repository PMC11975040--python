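"""Functional z-scores for pooled DMS screens.

The screen measures each variant's abundance at an early and a late timepoint
in several replicate contexts.  Per replicate, a variant's log2 fold change
(L2FC) of pseudocounted relative frequency is standardized against a *rolling
silent baseline*: the mean and standard deviation of silent (synonymous)
variants' L2FC within a +/-2-codon window around the variant's residue,

    z = (L2FC_variant - rolling_mean_silents) / rolling_sd_silents.

Silent variants are the neutral controls of the screen, and the local window
absorbs position-dependent biases (codon context, tile effects) that a global
baseline would fold into the denominator instead.  Windows with too few
silents expand symmetrically until ``min_silent`` silents are captured.
Per-replicate z-scores are averaged into the final functional score; the
across-replicate SD measures consistency between contexts.

The primary surface is the sklearn-style :class:`FunctionalScorer`
transformer; the module functions implement the individual steps.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "SampleSpec",
    "CountsMatrix",
    "SilentBaseline",
    "to_frequencies",
    "compute_l2fc",
    "silent_baseline",
    "replicate_zscores",
    "aggregate_replicates",
    "FunctionalScorer",
    "score_screen",
]


@dataclass(frozen=True)
class SampleSpec:
    sample_id: str
    replicate_id: str
    timepoint: str  # "early" | "late"

    def __post_init__(self) -> None:
        if self.timepoint not in ("early", "late"):
            raise ValueError(f"timepoint must be early/late, got {self.timepoint!r}")


@dataclass
class CountsMatrix:
    """Integer read counts per variant per sample.

    ``counts`` is indexed by variant_id with one column per sample_id;
    ``samples`` maps each sample to its replicate and timepoint.  In a
    scoring run every replicate must have exactly one early and one late
    sample.
    """

    counts: pd.DataFrame
    samples: list[SampleSpec]

    def __post_init__(self) -> None:
        if self.counts.index.has_duplicates:
            dupes = self.counts.index[self.counts.index.duplicated()].unique()
            raise ValueError(f"duplicate variant ids: {list(dupes)[:5]}")
        sample_ids = [s.sample_id for s in self.samples]
        if len(set(sample_ids)) != len(sample_ids):
            raise ValueError("duplicate sample ids in sample sheet")
        missing = set(sample_ids) - set(self.counts.columns)
        if missing:
            raise ValueError(f"samples missing from counts: {sorted(missing)}")
        vals = self.counts[sample_ids]
        if (vals.to_numpy() < 0).any():
            raise ValueError("negative counts")
        if (vals.sum(axis=0) <= 0).any():
            bad = vals.columns[vals.sum(axis=0) <= 0].tolist()
            raise ValueError(f"samples with zero total reads: {bad}")
        self.counts = vals

    @property
    def variant_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def replicates(self) -> list[str]:
        seen: list[str] = []
        for s in self.samples:
            if s.replicate_id not in seen:
                seen.append(s.replicate_id)
        return seen

    def sample_for(self, replicate_id: str, timepoint: str) -> SampleSpec:
        hits = [s for s in self.samples
                if s.replicate_id == replicate_id and s.timepoint == timepoint]
        if len(hits) != 1:
            raise ValueError(
                f"replicate {replicate_id!r} needs exactly one {timepoint} sample, "
                f"found {len(hits)}"
            )
        return hits[0]


@dataclass
class SilentBaseline:
    """Per-replicate rolling silent statistics, one row per residue position.

    Each table has columns position, rolling_mean, rolling_sd, n_silent,
    window_used (half-width actually applied) and sd_floored.
    """

    per_replicate: dict[str, pd.DataFrame]
    half_width: int
    min_silent: int

    def at(self, replicate_id: str, position: int) -> pd.Series:
        tab = self.per_replicate[replicate_id]
        return tab.loc[tab["position"] == position].iloc[0]


def to_frequencies(counts: np.ndarray, pseudocount: float = 0.5) -> np.ndarray:
    """Pseudocounted relative frequencies: (c_i + pc) / sum_j (c_j + pc)."""
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    shifted = counts + pseudocount
    total = shifted.sum()
    if total <= 0:
        raise ValueError("all-zero counts with zero pseudocount: frequencies undefined")
    return shifted / total


def compute_l2fc(early_freq: np.ndarray, late_freq: np.ndarray) -> np.ndarray:
    """log2(late / early) for aligned frequency vectors."""
    early = np.asarray(early_freq, dtype=float)
    late = np.asarray(late_freq, dtype=float)
    if early.shape != late.shape:
        raise ValueError("frequency vectors are not aligned")
    if (early <= 0).any() or (late <= 0).any():
        bad = np.flatnonzero((early <= 0) | (late <= 0))
        raise ValueError(
            f"nonpositive frequencies at indices {bad[:5].tolist()}; "
            "set a positive pseudocount"
        )
    return np.log2(late / early)


def _window_stats(silent_pos: np.ndarray, silent_l2fc: np.ndarray,
                  position: int, n_residues: int,
                  half_width: int, min_silent: int) -> tuple[float, float, int, int]:
    """Mean/SD of silent L2FC in the expanding window around ``position``.

    Returns (mean, sd, n_silent, window_used).  sd is NaN when n < 2.
    The window starts at +/-half_width, truncated at the ORF ends, and grows
    by 1 until >= min_silent silents are captured or the whole ORF is covered.
    """
    h = half_width
    while True:
        lo = np.searchsorted(silent_pos, position - h, side="left")
        hi = np.searchsorted(silent_pos, position + h, side="right")
        n = hi - lo
        covers_all = (position - h <= 1) and (position + h >= n_residues)
        if n >= min_silent or covers_all:
            break
        h += 1
    vals = silent_l2fc[lo:hi]
    if n == 0:
        return np.nan, np.nan, 0, h
    mean = float(vals.mean())
    sd = float(vals.std(ddof=1)) if n >= 2 else np.nan
    return mean, sd, n, h


def silent_baseline(
    l2fc: dict[str, pd.Series],
    library: pd.DataFrame,
    n_residues: int,
    half_width: int = 2,
    min_silent: int = 3,
) -> SilentBaseline:
    """Rolling silent-variant mean/SD per residue position and replicate.

    ``l2fc`` maps replicate_id -> Series of L2FC indexed by variant_id;
    ``library`` needs columns variant_id, position, consequence.  Windows
    with undefined or zero SD fall back to the replicate-wide silent SD
    (flagged ``sd_floored``); a replicate whose silent L2FCs are all
    identical has no usable scale and raises.
    """
    lib = library.set_index("variant_id")
    silent_ids = lib.index[lib["consequence"] == "silent"]
    if len(silent_ids) == 0:
        raise ValueError("library contains no silent variants: baseline undefined")
    per_replicate: dict[str, pd.DataFrame] = {}
    for rep, series in l2fc.items():
        avail = series.dropna()
        sil = avail.index.intersection(silent_ids)
        if len(sil) == 0:
            raise ValueError(f"replicate {rep!r}: no silent variants with L2FC")
        pos = lib.loc[sil, "position"].to_numpy()
        vals = avail.loc[sil].to_numpy(dtype=float)
        order = np.argsort(pos, kind="stable")
        pos, vals = pos[order], vals[order]
        global_sd = float(vals.std(ddof=1)) if len(vals) >= 2 else 0.0
        rows = []
        for p in range(1, n_residues + 1):
            mean, sd, n, h = _window_stats(pos, vals, p, n_residues,
                                           half_width, min_silent)
            floored = False
            if not np.isfinite(sd) or sd == 0.0:
                if global_sd > 0:
                    sd, floored = global_sd, True
                else:
                    raise ValueError(
                        f"replicate {rep!r}: silent L2FCs have zero spread; "
                        "baseline unusable"
                    )
            rows.append((p, mean, sd, n, h, floored))
        per_replicate[rep] = pd.DataFrame(
            rows, columns=["position", "rolling_mean", "rolling_sd",
                           "n_silent", "window_used", "sd_floored"],
        )
    return SilentBaseline(per_replicate=per_replicate,
                          half_width=half_width, min_silent=min_silent)


def replicate_zscores(
    l2fc: dict[str, pd.Series],
    baseline: SilentBaseline,
    library: pd.DataFrame,
) -> pd.DataFrame:
    """Per-replicate z-scores: (L2FC - rolling_mean) / rolling_sd at the
    variant's own residue position.  Unscorable entries are NaN.
    """
    lib = library.set_index("variant_id")
    out = pd.DataFrame(index=lib.index)
    for rep, series in l2fc.items():
        base = baseline.per_replicate[rep].set_index("position")
        positions = lib["position"]
        mean = base["rolling_mean"].reindex(positions).to_numpy()
        sd = base["rolling_sd"].reindex(positions).to_numpy()
        vals = series.reindex(lib.index).to_numpy(dtype=float)
        out[f"z_{rep}"] = (vals - mean) / sd
    return out


def aggregate_replicates(z: pd.DataFrame) -> pd.DataFrame:
    """Cross-replicate mean, sample SD (n-1), and replicate count per variant."""
    arr = z.to_numpy(dtype=float)
    n = np.isfinite(arr).sum(axis=1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(np.where(np.isfinite(arr), arr, np.nan), axis=1)
        sd = np.full(len(z), np.nan)
        multi = n >= 2
        if multi.any():
            sd[multi] = np.nanstd(arr[multi], axis=1, ddof=1)
    mean = np.where(n >= 1, mean, np.nan)
    return pd.DataFrame(
        {"mean_z": mean, "sd_z": sd, "n_replicates": n}, index=z.index
    )


class FunctionalScorer(BaseEstimator, TransformerMixin):
    """Compute functional z-scores from a screen's counts (sklearn-style).

    Parameters
    ----------
    pseudocount : float, default 0.5
        Added to every count before converting to relative frequencies.
    half_width : int, default 2
        Initial rolling-window half-width in codons (+/-2 codons).
    min_silent : int, default 3
        Minimum silent variants per window before symmetric expansion.
    baseline_mode : {"rolling", "global"}, default "rolling"
        "global" replaces the rolling baseline with the replicate-wide
        silent mean/SD (an ablation of the positional window).
    leave_one_out : bool, default False
        Exclude each silent variant from its own baseline window.

    Fitted attributes
    -----------------
    l2fc_ : DataFrame of per-replicate L2FC (variants x replicates)
    baseline_ : SilentBaseline
    scores_ : DataFrame with variant_id index, position, consequence,
        per-replicate z columns, mean_z, sd_z, n_replicates.
    """

    def __init__(self, pseudocount: float = 0.5, half_width: int = 2,
                 min_silent: int = 3, baseline_mode: str = "rolling",
                 leave_one_out: bool = False):
        self.pseudocount = pseudocount
        self.half_width = half_width
        self.min_silent = min_silent
        self.baseline_mode = baseline_mode
        self.leave_one_out = leave_one_out

    def fit(self, X: CountsMatrix, y=None, *, library: pd.DataFrame,
            n_residues: int | None = None):
        if self.baseline_mode not in ("rolling", "global"):
            raise ValueError(f"unknown baseline_mode {self.baseline_mode!r}")
        lib = library.reset_index(drop=True)
        missing = set(X.variant_ids) - set(lib["variant_id"])
        if missing:
            raise ValueError(
                f"counts contain variants absent from library: {sorted(missing)[:5]}"
            )
        if n_residues is None:
            n_residues = int(lib["position"].max())
        l2fc: dict[str, pd.Series] = {}
        for rep in X.replicates:
            early = X.counts[X.sample_for(rep, "early").sample_id].to_numpy()
            late = X.counts[X.sample_for(rep, "late").sample_id].to_numpy()
            ef = to_frequencies(early, self.pseudocount)
            lf = to_frequencies(late, self.pseudocount)
            l2fc[rep] = pd.Series(compute_l2fc(ef, lf), index=X.variant_ids)
        half_width = n_residues if self.baseline_mode == "global" else self.half_width
        baseline = silent_baseline(l2fc, lib, n_residues,
                                   half_width=half_width,
                                   min_silent=self.min_silent)
        z = replicate_zscores(l2fc, baseline, lib)
        if self.leave_one_out:
            z = self._leave_one_out_silents(z, l2fc, lib, n_residues)
        z = z.reindex(X.variant_ids)
        agg = aggregate_replicates(z)
        lib_idx = lib.set_index("variant_id")
        scores = pd.concat(
            [lib_idx.loc[X.variant_ids, ["position", "consequence"]], z, agg],
            axis=1,
        )
        scores.index.name = "variant_id"
        self.l2fc_ = pd.DataFrame(l2fc)
        self.baseline_ = baseline
        self.scores_ = scores
        self.n_residues_ = n_residues
        return self

    def _leave_one_out_silents(self, z, l2fc, lib, n_residues):
        """Rescore each silent variant against a window excluding itself."""
        z = z.copy()
        lib_idx = lib.set_index("variant_id")
        silent_ids = lib_idx.index[lib_idx["consequence"] == "silent"]
        for rep, series in l2fc.items():
            avail = series.dropna()
            sil = avail.index.intersection(silent_ids)
            pos_all = lib_idx.loc[sil, "position"].to_numpy()
            vals_all = avail.loc[sil].to_numpy(dtype=float)
            for vid in sil:
                mask = np.ones(len(sil), dtype=bool)
                mask[list(sil).index(vid)] = False
                pos, vals = pos_all[mask], vals_all[mask]
                order = np.argsort(pos, kind="stable")
                p = int(lib_idx.loc[vid, "position"])
                mean, sd, n, _ = _window_stats(
                    pos[order], vals[order], p, n_residues,
                    self.half_width, self.min_silent)
                if not np.isfinite(sd) or sd == 0:
                    sd = float(vals.std(ddof=1))
                z.loc[vid, f"z_{rep}"] = (avail.loc[vid] - mean) / sd
        return z

    def transform(self, X=None) -> pd.DataFrame:
        """Return the fitted score table."""
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "scores_")
        return self.scores_

    def fit_transform(self, X: CountsMatrix, y=None, **fit_params) -> pd.DataFrame:
        return self.fit(X, y, **fit_params).transform(X)


def score_screen(counts: CountsMatrix, library: pd.DataFrame,
                 **params) -> pd.DataFrame:
    """One-call wrapper: fit a :class:`FunctionalScorer` and return scores."""
    return FunctionalScorer(**params).fit_transform(counts, library=library)
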