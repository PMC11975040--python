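"""Loss-of-function calls and residue intolerance ranking.

A variant is called LOF when its cross-replicate mean functional z-score
strictly exceeds the threshold (default 2.0: enrichment two silent-baseline
SDs above neutral).  Residue intolerance averages the available missense
mean_z at each residue (up to 19 substitutions); residues whose average
strictly exceeds mean + 2*SD of the residue averages are flagged
mutation-intolerant.  The cutoff is always recomputed from the supplied
score set.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

__all__ = [
    "call_lof",
    "LofClassifier",
    "residue_intolerance",
    "positional_consequence_profile",
    "heatmap_matrix",
]

_CONSEQUENCES = ("silent", "missense", "nonsense", "frameshift")


def call_lof(scores: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """LOF calls: strict mean_z > threshold.

    ``scores`` must carry a mean_z column indexed by variant_id.  Variants
    with undefined mean_z are never LOF.
    """
    mean_z = scores["mean_z"]
    is_lof = (mean_z > threshold) & mean_z.notna()
    out = pd.DataFrame({"mean_z": mean_z, "is_lof": is_lof})
    out["threshold"] = threshold
    return out


class LofClassifier(BaseEstimator):
    """Thresholding classifier over functional scores (sklearn-style).

    ``predict`` returns a boolean LOF array for a score table or a mean_z
    vector; ``fit`` only validates the threshold.
    """

    def __init__(self, threshold: float = 2.0):
        self.threshold = threshold

    def fit(self, X=None, y=None):
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")
        self.threshold_ = float(self.threshold)
        return self

    def predict(self, X) -> np.ndarray:
        from sklearn.utils.validation import check_is_fitted

        check_is_fitted(self, "threshold_")
        mean_z = X["mean_z"] if isinstance(X, pd.DataFrame) else pd.Series(np.asarray(X, dtype=float))
        return ((mean_z > self.threshold_) & mean_z.notna()).to_numpy()


def residue_intolerance(
    scores: pd.DataFrame,
    min_substitutions: int = 10,
    cutoff_over_all_residues: bool = False,
) -> pd.DataFrame:
    """Rank residues by mean missense z and flag mutation-intolerant ones.

    Only missense variants enter residue averages.  Residues with fewer than
    ``min_substitutions`` scored substitutions are excluded from the cutoff
    estimate (set ``cutoff_over_all_residues`` to include them); the cutoff
    is mean + 2*SD (n-1) of the included residue averages, flags by strict >.
    """
    mis = scores[(scores["consequence"] == "missense") & scores["mean_z"].notna()]
    if mis.empty:
        raise ValueError("no scored missense variants")
    grp = mis.groupby("position")["mean_z"]
    prof = pd.DataFrame({
        "mean_missense_z": grp.mean(),
        "n_substitutions": grp.size(),
    }).reset_index()
    in_cutoff = (prof["n_substitutions"] >= min_substitutions) | cutoff_over_all_residues
    if not in_cutoff.any():
        raise ValueError(
            f"no residue has >= {min_substitutions} scored missense substitutions"
        )
    vals = prof.loc[in_cutoff, "mean_missense_z"].to_numpy()
    sd = float(vals.std(ddof=1)) if len(vals) >= 2 else 0.0
    cutoff = float(vals.mean()) + 2.0 * sd
    prof["cutoff"] = cutoff
    prof["in_cutoff_set"] = in_cutoff
    prof["is_intolerant"] = prof["mean_missense_z"] > cutoff
    return prof


def positional_consequence_profile(
    scores: pd.DataFrame,
    consequence: str,
    smooth_half_width: int = 5,
) -> pd.DataFrame:
    """Per-position mean z for one consequence class plus a centered moving
    average (window truncated at the ends).  Defined only at positions where
    the class has at least one scored variant.
    """
    if consequence not in _CONSEQUENCES:
        raise ValueError(f"unknown consequence {consequence!r}")
    sub = scores[(scores["consequence"] == consequence) & scores["mean_z"].notna()]
    if sub.empty:
        raise ValueError(f"no scored {consequence} variants")
    per_pos = sub.groupby("position")["mean_z"].mean().sort_index()
    positions = per_pos.index.to_numpy()
    raw = per_pos.to_numpy()
    smoothed = np.empty_like(raw)
    for i, p in enumerate(positions):
        mask = np.abs(positions - p) <= smooth_half_width
        smoothed[i] = raw[mask].mean()
    return pd.DataFrame({
        "position": positions,
        "mean_z": raw,
        "smoothed_z": smoothed,
        "consequence": consequence,
    })


def heatmap_matrix(scores: pd.DataFrame, n_residues: int | None = None) -> pd.DataFrame:
    """Variant-effect-map matrix: one row per alternate amino acid (20 AAs +
    stop + frameshift) plus a residue-average row, one column per position;
    cells hold mean_z, missing entries NaN.
    """
    from .variants import AMINO_ACIDS, FRAMESHIFT, STOP

    if n_residues is None:
        n_residues = int(scores["position"].max())
    cols = list(range(1, n_residues + 1))
    rows = list(AMINO_ACIDS) + [STOP, FRAMESHIFT, "residue_avg"]
    mat = pd.DataFrame(np.nan, index=rows, columns=cols)
    scored = scores[scores["mean_z"].notna()].copy()

    def row_key(item) -> str:
        vid, cons, alt_aa = item
        if cons == "nonsense":
            return STOP
        if cons == "frameshift":
            return FRAMESHIFT
        if alt_aa is not None:
            return alt_aa
        # fall back to parsing canonical ids: K2K.AAG -> K, K2N -> N
        return vid.split(".")[0][-1]

    alt_col = scored["alt_aa"] if "alt_aa" in scored.columns else [None] * len(scored)
    keys = [row_key(item) for item in zip(scored.index, scored["consequence"], alt_col)]
    scored["_row"] = keys
    cells = scored.groupby(["_row", "position"])["mean_z"].mean()
    for (key, pos), val in cells.items():
        if key in mat.index and pos in mat.columns:
            mat.loc[key, int(pos)] = val
    mis = scored[scored["consequence"] == "missense"]
    if not mis.empty:
        avg = mis.groupby("position")["mean_z"].mean()
        mat.loc["residue_avg", avg.index.astype(int)] = avg.to_numpy()
    mat.index.name = "alt_aa"
    return mat
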