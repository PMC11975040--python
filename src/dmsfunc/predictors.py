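"""Benchmarking DMS scores against computational variant-effect predictors.

SNV-level predictor tables (CADD PHRED, REVEL, AlphaMissense) are merged with
codon-level DMS scores through explicit SNV expansion of the library, each
tool is thresholded at its published pathogenicity cutoff (CADD >= 20,
AlphaMissense >= 0.56, REVEL >= 0.78), and agreement is summarized as
per-consequence concordance fractions.  Discriminative power against a
binary pathogenicity label set is measured by ROC/AUC with the tie-corrected
(midrank) Mann-Whitney statistic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .variants import OrfSequence, Variant, translate_codon

__all__ = [
    "PathogenicityThresholds",
    "classify_pathogenic",
    "snv_consequence",
    "merge_dms_predictor",
    "concordance_summary",
    "fraction_pathogenic",
    "RocResult",
    "roc_auc",
]


@dataclass(frozen=True)
class PathogenicityThresholds:
    """Inclusive (>=) pathogenicity thresholds per tool."""

    CADD: float = 20.0
    AlphaMissense: float = 0.56
    REVEL: float = 0.78

    def for_tool(self, tool: str) -> float:
        try:
            t = getattr(self, tool)
        except AttributeError:
            raise ValueError(f"unknown predictor tool {tool!r}") from None
        if not (np.isfinite(t) and t > 0):
            raise ValueError(f"threshold for {tool} must be a positive real")
        return float(t)


def classify_pathogenic(score: float, tool: str,
                        thresholds: PathogenicityThresholds | None = None) -> str:
    """"pathogenic" iff score >= the tool's threshold (inclusive), else "benign"."""
    thresholds = thresholds or PathogenicityThresholds()
    return "pathogenic" if score >= thresholds.for_tool(tool) else "benign"


def _codon_index(library: list[Variant]) -> dict[tuple[int, str], list[Variant]]:
    idx: dict[tuple[int, str], list[Variant]] = {}
    for v in library:
        if v.consequence == "frameshift":
            continue
        idx.setdefault((v.position, v.alt_aa), []).append(v)
    return idx


def snv_consequence(cds_position: int, ref_base: str, alt_base: str,
                    orf: OrfSequence) -> tuple[int, str, str, str]:
    """Resolve an SNV to (residue position, mutated codon, alt_aa, consequence)."""
    if not 1 <= cds_position <= len(orf.nt_sequence):
        raise ValueError(f"cds_position {cds_position} outside ORF")
    pos = (cds_position - 1) // 3 + 1
    offset = (cds_position - 1) % 3
    ref_codon = orf.codon(pos)
    if ref_codon[offset] != ref_base:
        raise ValueError(
            f"SNV ref base {ref_base} does not match ORF base "
            f"{ref_codon[offset]} at CDS position {cds_position}"
        )
    mutated = ref_codon[:offset] + alt_base + ref_codon[offset + 1:]
    alt_aa = translate_codon(mutated)
    ref_aa = translate_codon(ref_codon)
    if alt_aa == "*":
        cons = "nonsense"
    elif alt_aa == ref_aa:
        cons = "silent"
    else:
        cons = "missense"
    return pos, mutated, alt_aa, cons


def merge_dms_predictor(
    scores: pd.DataFrame,
    library: list[Variant],
    orf: OrfSequence,
    predictor: pd.DataFrame,
    tool: str,
    thresholds: PathogenicityThresholds | None = None,
    dms_threshold: float = 2.0,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Join SNV-level predictor scores onto codon-level DMS scores.

    ``predictor`` needs columns cds_position, ref, alt, score.  Each SNV is
    matched at the protein level to the library variant it encodes (ties
    between several synonymous library entries are resolved by exact
    alternate-codon match; residual ambiguity is an error).  Returns the
    concordance records plus tallies of dropped SNVs.
    """
    thresholds = thresholds or PathogenicityThresholds()
    thr = thresholds.for_tool(tool)
    idx = _codon_index(library)
    records = []
    tallies = {"matched": 0, "no_library_match": 0, "unscored_parent": 0,
               "bad_reference": 0}
    mean_z = scores["mean_z"]
    for row in predictor.itertuples(index=False):
        try:
            pos, mutated, alt_aa, cons = snv_consequence(
                int(row.cds_position), str(row.ref), str(row.alt), orf)
        except ValueError:
            tallies["bad_reference"] += 1
            continue
        candidates = idx.get((pos, alt_aa), [])
        if len(candidates) > 1:
            exact = [v for v in candidates if v.alt == mutated]
            if len(exact) == 1:
                candidates = exact
            else:
                raise ValueError(
                    f"SNV {row.cds_position}{row.ref}>{row.alt} matches "
                    f"{len(candidates)} library variants ambiguously"
                )
        if not candidates:
            tallies["no_library_match"] += 1
            continue
        parent = candidates[0]
        z = mean_z.get(parent.variant_id, np.nan)
        if not np.isfinite(z):
            tallies["unscored_parent"] += 1
            continue
        tallies["matched"] += 1
        dms_class = "LOF" if z > dms_threshold else "tolerated"
        pred_class = "pathogenic" if row.score >= thr else "benign"
        records.append({
            "cds_position": int(row.cds_position),
            "ref": row.ref, "alt": row.alt,
            "parent_variant_id": parent.variant_id,
            "consequence": cons,
            "mean_z": float(z),
            "score": float(row.score),
            "dms_class": dms_class,
            "predictor_class": pred_class,
            "concordant": (dms_class == "LOF") == (pred_class == "pathogenic"),
        })
    cols = ["cds_position", "ref", "alt", "parent_variant_id", "consequence",
            "mean_z", "score", "dms_class", "predictor_class", "concordant"]
    return pd.DataFrame(records, columns=cols), tallies


def concordance_summary(records: pd.DataFrame) -> pd.DataFrame:
    """Per-consequence concordance counts and fractions."""
    if records.empty:
        raise ValueError("no concordance records")
    grp = records.groupby("consequence")["concordant"]
    out = pd.DataFrame({
        "n_total": grp.size(),
        "n_concordant": grp.sum().astype(int),
    })
    out["fraction_concordant"] = out["n_concordant"] / out["n_total"]
    return out.reset_index()


def fraction_pathogenic(
    predictor: pd.DataFrame,
    tool: str,
    thresholds: PathogenicityThresholds | None = None,
    consequence_filter: str | None = "missense",
    orf: OrfSequence | None = None,
) -> float:
    """Fraction of predictor rows called pathogenic at the tool threshold.

    When ``consequence_filter`` is set, rows are restricted to that class;
    a ``consequence`` column is used if present, otherwise consequences are
    derived from the SNV columns against ``orf``.
    """
    thresholds = thresholds or PathogenicityThresholds()
    thr = thresholds.for_tool(tool)
    tab = predictor
    if consequence_filter is not None:
        if "consequence" in tab.columns:
            cons = tab["consequence"]
        elif orf is not None:
            cons = pd.Series([
                snv_consequence(int(r.cds_position), str(r.ref), str(r.alt), orf)[3]
                for r in tab.itertuples(index=False)
            ], index=tab.index)
        else:
            raise ValueError("need a consequence column or an ORF to filter")
        tab = tab[cons == consequence_filter]
    if tab.empty:
        raise ValueError("no predictor rows after consequence filter")
    return float((tab["score"] >= thr).mean())


@dataclass
class RocResult:
    auc: float
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    n_positive: int
    n_negative: int


def roc_auc(labels: pd.Series, scores: pd.Series) -> RocResult:
    """ROC curve and tie-corrected AUC of ``scores`` against binary ``labels``.

    Labels: 1/True/"positive" for positives.  AUC is the midrank
    Mann-Whitney statistic (ties count 1/2); curve points come from a
    threshold sweep over the unique scores (via sklearn).
    """
    from sklearn.metrics import roc_curve

    joined = pd.DataFrame({"label": labels, "score": scores}).dropna()
    y = joined["label"].map(
        lambda v: 1 if v in (1, True, "positive", "pathogenic") else 0
    ).to_numpy()
    s = joined["score"].to_numpy(dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("need at least one positive and one negative label")
    ranks = rankdata(s)  # midranks
    auc = (ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, thr = roc_curve(y, s)
    return RocResult(auc=float(auc), fpr=fpr, tpr=tpr, thresholds=thr,
                     n_positive=n_pos, n_negative=n_neg)
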