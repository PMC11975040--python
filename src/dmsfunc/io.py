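"""Readers and writers for the pipeline's tab-separated dialects.

All tables are plain TSV with a documented header; lines starting with ``#``
are metadata (config echo, software version) and are skipped on read.
Positions are 1-based residues, CDS nucleotide positions 1-based, intervals
closed.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .scoring import CountsMatrix, SampleSpec
from .variants import Variant

__all__ = [
    "read_table",
    "write_table",
    "read_counts",
    "write_counts",
    "read_sample_sheet",
    "write_sample_sheet",
    "read_library",
    "write_library",
    "read_predictor_table",
    "read_labels",
    "read_pairs",
    "load_run_config",
]


def write_table(df: pd.DataFrame, path, *, index: bool = False,
                echo: dict | None = None) -> None:
    """Write a TSV with ``#`` metadata header lines (version + config echo)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    buf = _io.StringIO()
    buf.write(f"# dmsfunc v{__version__}\n")
    for key, val in (echo or {}).items():
        buf.write(f"# {key}: {val}\n")
    df.to_csv(buf, sep="\t", index=index)
    path.write_text(buf.getvalue())


def read_table(path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_counts(counts: CountsMatrix, counts_path, sheet_path,
                 echo: dict | None = None) -> None:
    """Write a counts matrix in the long dialect plus its sample sheet."""
    long = counts.counts.reset_index().melt(
        id_vars="variant_id", var_name="sample_id", value_name="count")
    write_table(long, counts_path, echo=echo)
    write_sample_sheet(counts.samples, sheet_path, echo=echo)


def write_sample_sheet(samples: list[SampleSpec], path,
                       echo: dict | None = None) -> None:
    df = pd.DataFrame({
        "sample_id": [s.sample_id for s in samples],
        "replicate_id": [s.replicate_id for s in samples],
        "timepoint": [s.timepoint for s in samples],
    })
    write_table(df, path, echo=echo)


def read_sample_sheet(path) -> list[SampleSpec]:
    df = read_table(path, dtype=str)
    required = {"sample_id", "replicate_id", "timepoint"}
    if not required.issubset(df.columns):
        raise ValueError(f"sample sheet {path} needs columns {sorted(required)}")
    return [SampleSpec(r.sample_id, r.replicate_id, r.timepoint)
            for r in df.itertuples(index=False)]


def read_counts(counts_path, sample_sheet_path) -> CountsMatrix:
    """Read counts in either the long (variant_id, sample_id, count) or the
    wide (variant_id + one column per sample) dialect, validated against the
    sample sheet."""
    samples = read_sample_sheet(sample_sheet_path)
    df = read_table(counts_path)
    if {"variant_id", "sample_id", "count"}.issubset(df.columns) and len(df.columns) == 3:
        bad = df[df["count"] < 0]
        if not bad.empty:
            row = bad.iloc[0]
            raise ValueError(
                f"negative count for variant {row['variant_id']!r} "
                f"sample {row['sample_id']!r} in {counts_path}"
            )
        wide = df.pivot(index="variant_id", columns="sample_id", values="count")
        wide = wide.fillna(0).astype(int)
    elif "variant_id" in df.columns:
        wide = df.set_index("variant_id")
        neg = (wide < 0).any()
        if neg.any():
            raise ValueError(
                f"negative counts in column {neg.index[neg.argmax()]!r} "
                f"of {counts_path}"
            )
    else:
        raise ValueError(
            f"{counts_path}: expected long (variant_id, sample_id, count) "
            "or wide (variant_id + samples) dialect"
        )
    missing = {s.sample_id for s in samples} - set(wide.columns)
    if missing:
        raise ValueError(
            f"samples in sheet missing from counts table: {sorted(missing)}"
        )
    return CountsMatrix(counts=wide, samples=samples)


def write_library(library: list[Variant], path, echo: dict | None = None) -> None:
    from .variants import library_frame

    write_table(library_frame(library), path, echo=echo)


def read_library(path) -> pd.DataFrame:
    df = read_table(path)
    required = {"variant_id", "position", "consequence"}
    if not required.issubset(df.columns):
        raise ValueError(f"library table {path} needs columns {sorted(required)}")
    return df


def read_predictor_table(path) -> pd.DataFrame:
    """Read an SNV-level predictor table.

    Two dialects: CADD-style (Chrom, Pos, Ref, Alt, RawScore, PHRED; Pos is
    interpreted as the 1-based CDS position and PHRED as the score) and the
    generic (cds_position, ref, alt, score).
    """
    df = read_table(path)
    if {"Pos", "Ref", "Alt", "PHRED"}.issubset(df.columns):
        out = pd.DataFrame({
            "cds_position": df["Pos"].astype(int),
            "ref": df["Ref"], "alt": df["Alt"],
            "score": df["PHRED"].astype(float),
        })
    elif {"cds_position", "ref", "alt", "score"}.issubset(df.columns):
        out = df[["cds_position", "ref", "alt", "score"]].copy()
        out["cds_position"] = out["cds_position"].astype(int)
        out["score"] = out["score"].astype(float)
    else:
        raise ValueError(
            f"{path}: expected CADD dialect (Pos/Ref/Alt/PHRED) or generic "
            "(cds_position/ref/alt/score)"
        )
    if not out["score"].map(lambda v: v == v and abs(v) != float("inf")).all():
        raise ValueError(f"{path}: non-finite predictor scores")
    return out


def read_labels(path) -> pd.DataFrame:
    """Pathogenicity label table: variant_id (or protein_change), label
    {positive, negative}, optional provenance."""
    df = read_table(path, dtype=str)
    key = "variant_id" if "variant_id" in df.columns else "protein_change"
    if key not in df.columns or "label" not in df.columns:
        raise ValueError(f"{path}: needs variant_id/protein_change and label columns")
    bad = set(df["label"]) - {"positive", "negative"}
    if bad:
        raise ValueError(f"{path}: labels must be positive/negative, got {sorted(bad)}")
    if "provenance" not in df.columns:
        df["provenance"] = ""
    return df.rename(columns={key: "variant_id"})


def read_pairs(path) -> pd.DataFrame:
    """Paired region/gene L2FC table for the quadrant statistic."""
    df = read_table(path)
    required = {"region_l2fc", "gene_l2fc"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: needs columns {sorted(required)}")
    return df


def load_run_config(path) -> dict:
    """Load a YAML run configuration (plain key/value mapping)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    return cfg
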