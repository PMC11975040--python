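"""End-to-end orchestration: simulate/load counts, score, classify, report.

``run_pipeline`` consumes a plain dictionary (usually from a YAML file, see
:func:`dmsfunc.io.load_run_config`) and writes every artifact as TSV/JSON
with a config echo in the header.  Deterministic given inputs and seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import pandas as pd

from . import __version__
from . import io as dio
from .classify import call_lof, heatmap_matrix, positional_consequence_profile, residue_intolerance
from .multiomic import quadrant_concordance
from .predictors import PathogenicityThresholds, RocResult, concordance_summary, merge_dms_predictor, roc_auc
from .scoring import FunctionalScorer
from .simulate import SimConfig, simulate_screen
from .variants import LibraryScheme, library_frame, read_orf_fasta

log = logging.getLogger("dmsfunc")

__all__ = ["run_pipeline"]


def _sim_config_from(cfg: dict, seed: int) -> SimConfig:
    kwargs = dict(cfg)
    scheme = kwargs.pop("scheme", None)
    if scheme is not None:
        kwargs["scheme"] = LibraryScheme(**scheme)
    kwargs.setdefault("seed", seed)
    if "lof_cluster" in kwargs and kwargs["lof_cluster"] is not None:
        kwargs["lof_cluster"] = tuple(tuple(iv) for iv in kwargs["lof_cluster"])
    return SimConfig(**kwargs)


def run_pipeline(config: dict, out_dir) -> dict:
    """Run the configured stages; returns a run report (also written as JSON).

    Config keys: seed; either ``simulate`` (SimConfig fields) or ``counts`` +
    ``sample_sheet`` + ``library`` (+ optional ``orf``); ``scoring``
    (pseudocount/half_width/min_silent/...); ``lof_threshold``;
    ``min_substitutions``; optional ``predictor`` ({path, tool}), ``labels``,
    ``pairs`` (+ ``l2fc_min``) stages.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    echo = {"version": __version__, "seed": seed,
            "config": json.dumps(config, sort_keys=True, default=str)}
    report: dict = {"version": __version__, "seed": seed, "stages": []}

    orf = None
    library_objs = None
    if config.get("simulate") is not None:
        sim_cfg = _sim_config_from(config["simulate"], seed)
        sim = simulate_screen(sim_cfg)
        counts, orf, library_objs = sim.counts, sim.orf, sim.library
        library = library_frame(sim.library)
        dio.write_counts(counts, out / "counts.tsv", out / "samples.tsv", echo=echo)
        dio.write_library(sim.library, out / "library.tsv", echo=echo)
        dio.write_table(sim.truth, out / "truth.tsv", echo=echo)
        (out / "orf.fa").write_text(f">{orf.id}\n{orf.nt_sequence}\n")
        report["stages"].append("simulate")
        report["simulate"] = {"n_variants": len(sim.library),
                              "config": dataclasses.asdict(sim_cfg)}
    elif config.get("counts") and config.get("sample_sheet") and config.get("library"):
        counts = dio.read_counts(config["counts"], config["sample_sheet"])
        library = dio.read_library(config["library"])
        if config.get("orf"):
            orf = read_orf_fasta(config["orf"], config.get("orf_id"))
        report["stages"].append("load")
    else:
        raise ValueError(
            "configuration must provide either a 'simulate' block or "
            "'counts' + 'sample_sheet' + 'library' paths"
        )

    scorer = FunctionalScorer(**config.get("scoring", {}))
    scores = scorer.fit_transform(counts, library=library)
    dio.write_table(scores.reset_index(), out / "scores.tsv", echo=echo)
    for rep, base in scorer.baseline_.per_replicate.items():
        dio.write_table(base, out / f"baseline_{rep}.tsv", echo=echo)
    report["stages"].append("score")
    report["score"] = {"n_scored": int(scores["mean_z"].notna().sum())}

    threshold = float(config.get("lof_threshold", 2.0))
    lof = call_lof(scores, threshold)
    dio.write_table(lof.reset_index(), out / "lof.tsv", echo=echo)
    residues = residue_intolerance(
        scores, min_substitutions=int(config.get("min_substitutions", 10)))
    dio.write_table(residues, out / "residues.tsv", echo=echo)
    heat = heatmap_matrix(scores)
    dio.write_table(heat.reset_index(), out / "heatmap.tsv", echo=echo)
    profiles = []
    for cons in ("silent", "nonsense", "frameshift", "missense"):
        try:
            profiles.append(positional_consequence_profile(scores, cons))
        except ValueError:
            continue
    if profiles:
        dio.write_table(pd.concat(profiles), out / "positional_profiles.tsv", echo=echo)
    report["stages"].append("classify")
    report["classify"] = {
        "n_lof": int(lof["is_lof"].sum()),
        "intolerance_cutoff": float(residues["cutoff"].iloc[0]),
        "n_intolerant": int(residues["is_intolerant"].sum()),
    }

    thresholds = PathogenicityThresholds(**config.get("thresholds", {}))
    if config.get("predictor"):
        if orf is None or library_objs is None:
            raise ValueError("predictor concordance needs an ORF and codon-level library")
        ptab = dio.read_predictor_table(config["predictor"]["path"])
        tool = config["predictor"]["tool"]
        records, tallies = merge_dms_predictor(
            scores, library_objs, orf, ptab, tool, thresholds,
            dms_threshold=threshold)
        dio.write_table(records, out / "concordance_records.tsv", echo=echo)
        summary = concordance_summary(records)
        dio.write_table(summary, out / "concordance_summary.tsv", echo=echo)
        report["stages"].append("concord")
        report["concord"] = {"tallies": tallies,
                             "summary": summary.to_dict(orient="records")}

    if config.get("labels"):
        labels = dio.read_labels(config["labels"])
        joined = labels.set_index("variant_id")["label"]
        roc: RocResult = roc_auc(joined, scores["mean_z"])
        curve = pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr})
        dio.write_table(curve, out / "roc_curve.tsv", echo=echo)
        report["stages"].append("roc")
        report["roc"] = {"auc": roc.auc, "n_positive": roc.n_positive,
                         "n_negative": roc.n_negative}

    if config.get("pairs"):
        pairs = dio.read_pairs(config["pairs"])
        quad = quadrant_concordance(pairs, l2fc_min=float(config.get("l2fc_min", 1.0)))
        report["stages"].append("quadrant")
        report["quadrant"] = {
            "q_pp": quad.q_pp, "q_pm": quad.q_pm,
            "q_mp": quad.q_mp, "q_mm": quad.q_mm,
            "concordance_fraction": quad.concordance_fraction,
            "odds_ratio": quad.odds_ratio if quad.odds_ratio == quad.odds_ratio else None,
            "fisher_p": quad.fisher_p,
            "degenerate": quad.degenerate,
        }

    (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
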