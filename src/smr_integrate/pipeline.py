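"""End-to-end orchestration: meta-analysis -> EB shrinkage -> SMR -> report.

Each run writes its intermediates under one output directory together with
a JSON manifest recording stage parameters, input hashes, row counts at
every filter, the fitted shrinkage parameters, the thresholds used, and
the final SNP/gene/overlap counts. Reruns with ``resume=True`` skip any
stage whose output file already exists.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import aggregate_report, eb_shrink, meta, smr_test, sumstats_io

logger = logging.getLogger(__name__)


class DataError(RuntimeError):
    """A stage failed on its inputs; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    gwas_paths: Sequence[str]
    eqtl_path: str
    mqtl_path: str
    out_dir: str = "smr_run"
    alpha: float = 0.05
    n_probes_eqtl: Optional[int] = None   # override the probe count in the file
    n_probes_mqtl: Optional[int] = None
    min_studies: int = 1
    eq3_literal: bool = False
    eb_truncate: bool = True
    eb_mode: str = "beta"
    min_instrument_p: Optional[float] = None
    top_snp_only: bool = False
    figures: bool = True
    resume: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def validate(self) -> None:
        missing = [p for p in [*self.gwas_paths, self.eqtl_path, self.mqtl_path]
                   if not Path(p).exists()]
        if missing:
            raise FileNotFoundError(f"missing input files: {missing}")


def setup_logging(log_file=None, level=logging.INFO) -> None:
    handlers = [logging.StreamHandler(sys.stderr)]
    if log_file is not None:
        handlers.append(logging.FileHandler(log_file))
    logging.basicConfig(level=level, handlers=handlers, force=True,
                        format="%(asctime)s %(name)s %(levelname)s %(message)s")


def _sha1(path) -> str:
    h = hashlib.sha1()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute meta -> eb -> smr(eQTL) -> smr(mQTL) -> report; return the manifest."""
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    setup_logging(out_dir / "run.log")

    manifest: dict = {
        "started": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "inputs": {str(p): _sha1(p) for p in
                   [*config.gwas_paths, config.eqtl_path, config.mqtl_path]},
        "parameters": {
            "alpha": config.alpha, "min_studies": config.min_studies,
            "eq3_literal": config.eq3_literal, "eb_truncate": config.eb_truncate,
            "eb_mode": config.eb_mode, "min_instrument_p": config.min_instrument_p,
            "top_snp_only": config.top_snp_only, "seed": config.seed,
        },
        "stages": {},
    }

    meta_path = out_dir / "meta.ma"
    eb_path = out_dir / "meta_eb.ma"
    eb_json = out_dir / "eb_stats.json"

    # --- stage: meta-analysis -------------------------------------------
    stage = "meta"
    try:
        if config.resume and meta_path.exists():
            meta_df = sumstats_io.read_gwas(meta_path)
            manifest["stages"][stage] = {"resumed": True, "n_snps": len(meta_df)}
        else:
            studies = [sumstats_io.read_gwas(p) for p in config.gwas_paths]
            panel = sumstats_io.harmonize(studies)
            meta_df = meta.meta_panel(panel, min_studies=config.min_studies,
                                      eq3_literal=config.eq3_literal)
            sumstats_io.write_gwas(meta_df, meta_path)
            manifest["stages"][stage] = {
                "n_studies": len(studies),
                "rows_per_study": [len(s) for s in studies],
                "dropped_per_study": [s.attrs.get("n_dropped", 0) for s in studies],
                "n_allele_mismatch": panel.n_mismatched,
                "n_palindromic": panel.n_palindromic,
                "n_below_min_studies": meta_df.attrs.get("n_below_min_studies", 0),
                "n_snps": len(meta_df),
            }
    except Exception as exc:
        raise DataError(stage, str(exc)) from exc

    # --- stage: empirical-Bayes shrinkage -------------------------------
    stage = "eb"
    try:
        if config.resume and eb_path.exists() and eb_json.exists():
            eb_df = sumstats_io.read_gwas(eb_path)
            eb_stats = json.loads(eb_json.read_text())
            manifest["stages"][stage] = {"resumed": True, **eb_stats}
        else:
            eb_df, state = eb_shrink.shrink_gwas(
                meta_df, truncate=config.eb_truncate, mode=config.eb_mode)
            sumstats_io.write_gwas(eb_df, eb_path)
            eb_stats = {"N": state.n_snps, "theta_hat": state.theta_hat,
                        "S": state.S, "B": state.B, "B_raw": state.B_raw}
            eb_json.write_text(json.dumps(eb_stats) + "\n")
            manifest["stages"][stage] = dict(eb_stats)
    except Exception as exc:
        raise DataError(stage, str(exc)) from exc

    # --- stages: SMR against each QTL panel -----------------------------
    smr_outputs = {}
    for label, qtl_path, n_override in [
            ("smr_eqtl", config.eqtl_path, config.n_probes_eqtl),
            ("smr_mqtl", config.mqtl_path, config.n_probes_mqtl)]:
        try:
            out_path = out_dir / f"{label}.tsv"
            if config.resume and out_path.exists():
                smr_df = smr_test.read_smr(out_path)
                smr_outputs[label] = smr_df
                manifest["stages"][label] = {"resumed": True, "n_pairs": len(smr_df)}
                continue
            qtl = sumstats_io.read_qtl(qtl_path)
            n_probes = n_override or qtl["probe"].nunique()
            spec = smr_test.bonferroni(config.alpha, n_probes)
            pairs = sumstats_io.intersect_gwas_qtl(eb_df, qtl)
            smr_df = smr_test.smr_scan(pairs, spec,
                                       min_instrument_p=config.min_instrument_p,
                                       top_snp_only=config.top_snp_only)
            smr_test.write_smr(smr_df, out_path)
            smr_outputs[label] = smr_df
            manifest["stages"][label] = {
                "qtl_rows": len(qtl),
                "n_probes": n_probes,
                "threshold": spec.threshold,
                "n_pairs": len(pairs),
                "n_allele_mismatch": pairs.attrs.get("n_mismatched", 0),
                "n_zero_instrument": smr_df.attrs.get("n_zero_instrument", 0),
                "n_significant_pairs": int(smr_df["significant"].sum()),
            }
            assert abs(spec.threshold * spec.n_probes - config.alpha) < 1e-12
        except Exception as exc:
            raise DataError(label, str(exc)) from exc

    # --- stage: report ---------------------------------------------------
    stage = "report"
    try:
        eqtl_res, mqtl_res = smr_outputs["smr_eqtl"], smr_outputs["smr_mqtl"]
        gs_e = aggregate_report.summarize_genes(eqtl_res, source="eqtl")
        gs_m = aggregate_report.summarize_genes(mqtl_res, source="mqtl")
        gs_e.to_csv(out_dir / "gene_summary_eqtl.tsv", sep="\t", index=False)
        gs_m.to_csv(out_dir / "gene_summary_mqtl.tsv", sep="\t", index=False)
        rep = aggregate_report.overlap(gs_e, gs_m, eqtl_res, mqtl_res)
        aggregate_report.write_overlap(rep, out_dir / "overlap.json")
        figures = []
        if config.figures:
            figures = aggregate_report.render_figures(
                meta_df["p"].to_numpy(), eb_df["p"].to_numpy(),
                eqtl_res, out_dir / "figures")
        manifest["stages"][stage] = {
            "overlap": rep.to_dict(),
            "genes_eqtl": gs_e["gene"].tolist(),
            "genes_mqtl": gs_m["gene"].tolist(),
            "figures": [str(f) for f in figures],
        }
    except Exception as exc:
        raise DataError(stage, str(exc)) from exc

    manifest["finished"] = time.strftime("%Y-%m-%dT%H:%M:%S")
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    logger.info("pipeline complete: %s", out_dir / "manifest.json")
    return manifest
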