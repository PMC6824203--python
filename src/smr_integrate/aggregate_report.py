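"""Gene-level aggregation of SMR hits, eQTL/mQTL overlap, and summary plots."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

GENOME_WIDE_P = 5e-8  # conventional genome-wide significance line for the plots


@dataclass
class OverlapReport:
    """Distinct significant SNP / gene counts per analysis and their overlap."""

    snps_eqtl: int
    snps_mqtl: int
    snps_both: int
    genes_eqtl: int
    genes_mqtl: int
    genes_both: int

    def to_dict(self) -> dict:
        return asdict(self)


def summarize_genes(results: pd.DataFrame, source: str = "") -> pd.DataFrame:
    """Count distinct significant SNPs per gene, sorted by descending count.

    A SNP significant under two probes of the same gene counts once for
    that gene; a SNP mapped to several genes counts once per gene. Genes
    with no significant SNP are omitted.
    """
    sig = results.loc[results["significant"].astype(bool)]
    if len(sig) == 0:
        out = pd.DataFrame(columns=["gene", "n_significant_snps", "source"])
        return out
    counts = (sig.groupby("gene")["SNP"].nunique()
                 .sort_values(ascending=False)
                 .rename("n_significant_snps")
                 .reset_index())
    counts = counts.sort_values(["n_significant_snps", "gene"],
                                ascending=[False, True]).reset_index(drop=True)
    counts["source"] = source
    return counts


def overlap(eqtl_summary: pd.DataFrame, mqtl_summary: pd.DataFrame,
            eqtl_results: pd.DataFrame, mqtl_results: pd.DataFrame) -> OverlapReport:
    """Set intersections of significant SNP ids and gene symbols."""
    snps_e = set(eqtl_results.loc[eqtl_results["significant"].astype(bool), "SNP"])
    snps_m = set(mqtl_results.loc[mqtl_results["significant"].astype(bool), "SNP"])
    genes_e = set(eqtl_summary["gene"])
    genes_m = set(mqtl_summary["gene"])
    return OverlapReport(
        snps_eqtl=len(snps_e), snps_mqtl=len(snps_m),
        snps_both=len(snps_e & snps_m),
        genes_eqtl=len(genes_e), genes_mqtl=len(genes_m),
        genes_both=len(genes_e & genes_m),
    )


def write_overlap(report: OverlapReport, path) -> None:
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
        fh.write("\n")


def _neglog10(p: np.ndarray) -> np.ndarray:
    p = np.clip(np.asarray(p, dtype=float), 1e-300, 1.0)
    return -np.log10(p)


def render_figures(meta_p, eb_p, smr_results: pd.DataFrame, out_dir) -> list[Path]:
    """Render the three standard diagnostic figures; best effort, never fatal.

    1. p-value density before vs after EB shrinkage;
    2. scatter of GWAS vs QTL -log10 p per tested pair, with the
       genome-wide line at -log10(5e-8);
    3. -log10 p_SMR per pair with the Bonferroni threshold line.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths: list[Path] = []
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from scipy import stats as _st

        fig, ax = plt.subplots(figsize=(6, 4))
        bins = np.linspace(0, 1, 41)
        ax.hist(np.asarray(meta_p, float), bins=bins, density=True, alpha=0.5,
                color="tab:blue", label="after meta-analysis")
        ax.hist(np.asarray(eb_p, float), bins=bins, density=True, alpha=0.5,
                color="tab:red", label="after EB shrinkage")
        ax.set_xlabel("p-value")
        ax.set_ylabel("density")
        ax.legend()
        f1 = out_dir / "pvalue_density.png"
        fig.savefig(f1, dpi=120)
        plt.close(fig)
        paths.append(f1)

        z_zy = smr_results["b_zy"] / smr_results["se_zy"]
        z_zx = smr_results["b_zx"] / smr_results["se_zx"]
        p_zy = 2 * _st.norm.sf(np.abs(z_zy))
        p_zx = 2 * _st.norm.sf(np.abs(z_zx))
        fig, ax = plt.subplots(figsize=(5, 5))
        ax.scatter(_neglog10(p_zy), _neglog10(p_zx), s=6, alpha=0.4)
        ax.axvline(-np.log10(GENOME_WIDE_P), color="black", lw=1,
                   label=r"$-\log_{10}(5\times10^{-8})$")
        ax.set_xlabel(r"GWAS $-\log_{10} p$")
        ax.set_ylabel(r"QTL $-\log_{10} p$")
        ax.legend()
        f2 = out_dir / "gwas_vs_qtl.png"
        fig.savefig(f2, dpi=120)
        plt.close(fig)
        paths.append(f2)

        fig, ax = plt.subplots(figsize=(7, 4))
        ax.scatter(np.arange(len(smr_results)), _neglog10(smr_results["p_SMR"]),
                   s=6, alpha=0.5)
        thr = smr_results.attrs.get("threshold")
        if thr is None and "significant" in smr_results and smr_results["significant"].any():
            thr = float(smr_results.loc[smr_results["significant"], "p_SMR"].max())
        if thr:
            ax.axhline(-np.log10(thr), color="black", lw=1, label="Bonferroni threshold")
            ax.legend()
        ax.set_xlabel("SNP-probe pair")
        ax.set_ylabel(r"SMR $-\log_{10} p$")
        f3 = out_dir / "smr_track.png"
        fig.savefig(f3, dpi=120)
        plt.close(fig)
        paths.append(f3)
    except Exception:  # pragma: no cover - plotting must never kill a run
        logger.exception("figure rendering failed; continuing")
    return paths
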