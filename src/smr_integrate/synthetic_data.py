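"""Synthetic multi-study GWAS and cis-QTL summary statistics.

The generator emulates the statistical structure the downstream analysis
assumes, so every stage can be exercised end-to-end without any external
download:

* **GWAS.** Each SNP carries a true association score on the scale of a
  reference study, Z_i ~ N(theta, sigma^2) — the genome-wide normal prior
  that empirical-Bayes shrinkage targets. Study k (sample size n_k)
  observes Zhat_ik ~ N(Z_i * sqrt(n_k / n_ref), 1): larger studies see a
  proportionally stronger signal with unit sampling noise, the standard
  square-root-of-n scaling of association Z-scores. Betas are expressed
  on the per-allele scale via se_ik = 1 / sqrt(2 n_k p_i (1 - p_i)) with
  effect-allele frequencies p_i ~ Uniform(0.05, 0.95), the usual
  standardized-trait approximation.

* **cis-QTL.** Each probe (expression transcript or CpG site) owns a cis
  window of consecutive SNPs on one chromosome; windows never cross a
  chromosome boundary. Instrument scores z_zx are drawn with a random
  sign and |z_zx| ~ N(mu, sd) (strong instruments by default, as for
  genome-wide-significant cis-QTLs).

* **Mediation.** A chosen number of causal probes mediate SNP -> trait
  effects: at every SNP in a causal probe's window the true per-allele
  trait effect is overwritten with b_zy = b_xy_true * b_zx, and the study
  files are re-drawn there with their usual sampling noise, so the Wald
  ratio b_zy / b_zx centers on b_xy_true. All other probes are null. A
  configurable number of causal genes are shared between the eQTL and
  mQTL panels (the methylation probe targets the same gene and sits in
  the same cis window), giving the gene/SNP overlap the reporting stage
  measures.

SNPs are statistically independent (no linkage disequilibrium); see the
methods note for what this does and does not make the end-to-end tests
show about real data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import write_gwas, write_qtl

#: per-study sample sizes mirroring a typical five-cohort design:
#: three small clinical cohorts, one case-control consortium, one biobank
DEFAULT_STUDY_N = (1517, 1517, 1517, 54162, 314278)


@dataclass(frozen=True)
class SimConfig:
    """Generator settings; the defaults are the package's reference scenario."""

    n_snps: int = 20_000
    n_probes_eqtl: int = 500
    n_probes_mqtl: int = 1_000
    n_studies: int = 5
    study_n: Sequence[int] = DEFAULT_STUDY_N
    theta_true: float = 0.0       # mean of the true Z prior
    sigma2_true: float = 1.0      # variance of the true Z prior (polygenic spread)
    n_causal_probes: int = 10     # per QTL panel
    n_shared_causal: int = 2      # causal genes common to both panels
    b_xy_true: float = 0.03       # trait SD per expression/methylation SD
    instrument_mean_z: float = 20.0
    instrument_sd_z: float = 3.0
    snps_per_probe: int = 8
    n_eqtl_samples: int = 1194    # effective QTL study sizes (brain meta-analyses)
    n_mqtl_samples: int = 1160
    n_chromosomes: int = 22
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_snps, self.n_probes_eqtl, self.n_probes_mqtl,
               self.n_studies, self.snps_per_probe) <= 0:
            raise ValueError("all counts must be positive")
        if len(self.study_n) != self.n_studies:
            raise ValueError("study_n length must equal n_studies")
        if self.n_causal_probes > min(self.n_probes_eqtl, self.n_probes_mqtl):
            raise ValueError("n_causal_probes exceeds a probe count")
        if not (0 <= self.n_shared_causal <= self.n_causal_probes):
            raise ValueError("n_shared_causal must lie in [0, n_causal_probes]")
        if self.sigma2_true < 0:
            raise ValueError("sigma2_true must be >= 0")
        per_chrom = self.n_snps // self.n_chromosomes
        capacity = self.n_chromosomes * (per_chrom // self.snps_per_probe)
        needed = self.n_probes_eqtl + self.n_probes_mqtl - self.n_shared_causal
        if needed > capacity:
            raise ValueError(
                f"{needed} probe windows requested but only {capacity} disjoint "
                f"cis windows of {self.snps_per_probe} SNPs fit on "
                f"{self.n_chromosomes} chromosomes of {per_chrom} SNPs")


@dataclass
class SimTruth:
    """Ground truth aligned by id with the emitted summary files."""

    snps: pd.DataFrame      # SNP chr pos eaf z_true causal
    probes: pd.DataFrame    # probe source gene chr causal b_xy_true window
    pairs: pd.DataFrame     # probe SNP b_zx_true
    study_tables: list[pd.DataFrame] = field(default_factory=list, repr=False)


def _study_se(n: float, eaf: np.ndarray) -> np.ndarray:
    return 1.0 / np.sqrt(2.0 * n * eaf * (1.0 - eaf))


def _draw_study_tables(cfg: SimConfig, snps: pd.DataFrame,
                       rng: np.random.Generator) -> list[pd.DataFrame]:
    n_ref = max(cfg.study_n)
    eaf = snps["eaf"].to_numpy()
    z_true = snps["z_true"].to_numpy()
    tables = []
    for n_k in cfg.study_n:
        se = _study_se(n_k, eaf)
        zhat = z_true * np.sqrt(n_k / n_ref) + rng.standard_normal(cfg.n_snps)
        tables.append(pd.DataFrame({
            "SNP": snps["SNP"], "A1": snps["A1"], "A2": snps["A2"],
            "freq": eaf, "b": zhat * se, "se": se,
            "p": 2.0 * stats.norm.sf(np.abs(zhat)),
            "N": float(n_k),
        }))
    return tables


def simulate_gwas(cfg: SimConfig, out_dir) -> tuple[list[Path], SimTruth]:
    """Draw K study files under the genome-wide normal model; no mediation yet."""
    cfg.validate()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)

    per_chrom = cfg.n_snps // cfg.n_chromosomes
    chrom = np.minimum(np.arange(cfg.n_snps) // per_chrom, cfg.n_chromosomes - 1) + 1
    pos_within = np.concatenate([
        np.sort(rng.integers(1, 50_000_001, size=int((chrom == c).sum())))
        for c in range(1, cfg.n_chromosomes + 1)])
    eaf = rng.uniform(0.05, 0.95, size=cfg.n_snps)
    bases = np.array(list("ACGT"))
    a_idx = rng.integers(0, 4, size=cfg.n_snps)
    b_idx = (a_idx + rng.integers(1, 4, size=cfg.n_snps)) % 4
    z_true = cfg.theta_true + np.sqrt(cfg.sigma2_true) * rng.standard_normal(cfg.n_snps)

    snps = pd.DataFrame({
        "SNP": [f"rs{i + 1:07d}" for i in range(cfg.n_snps)],
        "chr": chrom.astype(str), "pos": pos_within,
        "A1": bases[a_idx], "A2": bases[b_idx],
        "eaf": eaf, "z_true": z_true, "causal": False,
    })

    tables = _draw_study_tables(cfg, snps, rng)
    paths = []
    for k, tbl in enumerate(tables, start=1):
        path = out_dir / f"study{k}.ma"
        write_gwas(tbl, path)
        paths.append(path)

    truth = SimTruth(snps=snps, probes=pd.DataFrame(), pairs=pd.DataFrame(),
                     study_tables=tables)
    return paths, truth


def _assign_windows(cfg: SimConfig) -> list[np.ndarray]:
    """Disjoint cis windows of consecutive SNP indices, none crossing a chromosome."""
    per_chrom = cfg.n_snps // cfg.n_chromosomes
    windows = []
    for c in range(cfg.n_chromosomes):
        start = c * per_chrom
        stop = start + per_chrom if c < cfg.n_chromosomes - 1 else cfg.n_snps
        for w0 in range(start, stop - cfg.snps_per_probe + 1, cfg.snps_per_probe):
            windows.append(np.arange(w0, w0 + cfg.snps_per_probe))
    return windows


def simulate_qtl(cfg: SimConfig, truth: SimTruth,
                 out_dir) -> tuple[Path, Path, SimTruth]:
    """Draw eQTL and mQTL panels and plant the mediated trait effects.

    Must follow :func:`simulate_gwas` (shares its SNP table and seed
    stream); rewrites the study files at the SNPs of causal probes.
    """
    cfg.validate()
    out_dir = Path(out_dir)
    rng = np.random.default_rng(cfg.seed + 1)
    snps = truth.snps
    windows = _assign_windows(cfg)
    order = rng.permutation(len(windows))

    n_e, n_m = cfg.n_probes_eqtl, cfg.n_probes_mqtl
    e_windows = [windows[i] for i in order[:n_e]]
    extra = order[n_e:n_e + n_m - cfg.n_shared_causal]
    # shared causal genes: the mQTL probe sits in the eQTL probe's cis window
    m_windows = [e_windows[j] for j in range(cfg.n_shared_causal)] + \
                [windows[i] for i in extra]

    probe_rows, pair_rows = [], []
    causal_snp_beta: dict[int, float] = {}

    def build_panel(prefix: str, source: str, wins, n_samples: int,
                    causal_flags: np.ndarray, genes: list[str]):
        for j, win in enumerate(wins):
            probe = f"{prefix}{j + 1:05d}"
            gene = genes[j]
            idx = win
            eaf = snps["eaf"].to_numpy()[idx]
            se_zx = _study_se(n_samples, eaf)
            sign = rng.choice([-1.0, 1.0], size=len(idx))
            z_true_zx = sign * rng.normal(cfg.instrument_mean_z,
                                          cfg.instrument_sd_z, size=len(idx))
            b_zx_true = z_true_zx * se_zx
            b_zx_hat = b_zx_true + se_zx * rng.standard_normal(len(idx))
            p_zx = 2.0 * stats.norm.sf(np.abs(b_zx_hat / se_zx))
            center = idx[len(idx) // 2]
            probe_rows.append({
                "probe": probe, "source": source, "gene": gene,
                "chr": snps["chr"].iloc[center],
                "probe_pos": int(snps["pos"].iloc[center]),
                "causal": bool(causal_flags[j]),
                "b_xy_true": cfg.b_xy_true if causal_flags[j] else 0.0,
            })
            for t, i in enumerate(idx):
                pair_rows.append({
                    "probe": probe, "source": source, "gene": gene,
                    "chr": snps["chr"].iloc[center],
                    "probe_pos": int(snps["pos"].iloc[center]),
                    "SNP": snps["SNP"].iloc[i], "snp_index": int(i),
                    "A1": snps["A1"].iloc[i], "A2": snps["A2"].iloc[i],
                    "b_zx_true": b_zx_true[t], "b": b_zx_hat[t],
                    "se": se_zx[t], "p": p_zx[t],
                })
                if causal_flags[j] and i not in causal_snp_beta:
                    causal_snp_beta[int(i)] = cfg.b_xy_true * b_zx_true[t]

    # the first n_causal_probes windows of each panel are causal; the first
    # n_shared_causal of the mQTL panel reuse causal eQTL windows/genes
    e_causal = np.zeros(n_e, bool); e_causal[:cfg.n_causal_probes] = True
    m_causal = np.zeros(n_m, bool); m_causal[:cfg.n_causal_probes] = True
    e_genes = [f"GENE{order[j]:05d}" for j in range(n_e)]
    m_genes = [e_genes[j] for j in range(cfg.n_shared_causal)] + \
              [f"GENE{i:05d}" for i in extra]

    build_panel("EPROBE", "eqtl", e_windows, cfg.n_eqtl_samples, e_causal, e_genes)
    build_panel("cg", "mqtl", m_windows, cfg.n_mqtl_samples, m_causal, m_genes)

    probes = pd.DataFrame(probe_rows)
    pairs = pd.DataFrame(pair_rows)

    # plant mediation: overwrite true trait effects at causal SNPs, re-draw
    # every study's observation there, rewrite the study files
    idx = np.array(sorted(causal_snp_beta), dtype=int)
    if len(idx):
        beta_true = np.array([causal_snp_beta[i] for i in idx])
        eaf = snps["eaf"].to_numpy()[idx]
        n_ref = max(cfg.study_n)
        snps.loc[idx, "z_true"] = beta_true / _study_se(n_ref, eaf)
        snps.loc[idx, "causal"] = True
        for n_k, tbl in zip(cfg.study_n, truth.study_tables):
            se = _study_se(n_k, eaf)
            zhat = beta_true / se + rng.standard_normal(len(idx))
            tbl.loc[idx, "b"] = zhat * se
            tbl.loc[idx, "p"] = 2.0 * stats.norm.sf(np.abs(zhat))
        for k, tbl in enumerate(truth.study_tables, start=1):
            write_gwas(tbl, out_dir / f"study{k}.ma")

    eqtl_path = out_dir / "eqtl.tsv"
    mqtl_path = out_dir / "mqtl.tsv"
    for source, path in (("eqtl", eqtl_path), ("mqtl", mqtl_path)):
        sub = pairs.loc[pairs["source"] == source,
                        ["probe", "chr", "probe_pos", "gene", "SNP",
                         "A1", "A2", "b", "se", "p"]]
        write_qtl(sub, path)

    truth = replace(truth, probes=probes,
                    pairs=pairs[["probe", "source", "gene", "SNP",
                                 "b_zx_true"]].copy())
    truth.probes.to_csv(out_dir / "truth.tsv", sep="\t", index=False)
    return eqtl_path, mqtl_path, truth


def simulate(cfg: Optional[SimConfig] = None, out_dir=".") -> dict:
    """Run the full generator; returns file paths and the ground truth."""
    cfg = cfg or SimConfig()
    gwas_paths, truth = simulate_gwas(cfg, out_dir)
    eqtl_path, mqtl_path, truth = simulate_qtl(cfg, truth, out_dir)
    return {"gwas": gwas_paths, "eqtl": eqtl_path, "mqtl": mqtl_path,
            "truth": truth, "config": cfg}
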