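"""Fixed-effect inverse-variance-weighted (IVW) meta-analysis.

Each study's effect estimate is weighted by its precision w_i = 1/SE_i^2;
the pooled effect is the weighted mean and the pooled standard error is
sqrt(1 / sum w_i), so the pooled Z-score is beta_meta / se_meta and the
p-value is recomputed from the normal distribution (never pooled from
per-study p-values).

A ``literal_se`` variant computing SE = 1/sum(w_i) — dimensionally a
reciprocal variance rather than a standard error — is available for audit;
it is not self-consistent (its Z grows without bound as studies are added)
and is never the default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import GWAS_COLUMNS, AlignedPanel


@dataclass
class MetaResult:
    """Pooled per-SNP statistics plus per-study weights."""

    snp_id: str
    weights: np.ndarray
    beta_meta: float
    se_meta: float
    z_meta: float
    p_meta: float
    k: int


def ivw_weight(se):
    """Precision weight w = 1/se^2. Accepts scalars or arrays; se must be > 0."""
    se = np.asarray(se, dtype=float)
    if np.any(se <= 0) or np.any(~np.isfinite(se)):
        raise ValueError("standard errors must be finite and > 0")
    w = 1.0 / se**2
    return float(w) if w.ndim == 0 else w


def meta_combine(betas, ses, snp_id: str = "", eq3_literal: bool = False) -> MetaResult:
    """Pool one SNP's per-study estimates into a single fixed-effect estimate.

    ``eq3_literal`` reproduces the audit variant SE = 1/sum(w) in place of
    the conventional sqrt(1/sum(w)).
    """
    betas = np.asarray(betas, dtype=float)
    ses = np.asarray(ses, dtype=float)
    if betas.shape != ses.shape or betas.ndim != 1 or betas.size == 0:
        raise ValueError("betas and ses must be equal-length non-empty 1-D arrays")
    w = ivw_weight(ses)
    w = np.atleast_1d(w)
    sw = w.sum()
    beta = float((betas * w).sum() / sw)
    se = float(1.0 / sw) if eq3_literal else float(np.sqrt(1.0 / sw))
    z = beta / se
    p = float(2.0 * stats.norm.sf(abs(z)))
    return MetaResult(snp_id=snp_id, weights=w, beta_meta=beta, se_meta=se,
                      z_meta=z, p_meta=p, k=int(betas.size))


def meta_panel(panel: AlignedPanel, min_studies: int = 1,
               eq3_literal: bool = False) -> pd.DataFrame:
    """Meta-analyse every SNP of an aligned panel.

    Returns a GWAS-dialect frame (``SNP A1 A2 freq b se p N``) with the
    pooled statistics: freq is the sample-size-weighted mean effect-allele
    frequency and N the summed sample size over contributing studies.
    SNPs carried by fewer than ``min_studies`` studies are dropped and
    counted in ``attrs['n_below_min_studies']``.
    """
    if panel.n_snps == 0:
        raise ValueError("empty panel")
    B = np.column_stack([s["b"].to_numpy(dtype=float) for s in panel.studies])
    S = np.column_stack([s["se"].to_numpy(dtype=float) for s in panel.studies])
    F = np.column_stack([pd.to_numeric(s["freq"], errors="coerce").to_numpy(dtype=float)
                         for s in panel.studies])
    N = np.column_stack([pd.to_numeric(s["N"], errors="coerce").to_numpy(dtype=float)
                         for s in panel.studies])

    present = np.isfinite(B) & np.isfinite(S) & (S > 0)
    k = present.sum(axis=1)
    keep = k >= max(min_studies, 1)
    n_dropped = int((~keep).sum())

    with np.errstate(divide="ignore", invalid="ignore"):
        w = np.where(present, 1.0 / S**2, 0.0)
    sw = w.sum(axis=1)
    beta = np.where(sw > 0, (np.where(present, B, 0.0) * w).sum(axis=1) / sw, np.nan)
    if eq3_literal:
        se = np.where(sw > 0, 1.0 / sw, np.nan)
    else:
        se = np.where(sw > 0, np.sqrt(1.0 / sw), np.nan)
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))

    nsum = np.where(present & np.isfinite(N), N, 0.0).sum(axis=1)
    have_fn = present & np.isfinite(F) & np.isfinite(N)
    fn_weight = np.where(have_fn, N, 0.0)
    with np.errstate(invalid="ignore"):
        freq = (np.where(have_fn, F, 0.0) * fn_weight).sum(axis=1) / fn_weight.sum(axis=1)

    out = pd.DataFrame({
        "SNP": panel.snps["SNP"].to_numpy(),
        "A1": panel.snps["A1"].to_numpy(),
        "A2": panel.snps["A2"].to_numpy(),
        "freq": freq,
        "b": beta,
        "se": se,
        "p": p,
        "N": nsum,
    })
    out = out.loc[keep].reset_index(drop=True)
    out.attrs["n_below_min_studies"] = n_dropped
    out.attrs["k_studies"] = k[keep]
    assert list(out.columns) == GWAS_COLUMNS
    return out
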