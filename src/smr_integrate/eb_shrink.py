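"""Empirical-Bayes (James-Stein) shrinkage of genome-wide Z-scores.

Model: the observed score for SNP i is Zhat_i ~ N(Z_i, 1), where the true
scores share a genome-wide prior Z_i ~ N(theta, sigma^2). Marginally
Zhat_i ~ N(theta, sigma^2 + 1), and the posterior mean of Z_i is

    theta + B * (Zhat_i - theta),   B = sigma^2 / (1 + sigma^2).

With theta and sigma^2 unknown, theta is estimated by the grand mean of
the observed scores and B by the James-Stein plug-in

    B_hat = 1 - (N - 3) / S,    S = sum_i (Zhat_i - mean)^2,

which is unbiased for 1/(sigma^2+1) under the marginal model (the N-3
comes from the mean of the inverse-chi-square with N-1 degrees of
freedom). B_hat is truncated at zero by default: the positive-part
estimator dominates the raw one, and a negative B would reverse every
effect direction.

Shrinkage is applied to the signed meta-analysed Z-scores in a single
pool across all chromosomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .sumstats_io import GWAS_COLUMNS


@dataclass
class EbState:
    """Fitted genome-wide shrinkage parameters and the scores they came from."""

    n_snps: int
    theta_hat: float
    S: float
    B: float
    B_raw: float
    sigma2_hat: float
    z_raw: np.ndarray
    z_shrunk: Optional[np.ndarray] = field(default=None, repr=False)


def eb_fit(z_raw, truncate: bool = True) -> EbState:
    """Estimate the shrinkage factor B from the genome-wide Z-scores.

    Requires N >= 4 (the inverse-chi-square moment needs N - 3 > 0) and
    non-zero dispersion.
    """
    z = np.asarray(z_raw, dtype=float)
    if z.ndim != 1:
        raise ValueError("z_raw must be 1-D")
    n = z.size
    if n <= 3:
        raise ValueError(f"insufficient SNPs for EB shrinkage: N={n} <= 3")
    theta = float(z.mean())
    S = float(((z - theta) ** 2).sum())
    if S == 0.0:
        raise ValueError("degenerate input: zero dispersion (all Z identical)")
    B_raw = 1.0 - (n - 3) / S
    B = max(B_raw, 0.0) if truncate else B_raw
    sigma2_hat = S / (n - 3) - 1.0
    return EbState(n_snps=n, theta_hat=theta, S=S, B=B, B_raw=B_raw,
                   sigma2_hat=sigma2_hat, z_raw=z)


def eb_apply(state: EbState) -> np.ndarray:
    """Shrink each observed score toward the grand mean: theta + B*(z - theta)."""
    z = state.z_raw
    shrunk = state.theta_hat + state.B * (z - state.theta_hat)
    state.z_shrunk = shrunk
    return shrunk


def eb_pvalues(z_shrunk) -> np.ndarray:
    """Two-sided normal p-values, p = 2*(1 - Phi(|Z|))."""
    z = np.asarray(z_shrunk, dtype=float)
    return 2.0 * stats.norm.sf(np.abs(z))


def shrink_gwas(gwas: pd.DataFrame, truncate: bool = True,
                mode: str = "beta") -> tuple[pd.DataFrame, EbState]:
    """Apply genome-wide EB shrinkage to a GWAS-dialect table.

    The revised Z must re-enter downstream analyses that consume beta and
    se separately, so two back-transformations are offered:

    * ``mode='beta'`` (default): beta' = Z_shrunk * se, keeping se fixed;
    * ``mode='z'``: se' = beta / Z_shrunk, keeping beta fixed (rows whose
      shrunk Z crosses or hits zero would need a negative or infinite se,
      so this mode leaves se unchanged there and flags the count).

    p-values are recomputed from the shrunk Z in both modes.
    """
    if mode not in ("beta", "z"):
        raise ValueError(f"mode must be 'beta' or 'z', got {mode!r}")
    z_raw = (gwas["b"] / gwas["se"]).to_numpy(dtype=float)
    state = eb_fit(z_raw, truncate=truncate)
    z_new = eb_apply(state)

    out = gwas.copy()
    n_unscalable = 0
    if mode == "beta":
        out["b"] = z_new * out["se"].to_numpy(dtype=float)
    else:
        b = out["b"].to_numpy(dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            se_new = b / z_new
        ok = np.isfinite(se_new) & (se_new > 0)
        n_unscalable = int((~ok).sum())
        out["se"] = np.where(ok, se_new, out["se"].to_numpy(dtype=float))
    out["p"] = eb_pvalues(z_new)
    out.attrs["eb"] = {"N": state.n_snps, "theta_hat": state.theta_hat,
                       "S": state.S, "B": state.B, "B_raw": state.B_raw,
                       "mode": mode, "n_unscalable": n_unscalable}
    assert list(out.columns) == GWAS_COLUMNS
    return out, state
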