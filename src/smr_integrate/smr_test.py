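"""Summary-data Mendelian randomization (SMR) pleiotropy test.

For a SNP z instrumenting exposure x (expression or methylation) against
outcome y (the trait), the Wald ratio estimate of the exposure effect is

    b_xy = b_zy / b_zx

and the test statistic, from the delta-method variance of the ratio, is

    T_SMR = (z_zy^2 * z_zx^2) / (z_zy^2 + z_zx^2) ~ chi-square(1)

under the null of no mediated/pleiotropic effect, where z_zy = b_zy/se_zy
and z_zx = b_zx/se_zx. T_SMR is bounded by the weaker of the two component
chi-squares, so a significant SMR hit needs both a trait association and
an instrument association. Significance is judged against a probe-count
Bonferroni threshold alpha / n_probes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

SMR_COLUMNS = ["probe", "gene", "SNP", "A1", "A2", "b_zx", "se_zx",
               "b_zy", "se_zy", "b_xy", "se_xy", "t_SMR", "p_SMR", "significant"]


@dataclass
class ThresholdSpec:
    """Probe-count Bonferroni threshold: alpha / n_probes."""

    alpha: float
    n_probes: int
    threshold: float


@dataclass
class SmrResult:
    """Wald ratio and chi-square(1) test for one SNP-probe pair."""

    b_zx: float
    se_zx: float
    b_zy: float
    se_zy: float
    z_zx: float
    z_zy: float
    b_xy: float
    se_xy: float
    t_smr: float
    p_smr: float
    probe_id: str = ""
    gene: str = ""
    snp_id: str = ""
    significant: Optional[bool] = None


def bonferroni(alpha: float = 0.05, n_probes: int = 1) -> ThresholdSpec:
    """Family-wise threshold alpha/n_probes over the distinct probes tested."""
    if not (0 < alpha < 1):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if n_probes < 1:
        raise ValueError(f"n_probes must be >= 1, got {n_probes}")
    return ThresholdSpec(alpha=alpha, n_probes=int(n_probes),
                         threshold=alpha / n_probes)


def smr_single(b_zy: float, se_zy: float, b_zx: float, se_zx: float) -> SmrResult:
    """Wald ratio and SMR test for a single SNP-probe pair."""
    if se_zy <= 0 or se_zx <= 0:
        raise ValueError("standard errors must be > 0")
    if b_zx == 0:
        raise ZeroDivisionError("b_zx = 0: Wald ratio undefined")
    z_zy = b_zy / se_zy
    z_zx = b_zx / se_zx
    b_xy = b_zy / b_zx
    q_y, q_x = z_zy**2, z_zx**2
    t = q_y * q_x / (q_y + q_x) if (q_y + q_x) > 0 else 0.0
    p = float(stats.chi2.sf(t, df=1))
    se_xy = abs(b_xy) / np.sqrt(t) if t > 0 else np.inf
    return SmrResult(b_zx=b_zx, se_zx=se_zx, b_zy=b_zy, se_zy=se_zy,
                     z_zx=z_zx, z_zy=z_zy, b_xy=b_xy, se_xy=float(se_xy),
                     t_smr=float(t), p_smr=p)


def smr_scan(pairs: pd.DataFrame, spec: ThresholdSpec,
             min_instrument_p: Optional[float] = None,
             top_snp_only: bool = False) -> pd.DataFrame:
    """SMR-test every aligned (SNP, probe) pair against a Bonferroni threshold.

    ``pairs`` is the output of :func:`~smr_integrate.sumstats_io.intersect_gwas_qtl`
    (b_zy and b_zx refer to the same effect allele). Pairs with b_zx = 0
    are skipped and counted in ``attrs['n_zero_instrument']``.
    ``min_instrument_p`` optionally drops pairs whose instrument p-value
    p_zx exceeds it; ``top_snp_only`` keeps only each probe's strongest
    instrument, as in the original single-SNP SMR tool.
    """
    df = pairs.copy()
    if min_instrument_p is not None:
        df = df.loc[df["p_zx"] <= min_instrument_p]
    if top_snp_only and len(df):
        df = df.loc[df.groupby("probe")["p_zx"].idxmin()]

    n_zero = int((df["b_zx"] == 0).sum()) if len(df) else 0
    df = df.loc[df["b_zx"] != 0].reset_index(drop=True) if len(df) else df

    if len(df) == 0:
        out = pd.DataFrame(columns=SMR_COLUMNS)
        out.attrs["n_zero_instrument"] = n_zero
        return out

    b_zy = df["b_zy"].to_numpy(dtype=float)
    se_zy = df["se_zy"].to_numpy(dtype=float)
    b_zx = df["b_zx"].to_numpy(dtype=float)
    se_zx = df["se_zx"].to_numpy(dtype=float)

    q_y = (b_zy / se_zy) ** 2
    q_x = (b_zx / se_zx) ** 2
    denom = q_y + q_x
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, q_y * q_x / denom, 0.0)
        b_xy = b_zy / b_zx
        se_xy = np.where(t > 0, np.abs(b_xy) / np.sqrt(t), np.inf)
    p = stats.chi2.sf(t, df=1)

    out = pd.DataFrame({
        "probe": df["probe"], "gene": df["gene"], "SNP": df["SNP"],
        "A1": df["A1"], "A2": df["A2"],
        "b_zx": b_zx, "se_zx": se_zx, "b_zy": b_zy, "se_zy": se_zy,
        "b_xy": b_xy, "se_xy": se_xy, "t_SMR": t, "p_SMR": p,
        "significant": p < spec.threshold,
    })
    out.attrs["n_zero_instrument"] = n_zero
    out.attrs["threshold"] = spec.threshold
    if n_zero:
        logger.info("smr_scan: skipped %d pairs with b_zx = 0", n_zero)
    return out


def write_smr(df: pd.DataFrame, path) -> None:
    df.loc[:, SMR_COLUMNS].to_csv(path, sep="\t", index=False)


def read_smr(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if list(df.columns) != SMR_COLUMNS:
        raise ValueError(f"{path}: not an SMR result table")
    return df
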