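"""Reading, writing and harmonizing GWAS / QTL summary-statistic tables.

Two flat-text dialects are supported:

* GWAS: whitespace-delimited with header ``SNP A1 A2 freq b se p N``
  (the de-facto ``.ma`` summary-statistics exchange format). ``A1`` is the
  effect allele, ``b`` the per-allele effect on the trait, ``se`` its
  standard error.
* QTL: tab-delimited with header
  ``probe chr probe_pos gene SNP A1 A2 b se p`` where ``b`` is the effect
  of the SNP on expression (in expression SD) or methylation (beta-value)
  per copy of ``A1``.

Coordinates are 1-based. Alleles are compared as upper-case strings;
palindromic (A/T, C/G) SNPs are counted but never strand-flipped, since
allele frequency is not a reliable disambiguator at desk scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

GWAS_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]
QTL_COLUMNS = ["probe", "chr", "probe_pos", "gene", "SNP", "A1", "A2", "b", "se", "p"]

#: sentinel strings treated as missing values in numeric columns
NA_STRINGS = {"", "NA", "NaN", "nan", "na", ".", "None"}

_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}


class DialectError(ValueError):
    """Unknown dialect name or header mismatch."""


class RowParseError(ValueError):
    """A required field could not be parsed; carries the 1-based line number."""

    def __init__(self, line_no: int, column: str, value: str):
        self.line_no = line_no
        self.column = column
        self.value = value
        super().__init__(
            f"line {line_no}: cannot parse required field {column!r} from {value!r}"
        )


@dataclass
class SnpStat:
    """One SNP's summary statistics in one study."""

    snp_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    p: float
    eaf: Optional[float] = None
    n: Optional[float] = None
    chrom: Optional[str] = None
    pos: Optional[int] = None

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.snp_id}: se must be > 0, got {self.se}")
        if not (0 < self.p <= 1):
            raise ValueError(f"{self.snp_id}: p must lie in (0, 1], got {self.p}")
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.snp_id}: effect and other allele are identical")

    @property
    def z(self) -> float:
        return self.beta / self.se


@dataclass
class QtlRecord:
    """One SNP-probe association with its probe annotation."""

    probe_id: str
    probe_chrom: str
    probe_pos: int
    gene: str
    snp_id: str
    effect_allele: str
    other_allele: str
    beta_zx: float
    se_zx: float
    p_zx: float

    def __post_init__(self) -> None:
        if self.se_zx <= 0:
            raise ValueError(f"{self.probe_id}/{self.snp_id}: se_zx must be > 0")


@dataclass
class AlignedPanel:
    """Studies aligned on a shared SNP index and a single reference allele.

    ``snps`` holds one row per retained SNP with the reference alleles
    (those of the first study); ``studies`` holds one frame per input
    study, row-aligned with ``snps``, betas sign-flipped onto the
    reference effect allele. In ``join='outer'`` mode a study may carry
    NaN at SNPs it did not measure.
    """

    snps: pd.DataFrame
    studies: list[pd.DataFrame]
    n_mismatched: int = 0
    n_palindromic: int = 0
    dropped_snps: list[str] = field(default_factory=list)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def n_studies(self) -> int:
        return len(self.studies)


def _parse_numeric(raw: pd.Series, column: str, required: bool) -> pd.Series:
    """Coerce a string column to float; raise on garbage in required columns."""
    stripped = raw.astype(str).str.strip()
    out = pd.to_numeric(stripped, errors="coerce")
    garbage = out.isna() & ~stripped.isin(NA_STRINGS)
    if required and garbage.any():
        idx = int(np.flatnonzero(garbage.to_numpy())[0])
        # +2: header line plus 1-based numbering
        raise RowParseError(idx + 2, column, stripped.iloc[idx])
    return out


def _read_table(path, columns: Sequence[str], sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype=str, comment=None)
    header = [c.strip() for c in df.columns]
    if header != list(columns):
        raise DialectError(
            f"{path}: header {header} does not match expected {list(columns)}"
        )
    df.columns = header
    return df


def read_gwas(path, dialect: str = "ma") -> pd.DataFrame:
    """Read a GWAS summary-statistics table.

    Rows with non-positive ``se`` or missing ``b`` are dropped and counted;
    duplicate SNP ids keep the first occurrence. Drop counts are logged and
    attached to ``df.attrs`` (``n_dropped``, ``n_duplicates``,
    ``n_zp_inconsistent``).
    """
    if dialect != "ma":
        raise DialectError(f"unknown GWAS dialect: {dialect!r}")
    df = _read_table(path, GWAS_COLUMNS, sep=r"\s+")
    n_raw = len(df)

    for col, required in [("b", True), ("se", True), ("p", True),
                          ("freq", False), ("N", False)]:
        df[col] = _parse_numeric(df[col], col, required)
    for col in ("SNP", "A1", "A2"):
        df[col] = df[col].astype(str).str.strip()
    df["A1"] = df["A1"].str.upper()
    df["A2"] = df["A2"].str.upper()

    bad = df["b"].isna() | df["se"].isna() | (df["se"] <= 0)
    n_dropped = int(bad.sum())
    df = df.loc[~bad]

    dup = df["SNP"].duplicated(keep="first")
    n_dup = int(dup.sum())
    df = df.loc[~dup].reset_index(drop=True)

    # z/p consistency diagnostic (not a filter): p should match 2*Phi(-|b/se|)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_implied = 2.0 * stats.norm.sf(np.abs(df["b"] / df["se"]))
    have_p = df["p"].notna()
    inconsistent = have_p & ~np.isclose(df["p"], p_implied, rtol=1e-2, atol=1e-4)
    n_inconsistent = int(inconsistent.sum())

    if n_dropped:
        logger.info("%s: dropped %d/%d rows (missing b or se <= 0)", path, n_dropped, n_raw)
    if n_dup:
        logger.info("%s: removed %d duplicate SNP ids (kept first)", path, n_dup)
    if n_inconsistent:
        logger.warning("%s: %d rows have p inconsistent with b/se", path, n_inconsistent)

    df.attrs.update(n_dropped=n_dropped, n_duplicates=n_dup,
                    n_zp_inconsistent=n_inconsistent)
    return df


def write_gwas(df: pd.DataFrame, path) -> None:
    df.loc[:, GWAS_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def read_qtl(path) -> pd.DataFrame:
    """Read a flat QTL association table (one row per SNP-probe pair)."""
    df = _read_table(path, QTL_COLUMNS, sep="\t")
    n_raw = len(df)
    for col, required in [("b", True), ("se", True), ("p", True),
                          ("probe_pos", False)]:
        df[col] = _parse_numeric(df[col], col, required)
    for col in ("probe", "chr", "gene", "SNP", "A1", "A2"):
        df[col] = df[col].astype(str).str.strip()
    df["A1"] = df["A1"].str.upper()
    df["A2"] = df["A2"].str.upper()

    bad = df["b"].isna() | df["se"].isna() | (df["se"] <= 0)
    n_dropped = int(bad.sum())
    df = df.loc[~bad]

    dup = df.duplicated(subset=["probe", "SNP"], keep="first")
    n_dup = int(dup.sum())
    df = df.loc[~dup].reset_index(drop=True)

    if n_dropped:
        logger.info("%s: dropped %d/%d QTL rows", path, n_dropped, n_raw)
    df.attrs.update(n_dropped=n_dropped, n_duplicates=n_dup)
    return df


def write_qtl(df: pd.DataFrame, path) -> None:
    df.loc[:, QTL_COLUMNS].to_csv(path, sep="\t", index=False, na_rep="NA")


def is_palindromic(a1: pd.Series, a2: pd.Series) -> pd.Series:
    pairs = list(zip(a1, a2))
    return pd.Series([p in _PALINDROMIC for p in pairs], index=a1.index)


def harmonize(studies: list[pd.DataFrame], join: str = "inner") -> AlignedPanel:
    """Align studies on shared SNPs and one reference effect allele per SNP.

    The first study defines the reference (A1, A2) per SNP. A study whose
    alleles are swapped relative to the reference has its beta negated and
    freq complemented; a study whose allele pair cannot be reconciled has
    that SNP removed from the whole panel (``n_mismatched`` counts them).

    ``join='inner'`` (default) keeps only SNPs present in every study;
    ``join='outer'`` keeps the union, with NaN statistics where a study
    lacks the SNP.
    """
    if not studies:
        raise ValueError("harmonize requires at least one study")
    if join not in ("inner", "outer"):
        raise ValueError(f"join must be 'inner' or 'outer', got {join!r}")

    ref = studies[0].set_index("SNP")
    snp_index = pd.Index(studies[0]["SNP"])
    for st in studies[1:]:
        ids = pd.Index(st["SNP"])
        snp_index = snp_index.intersection(ids) if join == "inner" else snp_index.union(ids)
    # SNPs only in later studies (outer join) take their alleles from the
    # first study that carries them
    ref_alleles = pd.DataFrame(index=snp_index, columns=["A1", "A2"], dtype=object)
    for st in studies:
        sub = st.set_index("SNP")[["A1", "A2"]]
        missing = ref_alleles["A1"].isna()
        fill = sub.reindex(snp_index[missing]).dropna()
        ref_alleles.loc[fill.index, ["A1", "A2"]] = fill

    if len(snp_index) == 0:
        raise ValueError("no SNPs shared across studies after intersection")

    aligned: list[pd.DataFrame] = []
    mismatch_ids: set[str] = set()
    for st in studies:
        sub = st.set_index("SNP").reindex(snp_index)
        a1, a2 = sub["A1"], sub["A2"]
        r1, r2 = ref_alleles["A1"], ref_alleles["A2"]
        present = a1.notna()
        same = (a1 == r1) & (a2 == r2)
        swapped = (a1 == r2) & (a2 == r1)
        bad = present & ~(same | swapped)
        mismatch_ids.update(snp_index[bad])
        out = sub.copy()
        out.loc[swapped, "b"] = -sub.loc[swapped, "b"]
        out.loc[swapped, "freq"] = 1.0 - sub.loc[swapped, "freq"]
        out.loc[swapped, ["A1", "A2"]] = ref_alleles.loc[swapped, ["A1", "A2"]].to_numpy()
        aligned.append(out)

    keep = ~snp_index.isin(mismatch_ids)
    snps = ref_alleles.loc[keep].reset_index().rename(columns={"index": "SNP"})
    aligned = [a.loc[keep].reset_index() for a in aligned]

    n_palin = int(is_palindromic(snps["A1"], snps["A2"]).sum())
    if mismatch_ids:
        logger.info("harmonize: removed %d SNPs with irreconcilable alleles",
                    len(mismatch_ids))
    if n_palin:
        logger.info("harmonize: %d palindromic SNPs kept as-is", n_palin)
    if len(snps) == 0:
        raise ValueError("empty panel after allele harmonization")

    return AlignedPanel(
        snps=snps,
        studies=aligned,
        n_mismatched=len(mismatch_ids),
        n_palindromic=n_palin,
        dropped_snps=sorted(mismatch_ids),
    )


def intersect_gwas_qtl(gwas: pd.DataFrame, qtl: pd.DataFrame) -> pd.DataFrame:
    """Pair GWAS SNPs with QTL records sharing the same SNP id.

    Returns one row per (SNP, probe) pair with QTL effects sign-flipped
    onto the GWAS effect allele. One SNP may pair with several probes.
    Pairs whose allele sets cannot be reconciled are dropped and counted
    in ``attrs['n_mismatched']``. An empty result is a warning, not an
    error.
    """
    if len(gwas) == 0 or len(qtl) == 0:
        raise ValueError("both GWAS and QTL inputs must be non-empty")

    g = gwas.rename(columns={"b": "b_zy", "se": "se_zy", "p": "p_zy",
                             "freq": "freq_zy", "N": "n_zy"})
    q = qtl.rename(columns={"b": "b_zx", "se": "se_zx", "p": "p_zx",
                            "A1": "A1_q", "A2": "A2_q"})
    merged = q.merge(g, on="SNP", how="inner")

    same = (merged["A1_q"] == merged["A1"]) & (merged["A2_q"] == merged["A2"])
    swapped = (merged["A1_q"] == merged["A2"]) & (merged["A2_q"] == merged["A1"])
    merged.loc[swapped, "b_zx"] = -merged.loc[swapped, "b_zx"]
    keep = same | swapped
    n_mismatched = int((~keep).sum())
    merged = merged.loc[keep].reset_index(drop=True)

    cols = ["probe", "chr", "probe_pos", "gene", "SNP", "A1", "A2",
            "b_zx", "se_zx", "p_zx", "b_zy", "se_zy", "p_zy"]
    out = merged.loc[:, cols]
    out.attrs["n_mismatched"] = n_mismatched
    if len(out) == 0:
        logger.warning("intersect_gwas_qtl: no shared SNPs between GWAS and QTL")
    return out
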