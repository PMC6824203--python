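import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as hst

from smr_integrate import sumstats_io as sio


class TestReadGwas:
    def test_clean_file_retains_all_rows(self, gwas_file):
        path = gwas_file([
            "rs1 A G 0.3 0.10 0.1 0.3173 1000",
            "rs2 C T 0.5 0.20 0.2 0.3173 1000",
            "rs3 A C 0.2 0.30 0.3 0.3173 1000",
        ])
        df = sio.read_gwas(path)
        assert len(df) == 3
        assert df.attrs["n_dropped"] == 0
        assert list(df["se"]) == [0.1, 0.2, 0.3]

    def test_nonpositive_se_rows_dropped_and_counted(self, gwas_file):
        path = gwas_file([
            "rs1 A G 0.3 0.1 0.1 0.3173 1000",
            "rs2 C T 0.5 0.2 0.0 0.3173 1000",
            "rs3 A C 0.2 0.3 0.3 0.3173 1000",
        ])
        df = sio.read_gwas(path)
        assert len(df) == 2
        assert df.attrs["n_dropped"] == 1

    def test_missing_beta_dropped(self, gwas_file):
        path = gwas_file([
            "rs1 A G 0.3 NA 0.1 0.3173 1000",
            "rs2 C T 0.5 0.2 0.2 0.3173 1000",
        ])
        df = sio.read_gwas(path)
        assert list(df["SNP"]) == ["rs2"]
        assert df.attrs["n_dropped"] == 1

    def test_z_p_consistency_flags_clean_row(self, gwas_file):
        # beta/se = 1.96 with p = 0.05: consistent under 2*(1 - Phi(1.96))
        path = gwas_file(["rs1 A G 0.3 0.196 0.1 0.05 1000"])
        df = sio.read_gwas(path)
        assert df.attrs["n_zp_inconsistent"] == 0

    def test_z_p_inconsistency_counted(self, gwas_file):
        path = gwas_file(["rs1 A G 0.3 0.196 0.1 0.9 1000"])
        df = sio.read_gwas(path)
        assert df.attrs["n_zp_inconsistent"] == 1

    def test_unknown_dialect_rejected(self, gwas_file):
        path = gwas_file(["rs1 A G 0.3 0.1 0.1 0.3 1000"])
        with pytest.raises(sio.DialectError):
            sio.read_gwas(path, dialect="vcfish")

    def test_header_mismatch_rejected(self, gwas_file):
        path = gwas_file(["rs1 A G 0.3 0.1 0.1 0.3 1000"],
                         header="CHR SNP A1 A2 freq b se p")
        with pytest.raises(sio.DialectError):
            sio.read_gwas(path)

    def test_unparseable_required_field_reports_line(self, gwas_file):
        path = gwas_file([
            "rs1 A G 0.3 0.1 0.1 0.3 1000",
            "rs2 C T 0.5 oops 0.2 0.3 1000",
        ])
        with pytest.raises(sio.RowParseError, match="line 3"):
            sio.read_gwas(path)

    def test_duplicate_snp_keeps_first(self, gwas_file):
        path = gwas_file([
            "rs1 A G 0.3 0.1 0.1 0.3173 1000",
            "rs1 A G 0.3 0.9 0.1 0.3173 1000",
        ])
        df = sio.read_gwas(path)
        assert len(df) == 1
        assert df["b"].iloc[0] == 0.1
        assert df.attrs["n_duplicates"] == 1

    def test_roundtrip_bit_identical(self, gwas_file, tmp_path):
        path = gwas_file([
            "rs1 A G 0.3 0.123456789 0.1 0.217 1000",
            "rs2 C T 0.5 -0.2 0.25 0.4237 2000",
        ])
        df = sio.read_gwas(path)
        out = tmp_path / "rt.ma"
        sio.write_gwas(df, out)
        df2 = sio.read_gwas(out)
        pd.testing.assert_frame_equal(df, df2)


class TestSnpStatInvariants:
    @pytest.mark.parametrize("kwargs", [
        dict(se=0.0), dict(se=-1.0), dict(p=0.0), dict(p=1.5),
        dict(other_allele="A"),
    ])
    def test_invalid_fields_rejected(self, kwargs):
        base = dict(snp_id="rs1", effect_allele="A", other_allele="G",
                    beta=0.1, se=0.1, p=0.32)
        base.update(kwargs)
        with pytest.raises(ValueError):
            sio.SnpStat(**base)

    def test_z_property(self):
        s = sio.SnpStat("rs1", "A", "G", beta=0.2, se=0.1, p=0.0455)
        assert s.z == pytest.approx(2.0)


class TestHarmonize:
    def _study(self, **kw):
        from .conftest import make_gwas_df
        return make_gwas_df(**kw)

    def test_swapped_alleles_flip_beta(self):
        from .conftest import make_gwas_df
        s1 = make_gwas_df(["rs1"], [0.2], [0.1], a1="A", a2="G")
        s2 = make_gwas_df(["rs1"], [-0.2], [0.1], a1="G", a2="A")
        panel = sio.harmonize([s1, s2])
        assert panel.studies[0]["b"].iloc[0] == pytest.approx(0.2)
        assert panel.studies[1]["b"].iloc[0] == pytest.approx(0.2)
        assert panel.studies[1]["A1"].iloc[0] == "A"

    def test_single_study_identity(self):
        from .conftest import make_gwas_df
        s1 = make_gwas_df(["rs1", "rs2"], [0.2, 0.1], [0.1, 0.1])
        panel = sio.harmonize([s1])
        assert panel.n_snps == 2
        assert list(panel.studies[0]["b"]) == [0.2, 0.1]

    def test_irreconcilable_alleles_removed_and_counted(self):
        from .conftest import make_gwas_df
        s1 = make_gwas_df(["rs1", "rs2"], [0.2, 0.1], [0.1, 0.1], a1="A", a2="G")
        s2 = make_gwas_df(["rs1", "rs2"], [0.2, 0.1], [0.1, 0.1],
                          a1=["A", "A"], a2=["C", "G"])
        panel = sio.harmonize([s1, s2])
        assert panel.n_mismatched == 1
        assert list(panel.snps["SNP"]) == ["rs2"]

    def test_empty_intersection_is_error(self):
        from .conftest import make_gwas_df
        s1 = make_gwas_df(["rs1"], [0.2], [0.1])
        s2 = make_gwas_df(["rs9"], [0.2], [0.1])
        with pytest.raises(ValueError):
            sio.harmonize([s1, s2])

    def test_idempotent(self):
        from .conftest import make_gwas_df
        s1 = make_gwas_df(["rs1", "rs2"], [0.2, -0.3], [0.1, 0.2], a1="A", a2="G")
        s2 = make_gwas_df(["rs2", "rs1"], [0.3, 0.1], [0.2, 0.1], a1="G", a2="A")
        panel = sio.harmonize([s1, s2])
        again = sio.harmonize([s.loc[:, s1.columns] for s in panel.studies])
        for a, b in zip(panel.studies, again.studies):
            assert np.allclose(a["b"].to_numpy(dtype=float),
                               b["b"].to_numpy(dtype=float))

    def test_palindromic_counted_not_flipped(self):
        from .conftest import make_gwas_df
        s1 = make_gwas_df(["rs1"], [0.2], [0.1], a1="A", a2="T")
        panel = sio.harmonize([s1])
        assert panel.n_palindromic == 1
        assert panel.studies[0]["b"].iloc[0] == pytest.approx(0.2)


def _qtl_df(records):
    return pd.DataFrame(records, columns=sio.QTL_COLUMNS)


class TestIntersect:
    def _gwas(self, snps, betas=None):
        from .conftest import make_gwas_df
        betas = betas or [0.1] * len(snps)
        return make_gwas_df(snps, betas, [0.1] * len(snps))

    def test_one_snp_many_probes(self):
        g = self._gwas(["rs1", "rs2"])
        q = _qtl_df([("p1", "1", 100, "G1", "rs2", "A", "G", 0.5, 0.1, 1e-6),
                     ("p2", "1", 200, "G2", "rs2", "A", "G", 0.4, 0.1, 1e-6)])
        pairs = sio.intersect_gwas_qtl(g, q)
        assert len(pairs) == 2
        assert set(pairs["SNP"]) == {"rs2"}

    def test_disjoint_sets_give_empty_output(self):
        g = self._gwas(["rs1"])
        q = _qtl_df([("p1", "1", 100, "G1", "rs9", "A", "G", 0.5, 0.1, 1e-6)])
        pairs = sio.intersect_gwas_qtl(g, q)
        assert len(pairs) == 0

    def test_partial_overlap_count(self):
        g = self._gwas([f"rs{i}" for i in range(1, 6)])
        q = _qtl_df([("p%d" % i, "1", 100, "G1", s, "A", "G", 0.5, 0.1, 1e-6)
                     for i, s in enumerate(["rs3", "rs4", "rs5", "rs6", "rs7"])])
        pairs = sio.intersect_gwas_qtl(g, q)
        assert len(pairs) == 3  # rs3, rs4, rs5

    def test_swapped_qtl_alleles_flip_b_zx(self):
        g = self._gwas(["rs1"])
        q = _qtl_df([("p1", "1", 100, "G1", "rs1", "G", "A", 0.5, 0.1, 1e-6)])
        pairs = sio.intersect_gwas_qtl(g, q)
        assert pairs["b_zx"].iloc[0] == pytest.approx(-0.5)

    def test_mismatched_alleles_dropped(self):
        g = self._gwas(["rs1"])
        q = _qtl_df([("p1", "1", 100, "G1", "rs1", "A", "C", 0.5, 0.1, 1e-6)])
        pairs = sio.intersect_gwas_qtl(g, q)
        assert len(pairs) == 0
        assert pairs.attrs["n_mismatched"] == 1

    @given(n_gwas=hst.integers(1, 12), n_qtl=hst.integers(1, 12))
    def test_output_size_bounded(self, n_gwas, n_qtl):
        g = self._gwas([f"rs{i}" for i in range(n_gwas)])
        q = _qtl_df([(f"p{j}", "1", 100, "G1", f"rs{j % (n_gwas + 2)}",
                      "A", "G", 0.5, 0.1, 1e-6) for j in range(n_qtl)])
        pairs = sio.intersect_gwas_qtl(g, q)
        assert len(pairs) <= min(n_gwas, n_qtl) * max(1, n_qtl)
        assert len(pairs) <= n_qtl
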