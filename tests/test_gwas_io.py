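"""Summary-statistics I/O, LD matrices, and two-sample harmonization."""

import numpy as np
import pandas as pd
import pytest

from cismr import (
    HarmonizationError,
    LdError,
    LdMatrix,
    SumstatsError,
    harmonize,
    read_sumstats,
    write_sumstats,
)
from cismr.gwas_io import SUMSTAT_COLUMNS, VariantAssociation
from cismr.pipeline import make_fixture


def _row(rsid="rs1", chrom="12", pos=6_440_000, ea="G", nea="A", eaf=0.5,
         beta=0.01, se=0.002, pval=0.05, n=1000):
    return dict(rsid=rsid, chrom=chrom, pos=pos, ea=ea, nea=nea, eaf=eaf,
                beta=beta, se=se, pval=pval, n=n)


def _table(*rows):
    return pd.DataFrame([_row(**r) for r in rows], columns=list(SUMSTAT_COLUMNS))


class TestReadWrite:
    def test_fixture_reads_back_published_values(self, tmp_path):
        paths = make_fixture(tmp_path)
        exp = read_sumstats(paths["exposure"])
        assert len(exp) == 4
        row = exp.set_index("rsid").loc["rs1800693"]
        assert row["beta"] == 0.022 and row["se"] == 0.002
        assert row["pval"] == pytest.approx(9.56e-27)

    def test_header_only_file_yields_empty_table(self, tmp_path):
        p = tmp_path / "empty.tsv"
        p.write_text("\t".join(SUMSTAT_COLUMNS) + "\n")
        df = read_sumstats(p)
        assert df.empty and list(df.columns) == list(SUMSTAT_COLUMNS)

    def test_zero_se_rejected_with_invariant_message(self, tmp_path):
        p = tmp_path / "bad.tsv"
        write_sumstats(_table({}), p)
        p.write_text(p.read_text().replace("0.002", "0"))
        with pytest.raises(SumstatsError, match="se must be > 0"):
            read_sumstats(p)

    def test_missing_column_named(self, tmp_path):
        df = _table({}).drop(columns=["eaf"])
        p = tmp_path / "m.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(SumstatsError, match="eaf"):
            read_sumstats(p)

    def test_unparseable_numeric_reports_line(self, tmp_path):
        df = _table({}, {"rsid": "rs2"}).astype({"beta": object})
        df.loc[1, "beta"] = "oops"
        p = tmp_path / "n.tsv"
        df.to_csv(p, sep="\t", index=False)
        with pytest.raises(SumstatsError, match="line 3"):
            read_sumstats(p)

    def test_roundtrip_is_lossless(self, tmp_path):
        df = _table(
            {"eaf": 1 / 3, "beta": -0.0123456789012345, "pval": 9.56e-27},
            {"rsid": "rs2", "pos": 6_441_000, "se": 0.0157913238, "n": 575_531},
        )
        p = tmp_path / "rt.tsv"
        write_sumstats(df, p)
        back = read_sumstats(p)
        pd.testing.assert_frame_equal(back, df.astype(back.dtypes.to_dict()))

    def test_write_is_byte_deterministic(self, tmp_path):
        df = _table({}, {"rsid": "rs2", "eaf": 0.123456789})
        a, b = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_sumstats(df, a)
        write_sumstats(df, b)
        assert a.read_bytes() == b.read_bytes()

    def test_case_insensitive_header(self, tmp_path):
        df = _table({})
        df.columns = [c.upper() for c in df.columns]
        p = tmp_path / "u.tsv"
        df.to_csv(p, sep="\t", index=False)
        assert read_sumstats(p)["rsid"].tolist() == ["rs1"]

    def test_record_invariants_enforced(self):
        with pytest.raises(SumstatsError):
            VariantAssociation("rs1", "12", 1, "G", "G", 0.5, 0.1, 0.01, 0.5, 10)
        with pytest.raises(SumstatsError):
            VariantAssociation("rs1", "12", 1, "G", "A", 1.5, 0.1, 0.01, 0.5, 10)


class TestLdMatrix:
    def test_validation_rejects_asymmetry_and_bad_diagonal(self):
        with pytest.raises(LdError, match="symmetric"):
            LdMatrix(["a", "b"], np.array([[1.0, 0.5], [0.2, 1.0]]))
        with pytest.raises(LdError, match="diagonal"):
            LdMatrix(["a", "b"], np.array([[0.9, 0.1], [0.1, 1.0]]))

    def test_validation_rejects_non_psd(self):
        r = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        with pytest.raises(LdError, match="semidefinite"):
            LdMatrix(["a", "b", "c"], r)

    def test_tsv_roundtrip_and_submatrix_reorder(self, tmp_path):
        r = np.array([[1.0, 0.3, -0.2], [0.3, 1.0, 0.1], [-0.2, 0.1, 1.0]])
        ld = LdMatrix(["a", "b", "c"], r)
        p = tmp_path / "ld.tsv"
        ld.to_tsv(p)
        back = LdMatrix.from_tsv(p)
        assert back.labels == ld.labels
        assert np.allclose(back.r, ld.r)
        sub = back.submatrix(["c", "a"])
        assert sub.labels == ["c", "a"]
        assert sub.r[0, 1] == pytest.approx(-0.2)

    def test_missing_label_named(self):
        with pytest.raises(LdError, match="rsX"):
            LdMatrix.identity(["a"]).submatrix(["rsX"])

    def test_r_squared_input_converted_with_warning(self, tmp_path):
        p = tmp_path / "r2.tsv"
        LdMatrix(["a", "b"], np.array([[1.0, 0.49], [0.49, 1.0]])).to_tsv(p)
        with pytest.warns(UserWarning, match="r-squared"):
            ld = LdMatrix.from_tsv(p, assume_positive_ld=True)
        assert ld.r[0, 1] == pytest.approx(0.7)


class TestHarmonize:
    def test_matching_alleles_kept_unchanged(self):
        exp = _table({})
        out = _table({"beta": 0.02})
        h = harmonize(exp, out, LdMatrix.identity(["rs1"]))
        assert h.by[0] == 0.02
        assert h.log["action"].tolist() == ["kept"]

    def test_swapped_alleles_flip_beta(self):
        exp = _table({"ea": "G", "nea": "A"})
        out = _table({"ea": "A", "nea": "G", "beta": 0.010, "eaf": 0.4})
        h = harmonize(exp, out, LdMatrix.identity(["rs1"]))
        assert h.by[0] == pytest.approx(-0.010)
        assert h.log["action"].tolist() == ["flipped"]

    def test_strand_complement_matched(self):
        exp = _table({"ea": "G", "nea": "A"})
        out = _table({"ea": "C", "nea": "T", "beta": 0.015})  # complement, same orientation
        h = harmonize(exp, out, LdMatrix.identity(["rs1"]))
        assert h.by[0] == 0.015
        assert h.log["reason"].str.contains("strand").all()

    # hand-enumerated palindromic truth table (limit 0.42):
    # (eaf_exp, eaf_out) -> expected action
    @pytest.mark.parametrize(
        "eaf1,eaf2,action",
        [
            (0.30, 0.30, "kept"),      # both informative, frequencies agree
            (0.30, 0.70, "flipped"),   # both informative, frequencies disagree
            (0.49, 0.49, "dropped"),   # both MAFs >= limit
            (0.30, 0.45, "dropped"),   # one MAF >= limit
            (0.70, 0.72, "kept"),      # informative on the major side, agree
        ],
    )
    def test_palindromic_policy_truth_table(self, eaf1, eaf2, action):
        exp = _table({"ea": "A", "nea": "T", "eaf": eaf1})
        out = _table({"ea": "A", "nea": "T", "eaf": eaf2, "beta": 0.01})
        if action == "dropped":
            with pytest.raises(HarmonizationError, match="no harmonizable"):
                harmonize(exp, out, LdMatrix.identity(["rs1"]), palindromic_eaf_limit=0.42)
        else:
            h = harmonize(exp, out, LdMatrix.identity(["rs1"]), palindromic_eaf_limit=0.42)
            assert h.log["action"].tolist() == [action]
            assert h.by[0] == pytest.approx(-0.01 if action == "flipped" else 0.01)

    def test_incompatible_alleles_and_missing_ld_dropped_with_reason(self):
        exp = _table({}, {"rsid": "rs2", "ea": "C", "nea": "T"},
                     {"rsid": "rs3", "pos": 6_440_100})
        out = _table({}, {"rsid": "rs2", "ea": "C", "nea": "A"},
                     {"rsid": "rs3", "pos": 6_440_100})
        h = harmonize(exp, out, LdMatrix.identity(["rs1", "rs2"]))
        log = h.log.set_index("rsid")
        assert log.loc["rs2", "reason"] == "incompatible alleles"
        assert log.loc["rs3", "reason"] == "absent from LD matrix"
        assert h.rsids == ["rs1"]

    def test_no_shared_rsids_errors(self):
        with pytest.raises(HarmonizationError, match="no shared"):
            harmonize(_table({}), _table({"rsid": "rsZ"}), LdMatrix.identity(["rs1"]))

    def test_idempotent(self, published_tables):
        exp, out, ld = published_tables
        h1 = harmonize(exp, out, ld)
        # rebuild an outcome table already in the exposure orientation
        out2 = exp.copy()
        out2["beta"] = h1.by
        out2["se"] = h1.sy
        h2 = harmonize(exp, out2, ld)
        assert np.array_equal(h1.by, h2.by)
        assert h2.log["action"].eq("kept").all()

    def test_outcome_allele_flip_equivariance(self, published_tables):
        exp, out, ld = published_tables
        flipped = out.copy()
        flipped["ea"], flipped["nea"] = out["nea"], out["ea"]
        flipped["beta"] = -out["beta"]
        flipped["eaf"] = 1 - out["eaf"]
        h1 = harmonize(exp, out, ld)
        h2 = harmonize(exp, flipped, ld)
        assert h1.rsids == h2.rsids
        assert np.allclose(h1.by, h2.by)
        assert np.allclose(h1.ld.r, h2.ld.r)

    def test_log_partitions_shared_variants(self, published_tables):
        exp, out, ld = published_tables
        mixed = out.copy()
        mixed.loc[0, ["ea", "nea"]] = ["A", "G"]          # swapped -> flipped
        mixed.loc[0, "beta"] = -mixed.loc[0, "beta"]
        mixed.loc[1, ["ea", "nea"]] = ["C", "A"]          # incompatible -> dropped
        h = harmonize(exp, mixed, ld)
        assert len(h.log) == len(set(exp["rsid"]) & set(mixed["rsid"]))
        counts = h.log["action"].value_counts()
        assert counts.sum() == len(h.log)
        assert len(h) == counts.get("kept", 0) + counts.get("flipped", 0)

    def test_outcome_aligned_ld_negates_flipped_rows(self, published_tables):
        exp, out, ld = published_tables
        swapped = out.copy()
        swapped.loc[1, ["ea", "nea"]] = ["T", "C"]  # rs767455 swapped
        swapped.loc[1, "beta"] = -swapped.loc[1, "beta"]
        h_exp = harmonize(exp, swapped, ld, ld_aligned_to="exposure")
        h_out = harmonize(exp, swapped, ld, ld_aligned_to="outcome")
        i = h_out.rsids.index("rs767455")
        mask = np.ones(len(h_out), dtype=bool)
        mask[i] = False
        assert np.allclose(h_out.ld.r[i, mask], -h_exp.ld.r[i, mask])
        assert h_out.ld.r[i, i] == 1.0
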