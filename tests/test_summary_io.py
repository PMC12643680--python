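"""Summary-statistics IO and allele harmonization."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from mrmediate.summary_io import (AssociationTable, EmptyInputError,
                                  NoOverlapError, SummaryFormatError,
                                  harmonize, read_summary_stats,
                                  write_summary_stats)
from .conftest import make_table


def _row(snp, ea="A", oa="G", eaf=0.3, beta=0.1, se=0.02, p=1e-6, n=3757,
         chrom="1", pos=1_000_000):
    return (snp, chrom, pos, ea, oa, eaf, beta, se, p, n)


class TestReadWrite:
    def test_well_formed_table_reads_fully(self, tmp_path):
        t = make_table([_row("rs1"), _row("rs2", pos=2e6),
                        _row("rs3", pos=3e6)])
        path = tmp_path / "t.tsv"
        write_summary_stats(t, path)
        back = read_summary_stats(path)
        assert len(back) == 3

    def test_roundtrip_preserves_full_precision(self, tmp_path):
        rng = np.random.default_rng(7)
        rows = [_row(f"rs{i}", beta=rng.normal() * 0.137,
                     se=abs(rng.normal()) * 0.02 + 1e-3,
                     eaf=rng.uniform(0.01, 0.99), pos=1e6 + i)
                for i in range(20)]
        t = make_table(rows)
        path = tmp_path / "t.tsv"
        write_summary_stats(t, path)
        back = read_summary_stats(path)
        assert np.array_equal(back.df["beta"].to_numpy(),
                              t.df["beta"].to_numpy())
        assert np.array_equal(back.df["se"].to_numpy(), t.df["se"].to_numpy())

    def test_invalid_rows_dropped_with_count(self, tmp_path, caplog):
        rows = [_row("rs1"), _row("rs2", se=0.0, pos=2e6), _row("rs3", pos=3e6)]
        df = pd.DataFrame(rows, columns=list(make_table([_row("x")]).df.columns))
        path = tmp_path / "t.tsv"
        df.rename(columns={"snp": "SNP", "chrom": "CHR", "pos": "POS",
                           "effect_allele": "EA", "other_allele": "OA",
                           "eaf": "EAF", "beta": "BETA", "se": "SE",
                           "pval": "P", "n": "N"}).to_csv(path, sep="\t",
                                                          index=False)
        with caplog.at_level("WARNING"):
            t = read_summary_stats(path)
        assert len(t) == 2
        assert "dropped 1" in caplog.text

    def test_custom_column_map_matches_default_dialect(self, tmp_path):
        t = make_table([_row("rs1"), _row("rs2", pos=2e6)])
        default_path = tmp_path / "default.tsv"
        write_summary_stats(t, default_path)
        alt = t.df.rename(columns={
            "snp": "rsid", "chrom": "chr", "pos": "bp",
            "effect_allele": "ea", "other_allele": "nea", "eaf": "freq",
            "beta": "b", "se": "stderr", "pval": "p", "n": "samplesize"})
        alt_path = tmp_path / "alt.tsv"
        alt.to_csv(alt_path, sep="\t", index=False)
        column_map = {"rsid": "snp", "chr": "chrom", "bp": "pos",
                      "ea": "effect_allele", "nea": "other_allele",
                      "freq": "eaf", "b": "beta", "stderr": "se",
                      "p": "pval", "samplesize": "n"}
        a = read_summary_stats(default_path)
        b = read_summary_stats(alt_path, column_map=column_map)
        pd.testing.assert_frame_equal(a.df, b.df)

    def test_missing_column_raises_format_error(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("SNP\tBETA\nrs1\t0.1\n")
        with pytest.raises(SummaryFormatError):
            read_summary_stats(path)

    def test_all_rows_invalid_raises_empty_error(self, tmp_path):
        t = make_table([_row("rs1")])
        bad = t.df.assign(se=0.0)
        with pytest.raises(EmptyInputError):
            AssociationTable.from_frame(bad, "bad")

    def test_duplicate_snp_ids_rejected(self):
        t = make_table([_row("rs1")])
        dup = pd.concat([t.df, t.df], ignore_index=True)
        with pytest.raises(SummaryFormatError):
            AssociationTable("t", "quantitative", dup)


class TestHarmonize:
    def _pair(self, exp_row, out_row):
        return make_table([exp_row], "exp"), make_table([out_row], "out")

    def test_same_orientation_kept(self):
        exp, out = self._pair(_row("rs1", "A", "G", beta=0.1),
                              _row("rs1", "A", "G", beta=0.05))
        h = harmonize(exp, out)
        assert h.pairs["action"].tolist() == ["kept"]
        assert h.pairs["beta_out"].iloc[0] == 0.05

    def test_swapped_alleles_flip_beta(self):
        exp, out = self._pair(_row("rs1", "A", "G", beta=0.1),
                              _row("rs1", "G", "A", beta=0.05, eaf=0.7))
        h = harmonize(exp, out)
        assert h.pairs["action"].tolist() == ["flipped"]
        assert h.pairs["beta_out"].iloc[0] == -0.05

    def test_strand_flip_resolved_by_complement(self):
        # exposure A/G reported as T/C on the other strand: same orientation
        exp, out = self._pair(_row("rs1", "A", "G", beta=0.1),
                              _row("rs1", "T", "C", beta=0.05))
        h = harmonize(exp, out)
        assert h.pairs["action"].tolist() == ["kept"]
        assert h.pairs["beta_out"].iloc[0] == 0.05

    def test_ambiguous_palindrome_dropped(self):
        exp, out = self._pair(_row("rs1", "A", "T", eaf=0.50),
                              _row("rs1", "A", "T", eaf=0.50))
        h = harmonize(exp, out)
        assert h.pairs["action"].tolist() == ["dropped_palindromic"]
        assert h.n_retained == 0

    def test_informative_palindrome_kept_by_frequency(self):
        exp, out = self._pair(_row("rs1", "A", "T", eaf=0.10),
                              _row("rs1", "A", "T", eaf=0.12, beta=0.05))
        h = harmonize(exp, out)
        assert h.pairs["action"].tolist() == ["kept"]

    def test_incompatible_alleles_dropped(self):
        exp, out = self._pair(_row("rs1", "A", "G"),
                              _row("rs1", "A", "C"))
        h = harmonize(exp, out)
        assert h.pairs["action"].tolist() == ["dropped_incompatible"]

    def test_empty_intersection_raises(self):
        exp = make_table([_row("rs1")], "exp")
        out = make_table([_row("rs2")], "out")
        with pytest.raises(NoOverlapError):
            harmonize(exp, out)

    def test_idempotent_on_aligned_pairs(self):
        exp = make_table([_row("rs1", "A", "G", beta=0.1),
                          _row("rs2", "T", "C", beta=0.2, pos=2e6)], "exp")
        out = make_table([_row("rs1", "G", "A", beta=0.05, eaf=0.7),
                          _row("rs2", "T", "C", beta=0.07, pos=2e6)], "out")
        h1 = harmonize(exp, out)
        # rebuild the outcome table in exposure orientation from h1
        aligned = exp.df.copy()
        aligned["beta"] = h1.pairs["beta_out"].to_numpy()
        out2 = AssociationTable("out", "quantitative", aligned)
        h2 = harmonize(exp, out2)
        assert (h2.pairs["action"] == "kept").all()
        assert np.array_equal(h2.pairs["beta_out"].to_numpy(),
                              h1.pairs["beta_out"].to_numpy())

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(st.lists(st.tuples(st.floats(-0.5, 0.5), st.floats(-0.5, 0.5)),
                    min_size=2, max_size=8))
    def test_flip_involution(self, betas):
        """Swapping every outcome allele pair (and beta sign) changes nothing."""
        exp = make_table([_row(f"rs{i}", "A", "G", beta=bx, pos=1e6 * (i + 1))
                          for i, (bx, _) in enumerate(betas)], "exp")
        out = make_table([_row(f"rs{i}", "A", "G", beta=by, pos=1e6 * (i + 1))
                          for i, (_, by) in enumerate(betas)], "out")
        flipped = out.df.copy()
        flipped[["effect_allele", "other_allele"]] = \
            flipped[["other_allele", "effect_allele"]].to_numpy()
        flipped["beta"] = -flipped["beta"]
        flipped["eaf"] = 1 - flipped["eaf"]
        out_flipped = AssociationTable("out", "quantitative", flipped)
        h1, h2 = harmonize(exp, out), harmonize(exp, out_flipped)
        r1, r2 = h1.retained, h2.retained
        assert np.array_equal(r1["beta_exp"].to_numpy(), r2["beta_exp"].to_numpy())
        assert np.array_equal(r1["beta_out"].to_numpy(), r2["beta_out"].to_numpy())
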