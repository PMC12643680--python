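"""Instrument selection: R²/F formulas, clumping, and the full pipeline."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mrmediate.iv_selection import (LDMatrix, PRESETS, SelectionParams, clump,
                                    f_statistic, read_ld, select_instruments,
                                    variance_explained, write_ld)
from .conftest import make_table


def _row(snp, p=1e-8, chrom="1", pos=1e6, beta=0.2, se=0.025, n=3757):
    return (snp, chrom, pos, "A", "G", 0.3, beta, se, p, n)


class TestStrengthFormulas:
    def test_zero_effect_explains_nothing(self):
        assert variance_explained(0.0, 0.02, 3757) == 0.0
        assert f_statistic(0.0, 3757) == 0.0

    @pytest.mark.parametrize("beta,se,n,expected", [
        (0.1, 0.02, 3757, 0.01 / (0.01 + 0.0004 * 3757)),
        (0.1, 0.1, 100, 0.01 / 1.01),
    ])
    def test_variance_explained_arithmetic(self, beta, se, n, expected):
        assert variance_explained(beta, se, n) == pytest.approx(expected,
                                                                rel=1e-12)

    def test_f_statistic_arithmetic(self):
        r2 = variance_explained(0.1, 0.02, 3757)
        assert r2 == pytest.approx(0.0066103, abs=5e-7)
        assert f_statistic(r2, 3757) == pytest.approx(
            r2 * 3755 / (1 - r2), rel=1e-12)
        assert f_statistic(r2, 3757) == pytest.approx(24.99, abs=0.02)

    def test_weak_instrument_boundary_at_f10(self):
        # r2 solving r2*3755/(1-r2) = 10 sits between these two values
        assert f_statistic(0.00266, 3757) > 10
        assert f_statistic(0.00265, 3757) < 10

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            variance_explained(0.1, 0.02, 2)
        with pytest.raises(ValueError):
            f_statistic(1.0, 100)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(st.floats(1e-6, 0.5), st.floats(1e-6, 0.5),
           st.integers(10, 10_000))
    def test_f_monotone_in_r2_and_n(self, r2a, r2b, n):
        lo, hi = sorted((r2a, r2b))
        if lo < hi:
            assert f_statistic(lo, n) < f_statistic(hi, n)
        assert f_statistic(hi, n) < f_statistic(hi, n + 1) or hi == 0


class TestLDMatrix:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            LDMatrix(["a", "b"], np.array([[1.0, 0.5], [0.4, 1.0]]))
        with pytest.raises(ValueError):
            LDMatrix(["a", "b"], np.array([[1.0, 1.5], [1.5, 1.0]]))

    def test_file_roundtrip_square_and_triplet(self, tmp_path):
        ld = LDMatrix(["rs1", "rs2"], np.array([[1.0, 0.25], [0.25, 1.0]]))
        sq = tmp_path / "ld.tsv"
        write_ld(ld, sq)
        back = read_ld(sq)
        assert back.snp_ids == ld.snp_ids
        assert np.allclose(back.r2, ld.r2)
        tri = tmp_path / "tri.tsv"
        tri.write_text("snp_a\tsnp_b\tr2\nrs1\trs2\t0.25\n")
        back2 = read_ld(tri)
        assert back2.lookup("rs1", "rs2") == 0.25


PARAMS = SelectionParams(p_threshold=1e-5, clump_r2=0.1, clump_window_kb=500)


class TestClump:
    def test_dominated_pair_keeps_lower_p(self):
        t = make_table([_row("rs1", p=1e-8, pos=1e6),
                        _row("rs2", p=1e-6, pos=1.1e6)])
        ld = LDMatrix(["rs1", "rs2"], np.array([[1, 0.5], [0.5, 1]], float))
        out = clump(t, ld, PARAMS)
        assert out.df["snp"].tolist() == ["rs1"]

    def test_outside_window_both_kept(self):
        t = make_table([_row("rs1", p=1e-8, pos=1e6),
                        _row("rs2", p=1e-6, pos=1.6e6)])
        ld = LDMatrix(["rs1", "rs2"], np.array([[1, 0.5], [0.5, 1]], float))
        out = clump(t, ld, PARAMS)
        assert out.df["snp"].tolist() == ["rs1", "rs2"]

    def test_cross_chromosome_never_clumps(self):
        t = make_table([_row("rs1", p=1e-8, chrom="1", pos=1e6),
                        _row("rs2", p=1e-6, chrom="2", pos=1e6)])
        ld = LDMatrix(["rs1", "rs2"], np.array([[1, 0.9], [0.9, 1]], float))
        assert len(clump(t, ld, PARAMS)) == 2

    def test_independent_snps_all_kept(self):
        rows = [_row(f"rs{i}", p=1e-7, pos=1e6 + i * 1e4) for i in range(6)]
        t = make_table(rows)
        out = clump(t, LDMatrix.identity(t.df["snp"]), PARAMS)
        assert len(out) == 6

    def test_greedy_maximality(self, rng):
        """No retained pair conflicts; every removed SNP conflicts with a
        retained SNP of smaller-or-equal p."""
        m = 15
        pos = rng.choice(np.arange(1e6, 5e6, 1e4), size=m, replace=False)
        corr = rng.uniform(0, 1, (m, m))
        r2 = np.clip((corr + corr.T) / 2, 0, 1)
        np.fill_diagonal(r2, 1.0)
        pvals = rng.uniform(1e-9, 1e-6, m)
        rows = [(f"rs{i:02d}", "1", pos[i], "A", "G", 0.3, 0.2, 0.025,
                 pvals[i], 3757) for i in range(m)]
        t = make_table(rows)
        ld = LDMatrix([f"rs{i:02d}" for i in range(m)], r2)
        kept = set(clump(t, ld, PARAMS).df["snp"])

        def conflict(i, j):
            return (abs(pos[i] - pos[j]) <= PARAMS.clump_window_kb * 1000
                    and r2[i, j] >= PARAMS.clump_r2)

        ids = t.df["snp"].tolist()
        for i in range(m):
            for j in range(i + 1, m):
                if ids[i] in kept and ids[j] in kept:
                    assert not conflict(i, j)
        for i in range(m):
            if ids[i] not in kept:
                assert any(ids[j] in kept and conflict(i, j)
                           and pvals[j] <= pvals[i] for j in range(m))


class TestSelectInstruments:
    def test_pipeline_counts(self):
        rows = ([_row(f"rs{i}", p=1e-8, pos=1e6 + i * 1e6) for i in range(10)]
                + [_row("rs_weakp", p=2e-5, pos=50e6)]          # fails p
                + [_row("rs_weakf", p=5e-6, pos=60e6, beta=0.01)])  # fails F
        t = make_table(rows)
        out = select_instruments(t, LDMatrix.identity(t.df["snp"]), PARAMS)
        assert len(out) == 10
        assert (out["f_stat"] >= 10).all()
        assert "rs_weakp" not in set(out["snp"])
        assert "rs_weakf" not in set(out["snp"])

    def test_order_invariance(self, rng):
        rows = [_row(f"rs{i}", p=10.0**-rng.uniform(6, 9), pos=1e6 + i * 1e5)
                for i in range(12)]
        t = make_table(rows)
        ld = LDMatrix.identity(t.df["snp"])
        base = select_instruments(t, ld, PARAMS)
        shuffled = t.df.sample(frac=1, random_state=1).reset_index(drop=True)
        t2 = make_table(list(shuffled.itertuples(index=False)))
        other = select_instruments(t2, ld, PARAMS)
        assert set(base["snp"]) == set(other["snp"])

    def test_snp_missing_from_ld_treated_independent(self, caplog):
        t = make_table([_row("rs1", p=1e-8, pos=1e6),
                        _row("rs_absent", p=1e-7, pos=1.05e6)])
        ld = LDMatrix(["rs1"], np.array([[1.0]]))
        with caplog.at_level("WARNING"):
            out = select_instruments(t, ld, PARAMS)
        assert len(out) == 2

    def test_presets_match_published_thresholds(self):
        assert PRESETS["immune"] == SelectionParams(1e-5, 0.1, 500.0, 10.0)
        assert PRESETS["cytokine_outcome"] == SelectionParams(
            5e-6, 0.001, 10_000.0, 10.0)
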