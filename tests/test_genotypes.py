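"""Recode / QC / imputation / VanRaden kinship / PCA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phsgp.genotypes import (
    EmptyPanelError,
    GenotypeMatrix,
    impute_missing,
    pca,
    qc_filter,
    recode_minor_allele,
    vanraden_grm,
)


def gm(dosages, **kw):
    d = np.asarray(dosages, dtype=float)
    return GenotypeMatrix(
        dosages=d,
        marker_ids=kw.pop("marker_ids", np.array([f"m{j}" for j in range(d.shape[1])])),
        line_ids=kw.pop("line_ids", np.array([f"l{i}" for i in range(d.shape[0])])),
        **kw,
    )


class TestRecode:
    def test_major_allele_column_is_flipped(self):
        g = recode_minor_allele(gm([[2], [2], [0]]))
        assert list(g.dosages[:, 0]) == [0.0, 0.0, 2.0]
        assert g.minor_coded

    def test_all_heterozygous_marker_unchanged_at_maf_half(self):
        g = recode_minor_allele(gm([[1], [1], [1]]))
        assert list(g.dosages[:, 0]) == [1.0, 1.0, 1.0]
        assert g.maf()[0] == 0.5

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_recode_is_idempotent(self, seed):
        rng = np.random.default_rng(seed)
        g = gm(rng.integers(0, 3, size=(10, 20)).astype(float))
        once = recode_minor_allele(g)
        twice = recode_minor_allele(once)
        np.testing.assert_array_equal(once.dosages, twice.dosages)
        assert (np.nanmean(once.dosages, axis=0) <= 1.0 + 1e-12).all()


class TestQcFilter:
    def test_monomorphic_marker_removed(self):
        g = gm([[0, 1], [0, 1], [0, 0], [0, 0]])
        out, rep = qc_filter(g, line_max_het=1.0)
        assert list(out.marker_ids) == ["m1"]
        assert rep.removed_maf == 1

    def test_duplicate_columns_collapsed_to_one(self):
        g = gm([[0, 0, 1], [1, 1, 0], [2, 2, 1], [0, 0, 2]])
        out, rep = qc_filter(g, line_max_het=1.0)
        assert rep.duplicates == 1
        assert out.n_markers == 2
        assert "m0" in out.marker_ids  # smallest id is the representative

    def test_hand_count_under_maf_rule(self):
        # 3 markers at MAF 0.005, 7 at 0.2, 100 lines, no missing
        rng = np.random.default_rng(0)
        cols = []
        for maf in [0.005] * 3 + [0.2] * 7:
            c = np.zeros(100)
            c[: int(round(200 * maf))] = 1.0
            cols.append(rng.permutation(c))
        out, rep = qc_filter(gm(np.column_stack(cols)), line_max_het=1.0)
        assert out.n_markers == 7
        assert rep.removed_maf == 3

    def test_line_with_excess_missingness_dropped(self):
        d = np.ones((5, 10))
        d[4, 1] = 0.0  # keep marker 1 polymorphic-ish for the others
        d[0, :3] = np.nan  # 30% missing
        out, rep = qc_filter(gm(d), maf_min=0.0, max_missing=0.5, line_max_het=1.0)
        assert rep.lines_removed_missing == 1
        assert "l0" not in out.line_ids

    def test_column_order_does_not_change_retained_set(self):
        rng = np.random.default_rng(3)
        d = rng.integers(0, 3, size=(30, 15)).astype(float)
        g = gm(d)
        out1, _ = qc_filter(g, line_max_het=1.0)
        perm = rng.permutation(15)
        g2 = GenotypeMatrix(
            dosages=d[:, perm],
            marker_ids=g.marker_ids[perm],
            line_ids=g.line_ids,
        )
        out2, _ = qc_filter(g2, line_max_het=1.0)
        assert set(out1.marker_ids) == set(out2.marker_ids)

    def test_everything_removed_is_a_distinct_error(self):
        with pytest.raises(EmptyPanelError):
            qc_filter(gm(np.zeros((4, 3))))


class TestImpute:
    def test_complete_matrix_returned_unchanged(self):
        g = gm([[0, 1], [2, 1]])
        assert impute_missing(g, seed=0) is g

    def test_degenerate_frequency_fills_deterministically(self):
        d = np.zeros((10, 2))
        d[0, 0] = np.nan
        d[:, 1] = 1.0
        out = impute_missing(gm(d), seed=5)
        assert out.dosages[0, 0] == 0.0

    def test_binomial_moment_at_half(self):
        d = np.ones((10_100, 2))
        d[100:, 0] = np.nan
        d[: 50, 0] = 0.0
        d[50:100, 0] = 2.0  # observed p_hat = 0.5
        out = impute_missing(gm(d), seed=9)
        imputed = out.dosages[100:, 0]
        se = np.sqrt(0.5 / len(imputed))  # sd of Binomial(2,1/2)/sqrt(n)
        assert abs(imputed.mean() - 1.0) < 3 * se

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(1)
        d = rng.integers(0, 3, size=(50, 20)).astype(float)
        d[rng.random(d.shape) < 0.1] = np.nan
        a = impute_missing(gm(d), seed=3)
        b = impute_missing(gm(d), seed=3)
        np.testing.assert_array_equal(a.dosages, b.dosages)

    def test_all_missing_marker_rejected(self):
        d = np.array([[np.nan, 1.0], [np.nan, 0.0]])
        with pytest.raises(ValueError, match="all calls missing"):
            impute_missing(gm(d), seed=0)


class TestVanRaden:
    def test_hand_example(self, tiny_genotypes):
        A = vanraden_grm(tiny_genotypes)
        np.testing.assert_allclose(
            A.values, [[2, -2, 0], [-2, 2, 0], [0, 0, 0]], atol=1e-12
        )
        assert A.denominator == pytest.approx(1.0)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.integers(0, 2**32 - 1))
    def test_matches_markerwise_accumulation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        g = gm(rng.integers(0, 3, size=(20, 50)).astype(float))
        A = vanraden_grm(g)
        p = g.dosages.mean(axis=0) / 2
        acc = np.zeros((20, 20))
        for j in range(50):
            z = g.dosages[:, j] - 2 * p[j]
            acc += np.outer(z, z)
        np.testing.assert_allclose(A.values, acc / (2 * np.sum(p * (1 - p))), atol=1e-10)
        # centering forces zero row sums; PSD up to round-off
        assert np.abs(A.values @ np.ones(20)).max() < 1e-8
        assert np.linalg.eigvalsh(A.values).min() > -1e-8

    def test_duplicated_lines_share_kinship_entries(self):
        rng = np.random.default_rng(2)
        d = rng.integers(0, 3, size=(6, 30)).astype(float)
        d[3] = d[0]
        A = vanraden_grm(gm(d))
        assert A.values[0, 0] == pytest.approx(A.values[0, 3], abs=1e-12)
        assert A.values[0, 0] == pytest.approx(A.values[3, 3], abs=1e-12)

    def test_monomorphic_panel_rejected(self):
        with pytest.raises(ValueError):
            vanraden_grm(gm(np.full((4, 3), 2.0)))

    def test_missing_values_rejected(self):
        d = np.array([[0.0, np.nan], [2.0, 1.0]])
        with pytest.raises(ValueError, match="impute"):
            vanraden_grm(gm(d))


class TestPca:
    def test_rank_one_matrix_explains_everything(self):
        d = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        res = pca(gm(d), k=1)
        assert res.explained_fraction[0] == pytest.approx(1.0)

    def test_k_beyond_rank_is_an_error(self):
        d = np.array([[0.0, 0.0], [1.0, 1.0], [2.0, 2.0]])
        with pytest.raises(ValueError, match="rank"):
            pca(gm(d), k=2)

    def test_no_structure_means_no_dominant_axis(self):
        from phsgp.synthetic import PopulationSpec, simulate_population

        spec = PopulationSpec(
            n_lines=100, programs=[("A", 50), ("B", 50)],
            season_split={"CS": 100, "VS15": 0, "VS16": 0},
            n_markers=500, structure_strength=0.0, seed=10,
        )
        res = pca(simulate_population(spec), k=2)
        assert res.explained_fraction[0] < 0.05
        assert res.explained_fraction[0] >= res.explained_fraction[1]

    def test_divergent_programs_separate_on_pc1(self):
        from phsgp.synthetic import PopulationSpec, simulate_population

        spec = PopulationSpec(
            n_lines=100, programs=[("A", 50), ("B", 50)],
            season_split={"CS": 100, "VS15": 0, "VS16": 0},
            n_markers=500, structure_strength=0.25, seed=10,
        )
        g = simulate_population(spec)
        res = pca(g, k=1)
        a = res.scores[g.program == "A", 0]
        b = res.scores[g.program == "B", 0]
        pooled_sd = np.sqrt((a.var() + b.var()) / 2)
        assert abs(a.mean() - b.mean()) > 2 * pooled_sd

    def test_variance_fractions_match_grm_eigenvalues(self, small_population):
        # centering by the column mean equals centering by 2p, so the PCA
        # spectrum is A's spectrum rescaled by the VanRaden denominator
        res = pca(small_population, k=3)
        A = vanraden_grm(small_population)
        ev = np.sort(np.linalg.eigvalsh(A.values))[::-1]
        np.testing.assert_allclose(res.explained_fraction, ev[:3] / ev.sum(), rtol=1e-8)
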