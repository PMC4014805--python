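"""Window correlation matrices, the eigen-score, scan, standardization,
and the permutation null."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from ldcontrast import (DatasetError, SimConfig, permutation_null,
                        raw_varld_score, scan, simulate_pair, standardize,
                        window_corr_matrix)
from ldcontrast.varld_core import VarLDTrack

from conftest import toy_dataset


def closed_form_eigs(mat):
    """Characteristic-polynomial eigenvalues (independent of eigvalsh)."""
    return np.sort(np.roots(np.poly(mat)).real)[::-1]


def sym(rng, d):
    x = rng.normal(size=(d, d))
    return (x + x.T) / 2.0


class TestWindowCorrMatrix:
    def test_duplicate_snp_gives_unit_entry(self):
        rng = np.random.default_rng(0)
        g = rng.integers(0, 3, size=(60, 5)).astype(float)
        g[:, 3] = g[:, 1]
        ds = toy_dataset(g)
        m = window_corr_matrix(ds, 0, 5)
        assert m[1, 3] == pytest.approx(1.0)
        np.testing.assert_allclose(np.diag(m), 1.0)
        np.testing.assert_allclose(m, m.T)

    def test_independent_snps_near_zero_offdiag(self):
        rng = np.random.default_rng(1)
        n = 400
        p = rng.uniform(0.2, 0.8, size=10)
        g = ((rng.random((n, 10)) < p).astype(float)
             + (rng.random((n, 10)) < p))
        m = window_corr_matrix(toy_dataset(g), 0, 10)
        off = m[~np.eye(10, dtype=bool)]
        assert np.abs(off).max() < 3 / np.sqrt(n)

    def test_eigenvalue_sum_equals_window_size(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(50, 20)).astype(float)
        m = window_corr_matrix(toy_dataset(g), 0, 20)
        assert np.linalg.eigvalsh(m).sum() == pytest.approx(20.0, abs=1e-10)

    def test_monomorphic_marker_raises_naming_it(self):
        g = np.array([[0.0, 1], [0, 2], [0, 1], [0, 0]])
        with pytest.raises(DatasetError, match="m0"):
            window_corr_matrix(toy_dataset(g), 0, 2)

    def test_window_across_chromosomes_raises(self, sim_pair_small):
        a, _, _ = sim_pair_small
        two = SimConfig(n_samples=(30, 30), n_chromosomes=2,
                        markers_per_chromosome=30, sweeps=(), seed=5)
        ds, _, _ = simulate_pair(two)
        with pytest.raises(DatasetError, match="chromosome"):
            window_corr_matrix(ds, 25, 10)


class TestRawScore:
    def test_identical_matrices_score_zero(self):
        rng = np.random.default_rng(3)
        a = sym(rng, 6)
        assert raw_varld_score(a, a) == 0.0

    def test_2x2_closed_form(self):
        a = np.array([[1.0, 0.5], [0.5, 1.0]])  # eigenvalues 1.5, 0.5
        b = np.eye(2)                            # eigenvalues 1, 1
        assert raw_varld_score(a, b) == pytest.approx(1.0, abs=1e-12)

    def test_sign_pattern_blind_after_ranking(self):
        a = np.array([[1.0, 1.0], [1.0, 1.0]])
        b = np.array([[1.0, -1.0], [-1.0, 1.0]])  # both spectra {2, 0}
        assert raw_varld_score(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_matches_characteristic_polynomial_oracle(self):
        rng = np.random.default_rng(4)
        for d in (2, 3):
            for _ in range(50):
                a, b = sym(rng, d), sym(rng, d)
                expect = np.abs(closed_form_eigs(a) - closed_form_eigs(b)).sum()
                assert raw_varld_score(a, b) == pytest.approx(expect, abs=1e-9)

    def test_dimension_mismatch_raises(self):
        with pytest.raises(ValueError):
            raw_varld_score(np.eye(2), np.eye(3))

    @given(st.integers(0, 10_000))
    def test_symmetry_nonnegativity_triangle(self, seed):
        rng = np.random.default_rng(seed)
        a, b, c = (sym(rng, 4) for _ in range(3))
        sab = raw_varld_score(a, b)
        assert sab == raw_varld_score(b, a)
        assert sab >= 0.0
        assert raw_varld_score(a, c) <= sab + raw_varld_score(b, c) + 1e-10


class TestScan:
    def test_window_count_arithmetic(self):
        rng = np.random.default_rng(6)
        g = rng.integers(0, 3, size=(80, 100)).astype(float)
        a, b = toy_dataset(g), toy_dataset(
            rng.integers(0, 3, size=(80, 100)).astype(float), population="POP2")
        track = scan(a, b, window_size=50, step=1)
        assert len(track.scores) == 100 - 50 + 1

    def test_mid_bp_is_mean_of_window_ends(self):
        rng = np.random.default_rng(7)
        g = rng.integers(0, 3, size=(50, 60)).astype(float)
        a = toy_dataset(g)
        b = toy_dataset(rng.integers(0, 3, size=(50, 60)).astype(float),
                        population="POP2")
        track = scan(a, b, window_size=10, step=1)
        row = track.scores.iloc[0]
        assert row["mid_bp"] == round((row["first_snp_bp"] + row["last_snp_bp"]) / 2)

    def test_scan_is_symmetric_in_populations(self, sim_pair_small):
        a, b, _ = sim_pair_small
        from ldcontrast.pipeline import run_comparison, _jointly_polymorphic
        from ldcontrast import intersect_common_snps
        oa, ob = intersect_common_snps(a, b)
        keep = _jointly_polymorphic(oa, ob)
        oa, ob = oa.select_markers(keep), ob.select_markers(keep)
        t1 = scan(oa, ob, window_size=20, step=37)
        t2 = scan(ob, oa, window_size=20, step=37)
        np.testing.assert_allclose(t1.scores["raw_score"], t2.scores["raw_score"],
                                   atol=1e-10)

    def test_marker_map_mismatch_raises(self):
        rng = np.random.default_rng(8)
        a = toy_dataset(rng.integers(0, 3, size=(30, 60)).astype(float))
        b = toy_dataset(rng.integers(0, 3, size=(30, 60)).astype(float),
                        population="POP2", spacing=1_001)
        with pytest.raises(ValueError, match="marker map"):
            scan(a, b)

    def test_short_chromosome_skipped_with_warning(self):
        rng = np.random.default_rng(9)
        a = toy_dataset(rng.integers(0, 3, size=(30, 20)).astype(float))
        b = toy_dataset(rng.integers(0, 3, size=(30, 20)).astype(float),
                        population="POP2")
        with pytest.raises(DatasetError):
            with pytest.warns(UserWarning, match="skipped"):
                scan(a, b, window_size=50)


class TestStandardize:
    def _track(self, raw):
        df = pd.DataFrame({
            "chromosome": "1",
            "first_snp_index": np.arange(len(raw)),
            "first_snp_bp": np.arange(len(raw)) + 1,
            "last_snp_bp": np.arange(len(raw)) + 10,
            "mid_bp": np.arange(len(raw)) + 5,
            "raw_score": np.asarray(raw, dtype=float),
            "std_score": np.nan,
        })
        return VarLDTrack("A/B", 10, 1, df)

    def test_three_window_example(self):
        out = standardize(self._track([1.0, 2.0, 3.0]))
        np.testing.assert_allclose(out.scores["std_score"], [-1.0, 0.0, 1.0])

    def test_mean_zero_sd_one_by_construction(self):
        rng = np.random.default_rng(10)
        out = standardize(self._track(rng.gamma(2.0, size=500)))
        s = out.scores["std_score"]
        assert s.mean() == pytest.approx(0.0, abs=1e-12)
        assert s.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_affine_invariance(self):
        rng = np.random.default_rng(11)
        raw = rng.gamma(2.0, size=100)
        s1 = standardize(self._track(raw)).scores["std_score"]
        s2 = standardize(self._track(3.5 * raw + 2.0)).scores["std_score"]
        np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_constant_track_raises(self):
        with pytest.raises(DatasetError, match="degenerate"):
            standardize(self._track([2.0, 2.0, 2.0]))


@pytest.fixture(scope="module")
def homogeneous_halves():
    cfg = SimConfig(n_samples=(60, 60), n_chromosomes=1,
                    markers_per_chromosome=500, sweeps=(),
                    switch_prob=(0.1, 0.1), missing_rate=0.0, seed=17)
    a, b, _ = simulate_pair(cfg)
    # two halves of ONE population: split a
    half1 = a.select_samples(np.arange(30))
    half2 = a.select_samples(np.arange(30, 60))
    from ldcontrast.pipeline import _jointly_polymorphic
    keep = _jointly_polymorphic(half1, half2)
    return half1.select_markers(keep), half2.select_markers(keep)


class TestPermutationNull:
    def test_same_seed_reproduces(self, homogeneous_halves):
        h1, h2 = homogeneous_halves
        p1 = permutation_null(h1, h2, n_perm=9, seed=5, window_size=20, step=20)
        p2 = permutation_null(h1, h2, n_perm=9, seed=5, window_size=20, step=20)
        pd.testing.assert_frame_equal(p1, p2)

    def test_null_pvalues_not_extreme(self, homogeneous_halves):
        h1, h2 = homogeneous_halves
        out = permutation_null(h1, h2, n_perm=49, seed=6, window_size=20, step=20)
        p = out["p_value"].to_numpy()
        assert (p >= 1 / 50).all() and (p <= 1.0).all()
        assert 0.25 < p.mean() < 0.75

    def test_sweep_window_has_minimal_pvalue(self):
        cfg = SimConfig(n_samples=(60, 60), n_chromosomes=1,
                        markers_per_chromosome=800,
                        sweeps=(__import__("ldcontrast").SweepSpec(
                            "1", 2_000_000, 2_300_000, "POP1", 2),),
                        missing_rate=0.0, seed=19)
        a, b, truth = simulate_pair(cfg)
        from ldcontrast.pipeline import _jointly_polymorphic
        from ldcontrast import intersect_common_snps
        oa, ob = intersect_common_snps(a, b)
        keep = _jointly_polymorphic(oa, ob)
        oa, ob = oa.select_markers(keep), ob.select_markers(keep)
        out = permutation_null(oa, ob, n_perm=99, seed=7, window_size=50, step=10)
        sweep = truth[0]
        in_sweep = ((out["first_snp_bp"] <= sweep.end_bp)
                    & (out["last_snp_bp"] >= sweep.start_bp))
        assert in_sweep.any()
        assert out.loc[in_sweep, "p_value"].min() == pytest.approx(1 / 100)

    def test_bad_n_perm_raises(self, homogeneous_halves):
        h1, h2 = homogeneous_halves
        with pytest.raises(ValueError):
            permutation_null(h1, h2, n_perm=0, seed=1)
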