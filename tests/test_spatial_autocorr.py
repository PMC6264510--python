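import numpy as np
import pytest

from aflpop import (
    ValidationError,
    autocorr_r,
    binary_squared_distance,
    bootstrap_ci,
    correlogram,
    double_center,
    make_distance_classes,
    permutation_null,
)
from aflpop.marker_data import filter_loci

from conftest import make_matrix, make_meta


def _geo(positions):
    p = np.asarray(positions, dtype=float)
    return np.abs(p[:, None] - p[None, :])


def _r_oracle(c, classes):
    """Explicit double-loop reimplementation of the class coefficient."""
    n = c.shape[0]
    out = []
    for h in range(classes.n_classes):
        num = 0.0
        den = 0.0
        for x in range(n):
            w = 0
            for y in range(n):
                if x != y and classes.class_of_pair[x, y] == h:
                    num += c[x, y]
                    w += 1
            den += w * c[x, x]
        out.append(num / den)
    return np.array(out)


class TestSquaredDistance:
    def test_hand_examples(self):
        x = np.array([[1, 1, 0, 0], [1, 0, 1, 0]])
        d2 = binary_squared_distance(x)
        assert d2[0, 1] == 2
        assert d2[0, 0] == 0

    def test_equals_mismatch_count_oracle(self, rng):
        x = (rng.random((10, 25)) < 0.5).astype(int)
        d2 = binary_squared_distance(x)
        for i in range(10):
            for j in range(10):
                assert d2[i, j] == int(np.sum(np.abs(x[i] - x[j])))


class TestDoubleCenter:
    def test_two_point_hand_computation(self):
        c = double_center(np.array([[0, 4], [4, 0]]))
        assert np.allclose(c, [[1, -1], [-1, 1]])

    def test_zeros_stay_zero(self):
        assert np.allclose(double_center(np.zeros((4, 4))), 0.0)

    def test_row_sums_vanish_on_random_input(self, rng):
        x = (rng.random((15, 40)) < 0.4).astype(int)
        c = double_center(binary_squared_distance(x))
        assert np.allclose(c.sum(axis=1), 0.0, atol=1e-9)
        assert np.allclose(c, c.T)


class TestDistanceClasses:
    def test_same_web_class_and_cross_class(self):
        geo = _geo([0.0, 0.0, 30.0, 30.0])
        spec = make_distance_classes(geo, [1.0, 50.0])
        assert spec.class_of_pair[0, 1] == 0
        assert spec.class_of_pair[0, 2] == 1
        assert spec.n_pairs.tolist() == [2, 4]

    def test_empty_class_strict_raises(self):
        geo = _geo([0.0, 0.0, 30.0])
        with pytest.raises(ValidationError, match="no pairs"):
            make_distance_classes(geo, [1.0, 5.0, 50.0], strict=True)

    def test_empty_class_merged_otherwise(self):
        geo = _geo([0.0, 0.0, 30.0])
        spec = make_distance_classes(geo, [1.0, 5.0, 50.0])
        assert spec.upper_bounds.tolist() == [1.0, 50.0]
        assert (spec.n_pairs > 0).all()

    def test_last_bound_auto_extended(self):
        geo = _geo([0.0, 0.0, 500.0])
        spec = make_distance_classes(geo, [1.0, 100.0])
        assert spec.upper_bounds[-1] >= 500.0

    def test_single_class_is_valid(self):
        geo = _geo([0.0, 10.0, 20.0])
        spec = make_distance_classes(geo, [100.0])
        assert spec.n_classes == 1 and spec.n_pairs[0] == 3

    def test_bounds_below_one_meter_rejected(self):
        with pytest.raises(ValidationError, match=">= 1 m"):
            make_distance_classes(_geo([0.0, 5.0]), [0.5, 10.0])


class TestAutocorrR:
    def test_clone_webs_give_r_one_within_webs(self):
        # two webs of two clones; every band differs between webs
        x = np.array([[1, 1, 0, 0]] * 2 + [[0, 0, 1, 1]] * 2)
        c = double_center(binary_squared_distance(x))
        spec = make_distance_classes(_geo([0, 0, 30, 30]), [1.0, 50.0])
        r = autocorr_r(c, spec)
        assert r[0] == pytest.approx(1.0, abs=1e-12)

    def test_two_points_single_pair_gives_minus_one(self):
        c = double_center(np.array([[0, 4], [4, 0]]))
        spec = make_distance_classes(_geo([0.0, 10.0]), [50.0])
        assert autocorr_r(c, spec)[0] == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("n", [3, 7, 16])
    def test_single_class_closed_form(self, rng, n):
        x = (rng.random((n, 30)) < 0.5).astype(int)
        c = double_center(binary_squared_distance(x))
        spec = make_distance_classes(_geo(rng.uniform(0, 100, n)), [1000.0])
        assert autocorr_r(c, spec)[0] == pytest.approx(-1.0 / (n - 1), abs=1e-12)

    def test_matches_double_loop_oracle(self, rng):
        for _ in range(10):
            n = int(rng.integers(6, 30))
            x = (rng.random((n, 20)) < 0.5).astype(int)
            c = double_center(binary_squared_distance(x))
            geo = _geo(rng.choice([0.0, 40.0, 90.0, 200.0], size=n))
            spec = make_distance_classes(geo, [1.0, 60.0, 300.0])
            assert np.allclose(autocorr_r(c, spec), _r_oracle(c, spec), atol=1e-12)


class TestBootstrapAndNull:
    def _clone_setup(self):
        x = np.array([[1, 1, 0, 0]] * 2 + [[0, 0, 1, 1]] * 2)
        c = double_center(binary_squared_distance(x))
        spec = make_distance_classes(_geo([0, 0, 30, 30]), [1.0, 50.0])
        return c, spec

    def test_zero_variance_class_has_degenerate_ci(self):
        c, spec = self._clone_setup()
        ci = bootstrap_ci(c, spec, n_boot=200, seed=0)
        assert ci[0, 0] == pytest.approx(1.0) and ci[0, 1] == pytest.approx(1.0)

    def test_bootstrap_seed_reproducible(self, rng):
        x = (rng.random((12, 30)) < 0.5).astype(int)
        c = double_center(binary_squared_distance(x))
        spec = make_distance_classes(_geo(rng.uniform(0, 100, 12)), [1.0, 200.0])
        assert np.array_equal(
            bootstrap_ci(c, spec, 100, seed=5), bootstrap_ci(c, spec, 100, seed=5)
        )

    def test_bootstrap_ci_brackets_point_estimate(self, rng):
        hits = 0
        for k in range(20):
            x = (np.random.default_rng(k).random((14, 40)) < 0.5).astype(int)
            c = double_center(binary_squared_distance(x))
            geo = _geo(np.random.default_rng(100 + k).choice([0.0, 50.0, 120.0], 14))
            spec = make_distance_classes(geo, [1.0, 80.0, 200.0])
            r = autocorr_r(c, spec)
            ci = bootstrap_ci(c, spec, 500, seed=k)
            hits += np.all((ci[:, 0] <= r + 1e-9) & (r - 1e-9 <= ci[:, 1]))
        assert hits >= 19

    def test_null_degenerate_when_single_location(self, rng):
        x = (rng.random((8, 30)) < 0.5).astype(int)
        c = double_center(binary_squared_distance(x))
        spec = make_distance_classes(_geo([0.0] * 8), [1.0])
        r = autocorr_r(c, spec)
        ci, null = permutation_null(c, spec, 99, seed=1)
        assert np.allclose(null, r[0])

    def test_null_seed_reproducible(self, rng):
        x = (rng.random((10, 30)) < 0.5).astype(int)
        c = double_center(binary_squared_distance(x))
        spec = make_distance_classes(_geo(rng.uniform(0, 100, 10)), [1.0, 200.0])
        a = permutation_null(c, spec, 50, seed=9)
        b = permutation_null(c, spec, 50, seed=9)
        assert np.array_equal(a[1], b[1])


class TestCorrelogram:
    def test_kin_structured_webs_show_same_web_signal(self, sib_dataset):
        m, _ = filter_loci(sib_dataset.matrix)
        meta = sib_dataset.meta[
            sib_dataset.meta.individual_id.isin(m.individual_ids)
        ]
        cg = correlogram(m, meta, bounds=[1.0, 300.0, 1100.0],
                         n_boot=200, n_perm=199, seed=7)
        t = cg.table
        assert t.loc[0, "r"] > 0
        assert bool(t.loc[0, "significant"])
        assert t.loc[0, "r"] > t.loc[len(t) - 1, "r"]  # decays with distance

    def test_panmictic_data_mostly_unflagged(self, panmictic_dataset):
        m, _ = filter_loci(panmictic_dataset.matrix)
        meta = panmictic_dataset.meta[
            panmictic_dataset.meta.individual_id.isin(m.individual_ids)
        ]
        cg = correlogram(m, meta, bounds=[1.0, 300.0, 1100.0],
                         n_boot=200, n_perm=199, seed=8)
        assert cg.table["significant"].sum() <= 1

    def test_web_level_null_fixes_same_web_class(self, sib_dataset):
        # shuffling whole webs across positions cannot move same-web
        # pairs (they stay at distance 0), so the class-1 null is
        # degenerate at the observed r while cross-web classes vary
        from aflpop import permutation_null_webs
        from aflpop.marker_data import align_metadata

        m, _ = filter_loci(sib_dataset.matrix)
        meta = align_metadata(
            sib_dataset.meta[
                sib_dataset.meta.individual_id.isin(m.individual_ids)
            ],
            m,
        )
        from aflpop.marker_data import geo_distance_matrix

        geo = geo_distance_matrix(meta)
        spec = make_distance_classes(geo, [1.0, 300.0, 1100.0])
        c = double_center(binary_squared_distance(m))
        r = autocorr_r(c, spec)
        _, null = permutation_null_webs(c, meta, spec, n_perm=49, seed=2)
        assert np.allclose(null[:, 0], r[0])
        assert np.nanstd(null[:, 1]) > 0

    def test_tiny_stratum_refused(self):
        ids = [f"i{k}" for k in range(6)]
        m = make_matrix(np.tile([[1, 0, 1], [0, 1, 0]], (3, 1)), ids)
        ages = ["adult"] * 5 + ["instar1"]
        meta = make_meta(ids, ["w1"] * 3 + ["w2"] * 3, ages,
                         ["female"] * 6)
        with pytest.raises(ValidationError, match="need >= 4"):
            correlogram(m, meta, stratum="juveniles", n_boot=10, n_perm=10)
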