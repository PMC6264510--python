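import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aflpop import (
    EmptyDataError,
    ParseError,
    ValidationError,
    filter_loci,
    filter_webs,
    geo_distance_matrix,
    read_binary_matrix,
    stratify,
    to_planar,
)
from aflpop.marker_data import JUVENILE_CLASSES, align_metadata

from conftest import make_matrix, make_meta


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

class TestReadBinaryMatrix:
    def test_minimal_parse_preserves_order(self, tmp_path):
        p = tmp_path / "m.csv"
        p.write_text("id,l1,l2\na,1,0\nb,0,1\n")
        m = read_binary_matrix(p)
        assert m.individual_ids == ["a", "b"]
        assert m.locus_ids == ["l1", "l2"]
        assert m.values.tolist() == [[1, 0], [0, 1]]

    def test_round_trip(self, tmp_path, rng):
        m = make_matrix(rng.integers(0, 2, size=(7, 9)))
        p = tmp_path / "m.csv"
        m.to_csv(p)
        back = read_binary_matrix(p)
        assert back.individual_ids == m.individual_ids
        assert back.locus_ids == m.locus_ids
        assert np.array_equal(back.values, m.values)

    def test_non_binary_cell_names_row_and_column(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("id,l1,l2\na,1,0\nb,2,1\n")
        with pytest.raises(ParseError, match="'b'.*'l1'"):
            read_binary_matrix(p)

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("id,l1\na,1\na,0\n")
        with pytest.raises(ValidationError, match="duplicate"):
            read_binary_matrix(p)

    def test_non_binary_value_in_constructor(self):
        with pytest.raises(ValidationError, match="non-binary"):
            make_matrix([[0, 2], [1, 0]])


# ---------------------------------------------------------------------------
# locus filter
# ---------------------------------------------------------------------------

class TestFilterLoci:
    def test_presence_count_rule(self):
        # n=5; locus presence counts 0,1,2,4,5 -> only c=2 is informative
        # (c=4 = n-1 is a reverse singleton)
        v = np.zeros((5, 5), dtype=int)
        v[:1, 1] = 1  # c=1
        v[:2, 2] = 1  # c=2
        v[:4, 3] = 1  # c=4
        v[:, 4] = 1   # c=5
        m = make_matrix(v)
        out, report = filter_loci(m, drop_empty_individuals=False)
        assert out.locus_ids == ["l2"]
        assert report.n_dropped_invariant == 2
        assert report.n_dropped_singleton == 2

    def test_identity_when_all_informative(self):
        v = np.array([[1, 1, 0, 0, 1, 0]] * 3 + [[0, 0, 1, 1, 0, 1]] * 3).T
        m = make_matrix(v)  # every locus c=3 of n=6
        out, report = filter_loci(m)
        assert out.n_loci == m.n_loci
        assert report.n_individuals_out == m.n_individuals

    def test_all_invariant_raises(self):
        with pytest.raises(EmptyDataError):
            filter_loci(make_matrix(np.ones((4, 3), dtype=int)))

    def test_drops_bandless_individuals(self):
        v = np.array([
            [1, 1, 0],
            [1, 0, 0],
            [1, 0, 0],
            [0, 1, 0],
            [0, 1, 0],
            [0, 0, 1],  # only carries the singleton locus l2
        ])
        out, report = filter_loci(make_matrix(v))
        assert "i5" in report.dropped_individuals
        assert "i5" not in out.individual_ids
        assert out.n_loci == 2

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**60))
    def test_idempotent_and_bounds(self, seed):
        rng = np.random.default_rng(seed)
        v = (rng.random((8, 20)) < rng.uniform(0.05, 0.95, size=20)).astype(int)
        m = make_matrix(v)
        try:
            once, _ = filter_loci(m)
        except EmptyDataError:
            return
        twice, rep2 = filter_loci(once)
        assert twice.locus_ids == once.locus_ids
        assert twice.individual_ids == once.individual_ids
        c = once.presence_counts()
        n = once.n_individuals
        assert c.min() >= 2 and c.max() <= n - 2
        assert (once.values.sum(axis=1) > 0).all()


# ---------------------------------------------------------------------------
# web filter
# ---------------------------------------------------------------------------

class TestFilterWebs:
    def _setup(self):
        ids = [f"i{k}" for k in range(8)]
        webs = ["w1"] + ["w2"] * 2 + ["w3"] * 5
        m = make_matrix(np.tile([[1, 0, 1, 0], [0, 1, 0, 1]], (4, 1))[:8], ids)
        return m, make_meta(ids, webs)

    def test_single_occupant_webs_removed(self):
        m, meta = self._setup()
        out, meta_out = filter_webs(m, meta, 2)
        assert "i0" not in out.individual_ids
        assert set(meta_out.web_id) == {"w2", "w3"}

    def test_min_size_three_for_relatedness(self):
        m, meta = self._setup()
        out, meta_out = filter_webs(m, meta, 3)
        assert set(meta_out.web_id) == {"w3"}
        assert out.n_individuals == 5

    def test_min_size_one_is_identity(self):
        m, meta = self._setup()
        out, _ = filter_webs(m, meta, 1)
        assert out.individual_ids == m.individual_ids


# ---------------------------------------------------------------------------
# UTM projection
# ---------------------------------------------------------------------------

def _snyder_utm(lat, lon):
    """Independent transverse-Mercator oracle (Snyder 1987 series)."""
    a = 6378137.0
    f = 1 / 298.257223563
    k0 = 0.9996
    e2 = f * (2 - f)
    ep2 = e2 / (1 - e2)
    zone = int(math.floor((lon + 180) / 6)) % 60 + 1
    lon0 = math.radians(zone * 6 - 183)
    phi = math.radians(lat)
    lam = math.radians(lon) - lon0
    N = a / math.sqrt(1 - e2 * math.sin(phi) ** 2)
    T = math.tan(phi) ** 2
    C = ep2 * math.cos(phi) ** 2
    A = lam * math.cos(phi)
    M = a * (
        (1 - e2 / 4 - 3 * e2**2 / 64 - 5 * e2**3 / 256) * phi
        - (3 * e2 / 8 + 3 * e2**2 / 32 + 45 * e2**3 / 1024) * math.sin(2 * phi)
        + (15 * e2**2 / 256 + 45 * e2**3 / 1024) * math.sin(4 * phi)
        - (35 * e2**3 / 3072) * math.sin(6 * phi)
    )
    x = (
        k0 * N * (A + (1 - T + C) * A**3 / 6
                  + (5 - 18 * T + T**2 + 72 * C - 58 * ep2) * A**5 / 120)
        + 500000
    )
    y = k0 * (
        M
        + N * math.tan(phi) * (
            A**2 / 2
            + (5 - T + 9 * C + 4 * C**2) * A**4 / 24
            + (61 - 58 * T + T**2 + 600 * C - 330 * ep2) * A**6 / 720
        )
    )
    if lat < 0:
        y += 10000000.0
    return x, y


class TestToPlanar:
    @pytest.mark.parametrize(
        "lat,lon",
        [
            (24.364167, 120.738889),  # subtropical forest site
            (1.406667, 103.966111),   # equatorial island site
            (38.9495, -95.268694),    # temperate site, western hemisphere
            (-33.9, 18.4),            # southern hemisphere
        ],
    )
    def test_matches_independent_series(self, lat, lon):
        e, n, _ = to_planar(lat, lon)
        xs, ys = _snyder_utm(lat, lon)
        assert abs(float(e[0]) - xs) < 0.01
        assert abs(float(n[0]) - ys) < 0.01

    def test_meridian_kilometer(self):
        # two points 1 geodesic km apart along one meridian project to a
        # planar separation within 1 m of 1000 m
        lat0, lon0 = 24.3, 121.0
        a, f = 6378137.0, 1 / 298.257223563
        e2 = f * (2 - f)
        M = a * (1 - e2) / (1 - e2 * math.sin(math.radians(lat0)) ** 2) ** 1.5
        dlat = math.degrees(1000.0 / M)
        e, n, _ = to_planar([lat0, lat0 + dlat], [lon0, lon0])
        d = math.hypot(e[1] - e[0], n[1] - n[0])
        assert abs(d - 1000.0) < 1.0

    def test_deterministic(self):
        a = to_planar(24.1, 120.9)
        b = to_planar(24.1, 120.9)
        assert a[0] == b[0] and a[1] == b[1] and a[2] == b[2]

    def test_domain_errors(self):
        with pytest.raises(ValidationError):
            to_planar(95.0, 10.0)
        with pytest.raises(ValidationError):
            to_planar(10.0, 200.0)

    def test_zone_straddle_rejected(self):
        with pytest.raises(ValidationError, match="zone"):
            to_planar([24.0, 24.0], [119.9, 120.1])  # 119.9 -> 50, 120.1 -> 51


class TestGeoDistance:
    def test_same_web_zero_and_345(self):
        meta = make_meta(["a", "b", "c"], ["w1", "w1", "w2"],
                         positions=[0.0, 0.0, 30.0])
        meta.loc[2, "northing"] = 40.0
        d = geo_distance_matrix(meta)
        assert d[0, 1] == 0.0
        assert d[0, 2] == pytest.approx(50.0)

    def test_symmetry_and_triangle_inequality(self, rng):
        meta = make_meta(
            [f"i{k}" for k in range(12)], [f"w{k}" for k in range(12)],
            positions=rng.uniform(0, 1000, 12),
        )
        meta["northing"] = rng.uniform(0, 50, 12)
        d = geo_distance_matrix(meta)
        assert np.allclose(d, d.T)
        assert np.all(np.diag(d) == 0)
        brute = np.array(
            [[math.hypot(*(meta.iloc[i][["easting", "northing"]]
                           - meta.iloc[j][["easting", "northing"]]))
              for j in range(12)] for i in range(12)]
        )
        assert np.allclose(d, brute)
        for i in range(12):
            for j in range(12):
                for k in range(12):
                    assert d[i, j] <= d[i, k] + d[k, j] + 1e-6


# ---------------------------------------------------------------------------
# strata
# ---------------------------------------------------------------------------

class TestStratify:
    def _meta(self):
        ages = ["instar1", "instar2", "instar3", "instar4", "adult", "adult"]
        sexes = ["unknown", "unknown", "male", "male", "female", "male"]
        return make_meta([f"i{k}" for k in range(6)], ["w"] * 6, ages, sexes)

    def test_juveniles_are_first_three_instars(self):
        assert stratify(self._meta(), "juveniles") == ["i0", "i1", "i2"]
        assert JUVENILE_CLASSES == {"instar1", "instar2", "instar3"}

    def test_sex_strata_cover_matures_only(self):
        meta = self._meta()
        assert stratify(meta, "males") == ["i3", "i5"]
        assert stratify(meta, "females") == ["i4"]

    def test_three_strata_partition_everyone(self):
        meta = self._meta()
        union = (
            set(stratify(meta, "juveniles"))
            | set(stratify(meta, "males"))
            | set(stratify(meta, "females"))
        )
        assert union == set(meta.individual_id)

    def test_empty_stratum_warns_not_fatal(self, caplog):
        meta = make_meta(["a"], ["w"], ["instar1"], ["unknown"])
        with caplog.at_level("WARNING"):
            assert stratify(meta, "adults") == []
        assert any("matched no individuals" in r.message for r in caplog.records)

    def test_custom_juvenile_mapping(self):
        meta = self._meta()
        ids = stratify(meta, "juveniles",
                       juvenile_classes=("instar1", "instar2"))
        assert ids == ["i0", "i1"]


def test_align_metadata_orders_rows():
    ids = ["a", "b", "c"]
    m = make_matrix(np.eye(3, 4, dtype=int) + np.eye(3, 4, k=1, dtype=int), ids)
    meta = make_meta(["c", "a", "b"], ["w1", "w1", "w1"])
    out = align_metadata(meta, m)
    assert out.individual_id.tolist() == ids
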