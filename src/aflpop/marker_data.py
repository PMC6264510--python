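"""Binary dominant-marker matrices and per-individual metadata.

AFLP-style fingerprinting scores every individual at every locus as band
present (1) or absent (0).  This module owns the on-disk formats (matrix
CSV with a header row of locus ids and a first column of individual ids;
metadata CSV with web assignment, age class, sex and coordinates), the
locus/web filtering rules applied before any analysis, the WGS84 -> UTM
planar projection, and pairwise geographic distances.

Filtering rules
---------------
A locus is informative only if its band is neither (nearly) fixed nor a
singleton: with ``n`` individuals, the presence count ``c`` must satisfy
``2 <= c <= n - 2``.  Invariant loci, single-carrier loci and loci absent
from exactly one individual carry no reproducible signal for band-sharing
statistics.  Webs (host-web groups) below a minimum size are excluded from
group-level analyses; relatedness permutation tests additionally require
at least 3 members per web.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import EmptyDataError, ParseError, ValidationError

logger = logging.getLogger(__name__)

AGE_CLASSES = ("instar1", "instar2", "instar3", "instar4", "adult", "unknown")
SEXES = ("male", "female", "unknown")

#: Age classes treated as juveniles (pre-sub-adult).  Instar 3 is the first
#: sexable stage but is grouped with juveniles; instar 4 ("sub-adult") and
#: adults form the mature stratum.  Override via ``stratify(..., juvenile_classes=...)``.
JUVENILE_CLASSES = frozenset({"instar1", "instar2", "instar3"})
MATURE_CLASSES = frozenset({"instar4", "adult"})

META_COLUMNS = ("individual_id", "web_id", "age_class", "sex", "easting", "northing")


# ---------------------------------------------------------------------------
# MarkerMatrix
# ---------------------------------------------------------------------------

@dataclass
class MarkerMatrix:
    """Individuals x loci binary band-phenotype matrix.

    Parameters
    ----------
    individual_ids
        Ordered unique row labels.
    locus_ids
        Ordered unique column labels.
    values
        ``(n_individuals, n_loci)`` array of 0/1 entries.
    """

    individual_ids: list[str]
    locus_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.individual_ids = [str(i) for i in self.individual_ids]
        self.locus_ids = [str(l) for l in self.locus_ids]
        self.values = np.asarray(self.values)
        self.validate()
        self.values = self.values.astype(np.int8)

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        v = self.values
        if v.ndim != 2:
            raise ValidationError("marker values must be a 2-D array")
        n, L = v.shape
        if n != len(self.individual_ids) or L != len(self.locus_ids):
            raise ValidationError(
                f"shape {v.shape} does not match id lists "
                f"({len(self.individual_ids)} individuals, {len(self.locus_ids)} loci)"
            )
        if len(set(self.individual_ids)) != n:
            raise ValidationError("duplicate individual ids")
        if len(set(self.locus_ids)) != L:
            raise ValidationError("duplicate locus ids")
        bad = ~np.isin(v, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-binary entry {v[i, j]!r} at individual "
                f"{self.individual_ids[i]!r}, locus {self.locus_ids[j]!r}"
            )

    @property
    def n_individuals(self) -> int:
        return self.values.shape[0]

    @property
    def n_loci(self) -> int:
        return self.values.shape[1]

    def presence_counts(self) -> np.ndarray:
        """Per-locus number of individuals carrying the band."""
        return self.values.sum(axis=0)

    def band_frequencies(self) -> np.ndarray:
        """Per-locus band (phenotype) frequency = presence count / n."""
        return self.values.mean(axis=0)

    def subset_individuals(self, ids: Sequence[str]) -> "MarkerMatrix":
        idx = _indices_for(self.individual_ids, ids)
        return MarkerMatrix(
            [self.individual_ids[i] for i in idx], list(self.locus_ids), self.values[idx]
        )

    def subset_loci(self, keep: np.ndarray) -> "MarkerMatrix":
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return MarkerMatrix(
            list(self.individual_ids),
            [self.locus_ids[j] for j in keep],
            self.values[:, keep],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.individual_ids, name="individual_id"),
            columns=self.locus_ids,
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


def _indices_for(universe: Sequence[str], wanted: Sequence[str]) -> list[int]:
    pos = {x: i for i, x in enumerate(universe)}
    missing = [w for w in wanted if w not in pos]
    if missing:
        raise ValidationError(f"unknown individual ids: {missing[:5]}")
    return [pos[w] for w in wanted]


def read_binary_matrix(path, *, id_column: int = 0) -> MarkerMatrix:
    """Read a binary marker matrix CSV.

    Layout: header row of locus ids; column ``id_column`` carries the
    individual ids; every remaining cell must parse to 0 or 1.  Row and
    column order of the file is preserved.
    """
    df = pd.read_csv(path, index_col=id_column, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate individual ids in {path}: {dups[:5]}")
    values = np.empty(df.shape, dtype=np.int8)
    raw = df.to_numpy()
    for i in range(df.shape[0]):
        for j in range(df.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell == "0":
                values[i, j] = 0
            elif cell == "1":
                values[i, j] = 1
            else:
                raise ParseError(
                    f"non-binary cell {raw[i, j]!r} at row {df.index[i]!r}, "
                    f"column {df.columns[j]!r} of {path}"
                )
    return MarkerMatrix(list(df.index.astype(str)), list(df.columns.astype(str)), values)


# ---------------------------------------------------------------------------
# Locus / individual / web filters
# ---------------------------------------------------------------------------

@dataclass
class FilterReport:
    """Counts of data removed by :func:`filter_loci`."""

    n_loci_in: int
    n_loci_out: int
    n_dropped_invariant: int
    n_dropped_singleton: int
    n_individuals_in: int
    n_individuals_out: int
    dropped_individuals: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


def filter_loci(
    m: MarkerMatrix, *, drop_empty_individuals: bool = True
) -> tuple[MarkerMatrix, FilterReport]:
    """Keep loci whose presence count ``c`` satisfies ``2 <= c <= n - 2``.

    Invariant loci (c = 0 or c = n) and singleton loci (c = 1 or c = n - 1)
    are discarded.  Individuals whose retained profile is all-zero are then
    dropped (a bandless profile makes band-sharing dissimilarity undefined;
    it is read as a failed fingerprint) unless ``drop_empty_individuals`` is
    False.  The filter iterates to a fixed point, so it is idempotent even
    when dropping individuals tightens the upper bound ``n - 2``.
    """
    ids = list(m.individual_ids)
    values = m.values
    loci = list(m.locus_ids)
    n_inv = n_single = 0
    dropped_ids: list[str] = []

    while True:
        n = values.shape[0]
        c = values.sum(axis=0)
        invariant = (c == 0) | (c == n)
        singleton = (~invariant) & ((c == 1) | (c == n - 1))
        keep = ~(invariant | singleton)
        n_inv += int(invariant.sum())
        n_single += int(singleton.sum())
        values = values[:, keep]
        loci = [l for l, k in zip(loci, keep) if k]
        if values.shape[1] == 0:
            raise EmptyDataError(
                "no informative loci remain after removing invariant and singleton loci"
            )
        if drop_empty_individuals:
            empty = values.sum(axis=1) == 0
            if empty.any():
                dropped_ids += [i for i, e in zip(ids, empty) if e]
                ids = [i for i, e in zip(ids, empty) if not e]
                values = values[~empty]
                continue  # n changed; re-check the c <= n - 2 bound
        if keep.all():
            break

    out = MarkerMatrix(ids, loci, values)
    report = FilterReport(
        n_loci_in=m.n_loci,
        n_loci_out=out.n_loci,
        n_dropped_invariant=n_inv,
        n_dropped_singleton=n_single,
        n_individuals_in=m.n_individuals,
        n_individuals_out=out.n_individuals,
        dropped_individuals=dropped_ids,
    )
    if dropped_ids:
        logger.info("filter_loci dropped all-zero individuals: %s", dropped_ids)
    return out, report


# ---------------------------------------------------------------------------
# Metadata
# ---------------------------------------------------------------------------

def read_metadata(path) -> pd.DataFrame:
    """Read per-individual metadata CSV.

    Required columns: ``individual_id, web_id, age_class, sex`` plus either
    ``easting, northing`` (meters) or ``lat, lon`` (degrees, converted to
    UTM here).  Returns a DataFrame with the canonical columns of
    ``META_COLUMNS``.
    """
    df = pd.read_csv(path, dtype={"individual_id": str, "web_id": str})
    for col in ("individual_id", "web_id", "age_class", "sex"):
        if col not in df.columns:
            raise ParseError(f"metadata file {path} lacks required column {col!r}")
    if {"easting", "northing"}.issubset(df.columns):
        pass
    elif {"lat", "lon"}.issubset(df.columns):
        east, north, zone = to_planar(df["lat"].to_numpy(), df["lon"].to_numpy())
        df["easting"], df["northing"] = east, north
        logger.info("metadata coordinates projected to UTM zone %s", zone)
    else:
        raise ParseError(
            f"metadata file {path} needs either easting/northing or lat/lon columns"
        )
    meta = df[list(META_COLUMNS)].copy()
    validate_metadata(meta)
    return meta


def validate_metadata(meta: pd.DataFrame, matrix: MarkerMatrix | None = None) -> None:
    if meta["individual_id"].duplicated().any():
        raise ValidationError("duplicate individual_id rows in metadata")
    bad_age = ~meta["age_class"].isin(AGE_CLASSES)
    if bad_age.any():
        raise ValidationError(
            f"unknown age_class values: {sorted(meta.loc[bad_age, 'age_class'].unique())}"
        )
    bad_sex = ~meta["sex"].isin(SEXES)
    if bad_sex.any():
        raise ValidationError(
            f"unknown sex values: {sorted(meta.loc[bad_sex, 'sex'].unique())}"
        )
    coords = meta[["easting", "northing"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        ids = meta.loc[~np.isfinite(coords).all(axis=1), "individual_id"].tolist()
        raise ValidationError(f"non-finite coordinates for individuals: {ids[:5]}")
    # all members of one web share the (GPS-recorded) web position
    for web, grp in meta.groupby("web_id"):
        xy = grp[["easting", "northing"]].to_numpy(dtype=float)
        if not np.allclose(xy, xy[0], atol=1e-6):
            raise ValidationError(f"web {web!r} has inconsistent coordinates")
    if matrix is not None:
        have = set(meta["individual_id"])
        missing = [i for i in matrix.individual_ids if i not in have]
        if missing:
            raise ValidationError(f"metadata missing for individuals: {missing[:5]}")


def align_metadata(meta: pd.DataFrame, matrix: MarkerMatrix) -> pd.DataFrame:
    """Return metadata rows re-ordered to match ``matrix.individual_ids``."""
    validate_metadata(meta, matrix)
    indexed = meta.set_index("individual_id")
    out = indexed.loc[matrix.individual_ids].reset_index()
    return out[list(META_COLUMNS)]


def filter_webs(
    m: MarkerMatrix, meta: pd.DataFrame, min_size: int = 2
) -> tuple[MarkerMatrix, pd.DataFrame]:
    """Drop individuals whose web holds fewer than ``min_size`` members.

    ``min_size=2`` reproduces the group-analysis rule (webs with a single
    occupant are uninformative about groups); relatedness permutation tests
    use ``min_size=3``.  Web sizes are counted among individuals present in
    the matrix.
    """
    if min_size < 1:
        raise ValidationError("min_size must be >= 1")
    meta = align_metadata(meta, m)
    sizes = meta.groupby("web_id")["individual_id"].transform("size")
    keep = sizes >= min_size
    if not keep.any():
        logger.warning("filter_webs(min_size=%d) removed every individual", min_size)
    kept_ids = meta.loc[keep, "individual_id"].tolist()
    out_m = m.subset_individuals(kept_ids)
    out_meta = meta.loc[keep].reset_index(drop=True)
    return out_m, out_meta


# ---------------------------------------------------------------------------
# WGS84 -> UTM projection (Krüger series) and planar distances
# ---------------------------------------------------------------------------

_WGS84_A = 6378137.0
_WGS84_F = 1.0 / 298.257223563
_UTM_K0 = 0.9996
_UTM_FALSE_E = 500000.0
_UTM_FALSE_N_SOUTH = 10000000.0


def _utm_zone(lon: float) -> int:
    return int(math.floor((lon + 180.0) / 6.0)) % 60 + 1


def to_planar(lat, lon) -> tuple[np.ndarray, np.ndarray, str]:
    """Project WGS84 geographic coordinates to UTM easting/northing (meters).

    Transverse-Mercator forward projection via the 4th-order Krüger
    alpha-series (accurate to well under a millimeter at study-site
    scales).  All points must fall in a single UTM zone and hemisphere;
    study sites straddling a zone boundary need a local planar projection
    instead and raise ``ValidationError``.
    """
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    if lat.shape != lon.shape:
        raise ValidationError("lat and lon must have the same shape")
    if np.any((lat < -90) | (lat > 90)):
        raise ValidationError("latitude outside [-90, 90]")
    if np.any((lon < -180) | (lon > 180)):
        raise ValidationError("longitude outside [-180, 180]")

    zones = {_utm_zone(x) for x in lon.ravel()}
    if len(zones) != 1:
        raise ValidationError(
            f"points span UTM zones {sorted(zones)}; use a local planar "
            "projection for sites crossing a zone boundary"
        )
    zone = zones.pop()
    south = bool(np.all(lat < 0))
    if not south and np.any(lat < 0):
        raise ValidationError("points span the equator; choose one hemisphere")

    lon0 = math.radians(zone * 6 - 183)
    phi = np.radians(lat)
    lam = np.radians(lon) - lon0

    f = _WGS84_F
    n = f / (2.0 - f)
    n2, n3, n4 = n * n, n**3, n**4
    # rectifying-sphere radius and series coefficients (Krüger, order n^4)
    A = _WGS84_A / (1 + n) * (1 + n2 / 4 + n4 / 64)
    alpha = (
        n / 2 - 2 * n2 / 3 + 5 * n3 / 16 + 41 * n4 / 180,
        13 * n2 / 48 - 3 * n3 / 5 + 557 * n4 / 1440,
        61 * n3 / 240 - 103 * n4 / 140,
        49561 * n4 / 161280,
    )

    e = math.sqrt(f * (2 - f))
    t = np.sinh(np.arctanh(np.sin(phi)) - e * np.arctanh(e * np.sin(phi)))
    xi = np.arctan2(t, np.cos(lam))
    eta = np.arctanh(np.sin(lam) / np.sqrt(1 + t * t))

    xi_s, eta_s = xi.copy(), eta.copy()
    for j, a_j in enumerate(alpha, start=1):
        xi_s += a_j * np.sin(2 * j * xi) * np.cosh(2 * j * eta)
        eta_s += a_j * np.cos(2 * j * xi) * np.sinh(2 * j * eta)

    easting = _UTM_FALSE_E + _UTM_K0 * A * eta_s
    northing = _UTM_K0 * A * xi_s
    if south:
        northing = northing + _UTM_FALSE_N_SOUTH
    hemi = "S" if south else "N"
    return easting, northing, f"{zone}{hemi}"


def geo_distance_matrix(meta: pd.DataFrame) -> np.ndarray:
    """Pairwise Euclidean distances (meters) on planar coordinates.

    Individuals sharing a web share coordinates, hence distance 0.
    """
    coords = meta[["easting", "northing"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        bad = meta.loc[~np.isfinite(coords).all(axis=1), "individual_id"].tolist()
        raise ValidationError(f"missing coordinates for: {bad[:5]}")
    diff = coords[:, None, :] - coords[None, :, :]
    d = np.sqrt((diff**2).sum(axis=-1))
    np.fill_diagonal(d, 0.0)
    return d


# ---------------------------------------------------------------------------
# Age/sex strata
# ---------------------------------------------------------------------------

#: Named strata used by the age/sex-specific analyses: juveniles are
#: instars 1-3; "males"/"females" are the sub-adult + adult animals of that
#: sex; "adults" pools sub-adults and adults of both sexes.
_NAMED_SELECTORS: dict[str, Callable[[str, str], bool]] = {
    "all": lambda age, sex: True,
    "juveniles": lambda age, sex: age in JUVENILE_CLASSES,
    "males": lambda age, sex: age in MATURE_CLASSES and sex == "male",
    "females": lambda age, sex: age in MATURE_CLASSES and sex == "female",
    "adults": lambda age, sex: age in MATURE_CLASSES,
}


def stratify(
    meta: pd.DataFrame,
    selector: str | Callable[[str, str], bool],
    *,
    juvenile_classes: Iterable[str] | None = None,
) -> list[str]:
    """Return the individual ids in an age/sex stratum.

    ``selector`` is a named stratum (``"all"``, ``"juveniles"``,
    ``"males"``, ``"females"``, ``"adults"``) or a predicate
    ``f(age_class, sex) -> bool``.  An empty stratum is flagged with a
    warning but returned (analyses decide whether they can proceed).
    """
    if callable(selector):
        pred = selector
    else:
        if selector not in _NAMED_SELECTORS:
            raise ValidationError(
                f"unknown stratum {selector!r}; known: {sorted(_NAMED_SELECTORS)}"
            )
        if juvenile_classes is not None:
            juv = frozenset(juvenile_classes)
            mature = frozenset(a for a in AGE_CLASSES if a not in juv and a != "unknown")
            base = {
                "all": lambda age, sex: True,
                "juveniles": lambda age, sex: age in juv,
                "males": lambda age, sex: age in mature and sex == "male",
                "females": lambda age, sex: age in mature and sex == "female",
                "adults": lambda age, sex: age in mature,
            }
            pred = base[selector]
        else:
            pred = _NAMED_SELECTORS[selector]
    ids = [
        row.individual_id
        for row in meta.itertuples()
        if pred(row.age_class, row.sex)
    ]
    if not ids:
        logger.warning("stratum %r matched no individuals", selector)
    return ids
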