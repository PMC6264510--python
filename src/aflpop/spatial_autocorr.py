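"""Multivariate genetic spatial autocorrelation for binary band profiles.

The pipeline follows the multilocus autocorrelation construction of
Smouse & Peakall: the squared genetic distance between two individuals is
the number of mismatching bands; the squared-distance matrix is
Gower-double-centered into a covariance-like matrix C (rows sum to zero);
and for each geographic distance class h the autocorrelation coefficient

    r_h = sum_{x != y in h} c_xy / sum_x w_x(h) c_xx,

with w_x(h) the number of partners of x in class h, measures whether pairs
at that spatial scale are genetically more alike (r > 0) or less alike
(r < 0) than expected.  Uncertainty comes from bootstrap resampling of the
pairs within a class; the null from permuting genotypes across geographic
positions.  A class is declared significant under the conservative joint
rule: the observed r falls outside the permutation 95% CI *and* the
bootstrap 95% CI lies entirely outside it.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .marker_data import MarkerMatrix, align_metadata, geo_distance_matrix, stratify

logger = logging.getLogger(__name__)

__all__ = [
    "binary_squared_distance",
    "double_center",
    "make_distance_classes",
    "default_bounds",
    "autocorr_r",
    "bootstrap_ci",
    "permutation_null",
    "permutation_null_webs",
    "correlogram",
    "DistanceClassSpec",
    "Correlogram",
]


def binary_squared_distance(m: MarkerMatrix | np.ndarray) -> np.ndarray:
    """Pairwise squared genetic distance = number of mismatching bands."""
    x = (m.values if isinstance(m, MarkerMatrix) else np.asarray(m)).astype(float)
    # (x - y)^2 summed over loci; for 0/1 data this is the Hamming count
    gram = x @ x.T
    sq = np.diag(gram)
    d2 = sq[:, None] + sq[None, :] - 2 * gram
    d2 = np.rint(d2).astype(np.int64)
    np.fill_diagonal(d2, 0)
    return d2


def double_center(d2: np.ndarray) -> np.ndarray:
    """Gower centering: c_xy = -1/2 (d2_xy - rowmean_x - rowmean_y + grandmean).

    Every row of the result sums to zero (checked); the diagonal holds the
    per-individual variance terms.
    """
    d2 = np.asarray(d2, dtype=float)
    row = d2.mean(axis=1)
    grand = d2.mean()
    c = -0.5 * (d2 - row[:, None] - row[None, :] + grand)
    scale = max(np.abs(c).max(), 1.0)
    if not np.allclose(c.sum(axis=1), 0.0, atol=1e-9 * scale * c.shape[0]):
        raise AssertionError("double-centered rows do not sum to zero")
    return c


@dataclass
class DistanceClassSpec:
    """Partition of all unordered pairs into geographic distance classes."""

    upper_bounds: np.ndarray  # class h covers (bounds[h-1], bounds[h]]
    class_of_pair: np.ndarray  # (n, n) int; diagonal = -1
    n_pairs: np.ndarray  # unordered pair count per class

    @property
    def n_classes(self) -> int:
        return len(self.upper_bounds)

    def mask(self, h: int) -> np.ndarray:
        return self.class_of_pair == h


def default_bounds(geo: np.ndarray, n_classes: int = 6) -> list[float]:
    """Equal-pair-count bounds: class 1 = [0, 1] m (same-web pairs), the
    rest quantiles of the remaining pairwise distances."""
    iu = np.triu_indices(geo.shape[0], k=1)
    d = geo[iu]
    far = d[d > 1.0]
    if far.size == 0:
        return [max(1.0, float(d.max()))]
    qs = np.quantile(far, np.linspace(0, 1, n_classes)[1:])
    bounds = [1.0] + sorted(set(float(np.ceil(q)) for q in qs))
    if bounds[-1] < d.max():
        bounds[-1] = float(d.max())
    return bounds


def make_distance_classes(
    geo: np.ndarray, bounds: list[float] | None = None, *, strict: bool = False
) -> DistanceClassSpec:
    """Assign every unordered pair to the first class whose upper bound
    covers its distance.

    ``bounds`` are strictly increasing upper bounds in meters and must
    start at >= 1 m so same-web pairs (distance 0) all land in class 1; the
    last bound is auto-extended to the maximum pairwise distance.  Empty
    classes are an error in ``strict`` mode and are merged into the next
    class otherwise (no empty distance classes are allowed).
    """
    geo = np.asarray(geo, dtype=float)
    n = geo.shape[0]
    if bounds is None:
        bounds = default_bounds(geo)
    bounds = [float(b) for b in bounds]
    if any(b2 <= b1 for b1, b2 in zip(bounds, bounds[1:])):
        raise ValidationError("bounds must be strictly increasing")
    if bounds[0] < 1.0:
        raise ValidationError("first bound must be >= 1 m (the same-web class)")
    iu = np.triu_indices(n, k=1)
    dmax = float(geo[iu].max()) if n > 1 else 0.0
    if bounds[-1] < dmax:
        bounds = bounds + [dmax]

    while True:
        b = np.asarray(bounds, dtype=float)
        cls = np.searchsorted(b, geo, side="left")  # first bound >= d
        np.fill_diagonal(cls, -1)
        counts = np.array(
            [(cls[iu] == h).sum() for h in range(len(bounds))], dtype=int
        )
        if (counts > 0).all():
            break
        h_empty = int(np.flatnonzero(counts == 0)[0])
        if strict:
            lo = 0.0 if h_empty == 0 else bounds[h_empty - 1]
            raise ValidationError(
                f"distance class ({lo}, {bounds[h_empty]}] m contains no pairs"
            )
        logger.info("merging empty distance class ending at %s m", bounds[h_empty])
        bounds = bounds[:h_empty] + bounds[h_empty + 1 :]
        if not bounds:
            raise ValidationError("no non-empty distance classes")
    return DistanceClassSpec(
        upper_bounds=np.asarray(bounds), class_of_pair=cls, n_pairs=counts
    )


def _r_from_c(c: np.ndarray, classes: DistanceClassSpec) -> np.ndarray:
    diag = np.diag(c)
    r = np.empty(classes.n_classes)
    nums = np.empty(classes.n_classes)
    for h in range(classes.n_classes):
        mask = classes.mask(h)
        num = c[mask].sum()  # ordered pairs (mask is symmetric)
        w = mask.sum(axis=1)
        den = float(w @ diag)
        if den == 0.0:
            raise ValidationError(
                f"autocorrelation undefined in class {h}: zero variance "
                "(all genotypes identical?)"
            )
        nums[h] = num
        r[h] = num / den
    # global identity: class numerators exhaust the off-diagonal of C,
    # whose total is -trace(C) because rows sum to zero
    total = nums.sum()
    if not np.isclose(total, -np.trace(c), atol=1e-8 * max(1.0, np.abs(c).max()) * c.shape[0]):
        raise AssertionError("class numerators do not sum to -trace(C)")
    return r


def autocorr_r(c: np.ndarray, classes: DistanceClassSpec) -> np.ndarray:
    """Autocorrelation coefficient r per distance class."""
    c = np.asarray(c, dtype=float)
    if c.shape[0] != classes.class_of_pair.shape[0]:
        raise ValidationError("covariance matrix and class spec sizes differ")
    return _r_from_c(c, classes)


def bootstrap_ci(
    c: np.ndarray,
    classes: DistanceClassSpec,
    n_boot: int = 1000,
    seed: int | None = None,
) -> np.ndarray:
    """Per-class 95% bootstrap CI for r: resample the unordered pairs of a
    class with replacement and recompute r from the resampled
    numerator/denominator contributions.  Returns ``(n_classes, 2)``.
    """
    c = np.asarray(c, dtype=float)
    if n_boot < 1:
        raise ValidationError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    diag = np.diag(c)
    out = np.empty((classes.n_classes, 2))
    for h in range(classes.n_classes):
        mask = np.triu(classes.mask(h), k=1)
        ii, jj = np.nonzero(mask)
        num_p = 2.0 * c[ii, jj]  # each unordered pair appears twice ordered
        den_p = diag[ii] + diag[jj]
        k = len(ii)
        if k == 1:
            r = num_p[0] / den_p[0]
            logger.warning("distance class %d has one pair: degenerate CI", h)
            out[h] = (r, r)
            continue
        idx = rng.integers(0, k, size=(n_boot, k))
        nums = num_p[idx].sum(axis=1)
        dens = den_p[idx].sum(axis=1)
        ok = dens != 0
        rs = nums[ok] / dens[ok]
        out[h] = np.percentile(rs, [2.5, 97.5])
    return out


def permutation_null(
    c: np.ndarray,
    classes: DistanceClassSpec,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Null distribution of r under no spatial structure.

    Each permutation shuffles genotypes across geographic positions
    (equivalently, relabels the rows/columns of C while the distance
    classes stay put) and recomputes r per class.  Returns
    ``(ci, null_r)`` with ``ci`` of shape ``(n_classes, 2)`` (2.5/97.5
    percentiles) and the raw ``(n_perm, n_classes)`` draws.
    """
    c = np.asarray(c, dtype=float)
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    n = c.shape[0]
    masks = [classes.mask(h) for h in range(classes.n_classes)]
    ws = [m.sum(axis=1) for m in masks]
    null = np.empty((n_perm, classes.n_classes))
    for p in range(n_perm):
        idx = rng.permutation(n)
        cp = c[np.ix_(idx, idx)]
        diag = np.diag(cp)
        for h in range(classes.n_classes):
            num = cp[masks[h]].sum()
            den = float(ws[h] @ diag)
            null[p, h] = num / den if den != 0 else 0.0
    ci = np.percentile(null, [2.5, 97.5], axis=0).T
    return ci, null


def permutation_null_webs(
    c: np.ndarray,
    meta,
    classes: DistanceClassSpec,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Web-level permutation null for sensitivity analysis.

    Whole webs keep their member genotypes but are shuffled across the
    recorded web positions, so within-web co-membership stays intact and
    only the spatial arrangement of groups is randomized.  Because the
    set of web positions is unchanged, every observed distance class
    remains populated; the same-web class is invariant under this null
    (its pairs stay at distance 0), so it is informative only about
    cross-web structure.  Returns ``(ci, null_r)`` like
    :func:`permutation_null`.
    """
    c = np.asarray(c, dtype=float)
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    webs = meta["web_id"].to_numpy()
    web_ids = pd.unique(webs)
    pos = np.stack(
        [
            meta.loc[webs == w, ["easting", "northing"]].iloc[0].to_numpy(dtype=float)
            for w in web_ids
        ]
    )
    web_index = {w: i for i, w in enumerate(web_ids)}
    member_of = np.array([web_index[w] for w in webs])
    bounds = np.asarray(classes.upper_bounds, dtype=float)
    null = np.empty((n_perm, classes.n_classes))
    diag = np.diag(c)
    for p in range(n_perm):
        perm = rng.permutation(len(web_ids))
        coords = pos[perm][member_of]
        diff = coords[:, None, :] - coords[None, :, :]
        geo = np.sqrt((diff**2).sum(axis=-1))
        cls = np.searchsorted(bounds, geo, side="left")
        np.fill_diagonal(cls, -1)
        for h in range(classes.n_classes):
            mask = cls == h
            den = float(mask.sum(axis=1) @ diag)
            null[p, h] = c[mask].sum() / den if den != 0 else np.nan
    ci = np.nanpercentile(null, [2.5, 97.5], axis=0).T
    return ci, null


@dataclass
class Correlogram:
    """Per-class autocorrelation estimates with bootstrap and null CIs."""

    table: pd.DataFrame
    n_individuals: int
    stratum: str | None = None

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def correlogram(
    m: MarkerMatrix,
    meta: pd.DataFrame,
    bounds: list[float] | None = None,
    n_boot: int = 1000,
    n_perm: int = 999,
    seed: int | None = None,
    stratum: str | None = None,
    *,
    strict_classes: bool = False,
    perm_unit: str = "individual",
) -> Correlogram:
    """Full spatial-autocorrelation analysis for one (optionally stratified)
    sample: r per distance class, bootstrap CI, permutation null CI, and
    the joint significance flag.

    ``perm_unit``: ``"individual"`` (default) shuffles genotypes across
    positions; ``"web"`` shuffles whole webs across web positions
    (sensitivity analysis; the same-web class is invariant under it).
    """
    meta = align_metadata(meta, m)
    if stratum is not None and stratum != "all":
        ids = stratify(meta, stratum)
        if len(ids) < 4:
            raise ValidationError(
                f"stratum {stratum!r} has {len(ids)} individuals; need >= 4"
            )
        m = m.subset_individuals(ids)
        meta = align_metadata(meta, m)
    geo = geo_distance_matrix(meta)
    classes = make_distance_classes(geo, bounds, strict=strict_classes)
    c = double_center(binary_squared_distance(m))
    r = autocorr_r(c, classes)
    seeds = np.random.SeedSequence(seed).spawn(2)
    boot = bootstrap_ci(c, classes, n_boot, np.random.default_rng(seeds[0]).integers(2**31))
    null_seed = int(np.random.default_rng(seeds[1]).integers(2**31))
    if perm_unit == "individual":
        null_ci, null = permutation_null(c, classes, n_perm, null_seed)
    elif perm_unit == "web":
        null_ci, null = permutation_null_webs(c, meta, classes, n_perm, null_seed)
    else:
        raise ValidationError("perm_unit must be 'individual' or 'web'")
    p_upper = (1 + (null >= r[None, :]).sum(axis=0)) / (n_perm + 1)
    perm_sig = (r < null_ci[:, 0]) | (r > null_ci[:, 1])
    joint_sig = perm_sig & (
        (boot[:, 0] > null_ci[:, 1]) | (boot[:, 1] < null_ci[:, 0])
    )
    table = pd.DataFrame(
        {
            "class_upper_m": classes.upper_bounds,
            "n_pairs": classes.n_pairs,
            "r": r,
            "boot_lo": boot[:, 0],
            "boot_hi": boot[:, 1],
            "null_lo": null_ci[:, 0],
            "null_hi": null_ci[:, 1],
            "p_upper": p_upper,
            "perm_significant": perm_sig,
            "significant": joint_sig,
        }
    )
    return Correlogram(table=table, n_individuals=m.n_individuals, stratum=stratum)
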