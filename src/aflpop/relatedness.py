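"""Frequency-corrected band-sharing relatedness for dominant markers.

Codominant relatedness estimators need allele dosages, which dominant
bands hide, so pairwise relatedness here is the centered band-sharing
correlation

    r_xy = sum_l (x_l - p_l)(y_l - p_l) / sum_l p_l (1 - p_l),

with p_l the sample band frequency at locus l.  Because the profiles are
centered by frequencies estimated from the sample itself, r averages ~0
over random pairs (matching a null of "relatedness 0") and identical
profiles score the maximum attainable for their band content.  The
estimator is pluggable: any ``f(values, p) -> (n, n) matrix`` with the
same centering convention can be passed to the group test.

The per-web test asks whether the mean pairwise relatedness inside a web
exceeds that of randomly assembled groups of the same size drawn from the
whole sample (permutation null), with a pair-resampling bootstrap CI
around the observed mean.  Webs need at least 3 members; with 2 or fewer
the permutation and sampling CIs coincide and the test is uninformative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .marker_data import MarkerMatrix, align_metadata

logger = logging.getLogger(__name__)

__all__ = [
    "band_frequencies",
    "pairwise_relatedness",
    "group_relatedness_test",
    "RelatednessReport",
]


def band_frequencies(m: MarkerMatrix | np.ndarray) -> np.ndarray:
    """Per-locus band frequency p_l = presence count / n."""
    x = m.values if isinstance(m, MarkerMatrix) else np.asarray(m)
    return x.mean(axis=0)


def pairwise_relatedness(
    m: MarkerMatrix | np.ndarray, p: np.ndarray | None = None
) -> np.ndarray:
    """Centered band-sharing relatedness matrix.

    With p estimated from the sample the off-diagonal entries sum to minus
    the sum of the diagonal self-terms (the centered profiles sum to zero
    across individuals), so random pairs average slightly below 0.
    """
    x = (m.values if isinstance(m, MarkerMatrix) else np.asarray(m)).astype(float)
    if x.shape[0] < 2:
        raise ValidationError("need at least 2 individuals")
    if p is None:
        p = x.mean(axis=0)
    p = np.asarray(p, dtype=float)
    denom = float(np.sum(p * (1.0 - p)))
    if denom == 0.0:
        raise ValidationError("all loci fixed: relatedness undefined (filter first)")
    centered = x - p
    return centered @ centered.T / denom


def _group_mean(r: np.ndarray, idx: np.ndarray) -> float:
    """Mean of within-group pairwise (off-diagonal, unordered) relatedness."""
    k = len(idx)
    sub = r[np.ix_(idx, idx)]
    return float((sub.sum() - np.trace(sub)) / (k * (k - 1)))


@dataclass
class RelatednessReport:
    """Per-web mean relatedness with bootstrap CI, permutation null CI,
    one-sided p-value and a higher/lower/ns flag."""

    table: pd.DataFrame
    n_perm: int
    n_boot: int
    excluded_webs: list[str]

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def group_relatedness_test(
    m: MarkerMatrix,
    meta: pd.DataFrame,
    n_perm: int = 999,
    n_boot: int = 1000,
    seed: int | None = None,
    *,
    min_web_size: int = 3,
    estimator: Callable[[np.ndarray, np.ndarray | None], np.ndarray] | None = None,
) -> RelatednessReport:
    """Permutation test of within-web relatedness against random groups.

    Per web with >= ``min_web_size`` members: the observed statistic is
    the mean pairwise relatedness among its members; the null consists of
    ``n_perm`` means of equally sized groups drawn without replacement
    from the whole sample; ``p_ge = (1 + #{null >= observed}) / (n_perm + 1)``
    (the +1 keeps p away from 0); the bootstrap CI resamples the web's
    pairs with replacement.  Flags: ``higher`` if the observed mean lies
    above the null 97.5th percentile, ``lower`` below the 2.5th, else
    ``ns``.  Band frequencies are always taken from the *whole* sample.
    """
    meta = align_metadata(meta, m)
    if estimator is None:
        r = pairwise_relatedness(m)
    else:
        r = estimator(m.values.astype(float), None)
    n = r.shape[0]
    rng = np.random.default_rng(seed)

    rows = []
    excluded: list[str] = []
    web_groups = meta.groupby("web_id", sort=True)
    for web, grp in web_groups:
        idx = grp.index.to_numpy()
        k = len(idx)
        if k < min_web_size:
            excluded.append(str(web))
            logger.info("web %s excluded from relatedness test (n=%d)", web, k)
            continue
        obs = _group_mean(r, idx)

        # permutation null: random groups of k individuals from the sample
        null = np.empty(n_perm)
        perm_idx = np.empty((n_perm, k), dtype=int)
        for b in range(n_perm):
            perm_idx[b] = rng.choice(n, size=k, replace=False)
        sub = r[perm_idx[:, :, None], perm_idx[:, None, :]]  # (n_perm, k, k)
        null = (sub.sum(axis=(1, 2)) - np.trace(sub, axis1=1, axis2=2)) / (
            k * (k - 1)
        )
        null_lo, null_hi = np.percentile(null, [2.5, 97.5])
        p_ge = float((1 + (null >= obs).sum()) / (n_perm + 1))

        # bootstrap over the web's unordered pairs
        ii, jj = np.triu_indices(k, k=1)
        pair_vals = r[idx[ii], idx[jj]]
        boot_idx = rng.integers(0, len(pair_vals), size=(n_boot, len(pair_vals)))
        boot_means = pair_vals[boot_idx].mean(axis=1)
        boot_lo, boot_hi = np.percentile(boot_means, [2.5, 97.5])

        flag = "higher" if obs > null_hi else ("lower" if obs < null_lo else "ns")
        rows.append(
            {
                "web_id": str(web),
                "n": k,
                "mean_r": obs,
                "boot_lo": boot_lo,
                "boot_hi": boot_hi,
                "null_lo": null_lo,
                "null_hi": null_hi,
                "p_ge": p_ge,
                "flag": flag,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "web_id", "n", "mean_r", "boot_lo", "boot_hi",
            "null_lo", "null_hi", "p_ge", "flag",
        ],
    )
    return RelatednessReport(
        table=table, n_perm=n_perm, n_boot=n_boot, excluded_webs=excluded
    )
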