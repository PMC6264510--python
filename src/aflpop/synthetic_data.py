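"""Synthetic dominant-marker colonies with known ground truth.

Emulates the sampling design of a kleptoparasite field survey: host webs
placed along a ~1 km transect, each web holding a group of spiders, with
genetic structure injected at three levels:

* **kinship** — a fraction of each web is one full-sib family bred from two
  local parents by Mendelian segregation; remaining residents are half sibs
  of that family (they share the mother) unless they are migrants;
* **dispersal limitation** — ``migrant_rate`` controls how many residents
  are instead drawn from the global gene pool;
* **admixture** — two divergent source pools with per-individual ancestry
  vectors, for testing cluster-number recovery.

The latent genetics are diploid and biallelic; the *observed* phenotype is
dominant (band present iff at least one dominant allele), exactly the
information loss of AFLP markers.  Downstream analyses treat the bands as
haploid profiles, mirroring standard practice for dominant data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional
import warnings

import numpy as np
import pandas as pd

from .exceptions import ConfigError
from .marker_data import AGE_CLASSES, META_COLUMNS, MarkerMatrix, read_binary_matrix

__all__ = [
    "SyntheticConfig",
    "SyntheticDataset",
    "simulate_population",
    "simulate_two_source_admixture",
    "write_fixture",
    "read_fixture",
]


@dataclass
class SyntheticConfig:
    """Parameters of the colony simulator.

    Defaults describe a mid-sized survey: 12 webs evenly spaced along a
    1000 m transect, 4-12 spiders per web, 200 informative loci with latent
    dominant-allele frequencies Uniform(0.1, 0.9) (avoids quasi-invariant
    loci the pre-analysis filter would remove), a quarter of each web being
    one full-sib family and a modest migrant fraction.
    """

    n_webs: int = 12
    transect_length: float = 1000.0  # meters
    position_jitter: float = 0.0  # uniform(0, jitter) noise on web positions
    group_size_min: int = 4
    group_size_max: int = 12
    n_loci: int = 200
    allele_freq_low: float = 0.1
    allele_freq_high: float = 0.9
    sib_fraction: float = 0.25
    migrant_rate: float = 0.1
    n_sources: int = 1
    source_divergence: float = 0.0
    admixed_fraction: float = 0.0  # individuals with 50/50 ancestry (2 sources)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("sib_fraction", "migrant_rate", "admixed_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {v}")
        if self.n_webs < 1 or self.n_loci < 1:
            raise ConfigError("n_webs and n_loci must be positive")
        if not 1 <= self.group_size_min <= self.group_size_max:
            raise ConfigError("need 1 <= group_size_min <= group_size_max")
        if self.sib_fraction > 0 and self.group_size_max < 2:
            raise ConfigError("sib_fraction > 0 requires groups of size >= 2")
        if not 0.0 < self.allele_freq_low <= self.allele_freq_high < 1.0:
            raise ConfigError("allele frequency law must sit inside (0, 1)")
        if self.n_sources not in (1, 2):
            raise ConfigError("n_sources must be 1 or 2")
        if not 0.0 <= self.source_divergence <= 1.0:
            raise ConfigError("source_divergence must be in [0, 1]")


@dataclass
class SyntheticDataset:
    """A simulated survey with ground truth."""

    matrix: MarkerMatrix
    meta: pd.DataFrame
    truth: pd.DataFrame  # per individual: family/parents/source/ancestry
    allele_freqs: np.ndarray  # (n_sources, n_loci) latent dominant-allele freqs
    config: SyntheticConfig = field(repr=False)

    def pedigree_relatedness(self) -> np.ndarray:
        """Pairwise pedigree relatedness: 0.25 per shared parent.

        Full sibs -> 0.5, half sibs -> 0.25, unrelated -> 0.  Diagonal 1.
        """
        mothers = self.truth["mother_id"].to_numpy()
        fathers = self.truth["father_id"].to_numpy()
        shared = (mothers[:, None] == mothers[None, :]).astype(float)
        shared += (fathers[:, None] == fathers[None, :]).astype(float)
        r = 0.25 * shared
        np.fill_diagonal(r, 1.0)
        return r


def _web_positions(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    if cfg.n_webs == 1:
        pos = np.array([0.0])
    else:
        pos = np.linspace(0.0, cfg.transect_length, cfg.n_webs)
    if cfg.position_jitter > 0:
        pos = pos + rng.uniform(0.0, cfg.position_jitter, size=cfg.n_webs)
    return pos


def _draw_source_freqs(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Latent dominant-allele frequencies per source, (n_sources, n_loci).

    For two sources, per-locus frequencies are pushed apart symmetrically
    by ``source_divergence``: a base draw u gets split into
    u -/+ divergence/2 (random sign per locus), clipped into (0, 1); at
    divergence 0.9 a central locus lands near 0.05 vs 0.95.
    """
    u = rng.uniform(cfg.allele_freq_low, cfg.allele_freq_high, size=cfg.n_loci)
    if cfg.n_sources == 1:
        return u[None, :]
    if cfg.source_divergence <= 0.01:
        warnings.warn("source_divergence ~ 0: the two sources coincide")
    sign = rng.choice([-1.0, 1.0], size=cfg.n_loci)
    half = cfg.source_divergence / 2.0
    qa = np.clip(u - sign * half, 0.02, 0.98)
    qb = np.clip(u + sign * half, 0.02, 0.98)
    return np.stack([qa, qb])


def _genotype_from_freqs(
    q: np.ndarray, rng: np.random.Generator, size: int
) -> np.ndarray:
    """(size, L, 2) diploid latent genotypes, alleles i.i.d. Bernoulli(q_l)."""
    return (rng.random((size, q.shape[0], 2)) < q[None, :, None]).astype(np.int8)


def _mendelian_child(
    parents: tuple[np.ndarray, np.ndarray], rng: np.random.Generator
) -> np.ndarray:
    """One (L, 2) child: one uniformly chosen allele from each parent."""
    mother, father = parents
    L = mother.shape[0]
    gm = mother[np.arange(L), rng.integers(0, 2, size=L)]
    gf = father[np.arange(L), rng.integers(0, 2, size=L)]
    return np.stack([gm, gf], axis=1)


def simulate_population(cfg: SyntheticConfig) -> SyntheticDataset:
    """Simulate a survey under the kinship/dispersal model.

    Per web: two parents are drawn from the global pool; each resident is,
    independently, a full sib (probability ``sib_fraction``), otherwise a
    migrant from the global pool (probability ``migrant_rate``), otherwise
    a maternal half sib (mother shared with the web family, father drawn
    globally).  Phenotype = band present iff the diploid genotype carries
    at least one dominant allele.
    """
    rng = np.random.default_rng(cfg.seed)
    freqs = _draw_source_freqs(cfg, rng)
    q = freqs[0]
    positions = _web_positions(cfg, rng)

    rows = []  # (id, web, age, sex, x, family, mother, father)
    genotypes = []
    uid = 0
    for w in range(cfg.n_webs):
        size = int(rng.integers(cfg.group_size_min, cfg.group_size_max + 1))
        if cfg.sib_fraction > 0 and size < 2:
            raise ConfigError("sib_fraction > 0 requires every group size >= 2")
        mother = _genotype_from_freqs(q, rng, 1)[0]
        father = _genotype_from_freqs(q, rng, 1)[0]
        family = f"fam{w}"
        for _ in range(size):
            u = rng.random()
            if u < cfg.sib_fraction:
                g = _mendelian_child((mother, father), rng)
                mom_id, dad_id = f"{family}.m", f"{family}.f"
                fam = family
            elif rng.random() < cfg.migrant_rate:
                g = _genotype_from_freqs(q, rng, 1)[0]
                mom_id, dad_id = f"mig{uid}.m", f"mig{uid}.f"
                fam = f"mig{uid}"
            else:
                stray_father = _genotype_from_freqs(q, rng, 1)[0]
                g = _mendelian_child((mother, stray_father), rng)
                mom_id, dad_id = f"{family}.m", f"stray{uid}.f"
                fam = f"{family}.half"
            age = AGE_CLASSES[rng.integers(0, 5)]  # excludes "unknown"
            sex = "male" if rng.random() < 0.5 else "female"
            rows.append(
                (f"ind{uid:04d}", f"web{w:02d}", age, sex, positions[w], fam,
                 mom_id, dad_id)
            )
            genotypes.append(g)
            uid += 1

    geno = np.stack(genotypes)  # (n, L, 2)
    bands = (geno.sum(axis=2) > 0).astype(np.int8)  # dominance
    ids = [r[0] for r in rows]
    matrix = MarkerMatrix(ids, [f"L{j:04d}" for j in range(cfg.n_loci)], bands)
    meta = pd.DataFrame(
        {
            "individual_id": ids,
            "web_id": [r[1] for r in rows],
            "age_class": [r[2] for r in rows],
            "sex": [r[3] for r in rows],
            "easting": [r[4] for r in rows],
            "northing": 0.0,
        }
    )[list(META_COLUMNS)]
    truth = pd.DataFrame(
        {
            "individual_id": ids,
            "web_id": [r[1] for r in rows],
            "family_id": [r[5] for r in rows],
            "mother_id": [r[6] for r in rows],
            "father_id": [r[7] for r in rows],
            "source": 0,
            "ancestry_source2": 0.0,
        }
    )
    return SyntheticDataset(matrix, meta, truth, freqs, cfg)


def simulate_two_source_admixture(cfg: SyntheticConfig) -> SyntheticDataset:
    """Simulate two divergent source pools with per-individual ancestry.

    Webs are assigned alternately to the two sources; each resident is pure
    (ancestry of its web's source) except a fraction ``admixed_fraction``
    with 50/50 ancestry.  Per locus, an ancestral origin is drawn from the
    individual's ancestry vector and the diploid genotype from that
    source's allele frequency — so an individual's expected band frequency
    is the ancestry-weighted mean of the source *band* frequencies.
    No sib structure: this generator isolates admixture signal.
    """
    if cfg.n_sources != 2:
        raise ConfigError("simulate_two_source_admixture requires n_sources=2")
    if cfg.source_divergence <= 0:
        raise ConfigError("source_divergence must be > 0")
    rng = np.random.default_rng(cfg.seed)
    freqs = _draw_source_freqs(cfg, rng)
    positions = _web_positions(cfg, rng)

    rows, genotypes, sources, ancestries = [], [], [], []
    uid = 0
    for w in range(cfg.n_webs):
        size = int(rng.integers(cfg.group_size_min, cfg.group_size_max + 1))
        web_source = w % 2
        for _ in range(size):
            if rng.random() < cfg.admixed_fraction:
                a2 = 0.5
                src = -1  # mixed
            else:
                a2 = float(web_source)
                src = web_source
            origin = (rng.random(cfg.n_loci) < a2).astype(int)  # 0 or 1 per locus
            q_per_locus = freqs[origin, np.arange(cfg.n_loci)]
            g = (rng.random((cfg.n_loci, 2)) < q_per_locus[:, None]).astype(np.int8)
            age = AGE_CLASSES[rng.integers(0, 5)]
            sex = "male" if rng.random() < 0.5 else "female"
            rows.append((f"ind{uid:04d}", f"web{w:02d}", age, sex, positions[w]))
            genotypes.append(g)
            sources.append(src)
            ancestries.append(a2)
            uid += 1

    geno = np.stack(genotypes)
    bands = (geno.sum(axis=2) > 0).astype(np.int8)
    ids = [r[0] for r in rows]
    matrix = MarkerMatrix(ids, [f"L{j:04d}" for j in range(cfg.n_loci)], bands)
    meta = pd.DataFrame(
        {
            "individual_id": ids,
            "web_id": [r[1] for r in rows],
            "age_class": [r[2] for r in rows],
            "sex": [r[3] for r in rows],
            "easting": [r[4] for r in rows],
            "northing": 0.0,
        }
    )[list(META_COLUMNS)]
    truth = pd.DataFrame(
        {
            "individual_id": ids,
            "web_id": [r[1] for r in rows],
            "family_id": [f"solo{i}" for i in range(len(ids))],
            "mother_id": [f"solo{i}.m" for i in range(len(ids))],
            "father_id": [f"solo{i}.f" for i in range(len(ids))],
            "source": sources,
            "ancestry_source2": ancestries,
        }
    )
    return SyntheticDataset(matrix, meta, truth, freqs, cfg)


# ---------------------------------------------------------------------------
# Fixtures on disk
# ---------------------------------------------------------------------------

def write_fixture(ds: SyntheticDataset, path) -> dict[str, Path]:
    """Write matrix/metadata/truth CSVs; round-trips losslessly."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = {
        "matrix": path / "matrix.csv",
        "meta": path / "meta.csv",
        "truth": path / "truth.csv",
    }
    ds.matrix.to_csv(files["matrix"])
    ds.meta.to_csv(files["meta"], index=False)
    ds.truth.to_csv(files["truth"], index=False)
    return files


def read_fixture(path) -> tuple[MarkerMatrix, pd.DataFrame, Optional[pd.DataFrame]]:
    path = Path(path)
    matrix = read_binary_matrix(path / "matrix.csv")
    meta = pd.read_csv(path / "meta.csv", dtype={"individual_id": str, "web_id": str})
    truth_path = path / "truth.csv"
    truth = pd.read_csv(truth_path, dtype={"individual_id": str}) if truth_path.exists() else None
    return matrix, meta, truth
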