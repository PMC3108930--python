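"""Association tables, phenotype similarities, and the two regression profiles.

For a query phenotype *p* the response is its phenotype similarity profile
``y_p``: similarity scores between *p* and every seed phenotype (a phenotype
with at least one known associated domain). For a query domain *d* the
predictor is its domain proximity profile ``x_d`` over the same seed
phenotypes, with entries ``x_dp = sum over d' in D(p) of x_dd'`` — the summed
network proximity from *d* to the domains known for each seed phenotype.

Before regression the response is rank-based inverse-normal transformed,
``z_i = Phi^-1((r_i - c) / (m - 2c + 1))``, which makes it marginally normal
regardless of the raw similarity distribution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .net_kernels import ProximityMatrix

__all__ = [
    "AssociationSet",
    "PhenotypeSimilarity",
    "SimilarityProfile",
    "ProximityProfile",
    "RankTransform",
    "domain_phenotype_proximity",
    "build_proximity_profile",
    "build_similarity_profile",
    "inverse_normal_transform",
    "shuffle_associations",
    "shuffle_similarity_profile",
]


class AssociationSet:
    """Known (domain, phenotype) associations.

    ``seed_phenotypes`` is the ordered (sorted) list of phenotypes with at
    least one associated domain; ``D(p)`` is exposed via :meth:`domains_for`.
    """

    def __init__(self, pairs: Iterable[tuple[str, str]]):
        self.pairs: frozenset[tuple[str, str]] = frozenset(
            (str(d), str(p)) for d, p in pairs
        )
        by_phen: dict[str, set[str]] = {}
        for d, p in self.pairs:
            by_phen.setdefault(p, set()).add(d)
        self._by_phen = by_phen
        self.seed_phenotypes: list[str] = sorted(by_phen)

    @property
    def m(self) -> int:
        return len(self.seed_phenotypes)

    @property
    def domains(self) -> set[str]:
        return {d for d, _ in self.pairs}

    def domains_for(self, phenotype: str) -> set[str]:
        return set(self._by_phen.get(phenotype, set()))

    def without(self, exclude_pairs: Iterable[tuple[str, str]]) -> "AssociationSet":
        """Copy with the given pairs treated as unknown."""
        excl = set(exclude_pairs)
        unknown = excl - self.pairs
        if unknown:
            raise ValueError(f"exclude_pairs not in association set: {sorted(unknown)[:3]}")
        return AssociationSet(self.pairs - excl)

    def __len__(self) -> int:
        return len(self.pairs)


@dataclass
class PhenotypeSimilarity:
    """Symmetric phenotype-phenotype similarity matrix with entries in [0, 1]."""

    ids: Sequence[str]
    values: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise ValueError("similarity matrix shape does not match id list")
        if not np.allclose(self.values, self.values.T, atol=1e-12):
            raise ValueError("similarity matrix must be symmetric")
        if self.values.min() < 0 or self.values.max() > 1 + 1e-12:
            raise ValueError("similarity out of [0,1]")
        self._index = {p: i for i, p in enumerate(self.ids)}

    def index_of(self, phenotype: str) -> int:
        return self._index[phenotype]

    def __contains__(self, phenotype: str) -> bool:
        return phenotype in self._index


@dataclass
class SimilarityProfile:
    """Response vector y_p over an ordered subset of seed phenotypes."""

    phenotype_ids: list[str]
    values: np.ndarray
    transformed: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.phenotype_ids) != self.values.size:
            raise ValueError("profile length mismatch")


@dataclass
class ProximityProfile:
    """Predictor vector x_d, index-aligned with its SimilarityProfile."""

    phenotype_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.phenotype_ids) != self.values.size:
            raise ValueError("profile length mismatch")
        if self.values.min() < 0:
            raise ValueError("proximity profile entries must be >= 0")


@dataclass(frozen=True)
class RankTransform:
    """Plotting-position constant c of the inverse-normal transform.

    Default c = 3/8 (Blom). ``z_i = Phi^-1((r_i - c) / (m - 2c + 1))``.
    """

    offset: float = 0.375

    def __post_init__(self) -> None:
        if not 0 <= self.offset <= 0.5:
            raise ValueError("offset must be in [0, 0.5]")


def domain_phenotype_proximity(
    d: str, p: str, prox: ProximityMatrix, assoc: AssociationSet
) -> float:
    """x_dp: summed proximity from domain d to all domains known for p.

    Domains of D(p) absent from the network contribute 0.
    """
    if d not in prox:
        raise KeyError(f"domain not in network: {d}")
    i = prox.index_of(d)
    return float(
        sum(prox.values[i, prox.index_of(d2)] for d2 in assoc.domains_for(p) if d2 in prox)
    )


def build_proximity_profile(
    d: str,
    assoc: AssociationSet,
    prox: ProximityMatrix,
    exclude_pairs: Iterable[tuple[str, str]] = (),
) -> ProximityProfile:
    """Proximity profile of domain d over the seed phenotypes.

    ``exclude_pairs`` are treated as unknown (the held-out pair in LOOCV, or
    all pairs of the query phenotype in ab initio mode); phenotypes left with
    no associated domain after exclusion are dropped from the index.
    """
    if d not in prox:
        raise KeyError(f"domain not in network: {d}")
    eff = assoc.without(exclude_pairs)
    phens = eff.seed_phenotypes
    if len(phens) < 3:
        raise ValueError("insufficient seed phenotypes")
    vals = np.array([domain_phenotype_proximity(d, p, prox, eff) for p in phens])
    return ProximityProfile(list(phens), vals)


def build_similarity_profile(
    p: str,
    sim: PhenotypeSimilarity,
    assoc: AssociationSet,
    exclude_query: bool = True,
) -> SimilarityProfile:
    """Similarity profile of query phenotype p over the seed phenotypes.

    If ``exclude_query`` and p is itself a seed phenotype, p is omitted from
    the profile (its self-similarity of 1 would leak label information).
    """
    if p not in sim:
        raise KeyError(f"phenotype not in similarity matrix: {p}")
    phens = [q for q in assoc.seed_phenotypes if q in sim]
    if exclude_query:
        phens = [q for q in phens if q != p]
    i = sim.index_of(p)
    vals = np.array([sim.values[i, sim.index_of(q)] for q in phens])
    return SimilarityProfile(list(phens), vals, transformed=False)


def inverse_normal_transform(
    values: np.ndarray, t: RankTransform = RankTransform()
) -> np.ndarray:
    """Rank-based inverse-normal transform with averaged ranks for ties."""
    values = np.asarray(values, dtype=float)
    m = values.size
    if m < 3:
        raise ValueError("need at least 3 values to transform")
    if np.ptp(values) == 0:
        raise ValueError("degenerate response (constant)")
    ranks = stats.rankdata(values, method="average")
    c = t.offset
    return stats.norm.ppf((ranks - c) / (m - 2 * c + 1))


def shuffle_associations(
    assoc: AssociationSet,
    all_domains: Sequence[str],
    mode: str,
    seed: int,
) -> AssociationSet:
    """Break the domain-phenotype relationship, fixing per-phenotype counts.

    mode="permute" redistributes the existing domain multiset over the
    phenotype slots; mode="random_replace" draws replacement domains
    uniformly from ``all_domains``. Either way |D(p)| is preserved for every
    phenotype (repeated draws for one phenotype collapse would change the
    count, so draws are made without replacement within a phenotype).
    """
    if not all_domains:
        raise ValueError("all_domains must be nonempty")
    rng = np.random.default_rng(seed)
    phens = assoc.seed_phenotypes
    counts = {p: len(assoc.domains_for(p)) for p in phens}
    new_pairs: list[tuple[str, str]] = []
    if mode == "permute":
        slots = sorted(assoc.pairs)  # (domain, phenotype), canonical order
        slot_phens = [p for _, p in slots]
        domains = [d for d, _ in slots]
        order = rng.permutation(len(domains))
        assigned = [domains[i] for i in order]
        # A pair set collapses duplicates, so a domain drawn twice for one
        # phenotype would change |D(p)|: repair collisions by swapping with
        # a compatible slot of another phenotype.
        for _ in range(100 * len(slots) + 10):
            held: dict[str, set[str]] = {p: set() for p in phens}
            bad = None
            for k, (d, p) in enumerate(zip(assigned, slot_phens)):
                if d in held[p]:
                    bad = k
                    break
                held[p].add(d)
            if bad is None:
                break
            j = int(rng.integers(len(slots)))
            dj, pj = assigned[j], slot_phens[j]
            db, pb = assigned[bad], slot_phens[bad]
            if (pj != pb and dj != db
                    and db not in held.get(pj, set())
                    and dj not in held.get(pb, set())):
                assigned[bad], assigned[j] = dj, db
        else:
            import warnings

            warnings.warn("association permutation could not resolve all "
                          "collisions; counts may differ", stacklevel=2)
        new_pairs = list(zip(assigned, slot_phens))
    elif mode == "random_replace":
        all_sorted = sorted(set(all_domains))
        for p in phens:
            take = rng.choice(len(all_sorted), size=counts[p], replace=False)
            new_pairs.extend((all_sorted[i], p) for i in sorted(take))
    else:
        raise ValueError(f"unknown shuffle mode: {mode}")
    return AssociationSet(new_pairs)


def shuffle_similarity_profile(profile: SimilarityProfile, seed: int) -> SimilarityProfile:
    """Permute profile values uniformly at random (multiset preserved)."""
    if profile.values.size < 2:
        raise ValueError("profile too short to shuffle")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(profile.values.size)
    return SimilarityProfile(
        list(profile.phenotype_ids), profile.values[perm], profile.transformed
    )
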