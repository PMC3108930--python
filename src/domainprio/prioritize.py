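"""Rank candidate domains for a query phenotype; gene scores; landscape export.

One query builds the similarity profile once (inverse-normal transformed
once), then scores every candidate domain against it with the Bayes factor.
Three exclusion modes control what counts as known:

* ``plain`` — all associations are used;
* ``loo_pair`` — one named (domain, phenotype) pair is held out;
* ``ab_initio`` — every association of the query phenotype is held out, as
  if the genetic basis of the disease were unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import stats

from .bayes import RegressionPriors, limit_log10_bf_many, log_marginal_alternative, log_marginal_null, LOG10
from .net_kernels import ProximityMatrix
from .profiles import (
    AssociationSet,
    PhenotypeSimilarity,
    RankTransform,
    build_similarity_profile,
    inverse_normal_transform,
)

__all__ = [
    "CandidateRanking",
    "GeneDomainMap",
    "score_candidates",
    "gene_scores",
    "landscape",
    "landscape_filter",
]


@dataclass
class CandidateRanking:
    """Ranked candidates for one query phenotype.

    ``entries`` is sorted by descending log10 BF; tied scores get averaged
    ranks; ``rank_ratio = rank / n_candidates``.
    """

    query_phenotype: str
    mode: str
    domain_ids: list[str]
    log10_bf: np.ndarray
    r_squared: np.ndarray
    ranks: np.ndarray
    rank_ratios: np.ndarray

    @property
    def n_candidates(self) -> int:
        return len(self.domain_ids)

    def rank_of(self, domain: str) -> float:
        return float(self.ranks[self.domain_ids.index(domain)])

    def rank_ratio_of(self, domain: str) -> float:
        return float(self.rank_ratios[self.domain_ids.index(domain)])

    @property
    def entries(self) -> list[tuple[str, float, float, float, float]]:
        order = np.argsort(-self.log10_bf, kind="stable")
        return [
            (
                self.domain_ids[i],
                float(self.log10_bf[i]),
                float(self.r_squared[i]),
                float(self.ranks[i]),
                float(self.rank_ratios[i]),
            )
            for i in order
        ]


class GeneDomainMap:
    """gene_id -> set of domain ids carried by the gene's protein products."""

    def __init__(self, mapping: Mapping[str, Iterable[str]]):
        self.mapping: dict[str, frozenset[str]] = {
            str(g): frozenset(str(d) for d in ds) for g, ds in mapping.items()
        }
        if any(len(ds) == 0 for ds in self.mapping.values()):
            raise ValueError("every gene needs at least one domain")

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "GeneDomainMap":
        mp: dict[str, set[str]] = {}
        for g, d in pairs:
            mp.setdefault(str(g), set()).add(str(d))
        return cls(mp)

    def __len__(self) -> int:
        return len(self.mapping)

    def items(self):
        return self.mapping.items()


def _exclusion_pairs(mode: str, p: str, assoc: AssociationSet,
                     held_out_pair: tuple[str, str] | None) -> set[tuple[str, str]]:
    if mode == "plain":
        return set()
    if mode == "loo_pair":
        if held_out_pair is None:
            raise ValueError("loo_pair mode requires held_out_pair")
        return {held_out_pair}
    if mode == "ab_initio":
        return {(d, p) for d in assoc.domains_for(p)}
    raise ValueError(f"unknown mode: {mode}")


def score_candidates(
    p: str,
    candidates: Sequence[str],
    assoc: AssociationSet,
    prox: ProximityMatrix,
    sim: PhenotypeSimilarity,
    mode: str = "plain",
    held_out_pair: tuple[str, str] | None = None,
    rank_transform: RankTransform = RankTransform(),
    priors: RegressionPriors = RegressionPriors(),
    exclude_query: bool = True,
    similarity_top_fraction: float | None = None,
) -> CandidateRanking:
    """Score and rank candidate domains for query phenotype ``p``.

    The similarity profile is built and transformed once and shared by all
    candidates; each candidate contributes only its proximity profile. With
    ``similarity_top_fraction`` set, only that fraction of seed phenotypes
    most similar to the query is kept in both profiles.
    """
    missing = [d for d in candidates if d not in prox]
    if missing:
        raise KeyError(f"candidate domains not in network: {missing[:3]}")
    excl = _exclusion_pairs(mode, p, assoc, held_out_pair)
    eff = assoc.without(excl)

    sprof = build_similarity_profile(p, sim, eff, exclude_query=exclude_query)
    phens = sprof.phenotype_ids
    y_raw = sprof.values
    if similarity_top_fraction is not None:
        if not 0 < similarity_top_fraction <= 1:
            raise ValueError("similarity_top_fraction must be in (0, 1]")
        keep = max(3, int(round(similarity_top_fraction * len(phens))))
        order = np.argsort(-y_raw, kind="stable")[:keep]
        order.sort()  # preserve phenotype order
        phens = [phens[i] for i in order]
        y_raw = y_raw[order]
    if len(phens) < 3:
        raise ValueError("insufficient seed phenotypes")
    y = inverse_normal_transform(y_raw, rank_transform)

    # proximity profiles for all candidates at once:
    # x[c, j] = sum over d' in D(phens[j]) of prox[c, d']
    dom_index = {d: i for i, d in enumerate(prox.node_ids)}
    indicator = np.zeros((len(prox.node_ids), len(phens)))
    for j, q in enumerate(phens):
        for d2 in eff.domains_for(q):
            i = dom_index.get(d2)
            if i is not None:
                indicator[i, j] = 1.0
    cand_idx = [prox.index_of(d) for d in candidates]
    xs = prox.values[cand_idx, :] @ indicator

    if priors.is_limit:
        log10_bf = limit_log10_bf_many(y, xs, priors.sigma1_sq)
    else:
        l0 = log_marginal_null(y, priors)
        log10_bf = np.array([
            (log_marginal_alternative(y, x, priors) - l0) / LOG10 if np.ptp(x) > 0 else 0.0
            for x in xs
        ])

    yc = y - y.mean()
    xc = xs - xs.mean(axis=1, keepdims=True)
    denom = np.sqrt(np.einsum("ij,ij->i", xc, xc) * (yc @ yc))
    with np.errstate(divide="ignore", invalid="ignore"):
        r2 = np.where(denom > 0, (xc @ yc) ** 2 / denom**2, 0.0)

    ranks = stats.rankdata(-log10_bf, method="average")
    return CandidateRanking(
        query_phenotype=p,
        mode=mode,
        domain_ids=list(candidates),
        log10_bf=np.asarray(log10_bf, dtype=float),
        r_squared=np.asarray(r2, dtype=float),
        ranks=ranks,
        rank_ratios=ranks / len(candidates),
    )


def gene_scores(
    gmap: GeneDomainMap, domain_log10_bf: Mapping[str, float]
) -> list[tuple[str, float]]:
    """Score genes by the maximum log10 BF over their domains, ranked descending.

    Genes with no scored domain are dropped with a warning; an empty result
    is an error.
    """
    import warnings

    out: list[tuple[str, float]] = []
    dropped = 0
    for g, doms in gmap.items():
        scores = [domain_log10_bf[d] for d in doms if d in domain_log10_bf]
        if not scores:
            dropped += 1
            continue
        out.append((g, max(scores)))
    if dropped:
        warnings.warn(f"{dropped} gene(s) had no scored domain and were dropped",
                      stacklevel=2)
    if not out:
        raise ValueError("no gene has a scored domain")
    out.sort(key=lambda gs: (-gs[1], gs[0]))
    return out


def landscape(
    phenotypes: Sequence[str],
    domains: Sequence[str],
    assoc: AssociationSet,
    prox: ProximityMatrix,
    sim: PhenotypeSimilarity,
    priors: RegressionPriors = RegressionPriors(),
    rank_transform: RankTransform = RankTransform(),
    mode: str = "plain",
    exclude_query: bool = True,
    progress: bool = False,
) -> np.ndarray:
    """Full log10 BF matrix, phenotype (rows) x domain (columns)."""
    mat = np.empty((len(phenotypes), len(domains)))
    for i, p in enumerate(phenotypes):
        ranking = score_candidates(
            p, domains, assoc, prox, sim, mode=mode, priors=priors,
            rank_transform=rank_transform, exclude_query=exclude_query,
        )
        mat[i] = ranking.log10_bf
        if progress and (i + 1) % 50 == 0:
            print(f"landscape: {i + 1}/{len(phenotypes)} phenotypes scored", flush=True)
    return mat


def landscape_filter(mat: np.ndarray, threshold: float = 0.1, axis: int = 1) -> np.ndarray:
    """Boolean keep-mask over domain rows of a log10 BF landscape.

    A row is kept when any of its values is >= ``threshold`` (rows that are
    everywhere below 0.1 after the log10 transform are dropped before
    clustering/export). ``axis`` is the axis reduced over (default: the
    phenotype axis of a domain x phenotype view).
    """
    return (mat >= threshold).any(axis=axis)
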