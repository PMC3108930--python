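"""Leave-one-out validation protocols, ranking metrics, and permutation nulls.

Every known (domain, phenotype) association is held out in turn and the true
domain is re-ranked among a candidate set chosen by protocol:

* ``random_control`` — the true domain plus 99 randomly drawn control
  domains (drawn from network domains outside D(p));
* ``linkage_interval`` — the true domain plus all domains with a genomic
  locus within 10 Mbp of any of its loci, simulating a linkage-mapping
  interval;
* ``genome_wide`` — the true domain against every domain in the network.

Summaries: precision (fraction of runs with the true domain ranked exactly
first), mean rank ratio, and AUC of the pooled disease-vs-control
rank-ratio ROC (Mann-Whitney convention, ties credited 1/2). All three are
reported in percent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .bayes import RegressionPriors
from .net_kernels import (
    DomainNetwork,
    KernelParams,
    ProximityMatrix,
    degree_preserving_shuffle,
    diffusion_kernel,
    sg_kernel,
)
from .profiles import (
    AssociationSet,
    PhenotypeSimilarity,
    RankTransform,
    shuffle_associations,
)
from .prioritize import score_candidates

__all__ = [
    "ValidationConfig",
    "association_bayes_factors",
    "DomainLocusMap",
    "EvaluationSummary",
    "loocv",
    "precision",
    "mean_rank_ratio",
    "auc_from_rank_ratios",
    "fold_enrichment",
    "robustness_suite",
]


@dataclass(frozen=True)
class ValidationConfig:
    """Protocol and knobs of one cross-validation experiment."""

    protocol: str = "random_control"
    n_controls: int = 99
    window_bp: int = 10_000_000
    seed: int = 0
    mode: str = "loo_pair"
    score: str = "bf"  # "bf" or "r2"
    control_pool: str = "non_seed"  # "non_seed" or "non_associated"
    seed_fraction: float | None = None
    similarity_top_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.protocol not in ("random_control", "linkage_interval", "genome_wide"):
            raise ValueError(f"unknown protocol: {self.protocol}")
        if self.mode not in ("loo_pair", "ab_initio"):
            raise ValueError(f"unknown mode: {self.mode}")
        if self.n_controls < 1:
            raise ValueError("n_controls must be >= 1")
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        if self.score not in ("bf", "r2"):
            raise ValueError("score must be 'bf' or 'r2'")
        if self.control_pool not in ("non_seed", "non_associated"):
            raise ValueError("control_pool must be 'non_seed' or 'non_associated'")


class DomainLocusMap:
    """domain_id -> list of (chromosome, start, end) 0-based half-open loci."""

    def __init__(self, loci: Mapping[str, Iterable[tuple[str, int, int]]]):
        self.loci: dict[str, list[tuple[str, int, int]]] = {}
        for d, ivals in loci.items():
            lst = []
            for chrom, start, end in ivals:
                start, end = int(start), int(end)
                if start >= end:
                    raise ValueError(f"empty interval for {d}: [{start}, {end})")
                lst.append((str(chrom), start, end))
            self.loci[str(d)] = lst

    @classmethod
    def from_records(cls, records: Iterable[tuple[str, int, int, str]]) -> "DomainLocusMap":
        """From BED-style rows (chrom, start, end, domain_id)."""
        mp: dict[str, list[tuple[str, int, int]]] = {}
        for chrom, start, end, d in records:
            mp.setdefault(str(d), []).append((str(chrom), int(start), int(end)))
        return cls(mp)

    def __contains__(self, d: str) -> bool:
        return d in self.loci

    def get(self, d: str) -> list[tuple[str, int, int]]:
        return self.loci.get(d, [])

    def domains_within(self, d: str, window_bp: int) -> set[str]:
        """Domains with any locus within window_bp of any locus of d.

        Distance is between interval boundaries on the same chromosome,
        0 for overlap; the window boundary is inclusive.
        """
        out: set[str] = set()
        mine = self.get(d)
        for other, ivals in self.loci.items():
            if other == d:
                continue
            hit = False
            for c1, s1, e1 in mine:
                for c2, s2, e2 in ivals:
                    if c1 != c2:
                        continue
                    gap = max(0, s2 - e1, s1 - e2)
                    if gap <= window_bp:
                        hit = True
                        break
                if hit:
                    break
            if hit:
                out.add(other)
        return out


@dataclass
class EvaluationSummary:
    """Precision / mean rank ratio / AUC (all percent) over validation runs."""

    precision: float
    mean_rank_ratio: float
    auc: float
    rank_ratios: list[float] = field(default_factory=list)
    n_runs: int = 0
    n_skipped: int = 0
    fold_enrichment_top1: float | None = None


def precision(ranks: Sequence[float]) -> float:
    """Percent of runs whose (tie-averaged) rank is exactly 1."""
    ranks = list(ranks)
    if not ranks:
        raise ValueError("no ranks")
    return 100.0 * sum(1 for r in ranks if r == 1) / len(ranks)


def mean_rank_ratio(rank_ratios: Sequence[float]) -> float:
    """Mean rank ratio, in percent."""
    rr = np.asarray(list(rank_ratios), dtype=float)
    if rr.size == 0:
        raise ValueError("no rank ratios")
    return float(rr.mean() * 100.0)


def auc_from_rank_ratios(disease_rr: Sequence[float], control_rr: Sequence[float]) -> float:
    """AUC (percent) of disease vs control rank ratios.

    Equals the fraction of (disease, control) pairs where the disease rank
    ratio is smaller, crediting ties 1/2 (Mann-Whitney convention); computed
    by rank sums so large pooled lists stay O((n+m) log(n+m)).
    """
    d = np.asarray(list(disease_rr), dtype=float)
    c = np.asarray(list(control_rr), dtype=float)
    if d.size == 0 or c.size == 0:
        raise ValueError("both rank-ratio lists must be nonempty")
    from scipy.stats import rankdata

    pooled = np.concatenate([d, c])
    r = rankdata(pooled, method="average")
    # U for "disease smaller": count pairs c > d
    u = d.size * c.size + d.size * (d.size + 1) / 2.0 - r[: d.size].sum()
    return float(100.0 * u / (d.size * c.size))


def fold_enrichment(b_percent: float, a_percent: float) -> float:
    """b/a: ranking in the top a% of candidates in b% of runs."""
    if a_percent == 0:
        raise ZeroDivisionError("undefined enrichment")
    return b_percent / a_percent


def association_bayes_factors(
    assoc: AssociationSet,
    prox: ProximityMatrix,
    sim: PhenotypeSimilarity,
    pairs: Sequence[tuple[str, str]] | None = None,
    rank_transform: RankTransform = RankTransform(),
    priors: RegressionPriors = RegressionPriors(),
    shuffle_profile_seed: int | None = None,
) -> np.ndarray:
    """log10 Bayes factor of each known (domain, phenotype) association.

    The distribution of these scores against their values under permuted
    inputs shows whether domain proximity genuinely carries phenotype
    similarity. With ``shuffle_profile_seed`` set, each query's similarity
    profile is permuted before scoring (the disease-disease null).
    """
    from .bayes import limit_log10_bf_many, bayes_factor
    from .profiles import (
        build_similarity_profile,
        inverse_normal_transform,
        shuffle_similarity_profile,
    )

    if pairs is None:
        pairs = sorted(assoc.pairs)
    rng = (np.random.default_rng(shuffle_profile_seed)
           if shuffle_profile_seed is not None else None)
    out = []
    for d, p in pairs:
        if d not in prox or p not in sim:
            out.append(np.nan)
            continue
        sprof = build_similarity_profile(p, sim, assoc, exclude_query=True)
        if rng is not None:
            sprof = shuffle_similarity_profile(sprof, int(rng.integers(2**31 - 1)))
        y = inverse_normal_transform(sprof.values, rank_transform)
        x = np.array([
            sum(prox.values[prox.index_of(d), prox.index_of(d2)]
                for d2 in assoc.domains_for(q) if d2 in prox and (d2, q) != (d, p))
            for q in sprof.phenotype_ids
        ])
        if priors.is_limit:
            out.append(float(limit_log10_bf_many(y, x[None, :], priors.sigma1_sq)[0]))
        else:
            out.append(bayes_factor(y, x, priors).log10_bf)
    return np.asarray(out)


def _candidate_set(
    pair: tuple[str, str],
    protocol: str,
    assoc: AssociationSet,
    network_domains: Sequence[str],
    loci: DomainLocusMap | None,
    n_controls: int,
    window_bp: int,
    rng: np.random.Generator,
    control_pool: str = "non_seed",
) -> list[str] | None:
    d, p = pair
    if protocol == "genome_wide":
        return list(network_domains)
    if protocol == "random_control":
        # "non_seed" keeps every known disease domain out of the control set:
        # other phenotypes' seeds are potential unlabelled positives AND carry
        # a structurally different (self-proximity spiked) predictor profile.
        excluded = assoc.domains if control_pool == "non_seed" else assoc.domains_for(p)
        pool = sorted(set(network_domains) - {d} - excluded)
        k = min(n_controls, len(pool))
        if k < n_controls:
            warnings.warn("control pool smaller than n_controls", stacklevel=2)
        take = rng.choice(len(pool), size=k, replace=False)
        return [d] + [pool[i] for i in sorted(take)]
    # linkage_interval
    assert loci is not None
    nearby = sorted(loci.domains_within(d, window_bp) & set(network_domains))
    if not nearby:
        return None
    return [d] + nearby


def loocv(
    assoc: AssociationSet,
    prox: ProximityMatrix,
    sim: PhenotypeSimilarity,
    config: ValidationConfig,
    loci: DomainLocusMap | None = None,
    rank_transform: RankTransform = RankTransform(),
    priors: RegressionPriors = RegressionPriors(),
) -> EvaluationSummary:
    """One leave-one-out cross-validation experiment.

    Runs one validation per known association; deterministic given
    ``config.seed``. With ``config.seed_fraction`` set, a random fraction of
    the associations is kept as the seed set first (held-out pairs are drawn
    from the kept set).
    """
    if config.protocol == "linkage_interval" and loci is None:
        raise ValueError("linkage_interval protocol requires loci")
    rng = np.random.default_rng(config.seed)
    eff_assoc = assoc
    if config.seed_fraction is not None:
        if not 0 < config.seed_fraction <= 1:
            raise ValueError("seed_fraction must be in (0, 1]")
        pairs = sorted(assoc.pairs)
        k = max(1, int(round(config.seed_fraction * len(pairs))))
        take = rng.choice(len(pairs), size=k, replace=False)
        eff_assoc = AssociationSet([pairs[i] for i in sorted(take)])

    network_domains = list(prox.node_ids)
    ranks: list[float] = []
    rank_ratios: list[float] = []
    control_rr: list[float] = []
    n_skipped = 0
    for pair in sorted(eff_assoc.pairs):
        d, p = pair
        if d not in prox:
            n_skipped += 1
            continue
        candidates = _candidate_set(
            pair, config.protocol, eff_assoc, network_domains, loci,
            config.n_controls, config.window_bp, rng, config.control_pool,
        )
        if candidates is None or len(candidates) < 2:
            warnings.warn(f"run for {pair} has < 2 candidates; skipped", stacklevel=2)
            n_skipped += 1
            continue
        try:
            ranking = score_candidates(
                p, candidates, eff_assoc, prox, sim,
                mode=config.mode, held_out_pair=pair,
                rank_transform=rank_transform, priors=priors,
                similarity_top_fraction=config.similarity_top_fraction,
            )
        except (ValueError, KeyError) as exc:
            warnings.warn(f"run for {pair} skipped: {exc}", stacklevel=2)
            n_skipped += 1
            continue
        if config.score == "r2":
            from scipy.stats import rankdata

            rr = rankdata(-ranking.r_squared, method="average")
            ranking.ranks = rr
            ranking.rank_ratios = rr / len(candidates)
        i_true = candidates.index(d)
        ranks.append(float(ranking.ranks[i_true]))
        rank_ratios.append(float(ranking.rank_ratios[i_true]))
        control_rr.extend(
            float(ranking.rank_ratios[i]) for i in range(len(candidates)) if i != i_true
        )
    if not ranks:
        raise ValueError("no validation runs completed")
    return EvaluationSummary(
        precision=precision(ranks),
        mean_rank_ratio=mean_rank_ratio(rank_ratios),
        auc=auc_from_rank_ratios(rank_ratios, control_rr),
        rank_ratios=rank_ratios,
        n_runs=len(ranks),
        n_skipped=n_skipped,
    )


def robustness_suite(
    assoc: AssociationSet,
    net: DomainNetwork,
    sim: PhenotypeSimilarity,
    config: ValidationConfig,
    which: str,
    seed: int,
    kernel: str = "dk",
    params: KernelParams = KernelParams(),
    loci: DomainLocusMap | None = None,
    rank_transform: RankTransform = RankTransform(),
    priors: RegressionPriors = RegressionPriors(),
    n_replicates: int = 1,
) -> EvaluationSummary:
    """Rerun loocv after destroying one layer of structure.

    ``which`` selects the null: ``shuffle_network`` (degree-preserving edge
    swaps, kernel recomputed), ``shuffle_associations`` / ``random_seed``
    (per-phenotype counts fixed), or ``shuffle_similarity`` (off-diagonal
    similarity values permuted, distribution fixed). With ``n_replicates``
    > 1 the shuffle is redrawn that many times and the summary metrics are
    averaged (one shuffle is a single draw from the null; averaging tightens
    the estimate of the null's location).
    """
    if n_replicates > 1:
        reps = [
            robustness_suite(assoc, net, sim, config, which, seed=seed + 1000 * r,
                             kernel=kernel, params=params, loci=loci,
                             rank_transform=rank_transform, priors=priors)
            for r in range(n_replicates)
        ]
        return EvaluationSummary(
            precision=float(np.mean([s.precision for s in reps])),
            mean_rank_ratio=float(np.mean([s.mean_rank_ratio for s in reps])),
            auc=float(np.mean([s.auc for s in reps])),
            rank_ratios=[rr for s in reps for rr in s.rank_ratios],
            n_runs=sum(s.n_runs for s in reps),
            n_skipped=sum(s.n_skipped for s in reps),
        )
    rng = np.random.default_rng(seed)
    net2, assoc2, sim2 = net, assoc, sim
    if which == "shuffle_network":
        net2 = degree_preserving_shuffle(net, seed=int(rng.integers(2**31 - 1)))
    elif which == "shuffle_associations":
        assoc2 = shuffle_associations(assoc, list(net.node_ids), "permute",
                                      int(rng.integers(2**31 - 1)))
    elif which == "random_seed":
        assoc2 = shuffle_associations(assoc, list(net.node_ids), "random_replace",
                                      int(rng.integers(2**31 - 1)))
    elif which == "shuffle_similarity":
        vals = sim.values.copy()
        iu = np.triu_indices_from(vals, k=1)
        off = vals[iu]
        perm = rng.permutation(off.size)
        vals[iu] = off[perm]
        vals.T[iu] = vals[iu]
        sim2 = PhenotypeSimilarity(list(sim.ids), vals)
    else:
        raise ValueError(f"unknown shuffle: {which}")
    prox = (diffusion_kernel(net2, params.gamma) if kernel == "dk"
            else sg_kernel(net2, params.beta))
    return loocv(assoc2, prox, sim2, config, loci=loci,
                 rank_transform=rank_transform, priors=priors)
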