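"""Permutation test for enrichment of susceptibility SNPs near top domains.

Given a ranked list of domains for a disease and a list of reported
susceptible SNPs, the observed statistic N0 is the number of SNPs lying
within a window (5 Mbp by default) of any of the top-k (default 10) ranked
domains' genomic loci. M random draws of k domains from the candidate
universe give permuted counts N_i, and p = m/M where m counts draws with
N_i >= N0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .evaluation import DomainLocusMap

__all__ = [
    "SnpSet",
    "EnrichmentResult",
    "snp_domain_distance",
    "count_snps_near_domains",
    "enrichment_permutation_test",
]

CATEGORY_WINDOWS_BP = {"inside": 0, "within_1mbp": 1_000_000, "within_5mbp": 5_000_000}


class SnpSet:
    """Reported susceptible SNPs: (snp_id, chromosome, position_bp)."""

    def __init__(self, snps: Iterable[tuple[str, str, int]]):
        seen: set[str] = set()
        rows: list[tuple[str, str, int]] = []
        for sid, chrom, pos in snps:
            sid = str(sid)
            pos = int(pos)
            if pos < 0:
                raise ValueError(f"negative SNP position: {sid}")
            if sid in seen:
                raise ValueError(f"duplicate snp_id: {sid}")
            seen.add(sid)
            rows.append((sid, str(chrom), pos))
        self.snps = rows

    def __len__(self) -> int:
        return len(self.snps)

    def __iter__(self):
        return iter(self.snps)


@dataclass
class EnrichmentResult:
    n0: int
    p_value: float
    m_exceed: int
    M: int
    per_domain: dict[str, dict[str, int]]


def snp_domain_distance(pos: int, start: int, end: int) -> int:
    """Distance (bp) from a SNP to a 0-based half-open locus; 0 if inside."""
    if pos < start:
        return start - pos
    if pos >= end:
        return pos - (end - 1)
    return 0


def _min_distances(snps: SnpSet, domains: Sequence[str], loci: DomainLocusMap
                   ) -> tuple[np.ndarray, list[str]]:
    """Matrix of min SNP-to-locus distances (n_snps x n_domains); inf off-chromosome."""
    usable = []
    for d in domains:
        if loci.get(d):
            usable.append(d)
        else:
            warnings.warn(f"domain without loci excluded: {d}", stacklevel=2)
    dist = np.full((len(snps), len(usable)), np.inf)
    for i, (_, chrom, pos) in enumerate(snps):
        for j, d in enumerate(usable):
            best = np.inf
            for c, s, e in loci.get(d):
                if c != chrom:
                    continue
                best = min(best, snp_domain_distance(pos, s, e))
            dist[i, j] = best
    return dist, usable


def count_snps_near_domains(
    snps: SnpSet,
    domains: Sequence[str],
    loci: DomainLocusMap,
    window_bp: int = 5_000_000,
) -> tuple[int, dict[str, dict[str, int]]]:
    """SNP-level count within window of any listed domain, plus per-domain tallies.

    The total counts each SNP once (a SNP near several domains still adds
    1); the per-domain breakdown counts SNP-domain incidences in three
    nested categories: inside a locus, within 1 Mbp, within 5 Mbp (the last
    capped at ``window_bp`` if smaller).
    """
    if window_bp <= 0:
        raise ValueError("window_bp must be > 0")
    dist, usable = _min_distances(snps, domains, loci)
    if not usable:
        return 0, {}
    total = int((dist <= window_bp).any(axis=1).sum())
    per_domain: dict[str, dict[str, int]] = {}
    for j, d in enumerate(usable):
        per_domain[d] = {
            cat: int((dist[:, j] <= min(w, window_bp)).sum())
            for cat, w in CATEGORY_WINDOWS_BP.items()
        }
    return total, per_domain


def enrichment_permutation_test(
    ranked_domains: Sequence[str],
    snps: SnpSet,
    loci: DomainLocusMap,
    universe: Sequence[str],
    top_k: int = 10,
    M: int = 10_000,
    window_bp: int = 5_000_000,
    seed: int = 0,
) -> EnrichmentResult:
    """p = m/M for the SNP-proximity count of the top-k ranked domains.

    Each permutation draws ``top_k`` domains uniformly without replacement
    from ``universe``; m counts permutations with N_i >= N0 (no continuity
    correction). Deterministic given ``seed``.
    """
    universe = list(universe)
    if top_k > len(universe):
        raise ValueError("top_k exceeds universe size")
    if M < 1:
        raise ValueError("M must be >= 1")
    top = list(ranked_domains)[:top_k]
    n0, per_domain = count_snps_near_domains(snps, top, loci, window_bp)

    # precompute SNP x universe-domain incidence once; each draw is a column gather
    dist, usable = _min_distances(snps, universe, loci)
    hit = dist <= window_bp
    usable_idx = np.arange(len(usable))
    rng = np.random.default_rng(seed)
    m_exceed = 0
    for _ in range(M):
        take = rng.choice(usable_idx, size=min(top_k, len(usable)), replace=False)
        n_i = int(hit[:, take].any(axis=1).sum())
        if n_i >= n0:
            m_exceed += 1
    return EnrichmentResult(
        n0=n0, p_value=m_exceed / M, m_exceed=m_exceed, M=M, per_domain=per_domain
    )
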