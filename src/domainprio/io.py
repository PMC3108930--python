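"""Readers and writers for the exchange formats, plus run configuration.

All tabular formats are tab-separated, UTF-8, with ``#`` comment lines and
no quoting. Genomic coordinates are 0-based half-open (BED native); 1-based
inputs must be converted upstream.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .bayes import RegressionPriors
from .evaluation import DomainLocusMap, ValidationConfig
from .gwas_enrich import SnpSet
from .net_kernels import DomainNetwork, KernelParams, ProximityMatrix
from .prioritize import CandidateRanking, GeneDomainMap
from .profiles import AssociationSet, PhenotypeSimilarity, RankTransform

__all__ = [
    "RunConfig",
    "read_edge_list",
    "read_associations",
    "read_similarity",
    "read_loci",
    "read_snps",
    "read_gene_map",
    "read_inputs",
    "write_proximity_matrix",
    "read_proximity_matrix",
    "write_ranking",
    "write_landscape",
]


def _data_rows(path: str | Path, n_cols: int) -> list[tuple[int, list[str]]]:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < n_cols:
                raise ValueError(f"{path}:{lineno}: expected {n_cols} tab-separated fields")
            rows.append((lineno, parts))
    return rows


def read_edge_list(path: str | Path) -> DomainNetwork:
    """2-column TSV of domain pairs; duplicates and reversals merged."""
    edges = [(p[0], p[1]) for _, p in _data_rows(path, 2)]
    if not edges:
        raise ValueError(f"{path}: empty network")
    return DomainNetwork.from_edges(edges)


def read_associations(path: str | Path) -> AssociationSet:
    """2-column TSV (domain_id, phenotype_id)."""
    return AssociationSet((p[0], p[1]) for _, p in _data_rows(path, 2))


def read_similarity(path: str | Path) -> PhenotypeSimilarity:
    """Square TSV with id header row/column, or 3-column long TSV.

    Long form is symmetrized by the maximum of the two directed entries;
    missing pairs default to 0 and the diagonal to 1.
    """
    with open(path) as fh:
        first = fh.readline().rstrip("\n").split("\t")
    if len(first) > 3 or (len(first) >= 2 and first[0].lower() in ("id", "")):
        df = pd.read_csv(path, sep="\t", index_col=0, comment=None)
        ids = [str(i) for i in df.index]
        if [str(c) for c in df.columns] != ids:
            raise ValueError(f"{path}: row and column ids differ")
        vals = df.to_numpy(dtype=float)
        vals = np.maximum(vals, vals.T)
    else:
        rows = _data_rows(path, 3)
        ids = sorted({p[0] for _, p in rows} | {p[1] for _, p in rows})
        index = {q: i for i, q in enumerate(ids)}
        vals = np.zeros((len(ids), len(ids)))
        for lineno, p in rows:
            try:
                v = float(p[2])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad similarity value") from exc
            i, j = index[p[0]], index[p[1]]
            vals[i, j] = max(vals[i, j], v)
            vals[j, i] = vals[i, j]
        np.fill_diagonal(vals, 1.0)
    if vals.min() < 0 or vals.max() > 1 + 1e-12:
        raise ValueError(f"{path}: similarity out of [0,1]")
    return PhenotypeSimilarity(ids, vals)


def read_loci(path: str | Path) -> DomainLocusMap:
    """BED (chrom, start, end, domain_id)."""
    recs = []
    for lineno, p in _data_rows(path, 4):
        try:
            recs.append((p[0], int(p[1]), int(p[2]), p[3]))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad BED coordinates") from exc
    return DomainLocusMap.from_records(recs)


def read_snps(path: str | Path) -> SnpSet:
    """BED-like TSV (chrom, pos, pos+1, snp_id)."""
    snps = []
    for lineno, p in _data_rows(path, 4):
        try:
            snps.append((p[3], p[0], int(p[1])))
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: bad SNP position") from exc
    return SnpSet(snps)


def read_gene_map(path: str | Path) -> GeneDomainMap:
    """2-column TSV (gene_id, domain_id)."""
    return GeneDomainMap.from_pairs((p[0], p[1]) for _, p in _data_rows(path, 2))


@dataclass
class InputBundle:
    network: DomainNetwork
    assoc: AssociationSet
    sim: PhenotypeSimilarity
    loci: DomainLocusMap | None = None
    gene_map: GeneDomainMap | None = None
    snps: SnpSet | None = None
    report: dict[str, Any] = field(default_factory=dict)


def read_inputs(
    edges: str | Path,
    associations: str | Path,
    similarity: str | Path,
    loci: str | Path | None = None,
    gene_map: str | Path | None = None,
    snps: str | Path | None = None,
) -> InputBundle:
    """Load and cross-validate all inputs.

    Associations naming domains absent from the network, or phenotypes
    absent from the similarity matrix, are retained (absent domains
    contribute zero proximity) but listed in the validation report.
    """
    net = read_edge_list(edges)
    assoc = read_associations(associations)
    sim = read_similarity(similarity)
    report: dict[str, Any] = {
        "domains_not_in_network": sorted(assoc.domains - set(net.node_ids)),
        "phenotypes_not_in_similarity": sorted(
            p for p in assoc.seed_phenotypes if p not in sim
        ),
    }
    if not (assoc.domains & set(net.node_ids)):
        raise ValueError("no association domain occurs in the network")
    if not (set(assoc.seed_phenotypes) & set(sim.ids)):
        raise ValueError("no seed phenotype occurs in the similarity matrix")
    bundle = InputBundle(net, assoc, sim, report=report)
    if loci is not None:
        bundle.loci = read_loci(loci)
    if gene_map is not None:
        bundle.gene_map = read_gene_map(gene_map)
    if snps is not None:
        bundle.snps = read_snps(snps)
    return bundle


def write_proximity_matrix(prox: ProximityMatrix, path: str | Path) -> None:
    df = pd.DataFrame(prox.values, index=prox.node_ids, columns=prox.node_ids)
    df.to_csv(path, sep="\t", float_format="%.10g", index_label="id")


def read_proximity_matrix(path: str | Path, kind: str = "DK") -> ProximityMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ProximityMatrix([str(i) for i in df.index], df.to_numpy(dtype=float), kind)


def write_ranking(ranking: CandidateRanking, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("phenotype_id\tdomain_id\tlog10_bf\tr_squared\trank\trank_ratio\n")
        for d, bf, r2, rank, rr in ranking.entries:
            fh.write(f"{ranking.query_phenotype}\t{d}\t{bf:.6g}\t{r2:.6g}"
                     f"\t{rank:g}\t{rr:.6g}\n")


def write_landscape(mat: np.ndarray, phenotypes: list[str], domains: list[str],
                    path: str | Path) -> None:
    pd.DataFrame(mat, index=phenotypes, columns=domains).to_csv(
        path, sep="\t", float_format="%.6g", index_label="phenotype_id")


@dataclass
class RunConfig:
    """Bundle of model settings; YAML/JSON-loadable, flags win over file."""

    kernel: str = "dk"
    kernel_params: KernelParams = field(default_factory=KernelParams)
    rank_transform: RankTransform = field(default_factory=RankTransform)
    priors: RegressionPriors = field(default_factory=RegressionPriors)
    validation: ValidationConfig = field(default_factory=ValidationConfig)
    seed: int = 0

    @classmethod
    def from_dict(cls, raw: dict[str, Any]) -> "RunConfig":
        kw: dict[str, Any] = {}
        if "kernel" in raw:
            kw["kernel"] = str(raw["kernel"]).lower()
        if "beta" in raw or "gamma" in raw:
            kw["kernel_params"] = KernelParams(
                beta=float(raw.get("beta", 1.0)), gamma=float(raw.get("gamma", 0.05)))
        if "rank_offset" in raw:
            kw["rank_transform"] = RankTransform(offset=float(raw["rank_offset"]))
        prior_keys = {"mu0", "sigma_mu_sq", "sigma1_sq", "n0", "sigma0_sq"}
        if prior_keys & raw.keys():
            pk = {k: raw[k] for k in prior_keys & raw.keys()}
            if "mu0" in pk:
                pk["mu0"] = tuple(float(v) for v in pk["mu0"])
            if "sigma_mu_sq" in pk and pk["sigma_mu_sq"] in ("inf", None):
                pk["sigma_mu_sq"] = math.inf
            kw["priors"] = RegressionPriors(**pk)
        val_keys = {f.name for f in dataclasses.fields(ValidationConfig)}
        if val_keys & raw.keys():
            kw["validation"] = ValidationConfig(**{k: raw[k] for k in val_keys & raw.keys()})
        if "seed" in raw:
            kw["seed"] = int(raw["seed"])
        return cls(**kw)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        import json

        import yaml

        text = Path(path).read_text()
        raw = (json.loads(text) if str(path).endswith(".json")
               else yaml.safe_load(text)) or {}
        return cls.from_dict(raw)
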