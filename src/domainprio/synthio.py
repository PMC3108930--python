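"""Seeded synthetic scenarios with the structure the method assumes.

The generative model makes "domain proximity implies phenotype similarity" a
tunable, recoverable ground truth:

1. a domain interaction network is grown (preferential attachment by
   default, mean degree matching the requested edge density);
2. each phenotype receives a small cluster of seed domains around a random
   center, so its domains are network-proximal;
3. domains are embedded by the network's Laplacian spectrum; a phenotype's
   latent vector mixes the mean embedding of its seed domains (weight
   ``signal_strength``) with an independent random direction (weight
   ``1 - signal_strength``); phenotype similarity is the cosine of latent
   vectors plus Gaussian noise, clipped to [0, 1];
4. domain loci are tiled in random order over a synthetic genome, and
   susceptibility SNPs are planted within 1 Mbp of designated risk domains.

At ``signal_strength = 0`` similarity is independent of the network and any
prioritization is at chance; at 1 it is a noisy deterministic function of
network proximity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .evaluation import DomainLocusMap
from .gwas_enrich import SnpSet
from .net_kernels import DomainNetwork, build_laplacian
from .prioritize import GeneDomainMap
from .profiles import AssociationSet, PhenotypeSimilarity

__all__ = ["SyntheticScenario", "ScenarioBundle", "simulate_network",
           "simulate_scenario", "uniform_snps", "write_fixture"]

_DOMAIN_LOCUS_BP = 20_000  # synthetic domain locus width
_LATENT_DIFFUSION_TIME = 0.3  # heat-kernel time of the latent domain embedding


@dataclass(frozen=True)
class SyntheticScenario:
    """Configuration of one synthetic study.

    Defaults mirror the study conditions of the method's primary
    evaluation: a sparse domain network (mean degree ~2.3), ~1.4 associated
    domains per phenotype, strong but noisy proximity-similarity coupling.
    """

    n_domains: int = 400
    n_phenotypes: int = 150
    network_model: str = "preferential_attachment"
    edge_density: float = 2.3  # target mean degree
    n_planted_pairs: int = 50
    signal_strength: float = 0.9
    noise_sd: float = 0.05
    genome: tuple[int, int] = (5, 100_000_000)  # (n_chromosomes, chrom length bp)
    n_snps: int = 40
    latent_diffusion_time: float = _LATENT_DIFFUSION_TIME
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_domains, self.n_phenotypes, self.n_planted_pairs,
               self.genome[0], self.genome[1], self.n_snps) <= 0:
            raise ValueError("all counts must be positive")
        if not 0 <= self.signal_strength <= 1:
            raise ValueError("signal_strength must be in [0, 1]")
        if self.network_model not in ("preferential_attachment", "erdos_renyi"):
            raise ValueError(f"unknown network model: {self.network_model}")
        if self.n_planted_pairs > self.n_domains:
            raise ValueError("more planted pairs than domains")


@dataclass
class ScenarioBundle:
    cfg: SyntheticScenario
    network: DomainNetwork
    assoc: AssociationSet
    sim: PhenotypeSimilarity
    loci: DomainLocusMap
    gene_map: GeneDomainMap
    snps: SnpSet
    planted_pairs: list[tuple[str, str]] = field(default_factory=list)
    risk_domains: list[str] = field(default_factory=list)


def _domain_id(i: int) -> str:
    return f"D{i:04d}"


def _phenotype_id(i: int) -> str:
    return f"P{i:03d}"


def simulate_network(n: int, model: str = "preferential_attachment",
                     density: float = 2.3, seed: int = 0) -> DomainNetwork:
    """Random domain network with realized mean degree 2*round(n*density/2)/n.

    Preferential attachment grows a connected tree and then adds extra edges
    with degree-proportional endpoint choice until the edge budget
    ``round(n * density / 2)`` is met; Erdos-Renyi draws exactly that many
    edges uniformly.
    """
    rng = np.random.default_rng(seed)
    ids = [_domain_id(i) for i in range(n)]
    if n == 1:
        return DomainNetwork(ids, [])
    target_edges = max(n - 1 if model == "preferential_attachment" else 1,
                       int(round(n * density / 2.0)))
    if model == "erdos_renyi":
        g = nx.gnm_random_graph(n, min(target_edges, n * (n - 1) // 2),
                                seed=int(rng.integers(2**31 - 1)))
        return DomainNetwork(ids, [(ids[u], ids[v]) for u, v in g.edges()])
    # preferential attachment: BA tree backbone + degree-biased extra edges
    g = nx.barabasi_albert_graph(n, 1, seed=int(rng.integers(2**31 - 1)))
    tries = 0
    while g.number_of_edges() < target_edges and tries < 100 * target_edges:
        tries += 1
        deg = np.array([g.degree(i) for i in range(n)], dtype=float)
        u = int(rng.integers(n))
        v = int(rng.choice(n, p=deg / deg.sum()))
        if u != v and not g.has_edge(u, v):
            g.add_edge(u, v)
    return DomainNetwork(ids, [(ids[u], ids[v]) for u, v in g.edges()])


def _spectral_embedding(net: DomainNetwork, t: float = _LATENT_DIFFUSION_TIME) -> np.ndarray:
    """Heat-kernel feature map: rows of ``exp(-t/2 * L)`` via eigendecomposition.

    Cosines between rows equal the degree-normalized heat-kernel affinity at
    time ``t``, so nearby nodes get similar coordinates with local (not just
    regional) resolution.
    """
    lap = build_laplacian(net).astype(float)
    eigval, eigvec = np.linalg.eigh(lap)
    return eigvec * np.exp(-0.5 * t * eigval)


def _unit(v: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(v)
    return v / nrm if nrm > 0 else v


def simulate_scenario(cfg: SyntheticScenario) -> ScenarioBundle:
    """Deterministic bundle of network, associations, similarity, loci,
    gene map and SNPs; all randomness flows from ``cfg.seed`` via named
    substreams."""
    ss = np.random.SeedSequence(cfg.seed)
    (s_net, s_assoc, s_latent, s_noise, s_loci, s_genes, s_snps) = ss.spawn(7)

    net = simulate_network(cfg.n_domains, cfg.network_model, cfg.edge_density,
                           seed=int(np.random.default_rng(s_net).integers(2**31 - 1)))
    emb = _spectral_embedding(net, cfg.latent_diffusion_time)
    emb_unit = np.array([_unit(r) for r in emb])

    # associations: one anchor domain per phenotype, anchors all distinct.
    # Disjoint seed sets keep every recoverable signal network-mediated: a
    # domain shared by two phenotypes would couple their similarity to the
    # candidate directly (through the kernel diagonal), a shortcut that
    # survives even a degree-preserving network shuffle.
    rng_a = np.random.default_rng(s_assoc)
    phen_ids = [_phenotype_id(i) for i in range(cfg.n_phenotypes)]
    if cfg.n_phenotypes > net.n:
        raise ValueError("need at least as many domains as phenotypes")
    center_pool = rng_a.choice(net.n, size=cfg.n_phenotypes, replace=False)
    centers = {p: net.node_ids[int(c)] for p, c in zip(phen_ids, center_pool)}
    pairs = [(centers[p], p) for p in phen_ids]
    assoc = AssociationSet(pairs)

    # phenotype latent vectors: network part vs independent random part
    rng_l = np.random.default_rng(s_latent)
    latents = np.empty((cfg.n_phenotypes, net.n))
    for i, p in enumerate(phen_ids):
        idx = [net.index_of(d) for d in sorted(assoc.domains_for(p))]
        v_net = _unit(emb_unit[idx].mean(axis=0))
        v_rand = _unit(rng_l.normal(size=net.n))
        latents[i] = _unit(cfg.signal_strength * v_net
                           + (1.0 - cfg.signal_strength) * v_rand)

    rng_n = np.random.default_rng(s_noise)
    cos = latents @ latents.T
    noise = rng_n.normal(scale=cfg.noise_sd, size=cos.shape)
    noise = (noise + noise.T) / np.sqrt(2.0)
    simvals = np.clip(cos + noise, 0.0, 1.0)
    np.fill_diagonal(simvals, 1.0)
    sim = PhenotypeSimilarity(phen_ids, simvals)

    # planted test pairs: (center domain, phenotype) for a random phenotype subset
    k_plant = min(cfg.n_planted_pairs, cfg.n_phenotypes)
    plant_idx = np.random.default_rng(s_assoc.spawn(1)[0]).choice(
        cfg.n_phenotypes, size=k_plant, replace=False)
    planted = [(centers[phen_ids[i]], phen_ids[i]) for i in sorted(plant_idx)]

    # loci: tile domains in random order over the genome
    rng_loc = np.random.default_rng(s_loci)
    n_chrom, chrom_len = cfg.genome
    order = rng_loc.permutation(net.n)
    spacing = (n_chrom * chrom_len) // max(net.n, 1)
    loci_map: dict[str, list[tuple[str, int, int]]] = {}
    for slot, i in enumerate(order):
        gpos = slot * spacing
        chrom = f"chr{gpos // chrom_len + 1}"
        start = gpos % chrom_len
        end = min(start + _DOMAIN_LOCUS_BP, chrom_len)
        loci_map[net.node_ids[i]] = [(chrom, start, end)]
    loci = DomainLocusMap(loci_map)

    # gene -> domain map: one gene per domain slot, 1 + Poisson(0.8) domains
    rng_g = np.random.default_rng(s_genes)
    gmap: dict[str, set[str]] = {}
    for i in range(cfg.n_domains):
        k = 1 + int(rng_g.poisson(0.8))
        take = rng_g.choice(net.n, size=min(k, net.n), replace=False)
        gmap[f"G{i:04d}"] = {net.node_ids[j] for j in take}
    gene_map = GeneDomainMap(gmap)

    # risk domains: domains of the first planted pairs; SNPs within 1 Mbp
    risk: list[str] = []
    for d, _ in planted:
        if d not in risk:
            risk.append(d)
        if len(risk) >= 10:
            break
    rng_s = np.random.default_rng(s_snps)
    snp_rows: list[tuple[str, str, int]] = []
    for i in range(cfg.n_snps):
        d = risk[int(rng_s.integers(len(risk)))]
        chrom, start, end = loci.get(d)[0]
        offset = int(rng_s.integers(-1_000_000, 1_000_001))
        pos = int(np.clip((start + end) // 2 + offset, 0, chrom_len - 1))
        snp_rows.append((f"rs{i:05d}", chrom, pos))
    snps = SnpSet(snp_rows)

    return ScenarioBundle(cfg=cfg, network=net, assoc=assoc, sim=sim, loci=loci,
                          gene_map=gene_map, snps=snps, planted_pairs=planted,
                          risk_domains=risk)


def uniform_snps(genome: tuple[int, int], n: int, seed: int) -> SnpSet:
    """Background SNPs scattered uniformly over the synthetic genome.

    Unlike the bundle's planted SNPs (clustered near risk domains), these
    carry no enrichment signal; they are the right input for calibrating
    the SNP-proximity permutation test under its null.
    """
    rng = np.random.default_rng(seed)
    n_chrom, chrom_len = genome
    return SnpSet([
        (f"bg{i:05d}", f"chr{int(rng.integers(1, n_chrom + 1))}",
         int(rng.integers(chrom_len)))
        for i in range(n)
    ])


def write_fixture(bundle: ScenarioBundle, outdir: str | Path) -> dict[str, Path]:
    """Write every exchange format; all readers round-trip these files."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "edges": outdir / "edges.tsv",
        "associations": outdir / "associations.tsv",
        "similarity": outdir / "similarity.tsv",
        "loci": outdir / "loci.bed",
        "snps": outdir / "snps.bed",
        "gene_map": outdir / "gene_map.tsv",
        "planted": outdir / "planted_pairs.tsv",
    }
    with open(paths["edges"], "w") as fh:
        fh.write("# domain_id\tdomain_id\n")
        for u, v in sorted(bundle.network.edges):
            fh.write(f"{u}\t{v}\n")
    with open(paths["associations"], "w") as fh:
        fh.write("# domain_id\tphenotype_id\n")
        for d, p in sorted(bundle.assoc.pairs):
            fh.write(f"{d}\t{p}\n")
    with open(paths["similarity"], "w") as fh:
        fh.write("id\t" + "\t".join(bundle.sim.ids) + "\n")
        for i, p in enumerate(bundle.sim.ids):
            row = "\t".join(format(v, ".6f") for v in bundle.sim.values[i])
            fh.write(f"{p}\t{row}\n")
    with open(paths["loci"], "w") as fh:
        for d in sorted(bundle.loci.loci):
            for chrom, start, end in bundle.loci.get(d):
                fh.write(f"{chrom}\t{start}\t{end}\t{d}\n")
    with open(paths["snps"], "w") as fh:
        for sid, chrom, pos in bundle.snps:
            fh.write(f"{chrom}\t{pos}\t{pos + 1}\t{sid}\n")
    with open(paths["gene_map"], "w") as fh:
        fh.write("# gene_id\tdomain_id\n")
        for gid in sorted(bundle.gene_map.mapping):
            for d in sorted(bundle.gene_map.mapping[gid]):
                fh.write(f"{gid}\t{d}\n")
    with open(paths["planted"], "w") as fh:
        fh.write("# domain_id\tphenotype_id\n")
        for d, p in bundle.planted_pairs:
            fh.write(f"{d}\t{p}\n")
    return paths
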