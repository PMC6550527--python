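"""Synthetic clade, immunity-phenotype, plate and binding-series generators.

The clade generator emulates the statistical structure of a temperate-phage
clade that the analysis pipeline assumes: genomes of ~50 kb carrying 20-30
planted 13-bp repressor-binding sites oriented with transcription relative
to a central inheritance-marker gene, a repressor protein whose C-terminal
region drifts faster than its N-terminal DNA-binding region, and gene
(pham) content that turns over along the tree, with motif, repressor and
pham divergence all increasing with tree distance.  Phenotypes are
generated from genotype distances through a saturating ordinal link with a
per-phage promiscuity term that produces mesoimmune asymmetry; they are a
deliberate statistical stand-in, not a biophysical model of repression.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import Phylo

from .binding import BindingSeries
from .core_io import AssayRecord, GeneRecord, PhageGenome
from .immunity import PlateObservation
from .motifs import MotifModel, StoperatorSite, build_pwm, revcomp

__all__ = [
    "CladeSimConfig",
    "SimulatedClade",
    "PhenotypeSimConfig",
    "simulate_clade",
    "simulate_immunity",
    "simulate_plate_observations",
    "simulate_binding",
    "simulate_unrelated_pair",
    "balanced_newick",
]

_BASES = "ACGT"
_AAS = "ACDEFGHIKLMNPQRSTVWY"


def balanced_newick(n_leaves: int, branch_length: float) -> str:
    """Newick string of a balanced binary tree with uniform branch lengths."""

    def build(lo: int, hi: int) -> str:
        if hi - lo == 1:
            return f"T{lo + 1:02d}:{branch_length}"
        mid = (lo + hi + 1) // 2
        return f"({build(lo, mid)},{build(mid, hi)}):{branch_length}"

    if n_leaves < 2:
        raise ValueError("need at least 2 taxa")
    return build(0, n_leaves) + ";"


@dataclass(frozen=True)
class CladeSimConfig:
    """Study conditions of the simulated clade.

    Rates are per unit branch length.  Defaults give a 16-taxon balanced
    clade whose pairwise motif distances span roughly the homotypic-to-
    mesotypic range, each genome carrying 20-30 planted sites with a high
    syn-orientation fraction.
    """

    n_phages: int = 16
    newick: str | None = None  # overrides n_phages/branch_length when given
    branch_length: float = 0.5
    genome_length: int = 50_000
    sites_range: tuple[int, int] = (20, 30)
    motif_width: int = 13
    nuc_sub_rate: float = 0.04  # background substitutions /site/unit branch
    motif_sub_rate: float = 0.3  # consensus substitutions /position/unit branch
    site_noise: float = 0.05  # per-base mismatch when stamping each site copy
    n_phams: int = 40
    pham_turnover_rate: float = 0.08  # pham replacement /pham/unit branch
    rep_length: int = 183
    rep_nterm_rate: float = 0.02  # aa substitutions /site/unit branch
    rep_cterm_rate: float = 0.06
    rep_split: int = 60  # N-/C-terminal boundary (residues 1..split = N)
    hth_range: tuple[int, int] = (21, 40)  # 20-aa DNA-binding domain (1-based)
    syn_probability: float = 0.95

    def __post_init__(self) -> None:
        if self.sites_range[0] < 10 or self.sites_range[1] > 50:
            raise ValueError("sites_range must lie within [10, 50]")
        for r in (self.motif_sub_rate, self.pham_turnover_rate,
                  self.rep_nterm_rate, self.rep_cterm_rate):
            if r < 0:
                raise ValueError("rates must be >= 0")


@dataclass
class SimulatedClade:
    """Genomes plus the ground truth needed to recompute every planted feature."""

    config: CladeSimConfig
    seed: int
    newick: str
    genomes: dict[str, PhageGenome]
    planted_sites: dict[str, list[StoperatorSite]]
    consensus: dict[str, str]  # per-taxon true motif consensus
    rep_seqs: dict[str, str]
    pham_sets: dict[str, set[str]]

    def true_motif(self, taxon: str) -> MotifModel:
        """Count-based motif model recomputed from the planted site copies."""
        return build_pwm(
            [s.sequence for s in self.planted_sites[taxon]],
            name=f"{taxon}:planted",
        )

    def hth_domain(self, taxon: str) -> str:
        lo, hi = self.config.hth_range
        return self.rep_seqs[taxon][lo - 1 : hi]


def _stable_seed(*parts: str) -> int:
    return zlib.crc32(";".join(parts).encode()) & 0x7FFFFFFF


def _evolve_state(state: dict, branch: float, cfg: CladeSimConfig,
                  rng: np.random.Generator, counters: dict) -> dict:
    bg = state["bg"]
    p_nuc = 1.0 - np.exp(-cfg.nuc_sub_rate * branch)
    if p_nuc > 0:
        mask = rng.random(bg.shape[0]) < p_nuc
        bg = bg.copy()
        bg[mask] = (bg[mask] + 1 + rng.integers(0, 3, int(mask.sum()))) % 4
    consensus = list(state["consensus"])
    for j in range(len(consensus)):
        if rng.random() < 1.0 - np.exp(-cfg.motif_sub_rate * branch):
            consensus[j] = _BASES[
                (_BASE_IDX[consensus[j]] + 1 + rng.integers(3)) % 4
            ]
    rep = list(state["rep"])
    lo, hi = cfg.hth_range
    for i in range(len(rep)):
        if lo - 1 <= i < hi:
            rate = cfg.rep_nterm_rate / 5.0  # DNA-binding domain under constraint
        elif i < cfg.rep_split:
            rate = cfg.rep_nterm_rate
        else:
            rate = cfg.rep_cterm_rate
        if rng.random() < 1.0 - np.exp(-rate * branch):
            rep[i] = _AAS[
                (_AAS.index(rep[i]) + 1 + rng.integers(len(_AAS) - 1))
                % len(_AAS)
            ]
    phams = set()
    p_turn = 1.0 - np.exp(-cfg.pham_turnover_rate * branch)
    for p in sorted(state["phams"]):
        if rng.random() < p_turn:
            counters["pham"] += 1
            phams.add(f"pham_{counters['pham']:05d}")
        else:
            phams.add(p)
    return {"bg": bg, "consensus": "".join(consensus), "rep": "".join(rep),
            "phams": phams}


_BASE_IDX = {b: i for i, b in enumerate(_BASES)}

# minimal codon table for writing a protein into genome sequence
_CODON_OF = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT", "G": "GGT",
    "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAT",
    "P": "CCT", "Q": "CAA", "R": "CGT", "S": "TCT", "T": "ACT", "V": "GTT",
    "W": "TGG", "Y": "TAT",
}


def _leaf_genome(
    taxon: str, state: dict, cfg: CladeSimConfig, seed: int
) -> tuple[PhageGenome, list[StoperatorSite]]:
    rng = np.random.default_rng(
        [seed, _stable_seed(state["consensus"], state["rep"],
                            ",".join(sorted(state["phams"])),
                            str(zlib.crc32(state["bg"].tobytes())))]
    )
    L = cfg.genome_length
    w = cfg.motif_width
    seq = ["ACGT"[i] for i in state["bg"]]

    genes: list[GeneRecord] = []
    # inheritance marker at the genome center
    inheritance = "integrase" if rng.random() < 0.5 else "parABS"
    marker_product = "integrase" if inheritance == "integrase" else "parA"
    center = L // 2
    genes.append(
        GeneRecord(
            gene_id=f"{taxon}_marker", start=center - 500, end=center + 500,
            strand="+", pham=f"{marker_product}_pham", product=marker_product,
        )
    )
    # repressor gene on the bottom strand in the right arm
    rep_nt = "".join(_CODON_OF[a] for a in state["rep"]) + "TAA"
    rep_end = int(L * 0.88)
    rep_start = rep_end - len(rep_nt) + 1
    seq[rep_start - 1 : rep_end] = list(revcomp(rep_nt))
    genes.append(
        GeneRecord(
            gene_id=f"{taxon}_rep", start=rep_start, end=rep_end, strand="-",
            pham="rep_pham", product="rep",
        )
    )
    # one annotation-only filler gene per pham, alternating arms
    phams = sorted(state["phams"])
    slot = 0
    for i, pham in enumerate(phams):
        arm_left = i % 2 == 0
        base = 1000 + (i // 2) * 450 if arm_left else center + 1500 + (i // 2) * 450
        if base + 300 > L - 1000:
            continue
        genes.append(
            GeneRecord(
                gene_id=f"{taxon}_g{slot:03d}", start=base, end=base + 299,
                strand="+" if arm_left else "-", pham=pham,
                product="hypothetical",
            )
        )
        slot += 1

    # plant stoperators outside gene-free guard zones
    n_sites = int(rng.integers(cfg.sites_range[0], cfg.sites_range[1] + 1))
    occupied = [(g.start, g.end) for g in genes]
    sites: list[StoperatorSite] = []
    attempts = 0
    while len(sites) < n_sites and attempts < 200 * n_sites:
        attempts += 1
        start = int(rng.integers(500, L - 500 - w))
        end = start + w - 1
        if any(start <= e and s <= end for s, e in occupied):
            continue
        left_arm = (start + end) // 2 < center
        syn = rng.random() < cfg.syn_probability
        strand = ("+" if left_arm else "-") if syn else ("-" if left_arm else "+")
        core = [
            b
            if rng.random() >= cfg.site_noise
            else _BASES[(_BASE_IDX[b] + 1 + rng.integers(3)) % 4]
            for b in state["consensus"]
        ]
        core = "".join(core)
        top = core if strand == "+" else revcomp(core)
        seq[start - 1 : end] = list(top)
        occupied.append((start - w, end + w))  # keep planted sites apart
        sites.append(
            StoperatorSite(
                genome_id=taxon, start=start, end=end, strand=strand,
                sequence=core, score=float("nan"),
                orientation="syn" if syn else "anti",
            )
        )
    if len(sites) < cfg.sites_range[0]:
        raise ValueError("genome too short to pack the requested sites")
    sites.sort(key=lambda s: s.start)
    genome = PhageGenome(
        id=taxon, sequence="".join(seq), genes=genes,
        subcluster="sim", inheritance=inheritance,
    )
    return genome, sites


def simulate_clade(config: CladeSimConfig | None = None, seed: int = 0) -> SimulatedClade:
    """Evolve a phage clade along a tree and emit genomes plus ground truth.

    Motif consensus, repressor sequence and pham content drift along each
    branch at the configured rates; each leaf genome is then assembled
    deterministically from its evolved state, so zero-length branches yield
    byte-identical genomes.
    """
    cfg = config or CladeSimConfig()
    newick = cfg.newick or balanced_newick(cfg.n_phages, cfg.branch_length)
    tree = Phylo.read(io.StringIO(newick), "newick")

    rng = np.random.default_rng([seed, 0xC1ADE])
    root_state = {
        "bg": rng.integers(0, 4, cfg.genome_length).astype(np.int8),
        "consensus": "".join(_BASES[i] for i in rng.integers(0, 4, cfg.motif_width)),
        "rep": "M" + "".join(
            _AAS[i] for i in rng.integers(0, len(_AAS), cfg.rep_length - 1)
        ),
        "phams": {f"pham_{i:05d}" for i in range(cfg.n_phams)},
    }
    counters = {"pham": cfg.n_phams}

    leaf_states: dict[str, dict] = {}

    def walk(clade, state):
        for child in clade.clades:
            branch = child.branch_length or 0.0
            child_rng = np.random.default_rng(
                [seed, _stable_seed(_clade_path(tree, child))]
            )
            child_state = _evolve_state(state, branch, cfg, child_rng, counters)
            if child.is_terminal():
                leaf_states[child.name] = child_state
            else:
                walk(child, child_state)

    walk(tree.root, root_state)

    genomes: dict[str, PhageGenome] = {}
    planted: dict[str, list[StoperatorSite]] = {}
    for taxon in sorted(leaf_states):
        genome, sites = _leaf_genome(taxon, leaf_states[taxon], cfg, seed)
        genomes[taxon] = genome
        planted[taxon] = sites
    return SimulatedClade(
        config=cfg,
        seed=seed,
        newick=newick,
        genomes=genomes,
        planted_sites=planted,
        consensus={t: s["consensus"] for t, s in leaf_states.items()},
        rep_seqs={t: s["rep"] for t, s in leaf_states.items()},
        pham_sets={t: set(s["phams"]) for t, s in leaf_states.items()},
    )


def _clade_path(tree, clade) -> str:
    """Stable identifier of a clade: the sorted tuple of its leaf names."""
    return ",".join(sorted(leaf.name for leaf in clade.get_terminals()))


def simulate_unrelated_pair(
    length: int = 20_000, seed: int = 0, k: int = 13, max_rounds: int = 100
) -> tuple[str, str]:
    """Two random sequences sharing no k-mer on either strand.

    Emulates a pair of genomes with no sequence similarity: independent
    random sequences are drawn and the rare chance k-mer collisions
    (including against the reverse complement) are re-randomized until the
    k-mer contents are verifiably disjoint, so the nucleotide distance of
    the pair sits at its theoretical maximum of 0.5.
    """
    rng = np.random.default_rng([seed, 0x0D15])

    def draw(n: int) -> str:
        return "".join("ACGT"[i] for i in rng.integers(0, 4, n))

    a = draw(length)
    b = draw(length)
    ka = {a[i : i + k] for i in range(length - k + 1)}
    for _ in range(max_rounds):
        cov: set[int] = set()
        for i in range(length - k + 1):
            if b[i : i + k] in ka:
                cov.update(range(i, i + k))
        rcb = revcomp(b)
        for i in range(length - k + 1):
            if rcb[i : i + k] in ka:
                j0 = length - (i + k)
                cov.update(range(j0, j0 + k))
        if not cov:
            return a, b
        bl = list(b)
        for j in cov:
            bl[j] = "ACGT"[rng.integers(4)]
        b = "".join(bl)
    raise RuntimeError("could not decorrelate the sequence pair")


# ---------------------------------------------------------------------------
# Immunity phenotypes


@dataclass(frozen=True)
class PhenotypeSimConfig:
    """Ordinal score model: I = clamp(round(5 * g(beta*D - alpha*prom)), 0, 6).

    g is a saturating (logistic-tail) link with g(x) = 0 for x <= 0, so a
    zero-distance noiseless pair scores 0 (homoimmunity) and a saturating
    distance scores 5 (heteroimmunity).  alpha scales per-defender latent
    promiscuity (broader repression -> stronger defense), which makes
    reciprocal scores asymmetric; ordinal noise jitters each replicate by
    +/-1 with the configured probability.
    """

    beta: float = 8.0
    alpha: float = 1.0
    noise: float = 0.15
    replicates: int = 3
    enhanced_prob: float = 0.02  # chance a fully infecting replicate reads 6

    def link(self, x: float) -> float:
        if x <= 0:
            return 0.0
        return 2.0 / (1.0 + np.exp(-x)) - 1.0


def simulate_immunity(
    distances,
    config: PhenotypeSimConfig | None = None,
    seed: int = 0,
    metric: str = "D_Stop_motif",
    outgroup: set[str] | frozenset[str] = frozenset(),
    include_crs: bool = False,
) -> list[AssayRecord]:
    """Generate replicate assay records from a pairwise distance table.

    ``distances`` is a DistanceTable (or any object with ``ids`` and
    ``value(metric, a, b)``).  Every ordered (challenger, defender-lysogen)
    pair is scored; pairs involving a heterotypic outgroup phage on either
    side are forced to complete superinfection (score 5).  With
    ``include_crs`` each defender also appears as a cloned-repressor strain
    (``<id>_CRS``) whose homotypic defense is one score weaker, mirroring
    the weaker homotypic immunity of repressor-only strains.
    """
    cfg = config or PhenotypeSimConfig()
    rng = np.random.default_rng([seed, 0x1111])
    ids = list(distances.ids)
    prom = {d: float(rng.random()) for d in ids}
    records: list[AssayRecord] = []
    for challenger in ids:
        for defender in ids:
            if challenger in outgroup or defender in outgroup:
                true = 5.0
            else:
                d = (
                    0.0
                    if challenger == defender
                    else distances.value(metric, challenger, defender)
                )
                true = 5.0 * cfg.link(cfg.beta * d - cfg.alpha * prom[defender])
            reps = []
            for _ in range(cfg.replicates):
                s = true
                if cfg.noise > 0:
                    u = rng.random()
                    if u < cfg.noise / 2:
                        s -= 1
                    elif u < cfg.noise:
                        s += 1
                s = int(np.clip(round(s), 0, 6))
                if s == 5 and cfg.noise > 0 and rng.random() < cfg.enhanced_prob:
                    s = 6
                reps.append(s)
            records.append(
                AssayRecord(
                    challenger_id=challenger,
                    defender_id=defender,
                    defender_kind="lysogen",
                    replicate_scores=reps,
                )
            )
            if include_crs:
                crs_true = min(true + 1, 5) if challenger == defender else true
                crs_reps = [int(np.clip(round(crs_true), 0, 6))] * cfg.replicates
                records.append(
                    AssayRecord(
                        challenger_id=challenger,
                        defender_id=f"{defender}_CRS",
                        defender_kind="CRS",
                        replicate_scores=crs_reps,
                    )
                )
    return records


# ---------------------------------------------------------------------------
# Plate observations


def simulate_plate_observations(
    true_score: int, seed: int = 0, rng: np.random.Generator | None = None
) -> PlateObservation:
    """Sample a plate observation from within the rubric cell of a score."""
    if not (0 <= true_score <= 6):
        raise ValueError("score must be in 0..6")
    rng = rng if rng is not None else np.random.default_rng([seed, true_score])
    if true_score == 0:
        return PlateObservation(plaques_present=False, spot_titers_with_lysis=0)
    if true_score == 1:
        return PlateObservation(
            plaques_present=False,
            spot_titers_with_lysis=int(rng.integers(1, 3)),
        )
    if true_score == 2:
        if rng.random() < 0.5:
            return PlateObservation(
                plaques_present=True, eop=10.0 ** rng.uniform(-6.0, -3.1)
            )
        return PlateObservation(plaques_present=False, spot_titers_with_lysis=3)
    if true_score == 3:
        if rng.random() < 0.5:
            return PlateObservation(
                plaques_present=True, eop=10.0 ** rng.uniform(-3.0, -1.1)
            )
        return PlateObservation(
            plaques_present=False,
            spot_titers_with_lysis=int(rng.integers(4, 6)),
        )
    eop = float(rng.uniform(0.8, 1.2))
    if true_score == 4:
        if rng.random() < 0.5:
            return PlateObservation(plaques_present=True, eop=eop,
                                    turbidity_vs_control="increased")
        return PlateObservation(plaques_present=True, eop=eop,
                                plaque_size_vs_control="reduced")
    if true_score == 5:
        return PlateObservation(plaques_present=True, eop=eop)
    if rng.random() < 0.5:
        return PlateObservation(plaques_present=True, eop=eop,
                                turbidity_vs_control="reduced")
    return PlateObservation(plaques_present=True, eop=eop,
                            plaque_size_vs_control="increased")


# ---------------------------------------------------------------------------
# Binding series


def simulate_binding(
    kd: float,
    bmax: float,
    concentrations,
    noise_sd: float = 0.0,
    seed: int = 0,
    substrate_id: str = "sim",
) -> BindingSeries:
    """One-site titration Y = bmax*X/(kd+X) with seeded Gaussian noise,
    clipped to [0, 1]."""
    if kd <= 0:
        raise ValueError("kd must be > 0")
    x = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng([seed, 0xB17D])
    y = bmax * x / (kd + x)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=x.shape)
    y = np.clip(y, 0.0, 1.0)
    return BindingSeries(substrate_id=substrate_id, concentrations=x,
                        fraction_bound=y)
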