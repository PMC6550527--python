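"""Stoperator motif discovery, PWM models, motif distances and site geography.

Cluster A phage repressors bind 20-30 asymmetric 13- to 14-bp sites
("stoperators") spread across the genome, predominantly oriented with the
direction of transcription.  This module discovers those sites de novo with
an expectation-maximization finder (any-number-of-repetitions site model,
both strands, widths 12-16), builds position weight matrices from the sites,
and compares motifs between phages with a normalized per-column Euclidean
distance (D_Stop-motif: zero iff identical, larger = more dissimilar).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .core_io import PhageGenome

__all__ = [
    "MotifModel",
    "StoperatorSite",
    "DiscoveryParams",
    "DiscoveryResult",
    "build_pwm",
    "motif_distance",
    "scan_sites",
    "discover_stoperators",
    "classify_orientation",
    "annotate_orientation",
    "positional_distribution",
    "write_meme",
    "read_meme",
]

_BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(_BASES)}
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

DEFAULT_PSEUDOCOUNT = 0.8  # pseudocount weight k in the sqrt(N) smoothing scheme
UNIFORM_BG = np.full(4, 0.25)


def _encode(seq: str) -> np.ndarray:
    """DNA string -> int8 array, A=0 C=1 G=2 T=3, anything else -1."""
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for b, i in _BASE_INDEX.items():
        out[arr == ord(b)] = i
    return out


def revcomp(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


# ---------------------------------------------------------------------------
# Motif model


@dataclass(frozen=True)
class MotifModel:
    """Position frequency/weight model of a repressor-binding motif.

    ``P`` is the smoothed probability matrix and ``W`` the log2 probability
    ratio (log-odds against ``bg``):

        P[b, j] = (n[b, j] + k * bg_b * sqrt(N)) / (N + k * sqrt(N))
        W[b, j] = log2(P[b, j] / bg_b)

    with N the per-column count total and k the pseudocount weight.
    """

    counts: np.ndarray  # (4, w) float
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    bg: np.ndarray = field(default_factory=lambda: UNIFORM_BG.copy())
    name: str = ""

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        if counts.ndim != 2 or counts.shape[0] != 4:
            raise ValueError("counts must be a 4 x w matrix")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", counts)
        bg = np.asarray(self.bg, dtype=float)
        if bg.shape != (4,) or not math.isclose(bg.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("bg must be 4 probabilities summing to 1")
        object.__setattr__(self, "bg", bg)
        if counts.sum(axis=0).min() <= 0:
            raise ValueError("every column needs a positive count total")

    @property
    def width(self) -> int:
        return self.counts.shape[1]

    @property
    def P(self) -> np.ndarray:
        N = self.counts.sum(axis=0)
        k = self.pseudocount
        return (self.counts + k * self.bg[:, None] * np.sqrt(N)) / (
            N + k * np.sqrt(N)
        )

    @property
    def W(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log2(self.P / self.bg[:, None])

    @property
    def consensus(self) -> str:
        return "".join(_BASES[i] for i in self.P.argmax(axis=0))

    def information_content(self) -> np.ndarray:
        """Per-column information content in bits (relative to uniform bg)."""
        P = self.P
        with np.errstate(divide="ignore", invalid="ignore"):
            h = np.where(P > 0, P * np.log2(P), 0.0).sum(axis=0)
        return 2.0 + h

    def score(self, seq: str) -> float:
        """Log-odds sum of a width-matched sequence."""
        if len(seq) != self.width:
            raise ValueError(f"sequence length {len(seq)} != width {self.width}")
        idx = _encode(seq)
        if (idx < 0).any():
            return float("-inf")
        return float(self.W[idx, np.arange(self.width)].sum())

    def reverse_complement(self) -> "MotifModel":
        """The model of the opposite strand (columns reversed, bases complemented)."""
        return replace(self, counts=self.counts[::-1, ::-1].copy())


def build_pwm(
    sites_or_counts: Sequence[str] | np.ndarray,
    k: float = DEFAULT_PSEUDOCOUNT,
    bg: np.ndarray | None = None,
    name: str = "",
) -> MotifModel:
    """Build a :class:`MotifModel` from aligned site strings or a count matrix.

    All sites must share one width; N in a site contributes to no base count.
    """
    if isinstance(sites_or_counts, np.ndarray):
        counts = np.asarray(sites_or_counts, dtype=float)
    else:
        sites = [s.upper() for s in sites_or_counts]
        if not sites:
            raise ValueError("no sites given")
        w = len(sites[0])
        if any(len(s) != w for s in sites):
            raise ValueError("sites have mixed widths")
        counts = np.zeros((4, w))
        for s in sites:
            idx = _encode(s)
            for j, b in enumerate(idx):
                if b >= 0:
                    counts[b, j] += 1
    return MotifModel(
        counts=counts,
        pseudocount=k,
        bg=UNIFORM_BG.copy() if bg is None else np.asarray(bg, dtype=float),
        name=name,
    )


def motif_distance(
    m1: MotifModel, m2: MotifModel, allow_offset: bool = False
) -> float:
    """Normalized per-column Euclidean distance between probability matrices.

        D = (1/w) * sum_j sqrt( sum_b (P1[b,j] - P2[b,j])^2 / 2 )

    D is in [0, 1], symmetric, and zero iff the matrices are identical.
    With ``allow_offset=True`` unequal widths are compared by sliding the
    narrower matrix along the wider one and taking the best (minimum)
    distance over the full-overlap offsets.
    """
    P1, P2 = m1.P, m2.P
    if P1.shape[1] == P2.shape[1]:
        return _column_distance(P1, P2)
    if not allow_offset:
        raise ValueError(
            f"motif widths differ ({P1.shape[1]} vs {P2.shape[1]}); "
            "use allow_offset=True"
        )
    if P1.shape[1] > P2.shape[1]:
        P1, P2 = P2, P1
    w1, w2 = P1.shape[1], P2.shape[1]
    return min(
        _column_distance(P1, P2[:, off : off + w1]) for off in range(w2 - w1 + 1)
    )


def _column_distance(P1: np.ndarray, P2: np.ndarray) -> float:
    d = np.sqrt(((P1 - P2) ** 2).sum(axis=0) / 2.0)
    return float(d.mean())


# ---------------------------------------------------------------------------
# Sites and scanning


@dataclass
class StoperatorSite:
    """A located motif instance (1-based inclusive top-strand coordinates).

    ``sequence`` is sense-converted: it reads in the motif orientation, i.e.
    it is the reverse complement of the top strand for minus-strand sites.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    sequence: str
    score: float
    orientation: str | None = None  # syn | anti, relative to the genome center

    @property
    def width(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2


def _window_scores(arr: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Log-odds sum for every window of width W.shape[1] along ``arr``."""
    w = W.shape[1]
    windows = np.lib.stride_tricks.sliding_window_view(arr, w)
    valid = (windows >= 0).all(axis=1)
    safe = np.clip(windows, 0, 3)
    scores = W[safe, np.arange(w)].sum(axis=1)
    return np.where(valid, scores, -np.inf)


def scan_sites(
    genome: PhageGenome | str,
    model: MotifModel,
    min_score: float,
    genome_id: str | None = None,
) -> list[StoperatorSite]:
    """All non-overlapping sites on both strands scoring >= ``min_score``.

    Overlaps are resolved greedily best-score-first; ties break to the
    leftmost site and then to the '+' strand (a palindromic hit is therefore
    reported once, on '+').
    """
    if not math.isfinite(min_score):
        if min_score > 0:  # +inf threshold: nothing can pass
            return []
        raise ValueError("min_score must be finite or +inf")
    seq = genome.sequence if isinstance(genome, PhageGenome) else genome.upper()
    gid = genome_id or (genome.id if isinstance(genome, PhageGenome) else "")
    w = model.width
    L = len(seq)
    if w > L:
        raise ValueError(f"motif width {w} exceeds genome length {L}")
    arr = _encode(seq)
    W = model.W

    candidates: list[tuple[float, int, int, str]] = []  # score, start0, end0, strand
    fwd = _window_scores(arr, W)
    for i in np.flatnonzero(fwd >= min_score):
        candidates.append((float(fwd[i]), int(i), int(i) + w, "+"))
    rc_arr = _encode(revcomp(seq))
    rev = _window_scores(rc_arr, W)
    for i in np.flatnonzero(rev >= min_score):
        start0 = L - int(i) - w
        candidates.append((float(rev[i]), start0, start0 + w, "-"))

    # greedy best-first; ties leftmost then '+'
    candidates.sort(key=lambda c: (-c[0], c[1], 0 if c[3] == "+" else 1))
    taken: list[tuple[int, int]] = []
    sites: list[StoperatorSite] = []
    for score, s0, e0, strand in candidates:
        if any(s0 < te and ts < e0 for ts, te in taken):
            continue
        taken.append((s0, e0))
        top = seq[s0:e0]
        sites.append(
            StoperatorSite(
                genome_id=gid,
                start=s0 + 1,
                end=e0,
                strand=strand,
                sequence=top if strand == "+" else revcomp(top),
                score=score,
            )
        )
    sites.sort(key=lambda s: s.start)
    return sites


# ---------------------------------------------------------------------------
# EM discovery


@dataclass
class DiscoveryParams:
    """Parameters of the EM stoperator finder (MEME-style ANR site model)."""

    w_range: tuple[int, int] = (12, 16)
    sites_range: tuple[int, int] = (10, 50)
    n_motifs: int = 2
    both_strands: bool = True
    n_seeds: int = 3
    n_iter: int = 30
    tol: float = 1e-4
    ic_floor: float = 1.0  # mean per-column bits below which a motif is noise
    seed: int = 2019  # deterministic tie-breaking / seed ordering

    def __post_init__(self) -> None:
        if not (12 <= self.w_range[0] <= self.w_range[1] <= 16):
            raise ValueError("w_range must lie within [12, 16]")
        if not (10 <= self.sites_range[0] <= self.sites_range[1] <= 50):
            raise ValueError("sites_range must lie within [10, 50]")
        if self.n_motifs > 2:
            raise ValueError("at most 2 motifs")


@dataclass
class DiscoveryResult:
    found: bool
    model: MotifModel | None
    sites: list[StoperatorSite]
    threshold: float
    candidates: list[MotifModel] = field(default_factory=list)

    def __iter__(self):  # (model, sites) unpacking convenience
        return iter((self.model, self.sites))


def _seed_kmers(seq: str, w: int, n_seeds: int) -> list[str]:
    """Most frequent exact w-mers (deterministic tie-break: lexicographic)."""
    counts: dict[str, int] = {}
    for i in range(len(seq) - w + 1):
        kmer = seq[i : i + w]
        if "N" in kmer:
            continue
        counts[kmer] = counts.get(kmer, 0) + 1
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return [k for k, _ in ranked[:n_seeds]]


def _em_anr(
    windows: np.ndarray,
    theta0: np.ndarray,
    bg: np.ndarray,
    lam0: float,
    n_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, np.ndarray]:
    """EM for the any-number-of-repetitions two-component mixture.

    Each window is a site with probability lam (product-multinomial theta)
    or background (0-order model).  Returns (theta, lam, posterior z).
    """
    n, w = windows.shape
    cols = np.arange(w)
    log_bg = np.log(bg)
    lp_bg = log_bg[windows].sum(axis=1)
    theta = theta0.copy()
    lam = lam0
    z = np.zeros(n)
    for _ in range(n_iter):
        with np.errstate(divide="ignore"):
            log_theta = np.log(theta)
        lp_m = log_theta[windows, cols].sum(axis=1)
        # posterior in log space
        with np.errstate(over="ignore"):
            z_new = 1.0 / (1.0 + np.exp(np.log1p(-lam) + lp_bg - np.log(lam) - lp_m))
        counts = np.empty((4, w))
        for j in range(w):
            counts[:, j] = np.bincount(
                windows[:, j], weights=z_new, minlength=4
            )
        total = z_new.sum()
        theta_new = (counts + 0.5 * bg[:, None]) / (total + 0.5)
        lam = min(max(total / n, 1.0 / n), 0.05)
        delta = np.abs(theta_new - theta).max()
        theta, z = theta_new, z_new
        if delta < tol:
            break
    return theta, lam, z


def discover_stoperators(
    genome: PhageGenome | str,
    params: DiscoveryParams | None = None,
    reference_motif: MotifModel | None = None,
    genome_id: str | None = None,
) -> DiscoveryResult:
    """De novo stoperator discovery in one genome.

    Runs the EM finder at every width in ``w_range`` over windows from both
    strands, keeps up to ``n_motifs`` candidates ranked by information
    content x site count, and selects the candidate closest to
    ``reference_motif`` when one is given (mirroring selection against
    empirically determined reference sites), else the top-ranked one.  The
    final site set is produced by :func:`scan_sites` with the returned model
    and threshold, with the site count clamped into ``sites_range`` by
    threshold adjustment.  Genomes in which no candidate reaches the
    information-content floor yield ``found=False`` and no sites.
    """
    params = params or DiscoveryParams()
    seq = genome.sequence if isinstance(genome, PhageGenome) else genome.upper()
    gid = genome_id or (genome.id if isinstance(genome, PhageGenome) else "")
    w_min, w_max = params.w_range
    if len(seq) < 10 * w_max:
        raise ValueError("genome too short for motif discovery")
    arr = _encode(seq)
    valid_frac = (arr >= 0).mean()
    if valid_frac < 0.5:
        raise ValueError("genome is mostly ambiguous bases")
    base_counts = np.bincount(arr[arr >= 0], minlength=4).astype(float)
    bg = (base_counts + 1.0) / (base_counts.sum() + 4.0)

    rc = revcomp(seq)
    rc_arr = _encode(rc)

    runs: list[tuple[float, MotifModel, int]] = []  # (metric, model, n_raw)
    for w in range(w_min, w_max + 1):
        fwd_win = np.lib.stride_tricks.sliding_window_view(arr, w)
        strands = [fwd_win]
        if params.both_strands:
            strands.append(np.lib.stride_tricks.sliding_window_view(rc_arr, w))
        windows = np.concatenate(strands, axis=0)
        windows = windows[(windows >= 0).all(axis=1)].astype(np.int64)
        n = windows.shape[0]
        if n == 0:
            continue
        lam0 = float(np.mean(params.sites_range)) / n
        seeds = _seed_kmers(seq if not params.both_strands else seq + "N" + rc,
                            w, params.n_seeds)
        best = None
        for kmer in seeds:
            theta0 = np.full((4, w), 0.1)
            theta0[_encode(kmer), np.arange(w)] = 0.7
            theta, lam, z = _em_anr(
                windows, theta0, bg, lam0, params.n_iter, params.tol
            )
            site_mask = z > 0.5
            n_raw = int(site_mask.sum())
            if n_raw == 0:
                continue
            counts = np.empty((4, w))
            for j in range(w):
                counts[:, j] = np.bincount(
                    windows[site_mask, j], weights=z[site_mask], minlength=4
                )
            model = MotifModel(counts=counts, bg=UNIFORM_BG.copy(),
                               name=f"{gid}:w{w}")
            ic = float(model.information_content().mean())
            metric = ic * min(n_raw, params.sites_range[1])
            if best is None or metric > best[0]:
                best = (metric, model, n_raw, ic)
        if best is not None and best[3] >= params.ic_floor:
            if best[2] >= params.sites_range[0]:
                runs.append((best[0], best[1], best[2]))

    if not runs:
        return DiscoveryResult(found=False, model=None, sites=[],
                               threshold=float("inf"))

    runs.sort(key=lambda r: -r[0])
    top = runs[: params.n_motifs]
    candidates = [r[1] for r in top]
    # strand orientation of a discovered motif is arbitrary: resolve it
    # against the reference motif when given, else canonicalize by the
    # lexicographically smaller consensus
    if reference_motif is not None:
        chosen, n_raw = min(
            (
                (m, r[2])
                for r in top
                for m in (r[1], r[1].reverse_complement())
            ),
            key=lambda mn: motif_distance(
                mn[0], reference_motif, allow_offset=True
            ),
        )
    else:
        chosen, n_raw = candidates[0], top[0][2]
        rc = chosen.reverse_complement()
        if rc.consensus < chosen.consensus:
            chosen = rc

    def call_sites(model: MotifModel) -> tuple[list[StoperatorSite], float]:
        # target the EM-supported site count, clamped into sites_range
        lo, hi = params.sites_range
        target = min(max(n_raw, lo), hi)
        floor = 0.0  # better than background
        found = scan_sites(seq, model, floor, genome_id=gid)
        if len(found) > target:
            thr = sorted((s.score for s in found), reverse=True)[target - 1]
            found = scan_sites(seq, model, thr, genome_id=gid)
        else:
            thr = floor
        return found, thr

    sites, threshold = call_sites(chosen)
    if len(sites) < params.sites_range[0]:
        return DiscoveryResult(found=False, model=chosen, sites=[],
                               threshold=threshold, candidates=candidates)
    final = build_pwm([s.sequence for s in sites], name=f"{gid}:stoperator")
    # rebuild sites/threshold under the final count-based model
    sites, threshold = call_sites(final)
    if len(sites) < params.sites_range[0]:
        return DiscoveryResult(found=False, model=final, sites=[],
                               threshold=threshold, candidates=candidates)
    return DiscoveryResult(found=True, model=final, sites=sites,
                           threshold=threshold, candidates=candidates)


# ---------------------------------------------------------------------------
# Orientation and geography


def classify_orientation(site: StoperatorSite, center: int) -> str:
    """'syn' when the site points with transcription: top strand left of the
    genome center, or bottom strand right of it; otherwise 'anti'.  A site
    whose midpoint falls exactly on the center classifies by strand ('+' ->
    syn)."""
    mid = site.midpoint
    if mid == center:
        warnings.warn(
            f"site at {site.start}-{site.end} midpoint coincides with the "
            "genome center; classifying by strand",
            stacklevel=2,
        )
        return "syn" if site.strand == "+" else "anti"
    if (site.strand == "+" and mid < center) or (
        site.strand == "-" and mid > center
    ):
        return "syn"
    return "anti"


def annotate_orientation(
    sites: Iterable[StoperatorSite], center: int
) -> list[StoperatorSite]:
    out = []
    for s in sites:
        s.orientation = classify_orientation(s, center)
        out.append(s)
    return out


def positional_distribution(
    sites_by_genome: Mapping[str, Sequence[StoperatorSite]],
    anchor: str | Mapping[str, int] | Callable[[str], int],
    genomes: Mapping[str, PhageGenome] | None = None,
    bin_width: int = 100,
) -> dict[int, int]:
    """Histogram of site offsets relative to a per-genome anchor, pooled.

    ``anchor`` is 'rep_3prime' (3' end of the gene with product 'rep',
    strand-aware), 'right_terminus', a mapping genome_id -> coordinate, or a
    callable.  Offset 0 means the site end coincides with the anchor
    coordinate; bins are keyed by their left edge.  Genomes whose anchor
    cannot be resolved are skipped with a warning.
    """

    def resolve(gid: str) -> int:
        if callable(anchor):
            return anchor(gid)
        if isinstance(anchor, Mapping):
            return anchor[gid]
        if genomes is None or gid not in genomes:
            raise KeyError(gid)
        g = genomes[gid]
        if anchor == "right_terminus":
            return len(g)
        if anchor == "rep_3prime":
            reps = g.genes_by_product("rep")
            if not reps:
                raise KeyError(f"no rep gene in {gid}")
            rep = reps[0]
            return rep.end if rep.strand == "+" else rep.start
        raise ValueError(f"unknown anchor spec {anchor!r}")

    hist: dict[int, int] = {}
    for gid, sites in sites_by_genome.items():
        try:
            a = resolve(gid)
        except (KeyError, ValueError) as e:
            warnings.warn(f"anchor unresolvable for {gid!r}: {e}", stacklevel=2)
            continue
        for s in sites:
            off = s.end - a
            b = (off // bin_width) * bin_width
            hist[b] = hist.get(b, 0) + 1
    return hist


# ---------------------------------------------------------------------------
# MEME minimal format I/O


def write_meme(models: Iterable[MotifModel], path) -> None:
    """Export motifs in MEME minimal text format (letter-probability matrices)."""
    models = list(models)
    with open(path, "w") as fh:
        fh.write("MEME version 4\n\nALPHABET= ACGT\n\nstrands: + -\n\n")
        bg = models[0].bg if models else UNIFORM_BG
        fh.write(
            "Background letter frequencies\n"
            + " ".join(f"{b} {f:.5f}" for b, f in zip(_BASES, bg))
            + "\n\n"
        )
        for m in models:
            name = m.name or "motif"
            N = int(round(m.counts.sum(axis=0).max()))
            fh.write(f"MOTIF {name}\n")
            fh.write(
                f"letter-probability matrix: alength= 4 w= {m.width} "
                f"nsites= {N} E= 0\n"
            )
            for col in m.P.T:
                fh.write(" ".join(f"{p:.6f}" for p in col) + "\n")
            fh.write("\n")


def read_meme(path) -> list[MotifModel]:
    """Import motifs from MEME minimal format as count-free probability models.

    Probabilities are rescaled by nsites into pseudo-counts so the model
    round-trips through the count-based representation (pseudocount 0 keeps
    P exact).
    """
    models: list[MotifModel] = []
    bg = UNIFORM_BG.copy()
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        ln = lines[i].strip()
        if ln.startswith("Background letter frequencies"):
            parts = lines[i + 1].split()
            bg = np.array([float(parts[k]) for k in (1, 3, 5, 7)])
            i += 2
            continue
        if ln.startswith("MOTIF"):
            name = ln.split(maxsplit=1)[1] if " " in ln else ""
            i += 1
            header = lines[i].strip()
            tokens = header.replace("=", " = ").split()
            w = int(tokens[tokens.index("w") + 2])
            nsites = 20
            if "nsites" in tokens:
                nsites = int(tokens[tokens.index("nsites") + 2])
            rows = []
            for j in range(w):
                rows.append([float(x) for x in lines[i + 1 + j].split()])
            P = np.array(rows).T  # (4, w)
            models.append(
                MotifModel(counts=P * nsites, pseudocount=0.0, bg=bg, name=name)
            )
            i += 1 + w
            continue
        i += 1
    return models
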