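"""EMSA substrate design and one-site equilibrium binding fits.

Repressor-DNA affinity is measured by electrophoretic mobility shift with
30-bp double-stranded substrates: a 13-bp binding site flanked by 8 bp
upstream and 9 bp downstream of genomic sequence.  Titration series of
fraction bound vs repressor concentration are fit to the one-site specific
binding model

    Y = Bmax * X / (K_D + X)

by bounded least squares; there is no cooperativity term because monomeric
binding shows none.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .core_io import PhageGenome
from .motifs import StoperatorSite

__all__ = [
    "SubstrateSpec",
    "BindingSeries",
    "BindingFit",
    "design_substrate",
    "substitution_series",
    "fit_one_site",
    "KD_ABOVE_RANGE",
]

CORE_WIDTH = 13
UPSTREAM_FLANK = 8
DOWNSTREAM_FLANK = 9
TOTAL_LENGTH = UPSTREAM_FLANK + CORE_WIDTH + DOWNSTREAM_FLANK  # 30

#: sentinel K_D (nM) reported when the data show no measurable binding
KD_ABOVE_RANGE = float("inf")


@dataclass(frozen=True)
class SubstrateSpec:
    """A 30-bp duplex substrate: 8-bp flank + 13-bp core + 9-bp flank."""

    substrate_id: str
    upstream: str
    core: str
    downstream: str
    genome_id: str | None = None
    core_start: int | None = None  # genomic coordinate of the core, if genomic

    def __post_init__(self) -> None:
        if len(self.upstream) != UPSTREAM_FLANK:
            raise ValueError(f"upstream flank must be {UPSTREAM_FLANK} bp")
        if len(self.core) != CORE_WIDTH:
            raise ValueError(f"core site must be {CORE_WIDTH} bp")
        if len(self.downstream) != DOWNSTREAM_FLANK:
            raise ValueError(f"downstream flank must be {DOWNSTREAM_FLANK} bp")

    @property
    def sequence(self) -> str:
        return self.upstream + self.core + self.downstream


def design_substrate(genome: PhageGenome, site: StoperatorSite) -> SubstrateSpec:
    """A 30-bp substrate around a genomic site, flanks taken from the genome.

    Flanks follow the site's strand (8 bp 5' and 9 bp 3' of the
    sense-converted core), so the spec sequence is a contiguous genomic
    slice read in the site orientation.
    """
    w = site.width
    if w != CORE_WIDTH:
        raise ValueError(f"core site must be {CORE_WIDTH} bp, got {w}")
    if site.strand == "+":
        s, e = site.start - UPSTREAM_FLANK, site.end + DOWNSTREAM_FLANK
    else:
        s, e = site.start - DOWNSTREAM_FLANK, site.end + UPSTREAM_FLANK
    if s < 1 or e > len(genome):
        raise ValueError(
            f"site {site.start}-{site.end} too close to a genome terminus "
            "for 8/9-bp flanks"
        )
    seq = genome.subsequence(s, e, site.strand)
    return SubstrateSpec(
        substrate_id=f"{site.genome_id}:{site.start}",
        upstream=seq[:UPSTREAM_FLANK],
        core=seq[UPSTREAM_FLANK : UPSTREAM_FLANK + CORE_WIDTH],
        downstream=seq[UPSTREAM_FLANK + CORE_WIDTH :],
        genome_id=site.genome_id,
        core_start=site.start,
    )


def substitution_series(
    site_from: str,
    site_to: str,
    anchor_position: int | None = None,
    upstream: str = "GCGGTGAC",
    downstream: str = "GTGGCTGTC",
) -> list[SubstrateSpec]:
    """Progressive substitution series converting one 13-bp site into another.

    Differing positions (1-based within the core) are substituted in all
    combinations; with an anchor, only subsets containing the anchor are
    produced (2^(k-1) substrates for k differing positions), ordered by
    subset size then position, ending with the full conversion.  Substrate
    ids name the substituted positions, e.g. ``C9G10C11A12``.  Flanks stay
    fixed (by default generic non-site sequence; pass the source substrate's
    flanks to reproduce a genomic series).
    """
    site_from, site_to = site_from.upper(), site_to.upper()
    if len(site_from) != len(site_to):
        raise ValueError("sites must have equal width")
    diffs = [i for i, (a, b) in enumerate(zip(site_from, site_to), 1) if a != b]
    if not diffs:
        return []
    if anchor_position is not None and anchor_position not in diffs:
        raise ValueError(
            f"anchor {anchor_position} is not a differing position {diffs}"
        )
    subsets = []
    for r in range(1, len(diffs) + 1):
        for combo in itertools.combinations(diffs, r):
            if anchor_position is not None and anchor_position not in combo:
                continue
            subsets.append(combo)
    subsets.sort(key=lambda c: (len(c), c))
    out = []
    for combo in subsets:
        core = list(site_from)
        for pos in combo:
            core[pos - 1] = site_to[pos - 1]
        name = "".join(f"{site_to[pos - 1]}{pos}" for pos in combo)
        out.append(
            SubstrateSpec(
                substrate_id=name,
                upstream=upstream,
                core="".join(core),
                downstream=downstream,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Binding fits


@dataclass
class BindingSeries:
    """One titration: repressor concentrations (nM) vs fraction of DNA bound.

    Percent inputs (max > 1.5) are auto-normalized to fractions.
    """

    substrate_id: str
    concentrations: np.ndarray
    fraction_bound: np.ndarray

    def __post_init__(self) -> None:
        x = np.asarray(self.concentrations, dtype=float)
        y = np.asarray(self.fraction_bound, dtype=float)
        if x.shape != y.shape or x.ndim != 1:
            raise ValueError("concentrations and fraction_bound must match")
        if (x < 0).any() or (np.diff(x) <= 0).any():
            raise ValueError("concentrations must be >= 0, strictly increasing")
        if not np.isfinite(y).all():
            raise ValueError("fraction_bound must be finite")
        if np.nanmax(y) > 1.5:  # given as percent
            y = y / 100.0
        self.concentrations = x
        self.fraction_bound = y


@dataclass(frozen=True)
class BindingFit:
    kd: float  # nM
    bmax: float
    kd_stderr: float
    bmax_stderr: float
    converged: bool
    message: str = ""

    def predict(self, x):
        x = np.asarray(x, dtype=float)
        return self.bmax * x / (self.kd + x)


def one_site(x, kd, bmax):
    """One-site specific binding model Y = Bmax * X / (K_D + X)."""
    return bmax * x / (kd + x)


def fit_one_site(series: BindingSeries, bmax_upper: float = 1.2) -> BindingFit:
    """Least-squares fit of the one-site model; returns K_D with its
    standard error from the fit covariance.

    Multi-start (K_D initialized at the min, median and max positive
    concentration) bounded fit with K_D > 0 and 0 < Bmax <= ``bmax_upper``;
    deterministic.  Data with no detectable binding (all fractions ~0)
    report an above-range K_D sentinel instead of a spurious estimate.
    """
    x = series.concentrations
    y = series.fraction_bound
    if len(x) < 3:
        return BindingFit(np.nan, np.nan, np.nan, np.nan, False,
                          "need >= 3 points")
    if float(y.max()) < 0.02:
        return BindingFit(KD_ABOVE_RANGE, 0.0, np.nan, np.nan, False,
                          "no measurable binding; K_D above tested range")
    xp = x[x > 0]
    starts = sorted({float(xp.min()), float(np.median(xp)), float(xp.max())})
    best = None
    for kd0 in starts:
        try:
            popt, pcov = curve_fit(
                one_site,
                x,
                y,
                p0=[kd0, min(max(float(y.max()), 0.1), bmax_upper)],
                bounds=([1e-9, 1e-9], [np.inf, bmax_upper]),
                maxfev=10000,
            )
        except (RuntimeError, ValueError):
            continue
        rss = float(((one_site(x, *popt) - y) ** 2).sum())
        if best is None or rss < best[0]:
            best = (rss, popt, pcov)
    if best is None:
        return BindingFit(np.nan, np.nan, np.nan, np.nan, False,
                          "fit did not converge")
    _, popt, pcov = best
    err = np.sqrt(np.diag(pcov))
    return BindingFit(
        kd=float(popt[0]),
        bmax=float(popt[1]),
        kd_stderr=float(err[0]),
        bmax_stderr=float(err[1]),
        converged=True,
    )
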