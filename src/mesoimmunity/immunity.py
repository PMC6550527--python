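"""Ordinal superinfection-immunity scoring and phenotype statistics.

An infection assay spots serial dilutions of a challenging phage on a lawn
of a defending strain (a lysogen, a cloned-repressor strain, or the naive
host) and reads out an ordinal infection score in 0..6 relative to the
naive-host control: 0 = complete immunity, 5 = infection indistinguishable
from the control, 6 = enhanced infection.  This module encodes that rubric,
aggregates replicate assays into a challenger x defender matrix, and
derives the phenotype statistics: reciprocal asymmetry (delta-I), profile
correlations, phenotype-vs-distance regressions, lysogen-vs-CRS score
deltas, and dataset-level assay counts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_io import AssayRecord, FormatError
from .distances import DistanceTable

__all__ = [
    "PlateObservation",
    "ScoreBins",
    "score_observation",
    "ImmunityMatrix",
    "aggregate_replicates",
    "ReciprocalPair",
    "reciprocal_asymmetry",
    "ProfileCorrelation",
    "profile_correlation",
    "RegressionResult",
    "regress_phenotype_vs_distance",
    "lysogen_crs_delta",
    "summarize_assay_counts",
]


# ---------------------------------------------------------------------------
# Rubric


@dataclass
class PlateObservation:
    """Raw qualitative read-out of one spot-titer assay vs the naive control."""

    plaques_present: bool
    eop: float | None = None  # efficiency of plating (titer ratio vs control)
    spot_titers_with_lysis: int = 0  # highest dilutions showing lysis, 0-8
    turbidity_vs_control: str = "equal"  # reduced | equal | increased
    plaque_size_vs_control: str = "equal"

    def __post_init__(self) -> None:
        if self.plaques_present and self.eop is None:
            raise FormatError("plaques present but no efficiency of plating")
        if self.eop is not None and self.eop < 0:
            raise FormatError("efficiency of plating must be >= 0")
        if not (0 <= self.spot_titers_with_lysis <= 8):
            raise FormatError("spot_titers_with_lysis must be in 0..8")
        for v in (self.turbidity_vs_control, self.plaque_size_vs_control):
            if v not in {"reduced", "equal", "increased"}:
                raise FormatError(f"invalid comparison level {v!r}")


@dataclass(frozen=True)
class ScoreBins:
    """Configurable efficiency-of-plating boundaries of the scoring rubric.

    The published wording leaves the bin edges fuzzy ("less than
    ~10^-3-10^-4", "of 1"); the defaults fix half-open bins: score 2 below
    ``low``, score 3 in [``low``, ``unity``), and order-unity plating
    (>= ``unity``) for scores 4-6.
    """

    low: float = 1e-3
    unity: float = 0.5


def score_observation(obs: PlateObservation, bins: ScoreBins = ScoreBins()) -> int:
    """Map a plate observation onto the ordinal 0-6 infection score.

    Plaque-free outcomes grade by how many of the highest spot dilutions show
    lysis (0 -> 0; 1-2 -> 1; 3 -> 2; >=4 -> 3).  Plaque-forming outcomes
    grade by efficiency of plating, and at order-unity plating by plaque
    phenotype vs the control: weakened (more turbid or smaller) -> 4,
    indistinguishable -> 5, strengthened (less turbid or larger) -> 6.
    """
    if not obs.plaques_present:
        n = obs.spot_titers_with_lysis
        if n == 0:
            return 0
        if n <= 2:
            return 1
        if n == 3:
            return 2
        return 3
    eop = obs.eop
    if eop < bins.low:
        return 2
    if eop < bins.unity:
        return 3
    if (
        obs.turbidity_vs_control == "increased"
        or obs.plaque_size_vs_control == "reduced"
    ):
        return 4
    if (
        obs.turbidity_vs_control == "reduced"
        or obs.plaque_size_vs_control == "increased"
    ):
        return 6
    return 5


# ---------------------------------------------------------------------------
# Matrix aggregation


@dataclass
class ImmunityMatrix:
    """Challengers x defenders grid of replicate-aggregated infection scores."""

    mean: pd.DataFrame  # challengers (rows) x defenders (columns)
    n: pd.DataFrame
    min: pd.DataFrame
    max: pd.DataFrame
    defender_kind: dict[str, str]  # defender id -> naive | lysogen | CRS

    @property
    def challengers(self) -> list[str]:
        return list(self.mean.index)

    @property
    def defenders(self) -> list[str]:
        return list(self.mean.columns)

    def defenders_of_kind(self, kind: str) -> list[str]:
        return [d for d in self.defenders if self.defender_kind[d] == kind]

    def score(self, challenger: str, defender: str) -> float:
        return float(self.mean.at[challenger, defender])


def aggregate_replicates(records: Iterable[AssayRecord]) -> ImmunityMatrix:
    """Average replicate scores per (challenger, defender) into a matrix.

    Summary-only records contribute their stored mean/n/min/max.  A defender
    id appearing with conflicting kinds is an error (lysogen and CRS
    defenders derived from the same phage must carry distinct ids).
    """
    records = list(records)
    kinds: dict[str, str] = {}
    for r in records:
        prev = kinds.setdefault(r.defender_id, r.defender_kind)
        if prev != r.defender_kind:
            raise FormatError(
                f"defender {r.defender_id!r} appears as both {prev} "
                f"and {r.defender_kind}"
            )
    cells: dict[tuple[str, str], dict] = {}
    for r in records:
        key = (r.challenger_id, r.defender_id)
        cell = cells.setdefault(key, {"scores": [], "n": 0, "sum": 0.0,
                                      "min": np.inf, "max": -np.inf})
        if r.replicate_scores:
            cell["scores"].extend(r.replicate_scores)
            cell["n"] += len(r.replicate_scores)
            cell["sum"] += sum(r.replicate_scores)
            cell["min"] = min(cell["min"], min(r.replicate_scores))
            cell["max"] = max(cell["max"], max(r.replicate_scores))
        else:
            cell["n"] += r.n
            cell["sum"] += r.mean * r.n
            if r.min is not None:
                cell["min"] = min(cell["min"], r.min)
            if r.max is not None:
                cell["max"] = max(cell["max"], r.max)

    challengers = sorted({c for c, _ in cells})
    defenders = sorted({d for _, d in cells})
    shape = (len(challengers), len(defenders))
    mean = np.full(shape, np.nan)
    nmat = np.zeros(shape)
    mn = np.full(shape, np.nan)
    mx = np.full(shape, np.nan)
    for (c, d), cell in cells.items():
        i, j = challengers.index(c), defenders.index(d)
        mean[i, j] = cell["sum"] / cell["n"]
        nmat[i, j] = cell["n"]
        if np.isfinite(cell["min"]):
            mn[i, j] = cell["min"]
            mx[i, j] = cell["max"]
    df = lambda M: pd.DataFrame(M, index=challengers, columns=defenders)
    return ImmunityMatrix(
        mean=df(mean), n=df(nmat), min=df(mn), max=df(mx), defender_kind=kinds
    )


# ---------------------------------------------------------------------------
# Asymmetry


@dataclass(frozen=True)
class ReciprocalPair:
    """delta-I = |I(A on B's lysogen) - I(B on A's lysogen)| for one pair."""

    a: str
    b: str
    score_ab: float  # A challenging B's lysogen
    score_ba: float

    @property
    def delta(self) -> float:
        return abs(self.score_ab - self.score_ba)


def reciprocal_asymmetry(
    matrix: ImmunityMatrix,
    lysogen_of: Mapping[str, str] | None = None,
) -> list[ReciprocalPair]:
    """One :class:`ReciprocalPair` per unordered phage pair tested both ways.

    Reciprocity is defined over lysogen defenders only.  ``lysogen_of`` maps
    a phage id to its lysogen's defender id; by default the lysogen defender
    shares the phage's id.  Pairs with only one direction scored are
    excluded (their count is logged as a warning).
    """
    lysogens = set(matrix.defenders_of_kind("lysogen"))
    lysogen_of = dict(lysogen_of) if lysogen_of else {
        d: d for d in lysogens
    }
    phages = [p for p in lysogen_of if lysogen_of[p] in lysogens]
    pairs: list[ReciprocalPair] = []
    dropped = 0
    for a, b in itertools.combinations(sorted(phages), 2):
        try:
            ab = matrix.score(a, lysogen_of[b])
            ba = matrix.score(b, lysogen_of[a])
        except KeyError:
            dropped += 1
            continue
        if np.isnan(ab) or np.isnan(ba):
            dropped += 1
            continue
        pairs.append(ReciprocalPair(a=a, b=b, score_ab=ab, score_ba=ba))
    if dropped:
        warnings.warn(
            f"{dropped} phage pair(s) lacked one reciprocal direction",
            stacklevel=2,
        )
    return pairs


# ---------------------------------------------------------------------------
# Profile correlations


@dataclass(frozen=True)
class ProfileCorrelation:
    a: str
    b: str
    axis: str  # challenging | defending
    r: float | None
    n: int


def profile_correlation(
    matrix: ImmunityMatrix,
    a: str,
    b: str,
    axis: Literal["challenging", "defending"] = "challenging",
    method: Literal["pearson", "spearman"] = "pearson",
) -> ProfileCorrelation:
    """Correlate two phages' superinfection profiles.

    ``challenging``: the two phages' score rows across the lysogen panel
    (how similarly they superinfect).  ``defending``: the score columns of
    the two phages' lysogens (how similarly they defend).  Requires >= 3
    shared scored entries; a constant profile yields r = None with a
    warning.
    """
    if axis == "challenging":
        x = matrix.mean.loc[a, matrix.defenders_of_kind("lysogen")]
        y = matrix.mean.loc[b, matrix.defenders_of_kind("lysogen")]
    elif axis == "defending":
        x = matrix.mean[a]
        y = matrix.mean[b]
    else:
        raise ValueError(f"unknown axis {axis!r}")
    mask = x.notna() & y.notna()
    xv, yv = x[mask].to_numpy(float), y[mask].to_numpy(float)
    n = int(mask.sum())
    if n < 3:
        raise ValueError(
            f"need >= 3 shared scored entries for {a!r} vs {b!r} ({n} found)"
        )
    if np.ptp(xv) == 0 or np.ptp(yv) == 0:
        warnings.warn(
            f"constant profile for {a!r}/{b!r}; correlation undefined",
            stacklevel=2,
        )
        return ProfileCorrelation(a=a, b=b, axis=axis, r=None, n=n)
    if method == "pearson":
        r = stats.pearsonr(xv, yv).statistic
    else:
        r = stats.spearmanr(xv, yv).statistic
    return ProfileCorrelation(a=a, b=b, axis=axis, r=float(r), n=n)


# ---------------------------------------------------------------------------
# Regression


@dataclass(frozen=True)
class RegressionResult:
    predictor: str
    response: str
    slope: float
    intercept: float
    r_squared: float
    n: int


def regress_phenotype_vs_distance(
    matrix: ImmunityMatrix,
    distances: DistanceTable,
    response: Literal["I", "deltaI"] = "I",
    predictor: str = "D_Stop_motif",
    clade: Sequence[str] | None = None,
    lysogen_of: Mapping[str, str] | None = None,
) -> RegressionResult:
    """Ordinary least squares of an immunity phenotype on a genotype distance.

    ``response`` "I" regresses every scored (challenger, lysogen-defender)
    mean score on the pair's distance; "deltaI" regresses the reciprocal
    asymmetry per unordered pair.  ``clade`` restricts to comparisons where
    both phages belong to the given membership list (the intra-clade scope
    used for the published R^2 values).
    """
    lysogens = matrix.defenders_of_kind("lysogen")
    lysogen_of = dict(lysogen_of) if lysogen_of else {d: d for d in lysogens}
    phage_of_lysogen = {v: k for k, v in lysogen_of.items()}
    member = set(clade) if clade is not None else None

    xs: list[float] = []
    ys: list[float] = []
    if response == "I":
        for c in matrix.challengers:
            for d in lysogens:
                p = phage_of_lysogen.get(d)
                if p is None:
                    continue
                if member is not None and (c not in member or p not in member):
                    continue
                score = matrix.mean.at[c, d]
                if np.isnan(score):
                    continue
                try:
                    dist = distances.value(predictor, c, p) if c != p else 0.0
                except (KeyError, ValueError):
                    continue
                if np.isnan(dist):
                    continue
                xs.append(dist)
                ys.append(float(score))
    elif response == "deltaI":
        for pair in reciprocal_asymmetry(matrix, lysogen_of=lysogen_of):
            if member is not None and (
                pair.a not in member or pair.b not in member
            ):
                continue
            try:
                dist = distances.value(predictor, pair.a, pair.b)
            except (KeyError, ValueError):
                continue
            if np.isnan(dist):
                continue
            xs.append(dist)
            ys.append(pair.delta)
    else:
        raise ValueError(f"unknown response {response!r}")

    if len(xs) < 3:
        raise ValueError(f"need >= 3 points, got {len(xs)}")
    fit = stats.linregress(xs, ys)
    return RegressionResult(
        predictor=predictor,
        response=response,
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        n=len(xs),
    )


# ---------------------------------------------------------------------------
# Lysogen vs cloned-repressor strain


def lysogen_crs_delta(
    matrix: ImmunityMatrix,
    system_of: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Per-challenger score change I_CRS - I_Lysogen for each paired system.

    ``system_of`` maps defender id -> immunity-system id; defenders sharing
    a system id across the two kinds (one lysogen, one CRS) form a pair.  By
    default a CRS defender named ``"<phage>_CRS"`` pairs with the lysogen
    defender ``"<phage>"``.  Unpaired systems are skipped with a warning.
    """
    if system_of is None:
        system_of = {}
        for d in matrix.defenders:
            kind = matrix.defender_kind[d]
            if kind == "CRS" and d.endswith("_CRS"):
                system_of[d] = d[: -len("_CRS")]
            elif kind == "lysogen":
                system_of[d] = d
    by_system: dict[str, dict[str, str]] = {}
    for d, sysid in system_of.items():
        if d in matrix.defenders:
            by_system.setdefault(sysid, {})[matrix.defender_kind[d]] = d
    rows = []
    for sysid, kinds in sorted(by_system.items()):
        if "lysogen" not in kinds or "CRS" not in kinds:
            warnings.warn(f"system {sysid!r} lacks a lysogen/CRS pair",
                          stacklevel=2)
            continue
        lys, crs = kinds["lysogen"], kinds["CRS"]
        for c in matrix.challengers:
            s_lys = matrix.mean.at[c, lys]
            s_crs = matrix.mean.at[c, crs]
            if np.isnan(s_lys) or np.isnan(s_crs):
                continue
            rows.append(
                {"challenger": c, "system": sysid,
                 "I_Lysogen": float(s_lys), "I_CRS": float(s_crs),
                 "delta": float(s_crs - s_lys)}
            )
    return pd.DataFrame(rows, columns=["challenger", "system", "I_Lysogen",
                                       "I_CRS", "delta"])


# ---------------------------------------------------------------------------
# Dataset-level counts


def summarize_assay_counts(
    records: Iterable[AssayRecord],
    lysogen_of: Mapping[str, str] | None = None,
    system_of: Mapping[str, str] | None = None,
) -> dict[str, float]:
    """Dataset-level bookkeeping of an assay table.

    Returns total assays (summed replicates), unique (challenger, defender,
    kind) comparisons, reciprocal lysogen pairs tested both ways, the number
    of comparisons belonging to complete lysogen-CRS pairs sharing a
    challenger (two per complete pair), the percentage of unique comparisons
    with >= 2 replicates, and the percentage of those whose replicate score
    range is < 2.
    """
    records = list(records)
    out = {
        "total_assays": 0,
        "unique_comparisons": 0,
        "reciprocal_pairs": 0,
        "lysogen_crs_paired_comparisons": 0,
        "pct_multireplicate": 0.0,
        "pct_multireplicate_range_lt2": 0.0,
    }
    if not records:
        return out
    cells: dict[tuple[str, str, str], dict] = {}
    for r in records:
        key = (r.challenger_id, r.defender_id, r.defender_kind)
        cell = cells.setdefault(key, {"n": 0, "min": np.inf, "max": -np.inf})
        cell["n"] += r.n
        if r.min is not None:
            cell["min"] = min(cell["min"], r.min)
            cell["max"] = max(cell["max"], r.max)
    out["total_assays"] = int(sum(c["n"] for c in cells.values()))
    out["unique_comparisons"] = len(cells)

    lysogens = {
        r.defender_id for r in records if r.defender_kind == "lysogen"
    }
    lysogen_of = dict(lysogen_of) if lysogen_of else {d: d for d in lysogens}
    scored = {(c, d) for c, d, k in cells if k == "lysogen"}
    phages = [p for p in lysogen_of if lysogen_of[p] in lysogens]
    out["reciprocal_pairs"] = sum(
        1
        for a, b in itertools.combinations(sorted(phages), 2)
        if (a, lysogen_of[b]) in scored and (b, lysogen_of[a]) in scored
    )

    if system_of is None:
        system_of = {}
        for _, d, kind in cells:
            if kind == "CRS" and d.endswith("_CRS"):
                system_of[d] = d[: -len("_CRS")]
            elif kind == "lysogen":
                system_of[d] = d
    by_system: dict[str, dict[str, str]] = {}
    for (c, d, kind) in cells:
        sysid = system_of.get(d)
        if sysid is not None:
            by_system.setdefault(sysid, {}).setdefault(kind, d)
    paired = 0
    for sysid, kinds in by_system.items():
        if "lysogen" not in kinds or "CRS" not in kinds:
            continue
        lys, crs = kinds["lysogen"], kinds["CRS"]
        for c in {c for c, _, _ in cells}:
            if (c, lys, "lysogen") in cells and (c, crs, "CRS") in cells:
                paired += 2
    out["lysogen_crs_paired_comparisons"] = paired

    multi = [c for c in cells.values() if c["n"] >= 2]
    out["pct_multireplicate"] = 100.0 * len(multi) / len(cells)
    if multi:
        tight = [
            c for c in multi
            if np.isfinite(c["min"]) and (c["max"] - c["min"]) < 2
        ]
        out["pct_multireplicate_range_lt2"] = 100.0 * len(tight) / len(multi)
    return out
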