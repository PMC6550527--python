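"""Pairwise genotype divergence metrics between phage genomes.

Metrics and their ranges:

* ``D_Nuc``   whole-genome nucleotide distance in [0, 0.5]; 0 for identical
  sequences, 0.5 for sequences sharing no similarity on either strand.
* ``D_GC``    gene-content dissimilarity in [0, 1] from shared phamilies
  ("phams"): 1 - mean(|A&B|/|A|, |A&B|/|B|).
* protein distances (repressor full length, N-/C-terminal regions, portal,
  DNA polymerase, endonuclease VII, Cas4-family, ...) as uncorrected
  substitutions per 100 aligned amino acids, gap columns carrying no weight.
* ``D_Rep_HTH``  Hamming distance between 20-residue helix-turn-helix
  DNA-binding domains, in {0..20}.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from Bio.Align import substitution_matrices

from .core_io import PhageGenome
from .motifs import MotifModel, motif_distance, revcomp

__all__ = [
    "DistanceTable",
    "nucleotide_distance",
    "gene_content_dissimilarity",
    "protein_distance",
    "split_rep_regions",
    "hth_hamming",
    "assemble_distance_table",
    "HTH_LENGTH",
    "DEFAULT_REP_SPLIT",
]

HTH_LENGTH = 20
#: default boundary between repressor N- and C-terminal regions (residues
#: 1..split = N-terminal block containing the helix-turn-helix; configurable)
DEFAULT_REP_SPLIT = 60


# ---------------------------------------------------------------------------
# Nucleotide distance (anchor-based estimator)


def _kmer_positions(seq: str, k: int) -> dict[str, list[int]]:
    index: dict[str, list[int]] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        if "N" in kmer:
            continue
        index.setdefault(kmer, []).append(i)
    return index


def _exact_segments(a: str, b: str, k: int) -> list[tuple[int, int, int]]:
    """Maximal exact shared segments as (a_start, b_start, length).

    Exact k-mer seeds on a common diagonal are merged into maximal runs;
    segments from the reverse complement of ``b`` are mapped back to
    ``b``'s top-strand interval.
    """
    segments: list[tuple[int, int, int]] = []
    for target, is_rc in ((b, False), (revcomp(b), True)):
        index = _kmer_positions(target, k)
        diag_hits: dict[int, list[int]] = {}
        for i in range(len(a) - k + 1):
            kmer = a[i : i + k]
            for j in index.get(kmer, ()):
                diag_hits.setdefault(j - i, []).append(i)
        for diag, a_starts in diag_hits.items():
            a_starts.sort()
            run_start = prev = a_starts[0]
            for i in a_starts[1:]:
                if i == prev + 1:
                    prev = i
                    continue
                segments.append(_map_segment(run_start, prev, diag, k,
                                             len(b), is_rc))
                run_start = prev = i
            segments.append(_map_segment(run_start, prev, diag, k,
                                         len(b), is_rc))
    return segments


def _map_segment(a_first: int, a_last: int, diag: int, k: int,
                 len_b: int, is_rc: bool) -> tuple[int, int, int]:
    length = a_last - a_first + k
    t_start = a_first + diag  # start in the (possibly rc'd) target
    if is_rc:
        b_start = len_b - (t_start + length)
    else:
        b_start = t_start
    return (a_first, b_start, length)


def nucleotide_distance(
    gA: PhageGenome | str, gB: PhageGenome | str, k: int = 13
) -> float:
    """Whole-genome nucleotide distance D_Nuc in [0, 0.5].

    Shared segments are detected by exact k-mer anchoring (both strands of
    the second genome) merged into maximal exact runs, then tiled greedily
    longest-first without overlap in either genome.  With f the aligned
    identical fraction, f = 2 * matches / (len A + len B):

        D_Nuc = (1 - f) / 2

    so identical genomes score 0 and genomes sharing no k-mers on either
    strand score 0.5.
    """
    a = gA.sequence if isinstance(gA, PhageGenome) else gA.upper()
    b = gB.sequence if isinstance(gB, PhageGenome) else gB.upper()
    if not a or not b:
        raise ValueError("empty sequence")
    segments = _exact_segments(a, b, k)
    segments.sort(key=lambda s: (-s[2], s[0], s[1]))
    taken_a: list[tuple[int, int]] = []
    taken_b: list[tuple[int, int]] = []
    matches = 0
    for a0, b0, length in segments:
        a1, b1 = a0 + length, b0 + length
        if any(a0 < e and s < a1 for s, e in taken_a):
            continue
        if any(b0 < e and s < b1 for s, e in taken_b):
            continue
        taken_a.append((a0, a1))
        taken_b.append((b0, b1))
        matches += length
    f = 2.0 * matches / (len(a) + len(b))
    return float(min(max((1.0 - f) / 2.0, 0.0), 0.5))


# ---------------------------------------------------------------------------
# Gene content


def gene_content_dissimilarity(phamsA: Iterable[str], phamsB: Iterable[str]) -> float:
    """D_GC = 1 - mean(|A&B|/|A|, |A&B|/|B|); 0 identical pham sets, 1 disjoint."""
    A, B = set(phamsA), set(phamsB)
    if not A or not B:
        raise ValueError("pham sets must be non-empty")
    shared = len(A & B)
    return 1.0 - 0.5 * (shared / len(A) + shared / len(B))


# ---------------------------------------------------------------------------
# Protein distances

_aligner = Align.PairwiseAligner()
_aligner.mode = "global"
_aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
_aligner.open_gap_score = -10.0
_aligner.extend_gap_score = -0.5


def protein_distance(seqA: str, seqB: str) -> float | None:
    """Uncorrected distance in substitutions per 100 aligned amino acids.

    Sequences are globally aligned (BLOSUM62, affine gaps); columns with a
    gap in either sequence carry no weight (excluded from numerator and
    denominator).  Returns None when no residue pairs align.
    """
    seqA, seqB = seqA.upper().rstrip("*"), seqB.upper().rstrip("*")
    if not seqA or not seqB:
        raise ValueError("empty protein sequence")
    if seqA == seqB:
        return 0.0
    alignment = _aligner.align(seqA, seqB)[0]
    cols = 0
    mismatches = 0
    for (a0, a1), (b0, b1) in zip(*alignment.aligned):
        cols += a1 - a0
        for x, y in zip(seqA[a0:a1], seqB[b0:b1]):
            if x != y:
                mismatches += 1
    if cols == 0:
        return None
    return 100.0 * mismatches / cols


def split_rep_regions(
    rep_seq: str, split_position: int = DEFAULT_REP_SPLIT
) -> tuple[str, str]:
    """Split a repressor into (N-terminal, C-terminal) regions at ``split_position``.

    The two regions of the Cluster A repressor evolve at markedly different
    rates (the C-terminal region is the more diverse); region distances are
    computed by applying :func:`protein_distance` to each piece.
    """
    if not (0 < split_position < len(rep_seq)):
        raise ValueError(
            f"split {split_position} outside sequence of length {len(rep_seq)}"
        )
    return rep_seq[:split_position], rep_seq[split_position:]


def hth_hamming(hthA: str, hthB: str) -> int:
    """Hamming distance between two 20-residue helix-turn-helix domains."""
    if len(hthA) != HTH_LENGTH or len(hthB) != HTH_LENGTH:
        raise ValueError(
            f"helix-turn-helix domains must be {HTH_LENGTH} aa "
            f"(got {len(hthA)} and {len(hthB)})"
        )
    return sum(1 for x, y in zip(hthA.upper(), hthB.upper()) if x != y)


# ---------------------------------------------------------------------------
# Assembly


@dataclass
class DistanceTable:
    """Symmetric pairwise distance matrices keyed by metric name.

    Missing values (gene absent in one genome of the pair) are NaN.
    """

    ids: list[str]
    matrices: dict[str, np.ndarray] = field(default_factory=dict)

    def matrix(self, metric: str) -> pd.DataFrame:
        return pd.DataFrame(self.matrices[metric], index=self.ids,
                            columns=self.ids)

    def value(self, metric: str, a: str, b: str) -> float:
        i, j = self.ids.index(a), self.ids.index(b)
        return float(self.matrices[metric][i, j])

    def to_long(self) -> pd.DataFrame:
        """Long form: one row per unordered pair per metric."""
        rows = []
        for metric, M in self.matrices.items():
            for i, j in itertools.combinations(range(len(self.ids)), 2):
                rows.append(
                    {"metric": metric, "a": self.ids[i], "b": self.ids[j],
                     "value": M[i, j]}
                )
        return pd.DataFrame(rows)

    def _check(self) -> None:
        for name, M in self.matrices.items():
            assert M.shape == (len(self.ids),) * 2
            assert np.allclose(np.nan_to_num(M), np.nan_to_num(M.T))


def _pairwise(ids: Sequence[str], fn) -> np.ndarray:
    n = len(ids)
    M = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        v = fn(ids[i], ids[j])
        M[i, j] = M[j, i] = np.nan if v is None else v
    return M


def assemble_distance_table(
    genomes: Mapping[str, PhageGenome],
    motif_models: Mapping[str, MotifModel] | None = None,
    proteins: Mapping[str, Mapping[str, str]] | None = None,
    hth_domains: Mapping[str, str] | None = None,
    rep_split: int = DEFAULT_REP_SPLIT,
    k: int = 13,
) -> DistanceTable:
    """Compute every available metric for every genome pair.

    ``proteins`` maps metric-base names (e.g. ``"rep"``, ``"portal"``) to
    per-genome amino-acid sequences; ``"rep"`` additionally yields the
    N-/C-terminal region metrics at ``rep_split``.  Pairs for which one side
    lacks the input are NaN.
    """
    ids = sorted(genomes)
    table = DistanceTable(ids=ids)

    table.matrices["D_Nuc"] = _pairwise(
        ids, lambda a, b: nucleotide_distance(genomes[a], genomes[b], k=k)
    )
    table.matrices["D_GC"] = _pairwise(
        ids,
        lambda a, b: gene_content_dissimilarity(
            genomes[a].phams, genomes[b].phams
        )
        if genomes[a].phams and genomes[b].phams
        else None,
    )
    if motif_models:
        table.matrices["D_Stop_motif"] = _pairwise(
            ids,
            lambda a, b: motif_distance(
                motif_models[a], motif_models[b], allow_offset=True
            )
            if a in motif_models and b in motif_models
            else None,
        )
    for base, seqs in (proteins or {}).items():
        metric = f"D_{base.capitalize()}" if not base.startswith("D_") else base
        table.matrices[metric] = _pairwise(
            ids,
            lambda a, b, seqs=seqs: protein_distance(seqs[a], seqs[b])
            if a in seqs and b in seqs
            else None,
        )
        if base.lower() == "rep":
            for region, piece in (("Nterm", 0), ("Cterm", 1)):
                table.matrices[f"D_Rep_{region}"] = _pairwise(
                    ids,
                    lambda a, b, seqs=seqs, piece=piece: protein_distance(
                        split_rep_regions(seqs[a], rep_split)[piece],
                        split_rep_regions(seqs[b], rep_split)[piece],
                    )
                    if a in seqs and b in seqs
                    else None,
                )
    if hth_domains:
        table.matrices["D_Rep_HTH"] = _pairwise(
            ids,
            lambda a, b: hth_hamming(hth_domains[a], hth_domains[b])
            if a in hth_domains and b in hth_domains
            else None,
        )
    return table
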