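"""Escape-mutant genotype notation: parsing, genome editing, and impact calls.

Mutant genotypes are written in a compact notation against the parent
genome's top strand, 1-based: point substitutions ``G44351A``, insertions
``44333:44334 27-bp ins`` / ``43427:43428 G insertion`` (coordinates flank
the insertion), deletions ``Δ45310:48001`` (first and last deleted
nucleotides), and recombinations ``rec Tx 44620:44630 and RR 44127:44137``
(crossover windows in each parent).  A parenthesized annotation names the
protein-level effect, e.g. ``(Rep Q138*)`` for a nonsense change at
repressor codon 138 or ``(Rep R52fs)`` for a frameshift first impacting
residue 52.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio.Seq import Seq

from .core_io import GeneRecord, PhageGenome
from .motifs import revcomp

__all__ = [
    "MutationSpec",
    "ProteinAnnotation",
    "RepImpact",
    "VirulenceProfile",
    "parse_mutation",
    "parse_genotype",
    "format_mutation",
    "apply_mutations",
    "build_hybrid",
    "classify_rep_impact",
    "virulence_breadth",
    "build_synthetic_parent",
]


# ---------------------------------------------------------------------------
# Notation


@dataclass(frozen=True)
class ProteinAnnotation:
    """Parsed parenthesized protein-effect tag of one mutation."""

    raw: str
    gene: str | None = None
    kind: str | None = None  # missense|nonsense|frameshift|sense|pm|deleted|truncated_5prime|tag
    position: int | None = None
    from_aa: str | None = None
    to_aa: str | None = None


@dataclass(frozen=True)
class MutationSpec:
    """One structured genotype edit (1-based, inclusive, top strand)."""

    kind: str  # substitution | insertion | deletion | recombination | annotation
    genome_tag: str | None = None  # parent tag for hybrid genotypes (e.g. Tx, RR)
    position: int | None = None  # substitution position
    ref_base: str | None = None
    alt_base: str | None = None
    ins_left: int | None = None  # insertion flanks (ins_right = ins_left + 1)
    ins_right: int | None = None
    ins_length: int | None = None
    ins_seq: str | None = None
    del_start: int | None = None
    del_end: int | None = None
    rec_a_tag: str | None = None  # recombination crossover windows
    rec_a: tuple[int, int] | None = None
    rec_b_tag: str | None = None
    rec_b: tuple[int, int] | None = None
    annotation: ProteinAnnotation | None = None

    def __post_init__(self) -> None:
        if self.kind == "substitution":
            if self.ref_base == self.alt_base:
                raise ValueError("substitution must change the base")
        elif self.kind == "insertion":
            if self.ins_right != self.ins_left + 1:
                raise ValueError("insertion coordinates must be adjacent")
        elif self.kind == "deletion":
            if self.del_start > self.del_end:
                raise ValueError("deletion start must be <= end")

    @property
    def length_change(self) -> int:
        if self.kind == "insertion":
            return self.ins_length
        if self.kind == "deletion":
            return -(self.del_end - self.del_start + 1)
        return 0


_SUB_RE = re.compile(r"^([ACGT])(\d+)([ACGT])$")
_INS_BP_RE = re.compile(r"^(?:(\w+) )?(\d+):(\d+) (\d+)-bp ins$")
_INS_SEQ_RE = re.compile(r"^(?:(\w+) )?(\d+):(\d+) ([ACGT]+) insertion$")
_DEL_RE = re.compile(r"^(?:(\w+) )?Δ(\d+):(\d+)$")
_REC_RE = re.compile(r"^rec (\w+) (\d+):(\d+) and (\w+) (\d+):(\d+)$")

_ANN_AA_RE = re.compile(r"^(\S+) ([A-Z])(\d+)([A-Z*])$")
_ANN_FS_RE = re.compile(r"^(\S+) ([A-Z])(\d+)fs$")


def _parse_annotation(raw: str) -> ProteinAnnotation:
    text = raw.strip()
    if m := _ANN_AA_RE.match(text):
        gene, faa, pos, taa = m.groups()
        kind = "nonsense" if taa == "*" else "missense"
        return ProteinAnnotation(raw=raw, gene=gene, kind=kind,
                                 position=int(pos), from_aa=faa, to_aa=taa)
    if m := _ANN_FS_RE.match(text):
        gene, faa, pos = m.groups()
        return ProteinAnnotation(raw=raw, gene=gene, kind="frameshift",
                                 position=int(pos), from_aa=faa)
    if m := re.match(r"^Δ(\S+)$", text):
        return ProteinAnnotation(raw=raw, gene=m.group(1), kind="deleted")
    if m := re.match(r"^(\S+) Δ5' end$", text):
        return ProteinAnnotation(raw=raw, gene=m.group(1),
                                 kind="truncated_5prime")
    if m := re.match(r"^(\S+) pm$", text):
        return ProteinAnnotation(raw=raw, gene=m.group(1), kind="pm")
    if m := re.match(r"^(\S+) sense$", text):
        return ProteinAnnotation(raw=raw, gene=m.group(1), kind="sense")
    if m := re.match(r"^Rep-(\w+)$", text):
        return ProteinAnnotation(raw=raw, gene="Rep", kind="tag")
    return ProteinAnnotation(raw=raw)


def parse_mutation(notation: str) -> MutationSpec:
    """Parse a single genotype token (one mutation, optional annotation)."""
    text = notation.strip()
    annotation = None
    if m := re.search(r"\s*\(([^()]*)\)$", text):
        annotation = _parse_annotation(m.group(1))
        text = text[: m.start()]
    text = text.strip()
    if not text:
        if annotation is None:
            raise ValueError(f"empty mutation token: {notation!r}")
        return MutationSpec(kind="annotation", annotation=annotation)
    if m := _SUB_RE.match(text):
        ref, pos, alt = m.groups()
        return MutationSpec(kind="substitution", position=int(pos),
                            ref_base=ref, alt_base=alt, annotation=annotation)
    if m := _INS_BP_RE.match(text):
        tag, left, right, n = m.groups()
        return MutationSpec(kind="insertion", genome_tag=tag,
                            ins_left=int(left), ins_right=int(right),
                            ins_length=int(n), annotation=annotation)
    if m := _INS_SEQ_RE.match(text):
        tag, left, right, seq = m.groups()
        return MutationSpec(kind="insertion", genome_tag=tag,
                            ins_left=int(left), ins_right=int(right),
                            ins_length=len(seq), ins_seq=seq,
                            annotation=annotation)
    if m := _DEL_RE.match(text):
        tag, start, end = m.groups()
        return MutationSpec(kind="deletion", genome_tag=tag,
                            del_start=int(start), del_end=int(end),
                            annotation=annotation)
    if m := _REC_RE.match(text):
        ta, a1, a2, tb, b1, b2 = m.groups()
        return MutationSpec(kind="recombination",
                            rec_a_tag=ta, rec_a=(int(a1), int(a2)),
                            rec_b_tag=tb, rec_b=(int(b1), int(b2)),
                            annotation=annotation)
    raise ValueError(f"unparseable mutation token at offset 0: {notation!r}")


def parse_genotype(notation: str) -> list[MutationSpec]:
    """Parse a full ';'-separated genotype string into ordered specs."""
    return [parse_mutation(tok) for tok in notation.split(";") if tok.strip()]


def format_mutation(spec: MutationSpec) -> str:
    """Inverse of :func:`parse_mutation` (format o parse is the identity)."""
    ann = f" ({spec.annotation.raw})" if spec.annotation else ""
    tag = f"{spec.genome_tag} " if spec.genome_tag else ""
    if spec.kind == "annotation":
        return ann.strip()
    if spec.kind == "substitution":
        return f"{spec.ref_base}{spec.position}{spec.alt_base}{ann}"
    if spec.kind == "insertion":
        if spec.ins_seq is not None:
            body = f"{tag}{spec.ins_left}:{spec.ins_right} {spec.ins_seq} insertion"
        else:
            body = f"{tag}{spec.ins_left}:{spec.ins_right} {spec.ins_length}-bp ins"
        return body + ann
    if spec.kind == "deletion":
        return f"{tag}Δ{spec.del_start}:{spec.del_end}{ann}"
    if spec.kind == "recombination":
        return (
            f"rec {spec.rec_a_tag} {spec.rec_a[0]}:{spec.rec_a[1]} "
            f"and {spec.rec_b_tag} {spec.rec_b[0]}:{spec.rec_b[1]}{ann}"
        )
    raise ValueError(f"unknown spec kind {spec.kind!r}")


# ---------------------------------------------------------------------------
# Genome surgery


def apply_mutations(parent: str, specs: Sequence[MutationSpec]) -> str:
    """Apply substitution/insertion/deletion specs to a parent sequence.

    Specs are applied right to left so coordinates stay valid against the
    parent.  Substitutions verify the reference base.  Recombination specs
    are not auto-applied (crossover windows do not determine exact
    junctions); use :func:`build_hybrid`.  Length-only insertions insert N
    placeholders.
    """
    seq = parent.upper()

    def anchor(s: MutationSpec) -> int:
        if s.kind == "substitution":
            return s.position
        if s.kind == "insertion":
            return s.ins_left
        if s.kind == "deletion":
            return s.del_start
        raise ValueError(
            f"cannot auto-apply a {s.kind} spec; "
            "recombinations need explicit junctions (build_hybrid)"
        )

    for s in sorted(specs, key=anchor, reverse=True):
        if s.kind == "substitution":
            p = s.position - 1
            if not (0 <= p < len(seq)):
                raise ValueError(f"position {s.position} outside parent")
            if seq[p] != s.ref_base:
                raise ValueError(
                    f"reference mismatch at {s.position}: parent has "
                    f"{seq[p]}, spec expects {s.ref_base}"
                )
            seq = seq[:p] + s.alt_base + seq[p + 1 :]
        elif s.kind == "insertion":
            if not (1 <= s.ins_left < len(seq)):
                raise ValueError(f"insertion flank {s.ins_left} outside parent")
            ins = s.ins_seq if s.ins_seq is not None else "N" * s.ins_length
            seq = seq[: s.ins_left] + ins + seq[s.ins_left :]
        elif s.kind == "deletion":
            if s.del_end > len(seq):
                raise ValueError(f"deletion end {s.del_end} outside parent")
            seq = seq[: s.del_start - 1] + seq[s.del_end :]
    return seq


def build_hybrid(
    parent_a: str,
    parent_b: str,
    spec: MutationSpec,
    junction_a: int | None = None,
    junction_b: int | None = None,
) -> str:
    """Join two parents at user-chosen junctions inside a recombination
    spec's crossover windows: parent A up to ``junction_a`` (inclusive),
    then parent B from ``junction_b + 1`` on.  Junctions default to the
    window midpoints."""
    if spec.kind != "recombination":
        raise ValueError("spec must be a recombination")
    a1, a2 = spec.rec_a
    b1, b2 = spec.rec_b
    ja = junction_a if junction_a is not None else (a1 + a2) // 2
    jb = junction_b if junction_b is not None else (b1 + b2) // 2
    if not (a1 <= ja <= a2) or not (b1 <= jb <= b2):
        raise ValueError("junction outside the crossover window")
    return parent_a[:ja] + parent_b[jb:]


# ---------------------------------------------------------------------------
# Repressor impact


@dataclass(frozen=True)
class RepImpact:
    """Classified effect of a genotype on the repressor gene."""

    category: str  # none|sense|missense|nonsense|frameshift|truncated_5prime|deleted
    position: int | None = None  # first affected codon, where applicable


def _coding_index(p: int, gene: GeneRecord) -> int:
    """0-based position of top-strand coordinate p within the coding sequence."""
    return (p - gene.start) if gene.strand == "+" else (gene.end - p)


def classify_rep_impact(
    parent: PhageGenome | str,
    rep: GeneRecord,
    specs: Sequence[MutationSpec],
) -> RepImpact:
    """Classify the repressor-gene impact of a set of genotype edits.

    Substitutions translate the affected codon (silent -> sense, stop ->
    nonsense, else missense); insertions and deletions inside the gene are
    frameshifts unless in-frame (then classified missense at the first
    affected codon); a deletion removing the gene's 5' end is a 5'
    truncation and one covering the whole gene a complete deletion.  When
    several edits touch the gene the earliest affected codon decides, with
    whole-gene and 5'-end deletions taking precedence.
    """
    seq = parent.sequence if isinstance(parent, PhageGenome) else parent.upper()
    if rep.end > len(seq):
        raise ValueError("rep interval outside the parent sequence")
    coding = seq[rep.start - 1 : rep.end]
    if rep.strand == "-":
        coding = revcomp(coding)

    five_prime = rep.start if rep.strand == "+" else rep.end
    impacts: list[RepImpact] = []
    for s in specs:
        if s.kind == "deletion":
            if s.del_start <= rep.start and s.del_end >= rep.end:
                return RepImpact(category="deleted")
            if s.del_start <= five_prime <= s.del_end:
                impacts.append(RepImpact(category="truncated_5prime"))
                continue
            if s.del_end < rep.start or s.del_start > rep.end:
                continue
            lo = max(s.del_start, rep.start)
            hi = min(s.del_end, rep.end)
            first = min(_coding_index(lo, rep), _coding_index(hi, rep))
            codon = first // 3 + 1
            if (hi - lo + 1) % 3:
                impacts.append(RepImpact(category="frameshift", position=codon))
            else:
                impacts.append(RepImpact(category="missense", position=codon))
        elif s.kind == "insertion":
            # the junction must fall strictly inside the gene to disturb it
            if not (rep.start <= s.ins_left < rep.end):
                continue
            cidx = min(
                _coding_index(s.ins_left, rep), _coding_index(s.ins_right, rep)
            ) + 1
            codon = cidx // 3 + 1
            if s.ins_length % 3:
                impacts.append(RepImpact(category="frameshift", position=codon))
            else:
                impacts.append(RepImpact(category="missense", position=codon))
        elif s.kind == "substitution":
            if not (rep.start <= s.position <= rep.end):
                continue
            cidx = _coding_index(s.position, rep)
            codon = cidx // 3
            within = cidx % 3
            parent_codon = coding[codon * 3 : codon * 3 + 3]
            base = s.alt_base if rep.strand == "+" else revcomp(s.alt_base)
            mutant_codon = (
                parent_codon[:within] + base + parent_codon[within + 1 :]
            )
            aa_from = str(Seq(parent_codon).translate())
            aa_to = str(Seq(mutant_codon).translate())
            if aa_from == aa_to:
                cat = "sense"
            elif aa_to == "*":
                cat = "nonsense"
            else:
                cat = "missense"
            impacts.append(RepImpact(category=cat, position=codon + 1))
    if not impacts:
        return RepImpact(category="none")
    for truncation in impacts:
        if truncation.category == "truncated_5prime":
            return truncation
    return min(impacts, key=lambda im: im.position)


# ---------------------------------------------------------------------------
# Virulence breadth


@dataclass
class VirulenceProfile:
    """Escape-gain profile of a defense escape mutant vs its parent."""

    dem_id: str
    parent_id: str
    scores: dict[str, tuple[float, float]]  # defender -> (I_DEM, I_Parent)
    gains: list[str]
    breadth: str  # none | narrow_homotypic | narrow_mesotypic | broad
    homotypic_untested: bool = False


def virulence_breadth(
    matrix,
    dem_id: str,
    parent_id: str,
    escape_threshold: float = 3.0,
    system_of: Mapping[str, str] | None = None,
) -> VirulenceProfile:
    """Classify how broadly an escape mutant's virulence extends.

    A defender counts as a gain when the mutant infects at or above
    ``escape_threshold`` (plaque formation) while the parent falls below
    it.  Gains confined to the homotypic system (the parent's own
    lysogen/CRS) are narrow homotypic virulence; gains confined to at most
    two non-homotypic systems are narrow mesotypic; gains spanning the
    homotypic system and beyond (or many mesotypic systems) are broad.
    """
    if system_of is None:
        system_of = {
            d: d[: -len("_CRS")] if d.endswith("_CRS") else d
            for d in matrix.defenders
        }
    shared = [
        d
        for d in matrix.defenders
        if not np.isnan(matrix.mean.at[dem_id, d])
        and not np.isnan(matrix.mean.at[parent_id, d])
    ]
    if len(shared) < 2:
        raise ValueError("need scores on >= 2 shared defenders")
    homotypic = {d for d in shared if system_of.get(d) == parent_id}
    homotypic_untested = not homotypic
    scores = {
        d: (matrix.score(dem_id, d), matrix.score(parent_id, d)) for d in shared
    }
    gains = [
        d
        for d, (s_dem, s_par) in scores.items()
        if s_dem >= escape_threshold > s_par
    ]
    gain_systems = {system_of.get(d, d) for d in gains}
    gained_homotypic = any(d in homotypic for d in gains)
    if not gains:
        breadth = "none"
    elif gained_homotypic and gain_systems <= {parent_id}:
        breadth = "narrow_homotypic"
    elif not gained_homotypic and len(gain_systems) <= 2:
        breadth = "narrow_mesotypic"
    else:
        breadth = "broad"
    return VirulenceProfile(
        dem_id=dem_id,
        parent_id=parent_id,
        scores=scores,
        gains=sorted(gains),
        breadth=breadth,
        homotypic_untested=homotypic_untested,
    )


# ---------------------------------------------------------------------------
# Synthetic parent reconstruction (test/validation support)

_AA_CODONS: dict[str, list[str]] = {}
for _c in [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"]:
    _AA_CODONS.setdefault(str(Seq(_c).translate()), []).append(_c)

_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A"}


def build_synthetic_parent(
    spec: MutationSpec,
    rep_length_aa: int = 183,
    genome_pad: int = 2000,
    seed: int = 0,
) -> tuple[PhageGenome, GeneRecord]:
    """Construct a SYNTHETIC parent genome on which a mutation's protein
    annotation holds at its real genomic coordinate.

    Real parent genomes are not distributed; this builder lays a repressor
    ORF on the bottom strand (the natural orientation of the gene) such
    that the spec's coordinate falls in the annotated codon and the
    annotated amino-acid change results, then embeds it in a random
    background.  It exists to validate :func:`classify_rep_impact` against
    annotated genotypes; it is a synthetic stand-in, not a reconstruction
    of any real genome.
    """
    ann = spec.annotation
    if ann is None or ann.kind not in {
        "missense", "nonsense", "frameshift", "sense", "deleted",
        "truncated_5prime",
    }:
        raise ValueError("spec carries no reconstructable protein annotation")
    rng = np.random.default_rng(seed)

    if spec.kind == "substitution":
        p = spec.position
        codon_no = ann.position
        placement = None
        for within in range(3):
            for parent_codon in _AA_CODONS.get(ann.from_aa, []):
                base = _COMP1[spec.alt_base]  # bottom-strand coding base
                ref = _COMP1[spec.ref_base]
                if parent_codon[within] != ref:
                    continue
                mutant_codon = (
                    parent_codon[:within] + base + parent_codon[within + 1 :]
                )
                target = "*" if ann.kind == "nonsense" else ann.to_aa
                if ann.kind == "sense":
                    target = ann.from_aa
                if str(Seq(mutant_codon).translate()) == target:
                    placement = (within, parent_codon)
                    break
            if placement:
                break
        if placement is None:
            raise ValueError(f"no codon realises annotation {ann.raw!r}")
        within, parent_codon = placement
        end = p + 3 * (codon_no - 1) + within
        special = {codon_no: parent_codon}
    elif spec.kind == "insertion":
        codon_no = ann.position
        # insertion junction between ins_left/ins_right on the bottom strand:
        # first disturbed coding index is end - ins_left + ... choose end so
        # that codon_no holds (see _coding_index)
        end = spec.ins_left + 3 * (codon_no - 1)
        special = {}
    elif spec.kind == "deletion":
        if ann.kind == "deleted":
            # rep entirely inside the deleted interval
            end = spec.del_end - 10
        else:
            # truncated_5prime: the 5' end (= top-strand gene end for a
            # bottom-strand gene) sits just inside the deletion, the 3' end
            # survives upstream of it
            end = spec.del_start + 10
            if end > spec.del_end:
                raise ValueError("deletion too short to truncate a 5' end")
        special = {}
    else:
        raise ValueError(f"cannot reconstruct a parent for kind {spec.kind!r}")

    n_codons = max(rep_length_aa, (ann.position or 0) + 2)
    start = end - 3 * (n_codons + 1) + 1  # + stop codon
    if spec.kind == "deletion" and ann.kind == "deleted":
        # whole gene must fit inside the deleted interval
        if start < spec.del_start:
            n_codons = (end - spec.del_start + 1) // 3 - 2
            start = end - 3 * (n_codons + 1) + 1
    if start < 2:
        raise ValueError("annotation does not fit upstream of the coordinate")

    sense_codons = [c for aa, cs in _AA_CODONS.items() if aa != "*" for c in cs]
    codons = ["ATG"]
    for i in range(2, n_codons + 1):
        if i in special:
            codons.append(special[i])
        else:
            codons.append(sense_codons[rng.integers(len(sense_codons))])
    codons.append("TAA")
    coding = "".join(codons)
    assert len(coding) == 3 * (n_codons + 1)

    max_coord = max(
        end,
        spec.del_end or 0,
        (spec.ins_right or 0),
        (spec.position or 0),
    )
    L = max_coord + genome_pad
    bg = rng.integers(0, 4, size=L)
    genome_seq = list("".join("ACGT"[i] for i in bg))
    top_block = revcomp(coding)  # bottom-strand gene
    genome_seq[start - 1 : end] = list(top_block)
    genome = PhageGenome(
        id="synthetic_parent",
        sequence="".join(genome_seq),
        genes=[],
    )
    rep = GeneRecord(
        gene_id="rep", start=start, end=end, strand="-", pham="rep_pham",
        product="rep",
    )
    genome.genes.append(rep)
    return genome, rep
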