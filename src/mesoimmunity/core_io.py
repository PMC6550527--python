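"""Data model and readers/writers for phage genome sets and infection-assay tables.

Coordinates are 1-based, inclusive, top-strand throughout (the convention used
for mutant genotype notation); :func:`to_zero_based` / :func:`to_one_based`
convert to and from Python's half-open slices internally.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "FormatError",
    "GeneRecord",
    "PhageGenome",
    "AssayRecord",
    "read_genome_set",
    "write_genome_set",
    "read_assay_table",
    "write_assay_table",
    "genome_center",
    "load_mutant_catalog",
    "load_scoring_rubric",
    "to_zero_based",
    "to_one_based",
]

DNA_ALPHABET = set("ACGTN")

#: gene products recognised as prophage-inheritance markers; the marker gene
#: defines the genome "center" used for stoperator orientation analysis.
CENTER_MARKERS = ("integrase", "parA")


class FormatError(ValueError):
    """Raised when an input file violates the expected format or coordinates."""


def to_zero_based(start: int, end: int) -> tuple[int, int]:
    """1-based inclusive interval -> 0-based half-open slice bounds."""
    return start - 1, end


def to_one_based(start0: int, end0: int) -> tuple[int, int]:
    """0-based half-open slice bounds -> 1-based inclusive interval."""
    return start0 + 1, end0


@dataclass
class GeneRecord:
    """A gene feature on the top-strand coordinate system of one genome."""

    gene_id: str
    start: int
    end: int
    strand: str
    pham: str
    product: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise FormatError(
                f"gene {self.gene_id!r}: invalid 1-based interval "
                f"[{self.start}, {self.end}]"
            )
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id!r}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def midpoint(self) -> int:
        """Interval midpoint, rounded down."""
        return (self.start + self.end) // 2


@dataclass
class PhageGenome:
    """One phage genome: sequence, gene features, pham assignments.

    ``inheritance`` records the prophage-inheritance strategy ("integrase"
    for integrating phages, "parABS" for extrachromosomal ones); the marker
    gene itself is found among ``genes`` by product name.
    """

    id: str
    sequence: str
    genes: list[GeneRecord] = field(default_factory=list)
    subcluster: str = ""
    inheritance: str | None = None

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise FormatError(f"genome {self.id!r}: empty sequence")
        bad = set(self.sequence) - DNA_ALPHABET
        if bad:
            raise FormatError(
                f"genome {self.id!r}: non-DNA characters {sorted(bad)!r}"
            )
        for g in self.genes:
            if g.end > len(self.sequence):
                raise FormatError(
                    f"genome {self.id!r}: gene {g.gene_id!r} interval "
                    f"[{g.start}, {g.end}] exceeds genome length "
                    f"{len(self.sequence)}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def phams(self) -> set[str]:
        return {g.pham for g in self.genes if g.pham}

    def gene(self, gene_id: str) -> GeneRecord:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    def genes_by_product(self, product: str) -> list[GeneRecord]:
        return [g for g in self.genes if g.product == product]

    def center_marker(self) -> GeneRecord:
        """The inheritance marker gene (integrase or parA)."""
        markers = [g for g in self.genes if g.product in CENTER_MARKERS]
        if not markers:
            raise FormatError(f"genome {self.id!r}: no center marker")
        if len(markers) > 1:
            raise FormatError(
                f"genome {self.id!r}: multiple center markers "
                f"{[g.gene_id for g in markers]!r}"
            )
        return markers[0]

    def subsequence(self, start: int, end: int, strand: str = "+") -> str:
        """Top-strand slice (1-based inclusive); reverse-complemented for '-'."""
        s0, e0 = to_zero_based(start, end)
        seq = self.sequence[s0:e0]
        if strand == "-":
            seq = str(Seq(seq).reverse_complement())
        return seq


def genome_center(genome: PhageGenome) -> int:
    """Genome center: midpoint of the inheritance marker gene.

    The center anchors the syn/anti orientation rule for repressor-binding
    sites; integrating phages use the integrase gene, extrachromosomal
    phages use parA.
    """
    return genome.center_marker().midpoint


# ---------------------------------------------------------------------------
# Assay records


@dataclass
class AssayRecord:
    """One unique (challenger, defender) infection comparison.

    Rows supplying individual replicate scores carry ``replicate_scores``;
    rows supplying only summary statistics (as in processed supplementary
    tables) carry ``n``/``mean``/``min``/``max`` with ``replicate_scores``
    empty.
    """

    challenger_id: str
    defender_id: str
    defender_kind: str  # naive | lysogen | CRS
    replicate_scores: list[int] = field(default_factory=list)
    n: int | None = None
    mean: float | None = None
    min: float | None = None
    max: float | None = None

    KINDS = ("naive", "lysogen", "CRS")

    def __post_init__(self) -> None:
        if self.defender_kind not in self.KINDS:
            raise FormatError(
                f"defender_kind must be one of {self.KINDS}, "
                f"got {self.defender_kind!r}"
            )
        if self.replicate_scores:
            for s in self.replicate_scores:
                if not (0 <= s <= 6):
                    raise FormatError(
                        f"score {s} outside the 0-6 rubric "
                        f"({self.challenger_id} vs {self.defender_id})"
                    )
            self.n = len(self.replicate_scores)
            self.mean = sum(self.replicate_scores) / len(self.replicate_scores)
            self.min = float(builtins_min(self.replicate_scores))
            self.max = float(builtins_max(self.replicate_scores))
        else:
            if self.n is None or self.mean is None:
                raise FormatError(
                    "summary-only assay record requires n and mean "
                    f"({self.challenger_id} vs {self.defender_id})"
                )
            if self.min is not None and self.max is not None and self.min > self.max:
                raise FormatError(
                    f"min > max for {self.challenger_id} vs {self.defender_id}"
                )
            for v in (self.mean, self.min, self.max):
                if v is not None and not (0 <= v <= 6):
                    raise FormatError(f"summary score {v} outside [0, 6]")

    @property
    def score_range(self) -> float | None:
        if self.min is None or self.max is None:
            return None
        return self.max - self.min


# builtins shadowed by dataclass field names
builtins_min = min
builtins_max = max


# ---------------------------------------------------------------------------
# Genome set I/O

_TSV_GENE_COLUMNS = ["gene_id", "start", "end", "strand", "pham", "product"]


def _read_gene_table(path: Path) -> dict[str, list[GeneRecord]]:
    """Parse a GFF3 file or 6/7-column TSV into per-genome gene lists.

    The TSV dialect is ``genome_id gene_id start end strand pham product``
    (header optional).  GFF3 is recognised by the ``##gff`` pragma or a
    ``.gff``/``.gff3`` suffix; ``pham=`` and ``product=`` attributes are
    honoured.
    """
    text = Path(path).read_text()
    lines = [ln for ln in text.splitlines() if ln.strip()]
    is_gff = str(path).endswith((".gff", ".gff3")) or (
        lines and lines[0].startswith("##gff")
    )
    genes: dict[str, list[GeneRecord]] = {}
    if is_gff:
        for i, ln in enumerate(lines, 1):
            if ln.startswith("#"):
                continue
            parts = ln.split("\t")
            if len(parts) < 9:
                raise FormatError(f"{path}:{i}: GFF3 line with <9 columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = parts[:9]
            if ftype not in {"gene", "CDS"}:
                continue
            attr = dict(
                kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
            )
            gid = attr.get("ID", f"{seqid}_{i}")
            try:
                rec = GeneRecord(
                    gene_id=gid,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    pham=attr.get("pham", ""),
                    product=attr.get("product", ""),
                )
            except FormatError as e:
                raise FormatError(f"{path}:{i}: {e}") from e
            genes.setdefault(seqid, []).append(rec)
    else:
        for i, ln in enumerate(lines, 1):
            parts = ln.split("\t")
            if i == 1 and parts[0].lower() in {"genome_id", "genome"}:
                continue
            if len(parts) < 6:
                raise FormatError(f"{path}:{i}: expected >=6 TSV columns")
            genome_id, gid, start, end, strand, pham = parts[:6]
            product = parts[6] if len(parts) > 6 else ""
            try:
                rec = GeneRecord(
                    gene_id=gid,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    pham=pham,
                    product=product,
                )
            except (FormatError, ValueError) as e:
                raise FormatError(f"{path}:{i}: {e}") from e
            genes.setdefault(genome_id, []).append(rec)
    return genes


def _read_pham_table(path: Path) -> dict[str, str]:
    """TSV of ``gene_id<TAB>pham`` (header optional)."""
    phams: dict[str, str] = {}
    for i, ln in enumerate(Path(path).read_text().splitlines(), 1):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if i == 1 and parts[0].lower() in {"gene_id", "gene"}:
            continue
        if len(parts) < 2:
            raise FormatError(f"{path}:{i}: expected 2 TSV columns")
        phams[parts[0]] = parts[1]
    return phams


def read_genome_set(
    fasta_path: str | Path,
    gene_table_path: str | Path | None = None,
    pham_table_path: str | Path | None = None,
    metadata: dict[str, dict] | None = None,
) -> dict[str, PhageGenome]:
    """Read a genome collection from FASTA plus gene-feature and pham tables.

    FASTA descriptions of the form ``id subcluster=A2 inheritance=integrase``
    populate subcluster/inheritance; an explicit ``metadata`` dict (keyed by
    genome id) overrides.  Genes lacking a pham assignment are warned about
    and placed in a singleton pham named after the gene.
    """
    genes = _read_gene_table(Path(gene_table_path)) if gene_table_path else {}
    phams = _read_pham_table(Path(pham_table_path)) if pham_table_path else {}
    metadata = metadata or {}

    genomes: dict[str, PhageGenome] = {}
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        desc_kv = dict(
            kv.split("=", 1) for kv in rec.description.split()[1:] if "=" in kv
        )
        meta = {**desc_kv, **metadata.get(rec.id, {})}
        glist = genes.pop(rec.id, [])
        for g in glist:
            if g.end > len(rec.seq):
                raise FormatError(
                    f"genome {rec.id!r}: gene {g.gene_id!r} interval "
                    f"[{g.start}, {g.end}] out of range"
                )
            if g.gene_id in phams:
                g.pham = phams[g.gene_id]
            elif not g.pham:
                warnings.warn(
                    f"gene {g.gene_id!r} has no pham assignment; "
                    "using a singleton pham",
                    stacklevel=2,
                )
                g.pham = f"singleton_{g.gene_id}"
        genomes[rec.id] = PhageGenome(
            id=rec.id,
            sequence=str(rec.seq),
            genes=glist,
            subcluster=meta.get("subcluster", ""),
            inheritance=meta.get("inheritance"),
        )
    if genes:
        warnings.warn(
            f"gene table rows for unknown genome ids: {sorted(genes)}",
            stacklevel=2,
        )
    return genomes


def write_genome_set(
    genomes: Iterable[PhageGenome],
    fasta_path: str | Path,
    gene_table_path: str | Path | None = None,
    pham_table_path: str | Path | None = None,
) -> None:
    """Write genomes back to the canonical FASTA / TSV trio (round-trippable)."""
    genomes = list(genomes)
    records = []
    for g in genomes:
        desc_parts = [g.id]
        if g.subcluster:
            desc_parts.append(f"subcluster={g.subcluster}")
        if g.inheritance:
            desc_parts.append(f"inheritance={g.inheritance}")
        records.append(
            SeqRecord(Seq(g.sequence), id=g.id, description=" ".join(desc_parts))
        )
    SeqIO.write(records, str(fasta_path), "fasta")
    if gene_table_path is not None:
        with open(gene_table_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["genome_id"] + _TSV_GENE_COLUMNS)
            for g in genomes:
                for gene in g.genes:
                    w.writerow(
                        [g.id, gene.gene_id, gene.start, gene.end,
                         gene.strand, gene.pham, gene.product]
                    )
    if pham_table_path is not None:
        with open(pham_table_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["gene_id", "pham"])
            for g in genomes:
                for gene in g.genes:
                    w.writerow([gene.gene_id, gene.pham])


# ---------------------------------------------------------------------------
# Assay table I/O

_ASSAY_COLUMNS = [
    "challenger", "defender", "defender_kind",
    "replicate_scores", "n", "mean", "min", "max",
]


def read_assay_table(tsv_path: str | Path) -> list[AssayRecord]:
    """Read a processed infection-assay table (one row per unique assay).

    Columns: ``challenger``, ``defender``, ``defender_kind`` and either a
    ``replicate_scores`` column of comma-separated integer scores or summary
    columns ``n``, ``mean``, ``min``, ``max``.
    """
    records: list[AssayRecord] = []
    with open(tsv_path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None:
            return records
        for i, row in enumerate(reader, 2):
            try:
                raw = (row.get("replicate_scores") or "").strip()
                if raw:
                    scores = [int(s) for s in raw.split(",")]
                    rec = AssayRecord(
                        challenger_id=row["challenger"],
                        defender_id=row["defender"],
                        defender_kind=row["defender_kind"],
                        replicate_scores=scores,
                    )
                else:
                    rec = AssayRecord(
                        challenger_id=row["challenger"],
                        defender_id=row["defender"],
                        defender_kind=row["defender_kind"],
                        n=int(row["n"]),
                        mean=float(row["mean"]),
                        min=float(row["min"]) if row.get("min") else None,
                        max=float(row["max"]) if row.get("max") else None,
                    )
            except (KeyError, ValueError, FormatError) as e:
                raise FormatError(f"{tsv_path}: row {i}: {e}") from e
            records.append(rec)
    return records


def write_assay_table(records: Iterable[AssayRecord], tsv_path: str | Path) -> None:
    with open(tsv_path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_ASSAY_COLUMNS)
        for r in records:
            w.writerow(
                [
                    r.challenger_id,
                    r.defender_id,
                    r.defender_kind,
                    ",".join(str(s) for s in r.replicate_scores),
                    r.n,
                    r.mean,
                    r.min,
                    r.max,
                ]
            )


# ---------------------------------------------------------------------------
# Packaged fixtures


def _data_path(name: str):
    return resources.files("mesoimmunity.data").joinpath(name)


def load_mutant_catalog() -> list[dict]:
    """The transcribed catalog of phages used for immunity assays.

    One dict per phage with keys ``phage``, ``subcluster``, ``inheritance``,
    ``lysogen_recovery``, ``parent``, ``mutant_type``, ``mutations`` (the raw
    genotype notation, ``;``-separated) and ``l5_clade`` (bool).
    """
    rows = []
    with resources.as_file(_data_path("mutant_catalog.tsv")) as p:
        with open(p, newline="") as fh:
            for row in csv.DictReader(fh, delimiter="\t"):
                row["l5_clade"] = row["l5_clade"] == "1"
                rows.append(row)
    return rows


def load_scoring_rubric() -> list[dict]:
    """The ordinal 0-6 infection-scoring rubric (score + phenotype description)."""
    with resources.as_file(_data_path("scoring_rubric.json")) as p:
        return json.loads(Path(p).read_text())
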