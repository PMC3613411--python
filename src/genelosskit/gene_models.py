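"""Core sequence/annotation data model and I/O.

Houses the domain objects shared by the rest of the toolkit — genomic
sequences, multi-exon coding gene models, locus records, protein
sequences — plus readers/writers for FASTA, a GFF3 subset (``gene`` +
``CDS`` features), and Newick trees.

Coordinate convention: 1-based, inclusive on both ends (the convention of
GFF3 and of genome-browser coordinate strings such as
``27,719,709-27,746,554``). Minus-strand gene models store plus-strand
coordinates; reverse complementing happens at extraction time, and exon
indices always count in transcription order.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal

import dendropy
from Bio import SeqIO
from Bio.Seq import Seq

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*X-")

#: Standard nuclear genetic code. Codons containing any non-ACGT symbol
#: translate to 'X'.
_STANDARD_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

STOP_CODONS = frozenset(c for c, aa in _STANDARD_CODE.items() if aa == "*")


class FastaParseError(ValueError):
    """Malformed or inadmissible FASTA input."""


class GeneModelError(ValueError):
    """Inconsistent gene model (overlapping CDS, mixed strands, ...)."""


class CoordinateError(ValueError):
    """Feature coordinates outside the bounds of their sequence."""


class NewickParseError(ValueError):
    """Unparseable Newick text."""


@dataclass(frozen=True)
class GenomicSequence:
    """A DNA sequence (chromosome, scaffold, or extracted region)."""

    id: str
    residues: str
    species: str = ""

    def __post_init__(self) -> None:
        bad = set(self.residues) - DNA_ALPHABET
        if bad:
            raise FastaParseError(
                f"sequence {self.id!r}: illegal DNA characters {sorted(bad)!r}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class ProteinSequence:
    """An amino-acid sequence; '-' allowed so aligned rows fit here too."""

    id: str
    residues: str
    intact: bool = False

    def __post_init__(self) -> None:
        if not self.residues:
            raise FastaParseError(f"protein {self.id!r} is empty")
        bad = set(self.residues) - PROTEIN_ALPHABET
        if bad:
            raise FastaParseError(
                f"protein {self.id!r}: illegal residues {sorted(bad)!r}"
            )
        if self.intact and "*" in self.residues[:-1]:
            raise FastaParseError(
                f"protein {self.id!r} flagged intact but has an internal stop"
            )

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class CodingExon:
    """One coding exon; ``phase`` is the number of bases carried over from
    the previous exon (GFF3 phase semantics)."""

    index: int
    start: int
    end: int
    phase: int = 0

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise CoordinateError(
                f"exon {self.index}: start {self.start} > end {self.end}"
            )
        if self.phase not in (0, 1, 2):
            raise GeneModelError(f"exon {self.index}: phase must be 0, 1 or 2")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneModel:
    """Ordered coding exons of one gene on a genomic sequence.

    ``exons`` are in transcription order (exon 1 first); on the minus
    strand exon 1 therefore has the largest plus-strand coordinates.
    """

    gene_id: str
    sequence_id: str
    strand: Literal["+", "-"]
    exons: list[CodingExon]
    species: str = ""
    reference: bool = False

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise GeneModelError(f"gene {self.gene_id!r}: strand must be + or -")
        if not self.exons:
            raise GeneModelError(f"gene {self.gene_id!r} has no exons")
        spans = sorted((e.start, e.end) for e in self.exons)
        for (s1, e1), (s2, _) in zip(spans, spans[1:]):
            if s2 <= e1:
                raise GeneModelError(f"gene {self.gene_id!r}: overlapping exons")
        idx = [e.index for e in self.exons]
        if idx != list(range(1, len(idx) + 1)):
            raise GeneModelError(
                f"gene {self.gene_id!r}: exon indices must be 1..n in "
                "transcription order"
            )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def coding_length(self) -> int:
        return sum(e.length for e in self.exons)


@dataclass(frozen=True)
class LocusRecord:
    """Genomic span of a gene in one species (one table row)."""

    species: str
    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise CoordinateError(
                f"{self.species}: locus end {self.end} < start {self.start}"
            )


def locus_span(record: LocusRecord) -> int:
    """Length in bases of a 1-based inclusive locus span (end − start + 1)."""
    return record.end - record.start + 1


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(
    path: str | Path, alphabet: Literal["dna", "protein"] = "dna"
) -> list[GenomicSequence] | list[ProteinSequence]:
    """Read a FASTA file into sequence records.

    Residues are uppercased; CRLF line endings are tolerated. Duplicate
    record ids, an empty file, or characters outside the stated alphabet
    raise :class:`FastaParseError`.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaParseError(f"{path}: no FASTA records found")
    seen: set[str] = set()
    out: list = []
    for rec in records:
        if rec.id in seen:
            raise FastaParseError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper().replace("\r", "")
        if alphabet == "dna":
            out.append(GenomicSequence(id=rec.id, residues=residues))
        else:
            out.append(ProteinSequence(id=rec.id, residues=residues))
    return out


def write_fasta(records: Iterable[GenomicSequence | ProteinSequence],
                path: str | Path, width: int = 60) -> None:
    """Write records as FASTA wrapped at ``width`` columns."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# GFF3 subset (gene + CDS)

_GFF_COLS = 9


def _gff_attributes(text: str) -> dict[str, str]:
    attrs = {}
    for part in text.strip().split(";"):
        if part and "=" in part:
            k, v = part.split("=", 1)
            attrs[k.strip()] = v.strip()
    return attrs


def read_gene_model(path: str | Path, gene_id: str | None = None) -> GeneModel:
    """Read one gene model from a GFF3-subset file (``gene``/``CDS`` lines).

    CDS lines are grouped by their ``Parent`` (or ``ID``) attribute and
    sorted into transcription order: ascending start on '+', descending on
    '-'. Phases are recomputed from cumulative coding length when absent.
    """
    path = Path(path)
    genes: dict[str, dict] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != _GFF_COLS:
                raise GeneModelError(f"{path}: expected 9 tab-separated columns")
            seqid, _src, ftype, start, end, _score, strand, phase, attr = cols
            attrs = _gff_attributes(attr)
            if ftype == "gene":
                gid = attrs.get("ID")
                if gid is None:
                    raise GeneModelError(f"{path}: gene feature without ID")
                genes.setdefault(gid, {"seqid": seqid, "strand": strand,
                                       "cds": []})
            elif ftype == "CDS":
                gid = attrs.get("Parent") or attrs.get("ID")
                if gid is None:
                    raise GeneModelError(f"{path}: CDS without Parent/ID")
                entry = genes.setdefault(
                    gid, {"seqid": seqid, "strand": strand, "cds": []})
                if entry["strand"] != strand:
                    raise GeneModelError(
                        f"{path}: mixed strands within gene {gid!r}")
                entry["cds"].append(
                    (int(start), int(end), None if phase == "." else int(phase))
                )
    candidates = {g: v for g, v in genes.items() if v["cds"]}
    if not candidates:
        raise GeneModelError(f"{path}: no CDS features found")
    if gene_id is None:
        if len(candidates) > 1:
            raise GeneModelError(
                f"{path}: multiple genes found, pass gene_id explicitly")
        gene_id, = candidates
    if gene_id not in candidates:
        raise GeneModelError(f"{path}: gene {gene_id!r} not found")
    entry = candidates[gene_id]
    strand = entry["strand"]
    cds = sorted(entry["cds"], key=lambda t: t[0], reverse=(strand == "-"))
    exons = []
    running = 0
    for i, (start, end, phase) in enumerate(cds, start=1):
        if phase is None:
            phase = (3 - running % 3) % 3
        exons.append(CodingExon(index=i, start=start, end=end, phase=phase))
        running += end - start + 1
    return GeneModel(gene_id=gene_id, sequence_id=entry["seqid"],
                     strand=strand, exons=exons)


def write_gene_model(model: GeneModel, path: str | Path) -> None:
    """Write a gene model back out as the GFF3 subset this package reads."""
    first = min(e.start for e in model.exons)
    last = max(e.end for e in model.exons)
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        fh.write("\t".join([
            model.sequence_id, "genelosskit", "gene", str(first), str(last),
            ".", model.strand, ".", f"ID={model.gene_id}",
        ]) + "\n")
        for exon in model.exons:
            fh.write("\t".join([
                model.sequence_id, "genelosskit", "CDS", str(exon.start),
                str(exon.end), ".", model.strand, str(exon.phase),
                f"ID={model.gene_id}.cds{exon.index};Parent={model.gene_id}",
            ]) + "\n")


# ---------------------------------------------------------------------------
# Sequence operations

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(dna: str) -> str:
    return dna.translate(_COMPLEMENT)[::-1]


def extract_cds(genome: GenomicSequence, model: GeneModel) -> str:
    """Concatenate exon substrings in transcription order.

    Minus-strand models are reverse complemented per exon, so the result
    always reads 5'→3' in the coding direction.
    """
    parts = []
    for exon in model.exons:
        if exon.start < 1 or exon.end > genome.length:
            raise CoordinateError(
                f"exon {exon.index} ({exon.start}-{exon.end}) outside "
                f"sequence {genome.id!r} (length {genome.length})"
            )
        sub = genome.residues[exon.start - 1 : exon.end]
        parts.append(reverse_complement(sub) if model.strand == "-" else sub)
    return "".join(parts)


def translate(cds: str) -> ProteinSequence:
    """Translate a coding DNA string under the standard genetic code.

    Stop codons become '*'; any codon containing a non-ACGT symbol becomes
    'X'. Trailing 1–2 bases are ignored (flagged on the returned record via
    id suffix being unchanged — callers needing the flag should check
    ``len(cds) % 3``).
    """
    cds = cds.upper()
    if len(cds) < 3:
        raise ValueError("CDS shorter than one codon")
    aas = []
    for i in range(0, len(cds) - len(cds) % 3, 3):
        codon = cds[i : i + 3]
        aas.append(_STANDARD_CODE.get(codon, "X"))
    return ProteinSequence(id="translation", residues="".join(aas))


# ---------------------------------------------------------------------------
# Newick trees (dendropy-backed)

def read_newick(source: str | Path) -> dendropy.Tree:
    """Read a Newick tree from a path or a literal Newick string."""
    if isinstance(source, Path):
        text = source.read_text()
    elif "(" in source and ";" in source:  # literal Newick, not a filename
        text = str(source)
    else:
        text = Path(source).read_text()
    if text.count("(") != text.count(")"):
        raise NewickParseError("unbalanced parentheses in Newick input")
    try:
        tree = dendropy.Tree.get(data=text, schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises various error classes
        raise NewickParseError(str(exc)) from exc
    return tree


def write_newick(tree: dendropy.Tree) -> str:
    """Serialize a tree to Newick, preserving labels and branch lengths."""
    return tree.as_string(schema="newick", unquoted_underscores=True,
                          suppress_rooting=True).strip()


def parse_coordinate_string(text: str) -> tuple[int, int]:
    """Parse a browser-style span like ``27,719,709-27,746,554``."""
    m = re.fullmatch(r"\s*([\d,]+)\s*-\s*([\d,]+)\s*", text)
    if not m:
        raise ValueError(f"cannot parse coordinate span {text!r}")
    return int(m.group(1).replace(",", "")), int(m.group(2).replace(",", ""))
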