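"""Detection of coding-sequence-disrupting mutations and gene-status calls.

A candidate gene is compared exon-by-exon against a reference gene model.
Three classes of disruption are recognised:

* frameshifts — net insertion/deletion within an exon of length not
  divisible by 3;
* premature stop codons — in-frame stops upstream of the reference
  terminal stop, read in the reference frame after "repairing" indels;
* splice-site mutations — intron-terminal dinucleotides departing from
  the canonical GT (donor) / AG (acceptor).

A gene with two or more disruptions is classified INACTIVATED; a single
disruption (possibly a sequencing error or a rare allele) leaves it
POTENTIALLY_INTACT.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import pandas as pd
from Bio import Align

from .gene_models import (
    GeneModel,
    GenomicSequence,
    STOP_CODONS,
    extract_cds,
    reverse_complement,
)
from .synteny import AbsenceCall, AbsenceStatus

CANONICAL_DONOR = "GT"
CANONICAL_ACCEPTOR = "AG"

#: Alignment scoring used for exon anchoring: match +1, mismatch −1,
#: gap of length k costs 4 + (k − 1).
MATCH_SCORE = 1.0
MISMATCH_SCORE = -1.0
GAP_OPEN_SCORE = -4.0
GAP_EXTEND_SCORE = -1.0

#: An exon counts as found when ≥50% of its reference bases are aligned,
#: ≥50% of the aligned columns match, and the alignment score over the
#: exon-proper columns reaches 0.2 per exon base. The score floor is what
#: rejects spurious placements: with ±1 match/mismatch scoring, optimal
#: alignments of unrelated sequence cherry-pick enough matches to reach
#: ~50% column identity but stay near score 0, while a genuine exon at
#: up to ~30–35% divergence scores well above 0.2/base.
FOUND_IDENTITY = 0.5
FOUND_COVERAGE = 0.5
FOUND_SCORE_PER_BASE = 0.2


class DisruptionCategory(str, Enum):
    FRAMESHIFT = "FRAMESHIFT"
    PREMATURE_STOP = "PREMATURE_STOP"
    SPLICE_DONOR = "SPLICE_DONOR"
    SPLICE_ACCEPTOR = "SPLICE_ACCEPTOR"


class GeneStatus(str, Enum):
    INTACT = "INTACT"
    POTENTIALLY_INTACT = "POTENTIALLY_INTACT"
    INACTIVATED = "INACTIVATED"
    DELETED = "DELETED"
    UNRESOLVED = "UNRESOLVED"


@dataclass(frozen=True)
class DisruptionEvent:
    species: str
    exon_index: int
    category: DisruptionCategory
    detail: str = ""


@dataclass
class ExonAlignmentResult:
    """Outcome of anchoring one reference exon in a target window."""

    exon_index: int
    ref_aligned: str
    tgt_aligned: str
    identity: float
    found: bool
    net_indel: int = 0
    donor_dinucleotide: str | None = None
    acceptor_dinucleotide: str | None = None
    coverage: float = 0.0
    repaired_exon: str = ""
    #: start of the exon proper in the target window (0-based), if found
    target_exon_start: int | None = None


@dataclass
class GeneStatusReport:
    species: str
    status: GeneStatus
    n_disruptions: int
    exons_found: int
    exons_total: int
    events: list[DisruptionEvent] = field(default_factory=list)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = MATCH_SCORE
    aligner.mismatch_score = MISMATCH_SCORE
    aligner.open_gap_score = GAP_OPEN_SCORE
    aligner.extend_gap_score = GAP_EXTEND_SCORE
    # The window may extend well past the exon: leading/trailing window
    # sequence is free (glocal alignment of the exon into the window).
    aligner.end_insertion_score = 0.0
    return aligner


_ALIGNER = _make_aligner()


def align_exon(
    ref_exon_with_flanks: str,
    target_window: str,
    exon_index: int = 1,
    flank5: int = 0,
    flank3: int = 0,
    first_exon: bool = False,
    last_exon: bool = False,
) -> ExonAlignmentResult:
    """Globally align a reference exon (with intronic flanks) into a
    target window and summarise what the alignment says about the exon.

    ``flank5``/``flank3`` give how many bases of intron flank the exon on
    each side of ``ref_exon_with_flanks``; splice dinucleotides are read
    off the *target* at the positions aligned to the intron boundaries.
    ``net_indel`` is the signed base count (target − reference) over the
    exon-proper columns.
    """
    if not ref_exon_with_flanks or not target_window:
        raise ValueError("empty sequence passed to align_exon")
    exon_len = len(ref_exon_with_flanks) - flank5 - flank3
    if exon_len <= 0:
        raise ValueError("flanks longer than the supplied reference string")

    alignment = _ALIGNER.align(ref_exon_with_flanks, target_window)[0]
    ref_row, tgt_row = str(alignment[0]), str(alignment[1])

    exon_lo, exon_hi = flank5, flank5 + exon_len  # ref coords of exon proper
    r = t = 0
    matches = aligned_cols = covered = 0
    insertions = deletions = 0
    donor = acceptor = None
    tgt_exon_start = None
    exon_score = 0.0
    prev_gap = None  # affine bookkeeping over exon-proper columns
    t_last_exon = None  # target index of last aligned exon base
    for rc, tc in zip(ref_row, tgt_row):
        in_exon = rc != "-" and exon_lo <= r < exon_hi
        if in_exon:
            if tc != "-":
                aligned_cols += 1
                covered += 1
                t_last_exon = t
                if rc == tc:
                    matches += 1
                    exon_score += MATCH_SCORE
                else:
                    exon_score += MISMATCH_SCORE
                prev_gap = None
            else:
                deletions += 1
                exon_score += (GAP_EXTEND_SCORE if prev_gap == "del"
                               else GAP_OPEN_SCORE)
                prev_gap = "del"
            if r == exon_lo:
                tgt_exon_start = t
                if not first_exon:
                    acceptor = target_window[t - 2 : t] if t >= 2 else None
        if rc == "-" and exon_lo + 1 <= r <= exon_hi - 1:
            insertions += 1
            exon_score += (GAP_EXTEND_SCORE if prev_gap == "ins"
                           else GAP_OPEN_SCORE)
            prev_gap = "ins"
        if rc != "-" and not (exon_lo <= r < exon_hi):
            prev_gap = None
        if rc != "-":
            r += 1
        if tc != "-":
            t += 1
    # The donor site is whatever immediately follows the exon in the
    # target, so read it after the last target base aligned inside the
    # exon (robust to insertions straddling the junction).
    if not last_exon and t_last_exon is not None:
        donor = target_window[t_last_exon + 1 : t_last_exon + 3] or None

    identity = matches / aligned_cols if aligned_cols else 0.0
    coverage = covered / exon_len
    found = (identity >= FOUND_IDENTITY and coverage >= FOUND_COVERAGE
             and exon_score >= FOUND_SCORE_PER_BASE * exon_len)
    net_indel = insertions - deletions

    result = ExonAlignmentResult(
        exon_index=exon_index,
        ref_aligned=ref_row,
        tgt_aligned=tgt_row,
        identity=identity,
        found=found,
        net_indel=net_indel,
        donor_dinucleotide=donor if len(donor or "") == 2 else None,
        acceptor_dinucleotide=acceptor if len(acceptor or "") == 2 else None,
        coverage=coverage,
        target_exon_start=tgt_exon_start,
    )
    result.repaired_exon = _repair_exon(result, exon_lo, exon_hi)
    return result


def _repair_exon(ear: ExonAlignmentResult, exon_lo: int, exon_hi: int) -> str:
    """Reference-frame repair of the target exon.

    Column-by-column over the exon proper: matched/substituted target
    bases are kept, deleted columns are restored with the reference base,
    inserted target bases are dropped. The result always has the
    reference exon's length, so the downstream stop-codon scan reads the
    reference frame.
    """
    out = []
    r = 0
    for rc, tc in zip(ear.ref_aligned, ear.tgt_aligned):
        if rc != "-":
            if exon_lo <= r < exon_hi:
                out.append(tc if tc != "-" else rc)
            r += 1
    return "".join(out)


def detect_frameshift(ear: ExonAlignmentResult,
                      species: str = "") -> list[DisruptionEvent]:
    """Frameshift call from the net indel of one found exon.

    Compensating indels within an exon cancel: only a net length change
    not divisible by 3 shifts the downstream reading frame.
    """
    if not ear.found:
        raise ValueError("frameshift detection requires a found exon")
    if ear.net_indel % 3 != 0:
        return [DisruptionEvent(
            species=species, exon_index=ear.exon_index,
            category=DisruptionCategory.FRAMESHIFT,
            detail=f"net_indel={ear.net_indel:+d}",
        )]
    return []


def detect_splice_mutations(
    model: GeneModel,
    junctions: dict[tuple[int, str], str | None],
    species: str = "",
) -> list[DisruptionEvent]:
    """Splice-consensus check over observed intron-boundary dinucleotides.

    ``junctions`` maps ``(exon_index, "donor"|"acceptor")`` to the
    observed target dinucleotide (donor follows the exon; acceptor
    precedes it). ``None`` values (exon not found) are skipped. GT–AG is
    canonical; a GC donor is still reported, flagged noncanonical.
    """
    events = []
    for (exon_index, side), dinuc in sorted(junctions.items()):
        if dinuc is None:
            continue
        if not 1 <= exon_index <= model.n_exons:
            raise ValueError(f"junction exon index {exon_index} out of range")
        dinuc = dinuc.upper()
        if side == "donor" and dinuc != CANONICAL_DONOR:
            detail = f"donor={dinuc}"
            if dinuc == "GC":
                detail += ";noncanonical"
            events.append(DisruptionEvent(
                species=species, exon_index=exon_index,
                category=DisruptionCategory.SPLICE_DONOR, detail=detail))
        elif side == "acceptor" and dinuc != CANONICAL_ACCEPTOR:
            events.append(DisruptionEvent(
                species=species, exon_index=exon_index,
                category=DisruptionCategory.SPLICE_ACCEPTOR,
                detail=f"acceptor={dinuc}"))
    return events


def detect_premature_stops(
    repaired_cds: str,
    exon_lengths: list[int],
    species: str = "",
) -> list[DisruptionEvent]:
    """In-frame stop codons strictly upstream of the reference terminal stop.

    ``repaired_cds`` must be the frame-restored CDS (one repaired exon per
    reference exon, concatenated), so its length equals the reference
    coding length and the final codon is the reference stop position.
    Each stop is attributed to the exon containing the codon's first base.
    """
    if len(repaired_cds) != sum(exon_lengths):
        raise ValueError("repaired CDS length does not match exon lengths")
    boundaries = []
    acc = 0
    for length in exon_lengths:
        acc += length
        boundaries.append(acc)

    def exon_of(base: int) -> int:
        for idx, b in enumerate(boundaries, start=1):
            if base < b:
                return idx
        return len(boundaries)

    events = []
    n_codons = len(repaired_cds) // 3
    for ci in range(n_codons - 1):  # exclude the terminal (reference) stop
        codon = repaired_cds[3 * ci : 3 * ci + 3]
        if codon in STOP_CODONS:
            events.append(DisruptionEvent(
                species=species, exon_index=exon_of(3 * ci),
                category=DisruptionCategory.PREMATURE_STOP,
                detail=f"codon={codon}@{3 * ci + 1}"))
    return events


def classify_status(
    events: list[DisruptionEvent],
    exons_found: int,
    exons_total: int,
    sequence_found: bool = True,
    absence: AbsenceCall | None = None,
    species: str = "",
) -> GeneStatusReport:
    """Per-species functional status from the disruption tally.

    No sequence at all defers to the synteny-based absence call (DELETED
    vs UNRESOLVED). Otherwise: ≥2 disruptions ⇒ INACTIVATED; exactly 1 ⇒
    POTENTIALLY_INTACT; 0 with all exons found ⇒ INTACT; 0 with missing
    exons ⇒ POTENTIALLY_INTACT (missing exons are not counted as
    disruptions).
    """
    if exons_found > exons_total:
        raise ValueError("exons_found exceeds exons_total")
    n = len(events)
    if not sequence_found:
        if absence is not None and absence.status == AbsenceStatus.DELETED:
            status = GeneStatus.DELETED
        else:
            status = GeneStatus.UNRESOLVED
        return GeneStatusReport(species=species, status=status,
                                n_disruptions=0, exons_found=0,
                                exons_total=exons_total, events=[])
    if n >= 2:
        status = GeneStatus.INACTIVATED
    elif n == 1:
        status = GeneStatus.POTENTIALLY_INTACT
    elif exons_found == exons_total:
        status = GeneStatus.INTACT
    else:
        status = GeneStatus.POTENTIALLY_INTACT
    return GeneStatusReport(species=species, status=status, n_disruptions=n,
                            exons_found=exons_found, exons_total=exons_total,
                            events=list(events))


def tabulate_disruptions(
    reports: list[GeneStatusReport],
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Disruption matrix (one row per species) plus status summary counts.

    Following the two-column convention of published disruption tables,
    premature stops are folded into the frameshift column of the matrix;
    the underlying event lists keep all four categories.
    """
    if not reports:
        raise ValueError("no reports to tabulate")
    rows = []
    for rep in reports:
        fs = sorted({e.exon_index for e in rep.events
                     if e.category in (DisruptionCategory.FRAMESHIFT,
                                       DisruptionCategory.PREMATURE_STOP)})
        sp = sorted({e.exon_index for e in rep.events
                     if e.category in (DisruptionCategory.SPLICE_DONOR,
                                       DisruptionCategory.SPLICE_ACCEPTOR)})
        rows.append({
            "species": rep.species,
            "frameshift_exons": ",".join(map(str, fs)),
            "splice_exons": ",".join(map(str, sp)),
            "n_distinct_exons": len(set(fs) | set(sp)),
            "n_events": len(rep.events),
            "status": rep.status.value,
        })
    matrix = pd.DataFrame(
        rows, columns=["species", "frameshift_exons", "splice_exons",
                       "n_distinct_exons", "n_events", "status"])
    summary = {status.value: 0 for status in GeneStatus}
    for rep in reports:
        summary[rep.status.value] += 1
    return matrix, summary


# ---------------------------------------------------------------------------
# Whole-gene scan

def scan_gene(
    ref_genome: GenomicSequence,
    ref_model: GeneModel,
    target: GenomicSequence,
    species: str,
    flank: int = 20,
    window_margin: int = 300,
) -> tuple[GeneStatusReport, list[ExonAlignmentResult]]:
    """Scan a target genomic sequence for disruptions of a reference gene.

    Each reference exon (with ``flank`` bp of intron on either side) is
    aligned into a window of the target centred on its expected position;
    the expectation assumes rough colinearity with the reference and is
    corrected by the drift observed at previously located exons.
    """
    if ref_model.strand == "-":
        # Work in transcription orientation throughout.
        ref_seq = reverse_complement(ref_genome.residues)
        n = ref_genome.length
        exon_coords = [(n - e.end, n - e.start + 1) for e in ref_model.exons]
    else:
        ref_seq = ref_genome.residues
        exon_coords = [(e.start - 1, e.end) for e in ref_model.exons]

    n_exons = ref_model.n_exons
    results: list[ExonAlignmentResult] = []
    drift = 0
    for i, (lo, hi) in enumerate(exon_coords, start=1):
        f5 = min(flank, lo)
        f3 = min(flank, len(ref_seq) - hi)
        ref_chunk = ref_seq[lo - f5 : hi + f3]
        w_lo = max(0, lo - f5 + drift - window_margin)
        w_hi = min(len(target.residues), hi + f3 + drift + window_margin)
        window = target.residues[w_lo:w_hi]
        if not window:
            results.append(ExonAlignmentResult(
                exon_index=i, ref_aligned="", tgt_aligned="", identity=0.0,
                found=False, repaired_exon=ref_seq[lo:hi]))
            continue
        ear = align_exon(ref_chunk, window, exon_index=i, flank5=f5,
                         flank3=f3, first_exon=(i == 1),
                         last_exon=(i == n_exons))
        if ear.found and ear.target_exon_start is not None:
            drift = (w_lo + ear.target_exon_start) - lo
        if not ear.found:
            ear.repaired_exon = ref_seq[lo:hi]  # neutral placeholder
        results.append(ear)

    events: list[DisruptionEvent] = []
    junctions: dict[tuple[int, str], str | None] = {}
    for ear in results:
        if ear.found:
            events.extend(detect_frameshift(ear, species=species))
        if ear.exon_index > 1:
            junctions[(ear.exon_index, "acceptor")] = (
                ear.acceptor_dinucleotide if ear.found else None)
        if ear.exon_index < n_exons:
            junctions[(ear.exon_index, "donor")] = (
                ear.donor_dinucleotide if ear.found else None)
    events.extend(detect_splice_mutations(ref_model, junctions,
                                          species=species))
    repaired = "".join(ear.repaired_exon for ear in results)
    exon_lengths = [hi - lo for lo, hi in exon_coords]
    events.extend(detect_premature_stops(repaired, exon_lengths,
                                         species=species))
    exons_found = sum(1 for ear in results if ear.found)
    report = classify_status(events, exons_found, n_exons,
                             sequence_found=True, species=species)
    return report, results
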