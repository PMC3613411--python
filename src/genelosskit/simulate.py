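"""Synthetic multi-exon gene families evolving along a species tree.

The generator emulates the data situation of a comparative pseudogene
survey: a multi-exon coding gene (by default 19 exons with GT–AG introns,
spread over tens of kilobases like the mammalian GCKR locus) evolves
along a rooted tree. On functional branches the ORF is conserved —
substitutions creating in-frame stops or touching splice dinucleotides
are rejected and resampled, and indels stay inside introns. On designated
loss branches the constraints are lifted, rates are multiplied, and
explicit disruptions (frameshifting indels, premature stops, splice-site
mutations) are injected and recorded.

The truth table is computed from the generator's exact final state (per-
exon net length changes, splice dinucleotides, a stop-codon scan of the
frame-restored CDS), so it stays correct even when later mutations
overlap earlier ones. All randomness flows through one seeded generator
in documented (preorder) traversal order, so output is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import dendropy
import numpy as np

from .disruption import DisruptionCategory, DisruptionEvent
from .gene_models import (
    CodingExon,
    GeneModel,
    GenomicSequence,
    STOP_CODONS,
)
from .rate_phylo import ProteinAlignment

_BASES = "ACGT"
_AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_NONSTOP_CODONS = sorted(
    a + b + c
    for a in _BASES for b in _BASES for c in _BASES
    if a + b + c not in STOP_CODONS
)


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the gene-family simulator.

    Rates are per site per unit branch length. ``loss_branches`` names
    branches by the frozenset of tip labels below them; everything at and
    below a loss branch evolves without coding constraints at
    ``post_loss_rate_multiplier`` times the base rates, and the loss
    branch itself receives the configured injected disruptions.
    """

    seed: int
    n_exons: int = 19
    exon_length_range: tuple[int, int] = (60, 150)
    intron_length_range: tuple[int, int] = (800, 2200)
    flank_length: int = 300
    substitution_rate: float = 0.02
    indel_rate: float = 0.002
    indel_length_p: float = 0.5
    loss_branches: frozenset[frozenset[str]] = frozenset()
    post_loss_rate_multiplier: float = 2.0
    loss_n_frameshifts: int = 2
    loss_n_stops: int = 1
    loss_n_splice: int = 2

    def __post_init__(self) -> None:
        if self.n_exons < 2:
            raise ValueError("need at least 2 exons")
        if min(self.substitution_rate, self.indel_rate) < 0:
            raise ValueError("rates must be non-negative")
        if self.post_loss_rate_multiplier < 1:
            raise ValueError("post-loss multiplier must be >= 1")


@dataclass
class _IndelRecord:
    """One injected exon indel: enough to undo it for truth repair."""

    exon: int  # 0-based
    pos: int  # position within the exon at injection time
    length: int
    is_insertion: bool
    deleted_ref: str = ""  # reference bases removed (deletions only)


@dataclass
class _Gene:
    flank5: str
    exons: list[str]
    introns: list[str]
    flank3: str
    indels: list[_IndelRecord] = field(default_factory=list)
    lost: bool = False

    def copy(self) -> "_Gene":
        return _Gene(self.flank5, list(self.exons), list(self.introns),
                     self.flank3, [replace(r) for r in self.indels],
                     self.lost)

    def assembled(self) -> str:
        parts = [self.flank5]
        for i, exon in enumerate(self.exons):
            parts.append(exon)
            if i < len(self.introns):
                parts.append(self.introns[i])
        parts.append(self.flank3)
        return "".join(parts)

    def exon_coords(self) -> list[tuple[int, int]]:
        """1-based inclusive exon spans within the assembled sequence."""
        coords = []
        pos = len(self.flank5)
        for i, exon in enumerate(self.exons):
            coords.append((pos + 1, pos + len(exon)))
            pos += len(exon)
            if i < len(self.introns):
                pos += len(self.introns[i])
        return coords

    def cds(self) -> str:
        return "".join(self.exons)


@dataclass
class TruthTable:
    events: dict[str, list[DisruptionEvent]]
    loss_edges: frozenset[frozenset[str]]

    def event_set(self, species: str) -> set[tuple[str, int]]:
        return {(e.category.value, e.exon_index)
                for e in self.events.get(species, [])}


@dataclass
class SimulatedFamily:
    ref_sequence: GenomicSequence
    ref_model: GeneModel
    tip_sequences: dict[str, GenomicSequence]
    tip_models: dict[str, GeneModel]
    truth: TruthTable


def _random_root_gene(rng: np.random.Generator,
                      config: SimulationConfig) -> _Gene:
    lo, hi = config.exon_length_range
    lengths = [int(rng.integers(lo, hi + 1)) for _ in range(config.n_exons)]
    total = sum(lengths)
    lengths[-1] += (3 - total % 3) % 3
    n_codons = sum(lengths) // 3
    codons = ["ATG"]
    codons += [
        _NONSTOP_CODONS[int(rng.integers(len(_NONSTOP_CODONS)))]
        for _ in range(n_codons - 2)
    ]
    codons.append(sorted(STOP_CODONS)[int(rng.integers(3))])
    coding = "".join(codons)
    exons = []
    pos = 0
    for length in lengths:
        exons.append(coding[pos : pos + length])
        pos += length
    ilo, ihi = config.intron_length_range
    introns = []
    for _ in range(config.n_exons - 1):
        ilen = int(rng.integers(ilo, ihi + 1))
        interior = "".join(_BASES[b] for b in rng.integers(0, 4, ilen - 4))
        introns.append("GT" + interior + "AG")
    flank = lambda n: "".join(_BASES[b] for b in rng.integers(0, 4, n))
    return _Gene(flank5=flank(config.flank_length), exons=exons,
                 introns=introns, flank3=flank(config.flank_length))


def _segment_of(gene: _Gene, pos: int):
    """Map an assembled-sequence position to (kind, index, offset)."""
    off = len(gene.flank5)
    if pos < off:
        return "flank5", 0, pos
    for i, exon in enumerate(gene.exons):
        if pos < off + len(exon):
            return "exon", i, pos - off
        off += len(exon)
        if i < len(gene.introns):
            if pos < off + len(gene.introns[i]):
                return "intron", i, pos - off
            off += len(gene.introns[i])
    return "flank3", 0, pos - off


def _repaired_exons(gene: _Gene) -> list[str]:
    """Exon strings with every recorded indel undone against the reference
    (deleted reference bases restored, inserted bases dropped), i.e. the
    reference-frame view a downstream repair would reconstruct."""
    repaired = list(gene.exons)
    for rec in gene.indels:
        raw = repaired[rec.exon]
        if rec.is_insertion:
            repaired[rec.exon] = raw[: rec.pos] + raw[rec.pos + rec.length :]
        else:
            repaired[rec.exon] = (raw[: rec.pos] + rec.deleted_ref
                                  + raw[rec.pos :])
    return repaired


def _changes_stop_status(gene: _Gene, exon_idx: int, off: int,
                         base: str) -> bool:
    """Would substituting ``base`` at this exon offset create or destroy a
    stop codon in the reference reading frame? Positions are evaluated on
    the indel-undone CDS, where offsets in indel-free exons coincide with
    reference offsets."""
    reps = _repaired_exons(gene)
    cds = "".join(reps)
    pos = sum(len(e) for e in reps[:exon_idx]) + off
    ci = pos // 3
    codon = cds[3 * ci : 3 * ci + 3]
    new_codon = codon[: pos % 3] + base + codon[pos % 3 + 1 :]
    return (new_codon in STOP_CODONS) != (codon in STOP_CODONS)


def _apply_substitutions(gene: _Gene, n: int,
                         rng: np.random.Generator) -> None:
    length = len(gene.assembled())
    for _ in range(n):
        for _attempt in range(50):
            pos = int(rng.integers(length))
            kind, idx, off = _segment_of(gene, pos)
            base = _BASES[int(rng.integers(4))]
            if kind == "exon":
                if gene.exons[idx][off] == base:
                    continue
                if gene.lost and any(r.exon == idx for r in gene.indels):
                    # frame-shifted exons change only via their injected
                    # indel, keeping the truth repair exact
                    continue
                # conserve start, terminal stop, and reference-frame stop
                # status; on lost lineages stops enter via injection so
                # the truth table stays unambiguous
                cds_pos = sum(len(e) for e in _repaired_exons(gene)[:idx]) \
                    + off
                if cds_pos < 3 or cds_pos >= sum(
                        len(e) for e in _repaired_exons(gene)) - 3:
                    continue
                if _changes_stop_status(gene, idx, off, base):
                    continue
                gene.exons[idx] = (gene.exons[idx][:off] + base
                                   + gene.exons[idx][off + 1 :])
                break
            if kind == "intron":
                intron = gene.introns[idx]
                if not gene.lost and (off < 2 or off >= len(intron) - 2):
                    continue
                if intron[off] == base:
                    continue
                gene.introns[idx] = intron[:off] + base + intron[off + 1 :]
                break
            seq = gene.flank5 if kind == "flank5" else gene.flank3
            if seq[off] == base:
                continue
            seq = seq[:off] + base + seq[off + 1 :]
            if kind == "flank5":
                gene.flank5 = seq
            else:
                gene.flank3 = seq
            break


def _apply_intron_indels(gene: _Gene, n: int, rng: np.random.Generator,
                         length_p: float = 0.5) -> None:
    """Background indels: intron interiors only, never the dinucleotides;
    intron length floor keeps junction windows usable."""
    for _ in range(n):
        for _attempt in range(50):
            idx = int(rng.integers(len(gene.introns)))
            intron = gene.introns[idx]
            size = int(rng.geometric(length_p))
            insert = bool(rng.integers(2))
            interior_lo, interior_hi = 2, len(intron) - 2
            if insert:
                pos = int(rng.integers(interior_lo, interior_hi))
                piece = "".join(_BASES[b] for b in rng.integers(0, 4, size))
                gene.introns[idx] = intron[:pos] + piece + intron[pos:]
                break
            if interior_hi - interior_lo - size < 1 or len(intron) - size < 12:
                continue
            pos = int(rng.integers(interior_lo, interior_hi - size))
            gene.introns[idx] = intron[:pos] + intron[pos + size :]
            break


def _inject_disruptions(gene: _Gene, ref: _Gene, config: SimulationConfig,
                        rng: np.random.Generator) -> None:
    """Explicit inactivating mutations on a loss branch.

    At most one indel per exon, premature stops only in indel-free exons,
    so the truth repair (undoing each indel) is exact.
    """
    n_exons = len(gene.exons)
    taken = {r.exon for r in gene.indels}
    free = [i for i in range(n_exons) if i not in taken]
    rng.shuffle(free)
    for _ in range(config.loss_n_frameshifts):
        if not free:
            break
        exon_idx = free.pop()
        exon = gene.exons[exon_idx]
        size = int(rng.integers(1, 5))
        if size % 3 == 0:
            size += 1
        size = min(size, max(1, len(exon) // 2))
        if size % 3 == 0:  # after capping
            size = 1
        insert = bool(rng.integers(2))
        # keep injected indels clear of the junctions: attribution of an
        # indel sitting on an exon/intron boundary is not well defined
        margin = 5
        lo, hi = margin, max(margin + 1, len(exon) - size - margin)
        pos = int(rng.integers(lo, hi))
        if insert:
            piece = "".join(_BASES[b] for b in rng.integers(0, 4, size))
            gene.exons[exon_idx] = exon[:pos] + piece + exon[pos:]
            gene.indels.append(_IndelRecord(exon=exon_idx, pos=pos,
                                            length=size, is_insertion=True))
        else:
            gene.exons[exon_idx] = exon[:pos] + exon[pos + size :]
            gene.indels.append(_IndelRecord(
                exon=exon_idx, pos=pos, length=size, is_insertion=False,
                deleted_ref=ref.exons[exon_idx][pos : pos + size]))
        taken.add(exon_idx)
    # premature stops in indel-free exons: single-base nonsense changes at
    # reference-frame codons (one substitution away from TAA/TAG/TGA)
    offsets = np.cumsum([0] + [len(e) for e in ref.exons])
    stop_list = sorted(STOP_CODONS)
    total_codons = sum(len(e) for e in ref.exons) // 3
    for _ in range(config.loss_n_stops):
        candidates = [i for i in range(n_exons) if i not in taken]
        if not candidates:
            break
        exon_idx = candidates[int(rng.integers(len(candidates)))]
        start_off = int(offsets[exon_idx])
        # codons fully inside this exon, excluding the terminal codon
        first_ci = -(-start_off // 3)
        last_ci = (int(offsets[exon_idx + 1]) - 3) // 3
        last_ci = min(last_ci, total_codons - 2)
        exon = gene.exons[exon_idx]
        options = []
        for ci in range(first_ci, last_ci + 1):
            codon_pos = 3 * ci - start_off
            codon = exon[codon_pos : codon_pos + 3]
            for stop in stop_list:
                if sum(a != b for a, b in zip(codon, stop)) == 1:
                    options.append((codon_pos, stop))
        if not options:
            continue
        codon_pos, stop = options[int(rng.integers(len(options)))]
        gene.exons[exon_idx] = (exon[:codon_pos] + stop
                                + exon[codon_pos + 3 :])
    # splice-site mutations
    junctions = [(i, side) for i in range(len(gene.introns))
                 for side in ("donor", "acceptor")]
    rng.shuffle(junctions)
    mutated = 0
    for i, side in junctions:
        if mutated >= config.loss_n_splice:
            break
        intron = gene.introns[i]
        canonical = "GT" if side == "donor" else "AG"
        current = intron[:2] if side == "donor" else intron[-2:]
        if current != canonical:
            continue  # already mutated on an ancestral loss branch
        while True:
            dinuc = "".join(_BASES[b] for b in rng.integers(0, 4, 2))
            if dinuc != canonical:
                break
        if side == "donor":
            gene.introns[i] = dinuc + intron[2:]
        else:
            gene.introns[i] = intron[:-2] + dinuc
        mutated += 1


def _truth_events(gene: _Gene, ref: _Gene, species: str
                  ) -> list[DisruptionEvent]:
    """Exact truth from the final state of one tip gene."""
    events: list[DisruptionEvent] = []
    n_exons = len(gene.exons)
    for i in range(n_exons):
        net = len(gene.exons[i]) - len(ref.exons[i])
        if net % 3 != 0:
            events.append(DisruptionEvent(
                species=species, exon_index=i + 1,
                category=DisruptionCategory.FRAMESHIFT,
                detail=f"net_indel={net:+d}"))
    for i, intron in enumerate(gene.introns):
        if intron[:2] != "GT":
            events.append(DisruptionEvent(
                species=species, exon_index=i + 1,
                category=DisruptionCategory.SPLICE_DONOR,
                detail=f"donor={intron[:2]}"))
        if intron[-2:] != "AG":
            events.append(DisruptionEvent(
                species=species, exon_index=i + 2,
                category=DisruptionCategory.SPLICE_ACCEPTOR,
                detail=f"acceptor={intron[-2:]}"))
    # frame-restored CDS: undo each recorded indel against the reference
    repaired_exons = _repaired_exons(gene)
    repaired = "".join(repaired_exons)
    assert len(repaired) == sum(len(e) for e in ref.exons)
    boundaries = np.cumsum([len(e) for e in repaired_exons])
    for ci in range(len(repaired) // 3 - 1):
        codon = repaired[3 * ci : 3 * ci + 3]
        if codon in STOP_CODONS:
            exon_idx = int(np.searchsorted(boundaries, 3 * ci, side="right"))
            events.append(DisruptionEvent(
                species=species, exon_index=exon_idx + 1,
                category=DisruptionCategory.PREMATURE_STOP,
                detail=f"codon={codon}@{3 * ci + 1}"))
    return events


def _gene_to_records(gene: _Gene, seq_id: str, species: str,
                     reference: bool = False
                     ) -> tuple[GenomicSequence, GeneModel]:
    seq = GenomicSequence(id=seq_id, residues=gene.assembled(),
                          species=species)
    exons = [CodingExon(index=i + 1, start=s, end=e)
             for i, (s, e) in enumerate(gene.exon_coords())]
    running = 0
    fixed = []
    for exon in exons:
        fixed.append(CodingExon(index=exon.index, start=exon.start,
                                end=exon.end, phase=(3 - running % 3) % 3))
        running += exon.length
    model = GeneModel(gene_id=f"{seq_id}_gene", sequence_id=seq_id,
                      strand="+", exons=fixed, species=species,
                      reference=reference)
    return seq, model


def simulate_gene_family(tree: dendropy.Tree,
                         config: SimulationConfig) -> SimulatedFamily:
    """Evolve one gene along a rooted tree and return per-tip records plus
    the exact truth table of injected/accumulated disruptions."""
    tips_below: dict[dendropy.Node, frozenset[str]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label if node.taxon else node.label
            tips_below[node] = frozenset([label])
        else:
            tips_below[node] = frozenset().union(
                *(tips_below[k] for k in node.child_nodes()))
    all_edges = {tips_below[n] for n in tree.preorder_node_iter()
                 if n is not tree.seed_node}
    unknown = set(config.loss_branches) - all_edges
    if unknown:
        raise ValueError(
            f"loss branches not in tree: {[sorted(e) for e in unknown]}")

    rng = np.random.default_rng(config.seed)
    root_gene = _random_root_gene(rng, config)
    ref_seq, ref_model = _gene_to_records(root_gene, "ref", "reference",
                                          reference=True)

    tip_sequences: dict[str, GenomicSequence] = {}
    tip_models: dict[str, GeneModel] = {}
    truth_events: dict[str, list[DisruptionEvent]] = {}

    genes: dict[dendropy.Node, _Gene] = {tree.seed_node: root_gene}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        gene = genes[node.parent_node].copy()
        branch_len = node.edge.length if node.edge.length else 1.0
        is_loss = tips_below[node] in config.loss_branches
        if is_loss:
            gene.lost = True
        mult = config.post_loss_rate_multiplier if gene.lost else 1.0
        length = len(gene.assembled())
        n_subs = int(rng.poisson(
            config.substitution_rate * mult * branch_len * length))
        n_indels = int(rng.poisson(
            config.indel_rate * mult * branch_len * length))
        _apply_substitutions(gene, n_subs, rng)
        _apply_intron_indels(gene, n_indels, rng, config.indel_length_p)
        if is_loss:
            _inject_disruptions(gene, root_gene, config, rng)
        genes[node] = gene
        if node.is_leaf():
            label = next(iter(tips_below[node]))
            seq, model = _gene_to_records(gene, f"{label}_locus", label)
            tip_sequences[label] = seq
            tip_models[label] = model
            truth_events[label] = (_truth_events(gene, root_gene, label)
                                   if gene.lost else [])

    return SimulatedFamily(
        ref_sequence=ref_seq, ref_model=ref_model,
        tip_sequences=tip_sequences, tip_models=tip_models,
        truth=TruthTable(events=truth_events,
                         loss_edges=frozenset(config.loss_branches)))


def make_relative_rate_case(
    rate_a: float, rate_b: float, n_sites: int, seed: int
) -> tuple[ProteinAlignment, dict[str, int]]:
    """Three-taxon protein alignment with unequal lineage rates.

    The outgroup row is uniform over the 20 amino acids; lineages a and b
    each mutate every site independently with their own rate, to a uniform
    choice among the 19 alternative residues. Returns the alignment and
    the true per-lineage exclusive mutation counts.
    """
    if not (0 <= rate_a < 1 and 0 <= rate_b < 1):
        raise ValueError("rates must be in [0, 1)")
    if n_sites < 1:
        raise ValueError("need at least one site")
    rng = np.random.default_rng(seed)
    out = rng.integers(0, 20, n_sites)

    def mutate(row: np.ndarray, rate: float) -> np.ndarray:
        hit = rng.random(n_sites) < rate
        shift = rng.integers(1, 20, n_sites)
        return np.where(hit, (row + shift) % 20, row)

    a = mutate(out, rate_a)
    b = mutate(out, rate_b)
    truth = {
        "n_a_exclusive": int(np.sum((a != out) & (b == out))),
        "n_b_exclusive": int(np.sum((b != out) & (a == out))),
    }
    to_str = lambda row: "".join(_AMINO_ACIDS[i] for i in row)
    aln = ProteinAlignment(rows={
        "lineage_a": to_str(a), "lineage_b": to_str(b),
        "outgroup": to_str(out),
    })
    return aln, truth
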