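"""Synteny-anchored gene presence/absence calls.

When similarity search finds no trace of a gene in a genome, two
explanations compete: the gene was deleted, or it sits in an unsequenced
assembly gap. If the genes that flank the target in outgroup genomes are
found adjacent on a single assembly fragment with nothing between them,
deletion is the parsimonious call; if the flanks land on different short
fragments, the question stays open.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import pandas as pd


class AbsenceStatus(str, Enum):
    PRESENT = "PRESENT"
    DELETED = "DELETED"
    UNRESOLVED = "UNRESOLVED"


class NoAnchorError(ValueError):
    """No flanking gene is shared across the reference neighborhood maps."""


@dataclass(frozen=True)
class GeneHit:
    symbol: str
    orientation: str  # '+' or '-'
    start: int


@dataclass
class FragmentMap:
    """Ordered gene hits on one assembly fragment of one species."""

    species: str
    fragment_id: str
    hits: list[GeneHit] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.hits = sorted(
            (GeneHit(h.symbol.upper(), h.orientation, h.start)
             for h in self.hits),
            key=lambda h: h.start,
        )

    def symbols(self) -> list[str]:
        return [h.symbol for h in self.hits]


@dataclass(frozen=True)
class AbsenceCall:
    species: str
    target: str
    status: AbsenceStatus
    evidence: str = ""


def read_gene_map(path: str | Path) -> dict[str, list[FragmentMap]]:
    """Read a TSV neighborhood map (species, fragment, symbol, strand, start)
    into per-species fragment maps."""
    df = pd.read_csv(path, sep="\t", comment="#",
                     names=["species", "fragment", "symbol", "strand",
                            "start"],
                     header=None, dtype={"start": int})
    out: dict[str, list[FragmentMap]] = {}
    for (species, fragment), grp in df.groupby(["species", "fragment"],
                                               sort=True):
        hits = [GeneHit(row.symbol, row.strand, int(row.start))
                for row in grp.itertuples()]
        out.setdefault(str(species), []).append(
            FragmentMap(species=str(species), fragment_id=str(fragment),
                        hits=hits))
    return out


def write_absence_calls(calls: list[AbsenceCall], path: str | Path) -> None:
    pd.DataFrame(
        [{"species": c.species, "target": c.target,
          "status": c.status.value, "evidence": c.evidence} for c in calls],
        columns=["species", "target", "status", "evidence"],
    ).to_csv(path, sep="\t", index=False)


def _neighbours(maps: list[FragmentMap], target: str):
    """5'- and 3'-side neighbour lists (nearest first, with orientation
    relative to the target) over every fragment of one species holding the
    target; None if the target is absent. A gene split over several
    fragments (draft assemblies) contributes the neighbours seen on each."""
    target = target.upper()
    up: list[tuple[str, bool]] = []
    down: list[tuple[str, bool]] = []
    seen = False
    for fmap in maps:
        syms = fmap.symbols()
        if target not in syms:
            continue
        seen = True
        i = syms.index(target)
        t_or = fmap.hits[i].orientation
        # 5' side is before the target in its transcription direction.
        upstream = fmap.hits[:i] if t_or == "+" else fmap.hits[i + 1:]
        downstream = fmap.hits[i + 1:] if t_or == "+" else fmap.hits[:i]
        if t_or == "+":
            up_order = list(reversed(upstream))  # nearest first
            down_order = downstream
        else:
            up_order = upstream
            down_order = list(reversed(downstream))
        up.extend((h.symbol, h.orientation == t_or) for h in up_order
                  if h.symbol != target)
        down.extend((h.symbol, h.orientation == t_or) for h in down_order
                    if h.symbol != target)
    return (up, down) if seen else None


def find_conserved_flanks(
    maps: dict[str, list[FragmentMap]], target: str
) -> tuple[str | None, str | None]:
    """Nearest 5' and 3' flanking gene symbols shared (same side, same
    orientation relative to the target) across the reference species maps
    containing the target.

    Short assembly fragments often show only one side of the target;
    a reference map with no information on a side abstains for that side
    rather than vetoing every candidate. A side with no shared symbol
    yields ``None``; if neither side resolves, :class:`NoAnchorError` is
    raised.
    """
    target = target.upper()
    per_species = []
    for species_maps in maps.values():
        nb = _neighbours(species_maps, target)
        if nb is not None:
            per_species.append(nb)
    if len(per_species) < 2:
        raise NoAnchorError(
            f"target {target!r} present in fewer than 2 reference maps")

    def shared(side: int) -> str | None:
        informative = [sp[side] for sp in per_species if sp[side]]
        if not informative:
            return None
        for sym, rel in informative[0]:  # nearest-first
            if all((sym, rel) in others for others in informative[1:]):
                return sym
        return None

    flank5, flank3 = shared(0), shared(1)
    if flank5 is None and flank3 is None:
        raise NoAnchorError(f"no shared flank for {target!r}")
    return flank5, flank3


def call_absence(
    species_maps: list[FragmentMap],
    target: str,
    flank5: str,
    flank3: str,
) -> AbsenceCall:
    """Presence/deletion/unresolved verdict for one species.

    PRESENT if the target is hit anywhere. DELETED only if both flanks sit
    on one fragment, in consistent relative orientation, with no target hit
    between them (intervening unrelated genes do not block the call).
    Otherwise UNRESOLVED. Fragment polarity is arbitrary, so all checks use
    relative order/orientation and calls are invariant to mirroring a
    fragment.
    """
    if not species_maps:
        raise ValueError("empty species map")
    target, flank5, flank3 = target.upper(), flank5.upper(), flank3.upper()
    species = species_maps[0].species
    for fmap in species_maps:
        if target in fmap.symbols():
            return AbsenceCall(species=species, target=target,
                               status=AbsenceStatus.PRESENT,
                               evidence=f"hit on {fmap.fragment_id}")
    for fmap in species_maps:
        syms = fmap.symbols()
        if flank5 in syms and flank3 in syms:
            i5, i3 = syms.index(flank5), syms.index(flank3)
            o5 = fmap.hits[i5].orientation
            o3 = fmap.hits[i3].orientation
            # Both flanks transcribed the same way relative to each other
            # is the conserved configuration around the target locus.
            if o5 != o3:
                continue
            lo, hi = sorted((i5, i3))
            between = syms[lo + 1 : hi]
            if target not in between:
                return AbsenceCall(
                    species=species, target=target,
                    status=AbsenceStatus.DELETED,
                    evidence=(f"{flank5} and {flank3} linked on "
                              f"{fmap.fragment_id}, no {target} between"))
    return AbsenceCall(species=species, target=target,
                       status=AbsenceStatus.UNRESOLVED,
                       evidence="flanks not co-located on one fragment")
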