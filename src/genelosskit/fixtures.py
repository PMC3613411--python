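"""Loaders for the packaged reference data.

The package bundles small, plain-text transcriptions of the published
survey of vertebrate GCKR loci (compiled originally from Ensembl/
PreEnsembl release 69): locus coordinates, the per-species disruption
matrix, gene-status categories, relative-rate substitution counts, gene
neighborhood maps, and the consensus species tree. These are data
transcriptions, not computed results.
"""

from __future__ import annotations

import shutil
from importlib import resources
from pathlib import Path

import dendropy
import pandas as pd

from .gene_models import LocusRecord, read_newick
from .parsimony import TipState
from .synteny import FragmentMap, read_gene_map

FIXTURE_FILES = (
    "locus_table.tsv",
    "disruption_table.tsv",
    "status_table.tsv",
    "rate_table.tsv",
    "neighborhoods.tsv",
    "species_tree.nwk",
)

TARGET_GENE = "GCKR"


def _data_path(name: str) -> Path:
    return Path(resources.files("genelosskit.data") / name)


def load_locus_table() -> tuple[list[LocusRecord], list[str]]:
    """Locus records for species with a found gene span, plus the list of
    species where no gene-like sequence was found.

    Spans are normalised to start ≤ end (minus-strand spans are published
    end-first).
    """
    df = pd.read_csv(_data_path("locus_table.tsv"), sep="\t", comment="#")
    records = []
    not_found = []
    for row in df.itertuples():
        if row.status == "found":
            lo, hi = sorted((int(row.start), int(row.end)))
            records.append(LocusRecord(species=row.species, contig=row.contig,
                                       start=lo, end=hi))
        elif row.status == "not_found":
            not_found.append(row.species)
    return records, not_found


def load_disruption_table() -> pd.DataFrame:
    """Per-species disrupted-exon lists with parsed integer exon sets in
    ``frameshift`` and ``splice`` columns."""
    df = pd.read_csv(_data_path("disruption_table.tsv"), sep="\t",
                     comment="#")

    def parse(cell: str) -> tuple[int, ...]:
        cell = str(cell).strip()
        if cell in ("-", "", "nan"):
            return ()
        return tuple(int(x) for x in cell.split(","))

    df["frameshift"] = df["frameshift_exons"].map(parse)
    df["splice"] = df["splice_exons"].map(parse)
    return df


def load_status_table() -> dict[str, str]:
    df = pd.read_csv(_data_path("status_table.tsv"), sep="\t", comment="#")
    return dict(zip(df["species"], df["status"]))


def load_rate_table() -> pd.DataFrame:
    return pd.read_csv(_data_path("rate_table.tsv"), sep="\t", comment="#")


def load_neighborhood_maps() -> dict[str, list[FragmentMap]]:
    return read_gene_map(_data_path("neighborhoods.tsv"))


def load_species_tree() -> dendropy.Tree:
    return read_newick(_data_path("species_tree.nwk"))


def loss_tip_states() -> dict[str, TipState]:
    """Tip states for parsimony mapping of inactivation events.

    NONFUNCTIONAL: species whose gene carries both a frameshift and a
    splice-junction mutation (the unambiguously dead genes). FUNCTIONAL:
    species with intact coding regions. Everything else (single-mutation
    or incomplete genes, and species where the gene or its neighborhood
    could not be resolved) is MISSING, i.e. unconstrained.
    """
    dual = {
        row.species
        for row in load_disruption_table().itertuples()
        if row.frameshift and row.splice
    }
    states: dict[str, TipState] = {}
    for species, status in load_status_table().items():
        if species in dual:
            states[species] = TipState.NONFUNCTIONAL
        elif status == "INTACT":
            states[species] = TipState.FUNCTIONAL
        else:
            states[species] = TipState.MISSING
    return states


def make_paper_fixtures(outdir: str | Path) -> dict[str, Path]:
    """Copy the packaged fixture files into ``outdir``; returns name→path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    out = {}
    for name in FIXTURE_FILES:
        dest = outdir / name
        shutil.copyfile(_data_path(name), dest)
        out[name] = dest
    return out
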