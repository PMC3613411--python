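"""Pipeline orchestration: scan → classify → tabulate → map → test.

Composes the detection, synteny, parsimony and rate-test modules into a
deterministic end-to-end run with versioned, byte-reproducible reports.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .disruption import (
    DisruptionCategory,
    DisruptionEvent,
    GeneStatus,
    GeneStatusReport,
    classify_status,
    scan_gene,
    tabulate_disruptions,
)
from .fixtures import (
    load_disruption_table,
    load_rate_table,
    load_species_tree,
    loss_tip_states,
)
from .gene_models import GeneModel, GenomicSequence
from .parsimony import EventPlacement, TipState, dollo_min_events
from .rate_phylo import ProteinAlignment, RateTestResult, relative_rate_test, tajima_chi2
from .synteny import AbsenceCall, FragmentMap, call_absence, find_conserved_flanks

logger = logging.getLogger("genelosskit")

REPORT_SCHEMA_VERSION = 1

#: Two or more coding-sequence-disrupting mutations mark a gene
#: inactivated; one may be a sequencing error or rare allele.
INACTIVATION_THRESHOLD = 2


@dataclass
class PipelineConfig:
    """Inputs and thresholds for one pipeline run."""

    seed: int = 0
    exon_found_identity: float = 0.5
    inactivation_threshold: int = INACTIVATION_THRESHOLD
    flank: int = 20
    window_margin: int = 300
    output_dir: Path | None = None

    def config_hash(self) -> str:
        payload = {k: str(v) for k, v in asdict(self).items()}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


@dataclass
class RunReport:
    reports: list[GeneStatusReport]
    disruption_matrix: pd.DataFrame
    status_summary: dict[str, int]
    absence_calls: list[AbsenceCall] = field(default_factory=list)
    placement: EventPlacement | None = None
    rate_results: list[RateTestResult] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)


def run_scan(
    config: PipelineConfig,
    ref_genome: GenomicSequence,
    ref_model: GeneModel,
    targets: dict[str, GenomicSequence | None],
    maps: dict[str, list[FragmentMap]] | None = None,
    target_gene: str = "GENE",
) -> RunReport:
    """Scan each target species for disruptions; species with no sequence
    fall back to the synteny absence call."""
    flank5 = flank3 = None
    if maps:
        try:
            flank5, flank3 = find_conserved_flanks(maps, target_gene)
        except ValueError:
            logger.info("no conserved flanks; absence calls unresolved")
    reports = []
    calls = []
    for species in sorted(targets):
        target = targets[species]
        if target is None:
            absence = None
            if maps and species in maps and flank5 and flank3:
                absence = call_absence(maps[species], target_gene,
                                       flank5, flank3)
                calls.append(absence)
            report = classify_status([], 0, ref_model.n_exons,
                                     sequence_found=False, absence=absence,
                                     species=species)
        else:
            logger.info("scanning %s", species)
            report, _ = scan_gene(ref_genome, ref_model, target, species,
                                  flank=config.flank,
                                  window_margin=config.window_margin)
        reports.append(report)
    matrix, summary = tabulate_disruptions(reports)
    return RunReport(
        reports=reports, disruption_matrix=matrix, status_summary=summary,
        absence_calls=calls,
        provenance=_provenance(config))


def replay_disruption_table(df: pd.DataFrame | None = None,
                            exons_total: int = 19
                            ) -> list[GeneStatusReport]:
    """Reconstruct per-species status reports from a published disrupted-
    exon table (one event per listed exon per category)."""
    if df is None:
        df = load_disruption_table()
    reports = []
    for row in df.itertuples():
        events = [
            DisruptionEvent(species=row.species, exon_index=e,
                            category=DisruptionCategory.FRAMESHIFT)
            for e in row.frameshift
        ] + [
            DisruptionEvent(species=row.species, exon_index=e,
                            category=DisruptionCategory.SPLICE_DONOR)
            for e in row.splice
        ]
        reports.append(classify_status(events, exons_total, exons_total,
                                       species=row.species))
    return reports


def run_parsimony(
    config: PipelineConfig,
    tree=None,
    states: dict[str, TipState] | None = None,
) -> EventPlacement:
    """Dollo parsimony on a species tree; defaults to the packaged
    consensus tree and the dual-mutation tip states."""
    if tree is None:
        tree = load_species_tree()
    if states is None:
        states = loss_tip_states()
    return dollo_min_events(tree, states)


def run_ratetests(
    config: PipelineConfig,
    aln: ProteinAlignment | None = None,
    triples: list[tuple[str, str, str]] | None = None,
) -> list[RateTestResult]:
    """Relative-rate tests.

    With an alignment, counts unique substitutions per triple and tests
    them; without one, replays the packaged published count table through
    the chi-square test.
    """
    if aln is not None:
        if not triples:
            raise ValueError("triples required when an alignment is given")
        return [relative_rate_test(aln, a, b, o) for a, b, o in triples]
    results = []
    for row in load_rate_table().itertuples():
        results.append(tajima_chi2(int(row.n_a), int(row.n_b),
                                   lineage_a=row.lineage_a,
                                   lineage_b=row.lineage_b,
                                   outgroup=row.outgroup))
    return results


def _provenance(config: PipelineConfig) -> dict:
    return {
        "package": "genelosskit",
        "version": __version__,
        "schema_version": REPORT_SCHEMA_VERSION,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }


def rate_results_frame(results: list[RateTestResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "lineage_a": r.lineage_a, "lineage_b": r.lineage_b,
            "outgroup": r.outgroup, "n_a": r.n_a, "n_b": r.n_b,
            "chi_square": round(r.chi_square, 2),
            "p_value": round(r.p_value, 4),
        } for r in results],
        columns=["lineage_a", "lineage_b", "outgroup", "n_a", "n_b",
                 "chi_square", "p_value"])


def write_report(report: RunReport, outdir: str | Path) -> dict[str, Path]:
    """Emit TSV + JSON artifacts; identical inputs give identical bytes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    matrix_path = outdir / "disruption_matrix.tsv"
    report.disruption_matrix.to_csv(matrix_path, sep="\t", index=False)
    paths["disruption_matrix"] = matrix_path

    status_path = outdir / "status_table.tsv"
    pd.DataFrame(
        [{"species": r.species, "status": r.status.value,
          "n_disruptions": r.n_disruptions, "exons_found": r.exons_found,
          "exons_total": r.exons_total} for r in report.reports],
        columns=["species", "status", "n_disruptions", "exons_found",
                 "exons_total"]).to_csv(status_path, sep="\t", index=False)
    paths["status_table"] = status_path

    if report.rate_results:
        rates_path = outdir / "rate_tests.tsv"
        rate_results_frame(report.rate_results).to_csv(
            rates_path, sep="\t", index=False)
        paths["rate_tests"] = rates_path

    payload = {
        "provenance": report.provenance,
        "status_summary": report.status_summary,
        "n_loss_events": (report.placement.n_events
                          if report.placement else None),
        "species": [
            {
                "species": r.species,
                "status": r.status.value,
                "n_disruptions": r.n_disruptions,
                "exons_found": r.exons_found,
                "exons_total": r.exons_total,
                "events": [
                    {"exon": e.exon_index, "category": e.category.value,
                     "detail": e.detail} for e in r.events
                ],
            }
            for r in report.reports
        ],
        "absence_calls": [
            {"species": c.species, "target": c.target,
             "status": c.status.value, "evidence": c.evidence}
            for c in report.absence_calls
        ],
    }
    json_path = outdir / "report.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True)
                         + "\n")
    paths["report_json"] = json_path
    return paths
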