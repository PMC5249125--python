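"""Pipeline orchestration and publication-shaped report tables.

``run_audit`` executes the full audit in a fixed stage order:

    QC/exclusion -> distances -> NJ + bootstrap -> OTUs -> misidentification
    calls -> relabelling -> summaries/cohesion on corrected labels ->
    sub-cluster splits -> OTU review & grades -> per-species networks

Misidentified specimens keep their original field label in an audit
column; all downstream tables use the corrected labels.  Internal values
are kept at full precision; percent formatting (half-up, two decimals)
happens only in the report layer.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .audit import (
    GradeAssignment,
    GradingError,
    MisidentificationCall,
    ReferenceMatch,
    ReviewedOtu,
    apply_relabelling,
    assign_grade,
    flag_misidentifications,
    misid_report,
    review_otu,
    sub_cluster_split,
)
from .cluster import (
    DEFAULT_RSL_THRESHOLD,
    OtuCluster,
    TreeWithSupport,
    bootstrap_supports,
    discordance_report,
    rsl_cluster,
    species_cohesion,
)
from .distance import (
    DistanceMatrix,
    SpeciesDistanceSummary,
    distance_matrix,
    gap_scatter,
    species_summaries,
)
from .haplonet import (
    HaplotypeNetwork,
    collapse_haplotypes,
    network_from_tree,
    parsimony_tree,
    private_haplotypes,
)
from .io import BarcodeLibrary, QcReport, composition_summary, screen_stop_codons

log = logging.getLogger("barcodeaudit")


def round_percent(fraction: Optional[float], decimals: int = 2) -> Optional[float]:
    """fraction -> percent, rounded half-up (report layer only)."""
    if fraction is None:
        return None
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(fraction * 100)).quantize(q, rounding=ROUND_HALF_UP))


def _fmt(fraction: Optional[float]) -> str:
    p = round_percent(fraction)
    return "N/A" if p is None else f"{p:.2f}"


@dataclass
class AuditRunConfig:
    fasta: Optional[str] = None
    meta: Optional[str] = None
    reference: Optional[str] = None
    out_dir: Optional[str] = None
    genetic_code: str = "vertebrate-mito"
    frame: Optional[int] = None  # None = auto-detect
    nn_semantics: str = "min"
    cluster_threshold: float = DEFAULT_RSL_THRESHOLD
    refine: bool = True
    bootstrap_reps: int = 1000
    seed: int = 0
    minority_k: int = 2
    min_split_support: float = 95.0
    make_plots: bool = False
    log_level: str = "INFO"


@dataclass
class AuditReport:
    config: AuditRunConfig
    qc: QcReport
    composition: dict
    matrix: DistanceMatrix
    tree: TreeWithSupport
    otus: list[OtuCluster]
    otu_frame: pd.DataFrame
    misid_calls: list[MisidentificationCall]
    misid_table: pd.DataFrame
    corrected_labels: dict[str, str]
    original_labels: dict[str, str]
    summaries: list[SpeciesDistanceSummary]
    cohesion: dict
    splits: list
    reviewed: list[ReviewedOtu]
    grades: list[GradeAssignment]
    ungraded: list[tuple[str, str]]
    networks: dict[str, HaplotypeNetwork]
    privacy: dict[str, dict]

    @property
    def misid_percent(self) -> float:
        return 100.0 * len(self.misid_calls) / self.qc.n_passed


# ---------------------------------------------------------------------------
# report tables


def summarise_grades(grades: list[GradeAssignment]) -> pd.DataFrame:
    """Per-grade counts and percentages over the graded taxa."""
    counts: dict[str, int] = {}
    for g in grades:
        counts[g.grade] = counts.get(g.grade, 0) + 1
    n = sum(counts.values())
    rows = [
        (grade, c, round_percent(c / n) if n else 0.0)
        for grade, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["grade", "count", "percent"])


def summary_table(summaries: list[SpeciesDistanceSummary]) -> pd.DataFrame:
    """Barcoding-gap table (percent, 2 decimals, N/A for undefined) with an
    Average row holding the unweighted mean of the defined values per
    column."""
    rows = []
    for s in sorted(summaries, key=lambda x: x.species):
        rows.append(
            (
                s.species,
                _fmt(s.mean_intra),
                _fmt(s.max_intra),
                s.nn_species or "N/A",
                _fmt(s.nn_distance),
            )
        )

    def col_mean(values: list[Optional[float]]) -> Optional[float]:
        vals = [v for v in values if v is not None]
        return sum(vals) / len(vals) if vals else None

    rows.append(
        (
            "Average",
            _fmt(col_mean([s.mean_intra for s in summaries])),
            _fmt(col_mean([s.max_intra for s in summaries])),
            "",
            _fmt(col_mean([s.nn_distance for s in summaries])),
        )
    )
    return pd.DataFrame(
        rows,
        columns=["species", "mean_intra", "max_intra", "nn_species", "nn_distance"],
    )


def grades_table(report: AuditReport) -> pd.DataFrame:
    rows = [(g.species, g.grade, g.rationale) for g in report.grades]
    rows += [(sp, "", f"ungraded: {why}") for sp, why in report.ungraded]
    return pd.DataFrame(rows, columns=["species", "grade", "rationale"])


def read_reference_table(path) -> dict[str, ReferenceMatch]:
    """Offline reference-match table (stands in for a live database query)."""
    df = pd.read_csv(path, sep="\t")
    out = {}
    for _, r in df.iterrows():
        div = r.get("matched_max_divergence")
        out[r["species"]] = ReferenceMatch(
            species=r["species"],
            match_found=bool(r["match_found"]),
            matched_species=r.get("matched_species") or None,
            matched_max_divergence=None if pd.isna(div) else float(div),
            matched_monophyletic=bool(r.get("matched_monophyletic", True)),
        )
    return out


# ---------------------------------------------------------------------------
# the pipeline


def run_audit(
    library: BarcodeLibrary,
    config: Optional[AuditRunConfig] = None,
    reference: Optional[dict[str, ReferenceMatch]] = None,
) -> AuditReport:
    """Run the complete audit on an in-memory library."""
    cfg = config or AuditRunConfig()
    log.info("audit started: %d records, seed=%d", len(library), cfg.seed)

    # stage 1: QC
    passed, qc = screen_stop_codons(library, code=cfg.genetic_code, frame=cfg.frame)
    composition = composition_summary(passed)
    qc.composition = composition
    log.info("QC: %d/%d passed (frame %s)", qc.n_passed, qc.n_input, qc.frame_used)

    # stage 2: distances
    m = distance_matrix(passed)

    # stage 3: NJ + bootstrap
    tree = bootstrap_supports(passed, n_reps=cfg.bootstrap_reps, seed=cfg.seed)

    # stage 4: OTUs
    otus = rsl_cluster(m, threshold=cfg.cluster_threshold, refine=cfg.refine)

    # stage 5: misidentification calls on the original labels
    original_labels = passed.labels()
    divisions = passed.divisions()
    calls = flag_misidentifications(otus, m, original_labels, divisions)
    misid_table = misid_report(calls, original_labels, divisions)
    log.info("misidentifications: %d calls", len(calls))

    # stage 6: relabel and recompute label-dependent structures
    corrected = dict(original_labels)
    corrected.update(apply_relabelling(calls))
    cohesion = species_cohesion(tree, corrected)

    # stage 7: sub-cluster splits for non-cohesive species
    splits = []
    for sp, info in sorted(cohesion.items()):
        if not info["cohesive"]:
            split = sub_cluster_split(
                sp, tree, corrected, m, min_support=cfg.min_split_support
            )
            if split is not None:
                splits.append(split)
                corrected.update(split.provisional_labels)
    if splits:
        cohesion = species_cohesion(tree, corrected)
    summaries = species_summaries(m, corrected, nn_semantics=cfg.nn_semantics)

    # stage 8: OTU review and grades
    otus, otu_frame = discordance_report(otus, corrected)
    reviewed = [review_otu(o, corrected, minority_k=cfg.minority_k) for o in otus]
    grades, ungraded = [], []
    for s in summaries:
        try:
            grades.append(
                assign_grade(
                    s.species,
                    s,
                    cohesion.get(s.species, {}),
                    (reference or {}).get(s.species),
                )
            )
        except GradingError as e:
            ungraded.append((s.species, str(e)))
            log.warning("ungraded: %s", e)

    # stage 9: per-species haplotype networks
    networks, privacy = {}, {}
    by_species: dict[str, list] = {}
    for rec in passed:
        by_species.setdefault(corrected[rec.specimen_id], []).append(rec)
    for sp, recs in sorted(by_species.items()):
        try:
            table = collapse_haplotypes(recs, species=sp)
        except ValueError as e:
            log.warning("network skipped for %s: %s", sp, e)
            continue
        ptree = parsimony_tree(table, seed=cfg.seed)
        net = network_from_tree(ptree, table)
        networks[sp] = net
        privacy[sp] = private_haplotypes(net)

    return AuditReport(
        config=cfg,
        qc=qc,
        composition=composition,
        matrix=m,
        tree=tree,
        otus=otus,
        otu_frame=otu_frame,
        misid_calls=calls,
        misid_table=misid_table,
        corrected_labels=corrected,
        original_labels=original_labels,
        summaries=summaries,
        cohesion=cohesion,
        splits=splits,
        reviewed=reviewed,
        grades=grades,
        ungraded=ungraded,
        networks=networks,
        privacy=privacy,
    )


def write_report(report: AuditReport, out_dir) -> None:
    """Write every report artefact (TSV/JSON/Newick/GraphML) to a directory."""
    import networkx as nx

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg = report.config
    meta = {
        "version": __version__,
        "seed": cfg.seed,
        "bootstrap_reps": cfg.bootstrap_reps,
        "cluster_threshold": cfg.cluster_threshold,
        "nn_semantics": cfg.nn_semantics,
        "note": "OTU refinement stage approximates the BIN system's "
        "unpublished cluster re-evaluation",
    }
    (out / "run.json").write_text(json.dumps(meta, indent=2))
    (out / "qc.json").write_text(report.qc.to_json())
    report.matrix.to_long_frame().to_csv(out / "distances.tsv", sep="\t", index=False)
    report.matrix.to_phylip(out / "distances.phy")
    (out / "tree.nwk").write_text(report.tree.to_newick() + "\n")
    report.otu_frame.to_csv(out / "otus.tsv", sep="\t", index=False)
    report.misid_table.to_csv(out / "misid.tsv", sep="\t", index=False)
    summary_table(report.summaries).to_csv(out / "summary.tsv", sep="\t", index=False)
    gap_scatter(report.summaries).to_csv(
        out / "gap_scatter.tsv", sep="\t", index=False
    )
    reviewed_rows = [
        (
            r.otu.otu_id,
            r.otu.status,
            r.post_review_status,
            ";".join(r.reasons),
            r.canonical_species or "",
            ";".join(r.suspected_misids),
        )
        for r in report.reviewed
    ]
    pd.DataFrame(
        reviewed_rows,
        columns=[
            "otu_id",
            "status",
            "after_review",
            "reasons",
            "canonical_species",
            "suspected_misids",
        ],
    ).to_csv(out / "reviewed_otus.tsv", sep="\t", index=False)
    grades_table(report).to_csv(out / "grades.tsv", sep="\t", index=False)
    summarise_grades(report.grades).to_csv(
        out / "grade_summary.tsv", sep="\t", index=False
    )
    netdir = out / "networks"
    netdir.mkdir(exist_ok=True)
    for sp, net in report.networks.items():
        stem = sp.replace(" ", "_").replace("/", "-")
        net.to_edge_frame().to_csv(netdir / f"{stem}.edges.tsv", sep="\t", index=False)
        net.to_node_frame().to_csv(netdir / f"{stem}.nodes.tsv", sep="\t", index=False)
        g = nx.Graph()
        for n, d in net.graph.nodes(data=True):
            g.add_node(
                n,
                frequency=d["frequency"],
                is_median=d["is_median"],
                regions=";".join(f"{k}:{v}" for k, v in sorted(d["region_counts"].items())),
            )
        for u, v, d in net.graph.edges(data=True):
            g.add_edge(u, v, substitutions=d["substitutions"])
        nx.write_graphml(g, netdir / f"{stem}.graphml")
    if cfg.make_plots:
        from .distance import plot_gap_scatter

        plot_gap_scatter(report.summaries, out / "gap_scatter.png")
    log.info("report written to %s", out)
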