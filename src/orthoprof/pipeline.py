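"""End-to-end pipeline: simulate/ingest -> search -> classify -> curate ->
profile -> tree -> enrich -> report.

`PipelineConfig` carries every threshold with the analysis defaults:
E-value cutoff 1e-10, minimum coverage 20%, enrichment p-cutoff 1e-4 with
a 3-protein retention floor, 500 bootstrap replicates flagged at 70%
support. Runs are deterministic under a fixed seed and emit a manifest
recording the configuration, per-stage row counts and output hashes.
"""

from __future__ import annotations

import json
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .enrichment import (
    AnnotationSet, assign_process_classes, enrich, enrichment_table,
    overlap_report,
)
from .io import (
    Proteome, file_sha256, read_config, read_fasta, read_hit_table,
    read_tsv, write_hit_table, write_tsv,
)
from .orthology import (
    assignments_table, best_hits, category_counts, category_label,
    classify_proteins, curate_coverage, enumerate_categories,
    pair_specific_proteins, reciprocal_best_hits,
)
from .phylo import MultipleAlignment, bootstrap_support, neighbor_joining, write_newick
from .profiles import build_presence_matrix, profile_distance_matrix
from .seqsim import ScoringScheme, search_all
from .synthetic import (
    SyntheticConfig, generate_annotations, generate_dataset,
    standard_fixture_config,
)


@dataclass
class PipelineConfig:
    """Pipeline thresholds and inputs. Defaults are the analysis values:
    E <= 1e-10, coverage >= 20%, enrichment p < 1e-4 over >= 3 proteins,
    500 bootstrap replicates, 70% support flag."""

    organisms: tuple[str, ...] = ()
    proteome_paths: dict[str, str] = field(default_factory=dict)
    hit_table_path: str | None = None
    annotation_path: str | None = None
    term_table_path: str | None = None
    alignment_path: str | None = None
    alignment_slice: tuple[int, int] | None = None
    matrix_name: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    e_cutoff: float = 1e-10
    min_coverage: float = 0.20
    p_cutoff: float = 1e-4
    min_proteins: int = 3
    bootstrap_reps: int = 500
    support_threshold: float = 0.70
    distance_correction: str = "none"
    prefilter: bool = True
    curation_scope: str = "pairs"
    seed: int = 0
    outdir: str = "orthoprof_out"

    def __post_init__(self) -> None:
        if self.e_cutoff <= 0:
            raise ValueError("e_cutoff must be positive")
        if not 0 <= self.min_coverage <= 1:
            raise ValueError("min_coverage must be in [0, 1]")
        if not 0 < self.p_cutoff <= 1:
            raise ValueError("p_cutoff must be in (0, 1]")
        if self.min_proteins < 0:
            raise ValueError("min_proteins must be non-negative")
        if self.bootstrap_reps < 1:
            raise ValueError("bootstrap_reps must be >= 1")
        if not 0 <= self.support_threshold <= 1:
            raise ValueError("support_threshold must be in [0, 1]")

    @property
    def scheme(self) -> ScoringScheme:
        return ScoringScheme(
            matrix_name=self.matrix_name,
            gap_open=self.gap_open,
            gap_extend=self.gap_extend,
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        data = read_config(path)
        if "organisms" in data:
            data["organisms"] = tuple(data["organisms"])
        if data.get("alignment_slice"):
            data["alignment_slice"] = tuple(data["alignment_slice"])
        return cls(**data)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["organisms"] = list(self.organisms)
        return d


@dataclass
class PipelineResult:
    config: PipelineConfig
    proteomes: dict[str, Proteome]
    truth: pd.DataFrame | None
    hits: list
    assignments: list
    rejections: pd.DataFrame
    counts: pd.DataFrame
    presence: pd.DataFrame
    profile_tree_newick: str
    domain_tree_newick: str | None
    bootstrap_table: pd.DataFrame | None
    sample_category: frozenset[str] | None
    enrichment: pd.DataFrame
    overlap: object | None
    manifest: dict


def _log(stage: str, message: str) -> None:
    print(f"[orthoprof] {stage}: {message}", file=sys.stderr)


def run_pipeline(config: PipelineConfig, simulate: SyntheticConfig | bool = False) -> PipelineResult:
    """Run all stages on ingested or simulated proteomes.

    ``simulate=True`` runs on the standard four-organism synthetic fixture
    (with planted annotations); a SyntheticConfig runs on that dataset.
    Otherwise proteome paths from the config are ingested, and a
    precomputed hit table is honoured when provided.
    """
    t0 = time.time()
    stage_counts: dict[str, int] = {}
    truth = None
    annotations_df = terms_df = None

    # --- simulate / ingest
    if simulate is True:
        simulate = standard_fixture_config(seed=config.seed)
    if isinstance(simulate, SyntheticConfig):
        dataset = generate_dataset(simulate)
        proteomes = dataset.proteomes
        truth = dataset.truth
        organisms = tuple(simulate.organisms)
        _log("simulate", f"{sum(len(p) for p in proteomes.values())} proteins across {len(proteomes)} organisms")
    else:
        if not config.proteome_paths:
            raise ValueError("no proteome paths configured and simulation not requested")
        for org, path in config.proteome_paths.items():
            if not Path(path).exists():
                raise FileNotFoundError(f"proteome file for {org!r} not found: {path}")
        proteomes = {
            org: read_fasta(path, organism=org)
            for org, path in config.proteome_paths.items()
        }
        organisms = tuple(config.organisms) if config.organisms else tuple(proteomes)
        _log("ingest", f"{sum(len(p) for p in proteomes.values())} proteins across {len(proteomes)} organisms")
    org_of = {pid: org for org, prot in proteomes.items() for pid, _ in prot}
    stage_counts["proteins"] = len(org_of)

    # --- search
    if config.hit_table_path:
        df = read_hit_table(config.hit_table_path)
        hits = list(df.itertuples(index=False))
        hits = [_ExternalHit(h) for h in hits]
        _log("search", f"loaded {len(hits)} external hit rows")
    else:
        hits = search_all(
            list(proteomes.values()), config.scheme,
            e_cutoff=config.e_cutoff, prefilter=config.prefilter,
        )
        _log("search", f"{len(hits)} hits at E <= {config.e_cutoff:g}")
    stage_counts["hits"] = len(hits)

    # --- classify
    best = best_hits(hits, config.e_cutoff, org_of)
    pairs = reciprocal_best_hits(best, org_of)
    assignments = classify_proteins(pairs, org_of)
    stage_counts["rbh_pairs"] = len(pairs)
    stage_counts["assignments"] = len(assignments)
    _log("classify", f"{len(pairs)} RBH pairs, {len(assignments)} assignments")

    # --- curate
    assignments, rejections = curate_coverage(
        assignments, best, min_cov=config.min_coverage,
        scope=config.curation_scope, organisms=organisms,
    )
    stage_counts["rejected"] = len(rejections)
    _log("curate", f"{len(rejections)} assignments rejected at coverage < {config.min_coverage:.0%}")
    counts = category_counts(assignments, organisms)

    # --- profile
    if truth is not None:
        fam_table = truth[truth["family"] != "decoy"][["organism", "protein_id", "family"]]
    else:
        fam_table = pd.DataFrame([
            {"organism": a.organism, "protein_id": a.protein_id,
             "family": category_label(a.category)}
            for a in assignments
        ])
    presence = build_presence_matrix(fam_table, organisms=organisms)
    profile_dm = profile_distance_matrix(presence)
    profile_tree = write_newick(neighbor_joining(profile_dm))
    stage_counts["families"] = len(presence)
    _log("profile", f"{len(presence)} families profiled")

    # --- tree (domain alignment, when provided)
    domain_tree = None
    boot_table = None
    if config.alignment_path:
        aln = MultipleAlignment.read_fasta(config.alignment_path)
        boot = bootstrap_support(
            aln, correction=config.distance_correction,
            n_reps=config.bootstrap_reps, seed=config.seed,
            col_slice=config.alignment_slice,
            flag_threshold=config.support_threshold,
        )
        domain_tree = write_newick(boot.tree)
        boot_table = boot.table
        _log("tree", f"{boot.n_success}/{boot.n_reps} bootstrap replicates succeeded")

    # --- enrich
    sample_category = None
    enr_df = enrichment_table([])
    overlap = None
    if isinstance(simulate, SyntheticConfig):
        rng = np.random.default_rng(np.random.SeedSequence([simulate.seed, 3]))
        pair = frozenset(sorted(organisms)[:2])
        sample_ids = pair_specific_proteins(assignments, pair, organisms)
        class_map = {
            "T0001": "trafficking", "T0002": "cytokinesis",
            "T0003": "metabolism", "T0004": "other",
        }
        enriched = {"T0001": sample_ids}
        # fully penetrant planted term: every sample protein annotated
        annotations_df, terms_df = generate_annotations(
            sorted(org_of), class_map, enriched, rng, enrichment_strength=1.0,
        )
        sample_category = pair
    elif config.annotation_path:
        annotations_df = read_tsv(config.annotation_path)
        terms_df = read_tsv(config.term_table_path) if config.term_table_path else None
        pair_cats = [c for c in enumerate_categories(organisms) if len(c) == 2]
        sizes = {c: len(pair_specific_proteins(assignments, c)) for c in pair_cats}
        sample_category = max(sizes, key=lambda c: (sizes[c], category_label(c)))

    if annotations_df is not None and sample_category is not None:
        ann = AnnotationSet.from_tables(annotations_df, terms_df)
        sample_ids = pair_specific_proteins(assignments, sample_category, organisms)
        background = sorted(org_of)
        results = enrich(
            sample_ids, ann, background,
            p_cutoff=config.p_cutoff, min_proteins=config.min_proteins,
        )
        enr_df = enrichment_table(results)
        retained = [r.term_id for r in results if r.retained]
        classes = assign_process_classes(sample_ids, ann, retained)
        overlap = overlap_report(classes)
        stage_counts["enriched_terms"] = len(retained)
        _log("enrich", f"sample {category_label(sample_category)}: "
                       f"{len(sample_ids)} proteins, {len(retained)} retained terms")

    manifest = {
        "package": "orthoprof",
        "version": __version__,
        "config": config.to_dict(),
        "seed": config.seed,
        "stage_counts": stage_counts,
        "elapsed_s": round(time.time() - t0, 3),
    }
    return PipelineResult(
        config=config, proteomes=proteomes, truth=truth, hits=hits,
        assignments=assignments, rejections=rejections, counts=counts,
        presence=presence, profile_tree_newick=profile_tree,
        domain_tree_newick=domain_tree, bootstrap_table=boot_table,
        sample_category=sample_category, enrichment=enr_df,
        overlap=overlap, manifest=manifest,
    )


class _ExternalHit:
    """Adapter giving attribute access over an external outfmt-6 row."""

    __slots__ = ("query", "subject", "evalue", "bits", "qstart", "qend",
                 "sstart", "send", "qlen", "slen")

    def __init__(self, row) -> None:
        self.query = row.query
        self.subject = row.subject
        self.evalue = float(row.evalue)
        self.bits = float(row.bitscore)
        self.qstart = int(row.qstart)
        self.qend = int(row.qend)
        self.sstart = int(row.sstart)
        self.send = int(row.send)
        self.qlen = int(getattr(row, "qlen", 0)) or None
        self.slen = int(getattr(row, "slen", 0)) or None

    @property
    def query_coverage(self) -> float:
        if not self.qlen or self.qend < self.qstart:
            return 0.0
        return (self.qend - self.qstart + 1) / self.qlen


def write_results(result: PipelineResult, outdir: str | Path | None = None) -> dict[str, Path]:
    """Write every stage output plus the manifest; returns the file map."""
    outdir = Path(outdir if outdir is not None else result.config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    native = bool(result.hits) and hasattr(result.hits[0], "to_outfmt6_row")
    if native:
        write_hit_table(result.hits, outdir / "hits.tsv")
        paths["hits"] = outdir / "hits.tsv"
    write_tsv(assignments_table(result.assignments), outdir / "assignments.tsv")
    paths["assignments"] = outdir / "assignments.tsv"
    write_tsv(result.rejections, outdir / "rejections.tsv")
    paths["rejections"] = outdir / "rejections.tsv"
    write_tsv(result.counts, outdir / "category_counts.tsv", index=True)
    paths["category_counts"] = outdir / "category_counts.tsv"
    write_tsv(result.presence, outdir / "presence_matrix.tsv", index=True)
    paths["presence_matrix"] = outdir / "presence_matrix.tsv"
    (outdir / "profile_tree.nwk").write_text(result.profile_tree_newick + "\n")
    paths["profile_tree"] = outdir / "profile_tree.nwk"
    if result.domain_tree_newick:
        (outdir / "domain_tree.nwk").write_text(result.domain_tree_newick + "\n")
        paths["domain_tree"] = outdir / "domain_tree.nwk"
    if result.bootstrap_table is not None:
        write_tsv(result.bootstrap_table, outdir / "bootstrap.tsv")
        paths["bootstrap"] = outdir / "bootstrap.tsv"
    write_tsv(result.enrichment, outdir / "enrichment.tsv")
    paths["enrichment"] = outdir / "enrichment.tsv"
    if result.overlap is not None:
        write_tsv(result.overlap.to_frame(), outdir / "overlap.tsv")
        paths["overlap"] = outdir / "overlap.tsv"
    (outdir / "report.txt").write_text(write_report(result))
    paths["report"] = outdir / "report.txt"

    manifest = dict(result.manifest)
    manifest["outputs"] = {
        name: {"path": str(p), "sha256": file_sha256(p)} for name, p in paths.items()
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = outdir / "manifest.json"
    return paths


def write_report(result: PipelineResult) -> str:
    """Human-readable summary: all categories with counts, pair-specific
    set sizes, retained terms per class, and the overlap breakdown."""
    organisms = list(result.counts.columns)
    lines = []
    lines.append("orthoprof analysis report")
    lines.append("=" * 40)
    lines.append("")
    lines.append(f"organisms ({len(organisms)}): {', '.join(organisms)}")
    lines.append(f"proteins assigned: {len(result.assignments)}")
    lines.append(f"assignments rejected by coverage curation: {len(result.rejections)}")
    lines.append("")
    lines.append(f"species-presence categories ({len(result.counts)}):")
    for cat, row in result.counts.iterrows():
        lines.append(f"  {cat:<40s} {int(row.sum()):6d}")
    lines.append("")
    lines.append("pair-specific protein sets:")
    for cat in enumerate_categories(organisms):
        if len(cat) != 2:
            continue
        size = len(pair_specific_proteins(result.assignments, cat))
        lines.append(f"  {category_label(cat):<40s} {size:6d}")
    lines.append("")
    if len(result.enrichment):
        retained = result.enrichment[result.enrichment["retained"]]
        lines.append(f"retained enrichment terms ({len(retained)}):")
        for _, r in retained.iterrows():
            lines.append(f"  {r['term_id']:<12s} {r['process_class']:<14s} "
                         f"k={r['k']:<4d} p={r['p']:.3g}")
        lines.append("")
    if result.overlap is not None:
        o = result.overlap
        lines.append("process-class overlap:")
        for c, v in o.class_totals.items():
            lines.append(f"  total {c:<22s} {v:6d}")
        for (a, b), v in o.pair_exclusive.items():
            lines.append(f"  {a}+{b} only{'':<{max(0, 22 - len(a) - len(b))}s} {v:6d}")
        lines.append(f"  all three processes        {o.triple:6d}")
        lines.append(f"  multi-class total          {o.multi_total:6d}")
        lines.append(f"  other function             {o.other:6d}")
        lines.append(f"  unknown function           {o.unknown:6d}")
        lines.append("")
    return "\n".join(lines) + "\n"
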