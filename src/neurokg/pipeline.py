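"""End-to-end orchestration: sources → harmonized tables → knowledge graph →
validation → cohort selection → defined-class materialization → statistics.

Every run writes a self-contained artifact bundle under one output
directory: the canonical graph serializations, the harmonization and
pattern-conformance reports, the cohort CSV/JSON, the statistics report, a
log, and a manifest with content digests. Graph output uses canonical
N-Triples (deterministic blank-node naming, sorted lines), so a rerun with
the same seed and configuration is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .instantiate import build_instance_graph, validate_patterns
from .mapping import (
    PseudonymPolicy,
    load_mapping_config,
    load_source_table,
    harmonize,
)
from .ontology import build_app_ontology, canonical_nt, extract_module, merge_graphs
from .simulate import generate_cohorts, load_cohort_config, table1_config, write_source_files
from .store import (
    DefinedClassRule,
    cohort_counts_by_source,
    materialize_defined_class,
    select_cohort_by_score,
)
from .stats import extract_analysis_frame, run_group_comparison
from .vocab import APP_TERMS, TERMS, core_registry, load_core_ontology

__all__ = ["PipelineConfig", "PipelineError", "PipelineResult", "run_pipeline"]

logger = logging.getLogger("neurokg")

EXIT_OK = 0
EXIT_VIOLATIONS = 2
EXIT_CONFIG = 3


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class SourceSpec:
    name: str
    path: str
    subject_id_column: str


@dataclass
class PipelineConfig:
    """Everything one run needs; all referenced files must exist at run start."""

    sources: list[SourceSpec]
    out_dir: str
    mapping_config: str | None = None  # None → bundled default mapping
    ontology_files: list[str] = field(default_factory=list)
    salt: str = "neurokg-demo-salt"
    comparator: str = "lt"
    threshold: float = 26
    volume: str = "bilateral"
    seed: int = 0
    allow_violations: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open(encoding="utf-8") as handle:
            doc = yaml.safe_load(handle)
        sources = [SourceSpec(**s) for s in doc.pop("sources")]
        return cls(sources=sources, **doc)

    def validate(self) -> None:
        missing = [
            spec.path for spec in self.sources if not Path(spec.path).exists()
        ]
        if self.mapping_config and not Path(self.mapping_config).exists():
            missing.append(self.mapping_config)
        missing += [p for p in self.ontology_files if not Path(p).exists()]
        if missing:
            raise PipelineError(f"config: missing input files: {missing}")
        try:
            Path(self.out_dir).mkdir(parents=True, exist_ok=True)
        except OSError as exc:
            raise PipelineError(f"config: cannot create output dir: {exc}") from exc


@dataclass
class PipelineResult:
    out_dir: Path
    graph: object
    pattern_report: object
    harmonization_report: object
    cohort: object
    cohort_counts: dict[str, int]
    comparison: object | None
    artifacts: dict[str, Path]
    exit_code: int


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _bundled_mapping() -> list:
    import importlib.resources
    ref = importlib.resources.files("neurokg.data").joinpath("default_mapping.yaml")
    import tempfile

    with tempfile.NamedTemporaryFile(
        "w", suffix=".yaml", delete=False, encoding="utf-8"
    ) as handle:
        handle.write(ref.read_text(encoding="utf-8"))
        tmp = handle.name
    try:
        return load_mapping_config(tmp)
    finally:
        Path(tmp).unlink(missing_ok=True)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute every stage in order and write the artifact bundle.

    Stage order: load → harmonize → instantiate → merge ontology → validate
    → cohort select → materialize defined class → statistics. Validation
    violations set exit code 2 unless ``allow_violations``; stage failures
    raise :class:`PipelineError` naming the stage.
    """
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    artifacts: dict[str, Path] = {}

    log_path = out_dir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w", encoding="utf-8")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(config.log_level.upper())
    try:
        return _run_stages(config, out_dir, artifacts, log_path)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _stage(name: str):
    logger.info("stage: %s", name)


def _run_stages(config, out_dir, artifacts, log_path) -> PipelineResult:
    _stage("load")
    try:
        tables = [
            load_source_table(s.path, s.name, s.subject_id_column)
            for s in config.sources
        ]
    except Exception as exc:
        raise PipelineError(f"load: {exc}") from exc

    _stage("harmonize")
    try:
        mappings = (
            load_mapping_config(config.mapping_config)
            if config.mapping_config
            else _bundled_mapping()
        )
        harmonized, report = harmonize(tables, mappings)
    except Exception as exc:
        raise PipelineError(f"harmonize: {exc}") from exc
    report_path = out_dir / "harmonization_report.json"
    report_path.write_text(
        json.dumps(
            {
                "mapped": report.mapped,
                "unmapped": report.unmapped,
                "exceptions": report.exceptions,
                "skipped_missing": report.skipped_missing,
            },
            indent=2,
        ),
        encoding="utf-8",
    )
    artifacts["harmonization_report"] = report_path

    _stage("instantiate")
    try:
        policy = PseudonymPolicy(secret_salt=config.salt)
        ig, _ = build_instance_graph(harmonized, policy)
    except Exception as exc:
        raise PipelineError(f"instantiate: {exc}") from exc

    _stage("merge-ontology")
    try:
        ontology = merge_graphs(load_core_ontology(), build_app_ontology(core_registry()))
        for extra in config.ontology_files:
            ontology.parse(extra)
        from rdflib.namespace import RDF

        from .ontology import _is_builtin

        seeds = {o for o in ig.graph.objects(None, RDF.type)} | {
            p for p in ig.graph.predicates() if not _is_builtin(p)
        }
        module = extract_module(ontology, seeds)
        merged = merge_graphs(module.graph, ig.graph)
    except Exception as exc:
        raise PipelineError(f"merge-ontology: {exc}") from exc

    _stage("validate")
    pattern_report = validate_patterns(ig)
    pattern_path = out_dir / "pattern_report.json"
    pattern_path.write_text(
        json.dumps(
            {
                "violations": pattern_report.violations,
                "counts": pattern_report.counts,
                "conformant": pattern_report.ok,
            },
            indent=2,
        ),
        encoding="utf-8",
    )
    artifacts["pattern_report"] = pattern_path
    if not pattern_report.ok:
        logger.warning("pattern violations: %s", pattern_report.counts)

    _stage("store")
    graph_nt = out_dir / "graph.nt"
    graph_nt.write_text(canonical_nt(merged), encoding="utf-8")
    artifacts["graph_nt"] = graph_nt
    graph_ttl = out_dir / "graph.ttl"
    merged.serialize(destination=str(graph_ttl), format="turtle")
    artifacts["graph_ttl"] = graph_ttl

    _stage("cohort-select")
    moca = TERMS["Montreal cognitive assessment assay"]
    cohort = select_cohort_by_score(
        merged, moca, comparator=config.comparator, threshold=config.threshold
    )
    counts = cohort_counts_by_source(merged, cohort)
    cohort_csv = out_dir / "cohort.csv"
    cohort.to_csv(cohort_csv)
    artifacts["cohort_csv"] = cohort_csv
    cohort_json = out_dir / "cohort.json"
    cohort_json.write_text(cohort.to_sparql_json(), encoding="utf-8")
    artifacts["cohort_json"] = cohort_json
    logger.info("cohort rows: %d (%s)", len(cohort), counts)

    _stage("materialize")
    rule = DefinedClassRule(
        class_iri=APP_TERMS["study subject with mild cognitive impairment"],
        assay_class=moca,
        comparator=config.comparator,
        threshold=config.threshold,
    )
    inferred = materialize_defined_class(merged, rule)
    logger.info("materialized %d defined-class assertions", len(inferred))

    _stage("stats")
    comparison = None
    try:
        frame = extract_analysis_frame(merged)
        comparison = run_group_comparison(
            frame, threshold=config.threshold, volume=config.volume
        )
    except ValueError as exc:
        logger.warning("statistics skipped: %s", exc)
    if comparison is not None:
        stats_json = out_dir / "stats.json"
        stats_json.write_text(json.dumps(comparison.to_dict(), indent=2), encoding="utf-8")
        artifacts["stats_json"] = stats_json
        stats_txt = out_dir / "stats.txt"
        stats_txt.write_text(comparison.to_text() + "\n", encoding="utf-8")
        artifacts["stats_txt"] = stats_txt

    artifacts["log"] = log_path
    manifest = {
        name: {"path": str(path), "sha256": _digest(path)}
        for name, path in sorted(artifacts.items())
        if path.exists() and name != "log"
    }
    manifest_path = out_dir / "manifest.json"
    manifest_path.write_text(
        json.dumps(
            {"config": dataclasses.asdict(config), "artifacts": manifest}, indent=2
        ),
        encoding="utf-8",
    )
    artifacts["manifest"] = manifest_path

    exit_code = EXIT_OK
    if not pattern_report.ok and not config.allow_violations:
        exit_code = EXIT_VIOLATIONS
    return PipelineResult(
        out_dir=out_dir,
        graph=merged,
        pattern_report=pattern_report,
        harmonization_report=report,
        cohort=cohort,
        cohort_counts=counts,
        comparison=comparison,
        artifacts=artifacts,
        exit_code=exit_code,
    )


def simulate_and_run(
    preset: str = "table1",
    seed: int = 0,
    out_dir: str | Path = "neurokg-run",
    **overrides,
) -> PipelineResult:
    """Convenience: generate a synthetic preset cohort, then run the pipeline."""
    from .simulate import cohort_demo_config

    out_dir = Path(out_dir)
    if preset == "table1":
        cohort_config = table1_config(seed=seed)
    elif preset in ("cohort_demo", "cohort-demo"):
        cohort_demo = cohort_demo_config(seed=seed)
        cohort_config = cohort_demo
    else:
        cohort_config = load_cohort_config(preset, seed=seed)
    cohort = generate_cohorts(cohort_config)
    paths = write_source_files(cohort, out_dir / "sources")
    sources = [
        SourceSpec(
            name=table.source_name,
            path=str(paths[table.source_name]),
            subject_id_column=table.subject_id_column,
        )
        for table in cohort.tables
    ]
    config = PipelineConfig(
        sources=sources, out_dir=str(out_dir), seed=seed, **overrides
    )
    return run_pipeline(config)
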