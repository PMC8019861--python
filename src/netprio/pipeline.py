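"""End-to-end pipeline orchestration.

Runs synthetic generation (optional) → differential expression → QQPPI
extraction → centrality → consensus prioritization → drug mapping from
a single config, writing every stage table as TSV plus a JSON run
report. All randomness flows from the single config seed; outputs are
byte-deterministic for a fixed config and seed (fixed column orders,
fixed float formatting, no timestamps).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, centrality, drugs, expression, interactome, prioritize, qqppi
from . import synthetic as synth

logger = logging.getLogger(__name__)

DEFAULT_GROUPS = ("approved", "experimental", "investigational")


class PipelineError(RuntimeError):
    """A stage failed; carries the failing stage's name."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    outdir: str = "netprio_run"
    seed: int = 0
    # exactly one of (synthetic, expression inputs) must be set
    synthetic: synth.SyntheticStudyConfig | None = None
    expression_tsv: str | None = None
    groups_tsv: str | None = None
    mitab_files: list = field(default_factory=list)
    edge_tsv: str | None = None
    drug_table: str | None = None
    de_route: str = "anova"
    alpha: float = 0.05
    use_lcc: bool = True
    k: int = 30
    min_measures: int = 2
    allowed_groups: tuple = DEFAULT_GROUPS
    hub_extra_degree: int = 40

    def __post_init__(self) -> None:
        real = self.expression_tsv is not None
        if real == (self.synthetic is not None):
            raise ValueError(
                "exactly one of synthetic config or real expression inputs must be set"
            )
        if real and self.groups_tsv is None:
            raise ValueError("real expression input needs a groups_tsv")
        if real and not (self.mitab_files or self.edge_tsv):
            raise ValueError("real input mode needs an interactome file")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as handle:
            raw = yaml.safe_load(handle) or {}
        synthetic = raw.pop("synthetic", None)
        config = cls(
            **{k: v for k, v in raw.items() if k != "allowed_groups"},
            allowed_groups=tuple(raw.get("allowed_groups", DEFAULT_GROUPS)),
            synthetic=None if synthetic is None else synth.config_from_mapping(synthetic),
        )
        return config


@dataclass
class RunReport:
    seed: int
    parameters: dict
    n_genes_tested: int = 0
    n_degs: int = 0
    n_degs_up: int = 0
    n_degs_down: int = 0
    n_queries_mapped: int = 0
    qqppi_nodes: int = 0
    qqppi_edges: int = 0
    interactome_nodes: int = 0
    interactome_edges: int = 0
    lcc_size: int = 0
    consensus_size: int = 0
    n_targets_with_drugs: int = 0
    n_drugs_mapped: int = 0
    consensus_nodes: list = field(default_factory=list)
    version: str = __version__

    def validate(self) -> None:
        assert self.n_degs_up + self.n_degs_down == self.n_degs
        assert self.qqppi_edges <= self.interactome_edges
        assert self.lcc_size <= self.qqppi_nodes

    def to_json(self, path) -> None:
        payload = {k: v for k, v in self.__dict__.items()}
        with open(path, "w") as out:
            json.dump(payload, out, indent=2, sort_keys=True)
            out.write("\n")


def _stage(name):
    def decorator(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - re-raised with stage context
                raise PipelineError(name, str(exc)) from exc
        return wrapped
    return decorator


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute all stages; write stage TSVs and report.json under outdir.

    On stage failure, partial outputs are retained alongside a FAILED
    marker file naming the stage, and :class:`PipelineError` is raised.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report = RunReport(
        seed=config.seed,
        parameters={
            "de_route": config.de_route,
            "alpha": config.alpha,
            "use_lcc": config.use_lcc,
            "k": config.k,
            "min_measures": config.min_measures,
            "allowed_groups": sorted(config.allowed_groups),
            "mode": "synthetic" if config.synthetic else "real",
        },
    )
    try:
        _run_stages(config, outdir, report)
    except PipelineError as exc:
        (outdir / "FAILED").write_text(exc.stage + "\n")
        raise
    report.validate()
    report.to_json(outdir / "report.json")
    return report


def _run_stages(config: PipelineConfig, outdir: Path, report: RunReport) -> None:
    truth = None
    if config.synthetic is not None:
        synth_config = synth.SyntheticStudyConfig(
            **{**config.synthetic.__dict__, "seed": config.seed}
        )
        graph, matrix, drug_records, truth = _stage("synthetic")(synth.generate_study)(
            synth_config, hub_extra_degree=config.hub_extra_degree
        )
        interactome.write_edge_tsv(graph, outdir / "interactome.edges.tsv")
        interactome.write_psimitab(graph, outdir / "interactome.mitab.tsv")
        matrix.to_tsv(outdir / "expression.tsv", outdir / "sample_groups.tsv")
        drugs.write_drug_table(drug_records, outdir / "drug_table.tsv")
        synth.write_truth(truth, outdir / "truth.tsv")
    else:
        matrix = _stage("load_expression")(expression.GeneExpressionMatrix.from_tsv)(
            config.expression_tsv, config.groups_tsv
        )
        graph = _stage("interactome")(_load_interactome)(config)
        drug_records = _stage("load_drugs")(drugs.read_drug_table)(
            config.drug_table if config.drug_table else drugs.table2_path()
        )
    report.interactome_nodes = graph.number_of_nodes()
    report.interactome_edges = graph.number_of_edges()

    result = _stage("de")(expression.call_degs)(matrix, alpha=config.alpha,
                                                route=config.de_route)
    degs = result.table
    expression.write_deg_table(degs, outdir / "degs.tsv")
    report.n_genes_tested = result.n_tested
    report.n_degs = len(degs)
    report.n_degs_up = int((degs["direction"] == "up").sum())
    report.n_degs_down = int((degs["direction"] == "down").sum())
    logger.info("DE: %d/%d genes called (%d up, %d down)", report.n_degs,
                report.n_genes_tested, report.n_degs_up, report.n_degs_down)

    network = _stage("qqppi")(qqppi.extract_qqppi)(graph, degs)
    report.n_queries_mapped = network.graph.number_of_nodes()
    report.qqppi_nodes = network.graph.number_of_nodes()
    report.qqppi_edges = network.graph.number_of_edges()
    interactome.write_edge_tsv(network.graph, outdir / "qqppi.edges.tsv")
    network.node_table().to_csv(outdir / "qqppi.nodes.tsv", sep="\t", index=False)
    analysis = _stage("qqppi")(qqppi.largest_component)(network) if config.use_lcc else network
    report.lcc_size = analysis.graph.number_of_nodes()

    table = _stage("centrality")(centrality.compute_all)(analysis.graph)
    centrality.write_centrality_table(table, outdir / "centrality.tsv")

    top_sets = _stage("prioritize")(prioritize.top_k_per_measure)(table, k=config.k)
    selection = _stage("prioritize")(prioritize.consensus_central)(
        top_sets, min_measures=config.min_measures, k=config.k
    )
    prioritize.write_top_sets(top_sets, outdir / "top_sets.tsv")
    prioritize.write_consensus(selection, outdir / "consensus.tsv")
    report.consensus_size = len(selection.counts)
    report.consensus_nodes = selection.nodes

    mapped = _stage("drug_mapping")(_map_or_empty)(
        selection, drug_records, config.allowed_groups
    )
    drugs.write_prioritized(mapped, outdir / "prioritized_drug_targets.tsv")
    report.n_targets_with_drugs = len(mapped)
    report.n_drugs_mapped = len(
        {rec.drug_name.lower() for target in mapped for rec in target.drugs}
    )


def _map_or_empty(selection, records, allowed_groups):
    if not selection.counts:
        logger.warning("empty consensus; no drug mapping performed")
        return []
    return drugs.map_drugs(selection, records, allowed_groups=allowed_groups)


def _load_interactome(config: PipelineConfig):
    if config.edge_tsv:
        return interactome.read_edge_tsv(config.edge_tsv)
    records = []
    for path in config.mitab_files:
        records.extend(interactome.read_psimitab(path))
    return interactome.build_graph(records)
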