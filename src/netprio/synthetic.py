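"""Synthetic study generator for the prioritization pipeline.

Emulates the three inputs the pipeline consumes — a whole-genome
interactome, a two-group expression matrix, and a drug-target table —
with known planted structure (true DEGs with directions, hub proteins,
drug-target links) so every downstream stage can be tested for recovery
without any external download.

The interactome is a preferential-attachment (Barabasi-Albert) graph:
protein-protein interaction networks are approximately scale-free, and
any connected generator with comparable degree heterogeneity would do.
The expression matrix is per-gene Gaussian: baseline + a +/- effect_size
case-group shift for the planted DEG fraction (half up, half down) +
noise. Drug targets are sampled with probability proportional to
degree^hub_bias, mimicking the enrichment of well-studied hub proteins
in curated drug databases.

Determinism: one global integer seed governs all sub-generators through
the derivation rule seed+0 (interactome), seed+1 (hub planting), seed+2
(expression), seed+3 (drug table), so stages can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .drugs import DrugTargetRecord
from .expression import GeneExpressionMatrix

SEED_OFFSETS = {"interactome": 0, "hubs": 1, "expression": 2, "drugs": 3}

GROUP_COMBOS = (
    frozenset({"approved"}),
    frozenset({"approved", "investigational"}),
    frozenset({"experimental", "investigational"}),
    frozenset({"approved", "experimental", "investigational"}),
)
ACTIONS = ("inhibitor", "antagonist", "agonist", "modulator", "")


@dataclass
class SyntheticStudyConfig:
    """Study-scale parameters of the synthetic generator.

    Defaults follow the emulated study design: 43 case vs 24 control
    samples; an interactome of 949 proteins with attachment parameter 2,
    whose ~2 edges/node matches the query-network densities the pipeline
    is meant for (~1.9-2.6 edges/node); a 10% planted DEG fraction with
    a 2 log-unit shift against unit noise (comfortably detectable at
    these group sizes); and a drug table of 20 drugs with a quadratic
    hub bias.
    """

    n_genes: int = 2000
    n_case: int = 43
    n_control: int = 24
    deg_fraction: float = 0.1
    effect_size: float = 2.0
    noise_sd: float = 1.0
    interactome_nodes: int = 949
    attachment_edges: int = 2
    n_planted_hubs: int = 5
    n_drugs: int = 20
    hub_bias: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_genes": self.n_genes,
            "n_case": self.n_case,
            "n_control": self.n_control,
            "interactome_nodes": self.interactome_nodes,
            "attachment_edges": self.attachment_edges,
            "n_drugs": self.n_drugs,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ValueError(f"{name} must be a positive integer, got {value!r}")
        if self.n_planted_hubs < 0:
            raise ValueError("n_planted_hubs must be >= 0")
        if not 0 < self.deg_fraction < 1:
            raise ValueError("deg_fraction must lie in (0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        if self.n_case + self.n_control < 4 or min(self.n_case, self.n_control) < 2:
            raise ValueError("need at least 2 samples per group")

    def stage_seed(self, stage: str) -> int:
        return int(self.seed) + SEED_OFFSETS[stage]


@dataclass
class SyntheticTruth:
    """Planted ground truth recorded for recovery tests."""

    true_deg_genes: set = field(default_factory=set)
    true_directions: dict = field(default_factory=dict)
    planted_hub_genes: set = field(default_factory=set)
    planted_drug_links: set = field(default_factory=set)


def gene_symbols(n: int) -> list[str]:
    """Deterministic zero-padded synthetic symbols G0001, G0002, ..."""
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_interactome(n_nodes: int, attachment_edges: int, seed: int) -> nx.Graph:
    """Connected preferential-attachment interactome with symbol labels.

    Has exactly (n_nodes - attachment_edges) * attachment_edges edges by
    construction.
    """
    if attachment_edges < 1 or n_nodes <= attachment_edges:
        raise ValueError("need n_nodes > attachment_edges >= 1")
    graph = nx.barabasi_albert_graph(n_nodes, attachment_edges, seed=int(seed))
    symbols = gene_symbols(n_nodes)
    relabeled = nx.relabel_nodes(graph, dict(zip(range(n_nodes), symbols)))
    for _, _, attrs in relabeled.edges(data=True):
        attrs["sources"] = {"synthetic"}
    return relabeled


def plant_hubs(graph: nx.Graph, n_hubs: int, extra_degree: int, seed: int):
    """Boost ``n_hubs`` random nodes by exactly ``extra_degree`` new edges.

    New edges attach each hub to random distinct non-neighbors; other
    hubs are excluded as endpoints so every hub's degree rises by
    exactly ``extra_degree``. Returns ``(graph, hub symbols)``.
    """
    if n_hubs > graph.number_of_nodes():
        raise ValueError("n_hubs exceeds node count")
    if extra_degree > graph.number_of_nodes() - 1:
        raise ValueError("extra_degree exceeds node count - 1")
    out = graph.copy()
    if n_hubs == 0:
        return out, set()
    rng = np.random.default_rng(int(seed))
    nodes = sorted(out)
    hubs = set(rng.choice(nodes, size=n_hubs, replace=False))
    for hub in sorted(hubs):
        candidates = sorted(set(nodes) - hubs - set(out[hub]) - {hub})
        if len(candidates) < extra_degree:
            raise ValueError(
                f"cannot add {extra_degree} edges to {hub}: only "
                f"{len(candidates)} eligible endpoints"
            )
        for target in rng.choice(candidates, size=extra_degree, replace=False):
            out.add_edge(hub, target, sources={"synthetic"})
    return out, hubs


def generate_expression(
    config: SyntheticStudyConfig,
    symbols,
    forced_deg_genes=(),
) -> tuple[GeneExpressionMatrix, SyntheticTruth]:
    """Two-group matrix with a planted DEG fraction.

    Each gene draws a baseline ~ N(8, 1) (log2-intensity scale typical of
    normalized arrays) and i.i.d. N(0, noise_sd) noise per sample; for
    planted DEGs the case group is shifted by +/- effect_size, half of
    the planted set in each direction. ``forced_deg_genes`` are included
    in the planted set (used to couple hubs to the DEG list at the
    pipeline level).
    """
    symbols = list(symbols)
    if not symbols:
        raise ValueError("empty gene list")
    rng = np.random.default_rng(config.stage_seed("expression"))
    n_genes = len(symbols)
    n_deg = max(int(round(config.deg_fraction * n_genes)), len(forced_deg_genes))
    forced = [g for g in forced_deg_genes if g in set(symbols)]
    remaining = sorted(set(symbols) - set(forced))
    extra = rng.choice(remaining, size=n_deg - len(forced), replace=False)
    deg_genes = forced + list(extra)
    shuffled = list(rng.permutation(deg_genes))
    n_up = (len(shuffled) + 1) // 2
    directions = {g: ("up" if i < n_up else "down") for i, g in enumerate(shuffled)}

    n_samples = config.n_case + config.n_control
    baseline = rng.normal(8.0, 1.0, size=n_genes)
    values = baseline[:, None] + rng.normal(0.0, config.noise_sd, size=(n_genes, n_samples))
    index = {g: i for i, g in enumerate(symbols)}
    for gene, direction in directions.items():
        shift = config.effect_size if direction == "up" else -config.effect_size
        values[index[gene], : config.n_case] += shift

    samples = [f"S{i:03d}" for i in range(1, n_samples + 1)]
    groups = pd.Series(
        ["case"] * config.n_case + ["control"] * config.n_control, index=samples
    )
    matrix = GeneExpressionMatrix(
        values=pd.DataFrame(values, index=pd.Index(symbols, name="gene"), columns=samples),
        sample_groups=groups,
        platform_id="synthetic",
    )
    truth = SyntheticTruth(
        true_deg_genes=set(directions),
        true_directions=directions,
    )
    return matrix, truth


def generate_drug_table(
    graph: nx.Graph, n_drugs: int, hub_bias: float, seed: int
) -> tuple[list[DrugTargetRecord], SyntheticTruth]:
    """Drug-target records with degree-biased target sampling.

    Each drug receives 1-4 target genes drawn without replacement with
    probability proportional to degree^hub_bias (hub_bias=0 is uniform),
    a development-group combination, and an action label.
    """
    if n_drugs < 1:
        raise ValueError("n_drugs must be >= 1")
    rng = np.random.default_rng(int(seed))
    nodes = sorted(graph)
    degrees = np.array([graph.degree(v) for v in nodes], dtype=float)
    weights = np.maximum(degrees, 1.0) ** float(hub_bias)
    probs = weights / weights.sum()
    records: list[DrugTargetRecord] = []
    links: set = set()
    for i in range(1, n_drugs + 1):
        name = f"Drug{i:03d}"
        drug_id = f"SYN{i:05d}"
        n_targets = int(rng.integers(1, 5))
        targets = rng.choice(nodes, size=min(n_targets, len(nodes)), replace=False, p=probs)
        groups = GROUP_COMBOS[rng.integers(0, len(GROUP_COMBOS))]
        action = ACTIONS[rng.integers(0, len(ACTIONS))]
        for gene in sorted(targets):
            records.append(
                DrugTargetRecord(gene=gene, drug_id=drug_id, drug_name=name,
                                 action=action, groups=groups)
            )
            links.add((name, gene))
    truth = SyntheticTruth(planted_drug_links=links)
    return records, truth


def generate_study(config: SyntheticStudyConfig, hub_extra_degree: int = 40):
    """Full synthetic study: interactome (+hubs), expression, drug table.

    Returns ``(interactome, matrix, records, truth)`` with one combined
    truth object. Planted hub genes are forced into the planted DEG set
    so hub recovery is meaningful through the DE filter.
    """
    graph = generate_interactome(
        config.interactome_nodes, config.attachment_edges, config.stage_seed("interactome")
    )
    graph, hubs = plant_hubs(
        graph,
        config.n_planted_hubs,
        extra_degree=min(hub_extra_degree, config.interactome_nodes - 1),
        seed=config.stage_seed("hubs"),
    )
    symbols = gene_symbols(config.n_genes)
    # interactome symbols are a prefix of the gene list when n_genes >= nodes
    forced = sorted(hubs) if config.n_genes >= config.interactome_nodes else []
    matrix, truth = generate_expression(config, symbols, forced_deg_genes=forced)
    records, drug_truth = generate_drug_table(
        graph, config.n_drugs, config.hub_bias, config.stage_seed("drugs")
    )
    truth.planted_hub_genes = set(hubs)
    truth.planted_drug_links = drug_truth.planted_drug_links
    return graph, matrix, records, truth


def write_truth(truth: SyntheticTruth, path) -> None:
    """Truth as a tidy TSV: kind, key, value."""
    with open(path, "w") as out:
        out.write("kind\tkey\tvalue\n")
        for gene in sorted(truth.true_deg_genes):
            out.write(f"deg\t{gene}\t{truth.true_directions[gene]}\n")
        for gene in sorted(truth.planted_hub_genes):
            out.write(f"hub\t{gene}\t\n")
        for drug, gene in sorted(truth.planted_drug_links):
            out.write(f"drug_link\t{drug}\t{gene}\n")


_INT_FIELDS = (
    "n_genes", "n_case", "n_control", "interactome_nodes",
    "attachment_edges", "n_planted_hubs", "n_drugs", "seed",
)
_FLOAT_FIELDS = ("deg_fraction", "effect_size", "noise_sd", "hub_bias")


def config_from_mapping(mapping: dict) -> SyntheticStudyConfig:
    """Build a config from a flat mapping (e.g. parsed YAML), type-coercing."""
    known = set(_INT_FIELDS) | set(_FLOAT_FIELDS)
    unknown = set(mapping) - known
    if unknown:
        raise ValueError(f"unknown synthetic config keys: {sorted(unknown)}")
    kwargs: dict = {}
    for name in _INT_FIELDS:
        if name in mapping:
            kwargs[name] = int(mapping[name])
    for name in _FLOAT_FIELDS:
        if name in mapping:
            kwargs[name] = float(mapping[name])
    return SyntheticStudyConfig(**kwargs)
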