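"""PSI-MITAB parsing and interactome graph construction.

The interactome is an undirected simple :class:`networkx.Graph` keyed by
gene symbol, the common backdrop on which query (differentially
expressed) genes are located. Only the MITAB 2.5 core is interpreted:
identifier columns 1/2 and alias columns 5/6 (gene symbols are preferred
from aliases tagged ``(gene name)``); everything else is opaque.
Self-interactions are dropped because all downstream centrality measures
assume simple graphs.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass

import networkx as nx

logger = logging.getLogger(__name__)

MITAB_MIN_COLUMNS = 15


@dataclass(frozen=True)
class InteractionRecord:
    interactor_a: str
    interactor_b: str
    source_db: str = "unknown"
    detection_method: str | None = None
    publication: str | None = None


def _field_value(field: str) -> str:
    """Strip the 'db:' prefix and any '(type)' suffix from a MITAB field."""
    value = field.split("|", 1)[0]
    if ":" in value:
        value = value.split(":", 1)[1]
    value = value.strip().strip('"')
    if "(" in value:
        value = value.split("(", 1)[0]
    return value.strip()


def _gene_symbol(alias_field: str, id_field: str) -> str:
    """Prefer an alias tagged as a gene name; fall back to the identifier."""
    for alias in alias_field.split("|"):
        if "(gene name)" in alias:
            value = alias.split(":", 1)[-1].split("(", 1)[0]
            return value.strip().strip('"').upper()
    fallback = _field_value(id_field)
    return fallback.upper()


def _source_db(field: str, default: str) -> str:
    # e.g. psi-mi:"MI:0469"(IntAct) -> IntAct
    if "(" in field and field.rstrip().endswith(")"):
        return field.rsplit("(", 1)[1].rstrip(")").strip()
    value = _field_value(field)
    return value if value and value != "-" else default


def read_psimitab(lines, source_db: str = "unknown") -> list[InteractionRecord]:
    """Parse PSI-MITAB 2.5 lines (or a file path) into interaction records.

    Lines with fewer than 15 tab-separated columns are skipped and
    counted; a header line starting with ``#`` is ignored. Zero parseable
    lines is an error.
    """
    if isinstance(lines, (str, os.PathLike)):
        with open(lines) as handle:
            return read_psimitab(handle.readlines(), source_db=source_db)
    records: list[InteractionRecord] = []
    skipped = 0
    for line in lines:
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < MITAB_MIN_COLUMNS:
            skipped += 1
            logger.warning("skipping MITAB line with %d < 15 columns", len(fields))
            continue
        a = _gene_symbol(fields[4], fields[0])
        b = _gene_symbol(fields[5], fields[1])
        if not a or not b or a == "-" or b == "-":
            skipped += 1
            continue
        records.append(
            InteractionRecord(
                interactor_a=a,
                interactor_b=b,
                source_db=_source_db(fields[12], source_db),
                detection_method=fields[6] or None,
                publication=fields[8] or None,
            )
        )
    if skipped:
        logger.warning("skipped %d unparseable MITAB line(s)", skipped)
    if not records:
        raise ValueError("no records parsed from MITAB input")
    return records


def build_graph(
    records,
    keep_isolated: bool = False,
    id_map: dict | None = None,
) -> nx.Graph:
    """Union interaction records into an undirected simple graph.

    Duplicate edges are collapsed with merged per-database provenance
    (edge attribute ``sources``). Self-interactions are dropped; their
    symbols survive as isolated nodes only when ``keep_isolated`` is set
    and they appear in no other record. ``id_map`` optionally translates
    raw identifiers to symbols; unmapped records are dropped and counted.
    """
    records = list(records)
    if not records:
        raise ValueError("no interaction records")
    if id_map is not None:
        mapped, unmapped = [], 0
        for rec in records:
            a = id_map.get(rec.interactor_a)
            b = id_map.get(rec.interactor_b)
            if a is None or b is None:
                unmapped += 1
                continue
            mapped.append(
                InteractionRecord(a.upper(), b.upper(), rec.source_db,
                                  rec.detection_method, rec.publication)
            )
        if unmapped:
            logger.warning("dropped %d record(s) with unmapped identifiers", unmapped)
        records = mapped
        if not records:
            raise ValueError("no records survived identifier mapping")
    graph = nx.Graph()
    self_loop_symbols: set[str] = set()
    for rec in records:
        a, b = rec.interactor_a, rec.interactor_b
        if a == b:
            self_loop_symbols.add(a)
            continue
        if graph.has_edge(a, b):
            graph.edges[a, b]["sources"].add(rec.source_db)
        else:
            graph.add_edge(a, b, sources={rec.source_db})
    if keep_isolated:
        for symbol in self_loop_symbols - set(graph.nodes):
            graph.add_node(symbol)
    return graph


def write_edge_tsv(graph: nx.Graph, path) -> None:
    """Normalized edge list: symbolA, symbolB (sorted), sources."""
    with open(path, "w") as out:
        out.write("symbolA\tsymbolB\tsources\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            sources = graph.edges[a, b].get("sources", set())
            out.write(f"{a}\t{b}\t{','.join(sorted(sources))}\n")


def read_edge_tsv(path) -> nx.Graph:
    graph = nx.Graph()
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:2] != ["symbolA", "symbolB"]:
            raise ValueError("edge TSV must start with columns symbolA, symbolB")
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 2 or not fields[0]:
                continue
            a, b = fields[0].upper(), fields[1].upper()
            if a == b:
                continue
            sources = set(fields[2].split(",")) if len(fields) > 2 and fields[2] else set()
            if graph.has_edge(a, b):
                graph.edges[a, b]["sources"] |= sources
            else:
                graph.add_edge(a, b, sources=sources)
    if graph.number_of_edges() == 0:
        raise ValueError("no edges read")
    return graph


def write_psimitab(graph: nx.Graph, path, source_db: str = "synthetic") -> None:
    """Minimal 15-column MITAB 2.5 dialect; aliases carry the gene names."""
    blank = "-"
    with open(path, "w") as out:
        out.write("#" + "\t".join(f"col{i}" for i in range(1, 16)) + "\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fields = [
                f"{source_db}:{a}",
                f"{source_db}:{b}",
                blank,
                blank,
                f"{source_db}:{a}(gene name)",
                f"{source_db}:{b}(gene name)",
                blank,
                blank,
                blank,
                blank,
                blank,
                blank,
                f'psi-mi:"MI:0000"({source_db})',
                blank,
                blank,
            ]
            out.write("\t".join(fields) + "\n")


def read_id_map(path) -> dict:
    """Two-column TSV: raw identifier -> gene symbol."""
    mapping: dict = {}
    with open(path) as handle:
        for line in handle:
            fields = line.rstrip("\n").split("\t")
            if len(fields) >= 2 and fields[0] and not fields[0].startswith("#"):
                mapping[fields[0]] = fields[1]
    if not mapping:
        raise ValueError("empty identifier map")
    return mapping
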