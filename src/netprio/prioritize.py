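"""Consensus selection of central proteins.

A node counts as "more central" when it ranks in the top ``k`` (default
30) for at least ``min_measures`` (default 2) of the five centrality
measures. All nodes tied with the k-th value are included, which makes
the selection independent of input order; eigenvector values within an
absolute tolerance of 1e-12 are treated as tied to avoid float-order
nondeterminism.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .centrality import MEASURES

#: Absolute near-tie tolerance applied to eigenvector values before ranking.
EIGENVECTOR_TIE_TOL = 1e-12


@dataclass
class ConsensusSelection:
    top_sets: dict
    counts: dict
    k: int = 30
    min_measures: int = 2

    @property
    def nodes(self) -> list:
        """Consensus nodes sorted by (measure count descending, symbol)."""
        return sorted(self.counts, key=lambda v: (-self.counts[v], v))

    def membership(self, node) -> list:
        return sorted(m for m, s in self.top_sets.items() if node in s)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "node": self.nodes,
                "n_measures": [self.counts[v] for v in self.nodes],
                "which_measures": [",".join(self.membership(v)) for v in self.nodes],
            }
        )


def top_k_per_measure(table: pd.DataFrame, k: int = 30) -> dict:
    """Top-k node set per centrality measure, ties at rank k included."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(table) == 0:
        raise ValueError("empty centrality table")
    top_sets = {}
    for measure in MEASURES:
        values = table[measure].to_numpy(dtype=float)
        order = values.argsort()[::-1]
        kth = values[order[min(k, len(values)) - 1]]
        tol = EIGENVECTOR_TIE_TOL if measure == "eigenvector" else 0.0
        keep = values >= kth - tol
        top_sets[measure] = frozenset(map(str, table["node"].to_numpy()[keep]))
    return top_sets


def consensus_central(top_sets: dict, min_measures: int = 2, k: int = 30) -> ConsensusSelection:
    """Nodes appearing in at least ``min_measures`` of the top sets."""
    if not 1 <= min_measures <= len(top_sets):
        raise ValueError("min_measures must be between 1 and the number of measures")
    counts = Counter()
    for members in top_sets.values():
        counts.update(members)
    selected = {node: c for node, c in counts.items() if c >= min_measures}
    return ConsensusSelection(top_sets=dict(top_sets), counts=selected,
                              k=k, min_measures=min_measures)


def write_top_sets(top_sets: dict, path) -> None:
    with open(path, "w") as out:
        out.write("measure\tnode\n")
        for measure in MEASURES:
            for node in sorted(top_sets.get(measure, ())):
                out.write(f"{measure}\t{node}\n")


def write_consensus(selection: ConsensusSelection, path) -> None:
    selection.to_frame().to_csv(path, sep="\t", index=False)


def read_consensus(path) -> ConsensusSelection:
    """Rebuild a minimal selection (counts only) from a consensus TSV."""
    table = pd.read_csv(path, sep="\t")
    counts = dict(zip(table["node"], table["n_measures"]))
    top_sets = {m: frozenset() for m in MEASURES}
    for node, measures in zip(table["node"], table["which_measures"]):
        for m in str(measures).split(","):
            if m in top_sets:
                top_sets[m] = top_sets[m] | {node}
    return ConsensusSelection(top_sets=top_sets, counts=counts)
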