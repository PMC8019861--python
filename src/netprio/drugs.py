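"""Drug-target table handling and joining against consensus proteins.

Replaces a manual drug-database lookup with a reproducible table join:
consensus central proteins are matched against a DrugBank-style TSV
(gene, drug_id, drug_name, action, groups) and filtered by drug
development group (approved / experimental / investigational). Drugs are
keyed by name because accessions repeat across target rows in curated
tables. A transcription of the study's curated drug-target table ships
as the packaged fixture ``data/table2_drug_targets.tsv``.
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass
from importlib import resources

import pandas as pd

logger = logging.getLogger(__name__)

VALID_GROUPS = frozenset({"approved", "experimental", "investigational"})
REQUIRED_COLUMNS = ["gene", "drug_id", "drug_name", "action", "groups"]


@dataclass(frozen=True)
class DrugTargetRecord:
    gene: str
    drug_id: str
    drug_name: str
    action: str
    groups: frozenset


@dataclass
class PrioritizedDrugTarget:
    gene: str
    n_measures: int
    drugs: list  # of DrugTargetRecord


def table2_path():
    """Path to the packaged curated drug-target fixture."""
    return resources.files("netprio").joinpath("data/table2_drug_targets.tsv")


def read_drug_table(source) -> list[DrugTargetRecord]:
    """Read and validate a drug-target TSV.

    Gene symbols are uppercased, group tokens lowercased; an action of
    ``-`` means "not annotated" and becomes the empty string. Malformed
    rows (missing gene/drug name, empty or unrecognized group set) are
    skipped and counted.
    """
    if isinstance(source, (list, tuple)):
        source = io.StringIO("\n".join(source))
    table = pd.read_csv(source, sep="\t", dtype=str).fillna("")
    missing = set(REQUIRED_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"drug table missing columns: {sorted(missing)}")
    records, skipped = [], 0
    for row in table.itertuples(index=False):
        gene = row.gene.strip().upper()
        drug_name = row.drug_name.strip()
        groups = frozenset(
            token.strip().lower() for token in row.groups.split(",") if token.strip()
        )
        if not gene or not drug_name or not groups or not groups <= VALID_GROUPS:
            skipped += 1
            continue
        action = row.action.strip()
        records.append(
            DrugTargetRecord(
                gene=gene,
                drug_id=row.drug_id.strip(),
                drug_name=drug_name,
                action="" if action == "-" else action,
                groups=groups,
            )
        )
    if skipped:
        logger.warning("skipped %d malformed drug-table row(s)", skipped)
    return records


def map_drugs(
    consensus,
    records,
    allowed_groups=VALID_GROUPS,
    keep_list=None,
) -> list[PrioritizedDrugTarget]:
    """Join consensus central genes to their candidate drugs.

    For each consensus gene, keep records whose gene matches and whose
    group set intersects ``allowed_groups``; genes with no surviving
    drugs are omitted. ``keep_list`` (drug names, case-insensitive)
    optionally represents a user-supplied shortlist such as a
    literature-verified subset. Output is sorted by
    (n_measures descending, gene ascending).
    """
    if not consensus.counts:
        raise ValueError("empty consensus selection")
    allowed = frozenset(g.lower() for g in allowed_groups)
    keep = None if keep_list is None else {name.lower() for name in keep_list}
    by_gene: dict[str, list[DrugTargetRecord]] = {}
    for rec in records:
        by_gene.setdefault(rec.gene, []).append(rec)
    out = []
    for gene in sorted(consensus.counts, key=lambda v: (-consensus.counts[v], v)):
        matches = [
            rec
            for rec in by_gene.get(gene, [])
            if rec.groups & allowed and (keep is None or rec.drug_name.lower() in keep)
        ]
        if matches:
            matches.sort(key=lambda r: r.drug_name.lower())
            out.append(
                PrioritizedDrugTarget(gene=gene, n_measures=int(consensus.counts[gene]),
                                      drugs=matches)
            )
    return out


def drug_summary(records) -> tuple[int, int, dict]:
    """Distinct drug count, distinct target count, per-drug target counts.

    Drug identity is the case-normalized drug name; the per-drug counts
    map each drug name (original spelling of first occurrence) to its
    number of distinct target genes.
    """
    records = list(records)
    if not records:
        raise ValueError("no drug-target records")
    canonical: dict[str, str] = {}
    targets: dict[str, set] = {}
    genes = set()
    for rec in records:
        key = rec.drug_name.lower()
        canonical.setdefault(key, rec.drug_name)
        targets.setdefault(key, set()).add(rec.gene)
        genes.add(rec.gene)
    per_drug = {canonical[key]: len(genes) for key, genes in targets.items()}
    return len(targets), len(genes), per_drug


def write_prioritized(targets, path) -> None:
    with open(path, "w") as out:
        out.write("gene\tn_measures\tdrug_id\tdrug_name\taction\tgroups\n")
        for target in targets:
            for rec in target.drugs:
                out.write(
                    f"{target.gene}\t{target.n_measures}\t{rec.drug_id}\t"
                    f"{rec.drug_name}\t{rec.action}\t{','.join(sorted(rec.groups))}\n"
                )


def write_drug_table(records, path) -> None:
    with open(path, "w") as out:
        out.write("\t".join(REQUIRED_COLUMNS) + "\n")
        for rec in records:
            out.write(
                f"{rec.gene}\t{rec.drug_id}\t{rec.drug_name}\t"
                f"{rec.action or '-'}\t{','.join(sorted(rec.groups))}\n"
            )


def read_keep_list(path) -> set:
    with open(path) as handle:
        names = {line.strip() for line in handle if line.strip() and not line.startswith("#")}
    if not names:
        raise ValueError("empty keep-list")
    return names
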