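"""Balanced host datasets from a virus-host association table.

The association table lists known virus-host pairs at the species level
together with the host lineage (genus..kingdom) and the virus genus, in the
style of a Virus-Host DB export. For each sufficiently populated host a
balanced binary dataset is built: the positives are the host's known
viruses, and an equal number of negatives is sampled from viruses with no
recorded association to that host, under one of two schemes:

* **strategy 1** draws negatives from viruses whose *virus* genus does not
  occur among the positives, minimizing false negatives;
* **strategy 2** draws negatives from viruses infecting *other hosts* that
  share the focal host's taxon at a chosen rank (genus..phylum), producing
  progressively harder discrimination tasks as the rank descends.

Multi-class datasets keep one class per host with at least a minimum number
of viruses, labelling each association row.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "TaxonomyRecord",
    "HostDataset",
    "MulticlassDataset",
    "InsufficientNegativesError",
    "read_association_table",
    "write_association_table",
    "merge_segmented",
    "eligible_hosts",
    "sample_negatives_strategy1",
    "sample_negatives_strategy2",
    "build_binary_dataset",
    "build_multiclass",
    "host_taxonomy",
]

#: lineage ranks, most to least specific
RANKS = ("genus", "family", "order", "class", "phylum", "kingdom")

#: required columns of the association table
TABLE_COLUMNS = [
    "virus_id", "virus_name", "virus_genus", "refseq_ids",
    "host_id", "host_name", "host_domain",
] + [f"host_{r}" for r in RANKS]


class InsufficientNegativesError(ValueError):
    """Raised when a negative candidate pool is smaller than the positive set."""


@dataclass(frozen=True)
class TaxonomyRecord:
    """A host species and its lineage at the six standard ranks."""

    species: str
    lineage: dict  # rank -> taxon (may omit ranks)

    def taxon(self, rank: str) -> str | None:
        return self.lineage.get(rank)


@dataclass
class HostDataset:
    """A balanced binary dataset for one host."""

    host: str
    positives: list[str]
    negatives: list[str]
    strategy: str
    seed: int

    def __post_init__(self):
        if len(self.positives) != len(self.negatives):
            raise ValueError("dataset is not balanced")
        if set(self.positives) & set(self.negatives):
            raise ValueError("positive/negative sets overlap")

    def labelled_ids(self) -> list[tuple[str, int]]:
        return [(v, 1) for v in self.positives] + [(v, 0) for v in self.negatives]

    def to_manifest(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("virus_id\tlabel\tstrategy\tseed\n")
            for vid, y in self.labelled_ids():
                fh.write(f"{vid}\t{y}\t{self.strategy}\t{self.seed}\n")


@dataclass
class MulticlassDataset:
    """One class per eligible host; one labelled copy per association row."""

    classes: list[str]
    labels: pd.DataFrame = field(repr=False)  # columns virus_id, host, class_index

    @property
    def n_classes(self) -> int:
        return len(self.classes)


def read_association_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    missing = set(TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"association table missing columns {sorted(missing)}")
    return df


def write_association_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def merge_segmented(table: pd.DataFrame) -> pd.DataFrame:
    """Pool segmented viruses into one row per (virus, host) pair.

    Segmented viruses list several RefSeq accessions; their segment rows are
    merged by unioning the semicolon-joined ``refseq_ids``. Exact duplicate
    association rows are dropped.
    """
    rows = []
    for _, group in table.groupby(["virus_id", "host_name"], sort=False):
        row = group.iloc[0].copy()
        ids: list[str] = []
        for cell in group["refseq_ids"]:
            for rid in str(cell).split(";"):
                if rid and rid not in ids:
                    ids.append(rid)
        row["refseq_ids"] = ";".join(ids)
        rows.append(row)
    return pd.DataFrame(rows).reset_index(drop=True)[list(table.columns)]


def eligible_hosts(table: pd.DataFrame, min_viruses: int) -> pd.DataFrame:
    """Hosts with at least ``min_viruses`` associated viruses, with counts."""
    counts = (table.groupby("host_name")["virus_id"].nunique()
              .rename("n_viruses").reset_index())
    out = counts[counts["n_viruses"] >= min_viruses]
    return out.sort_values(["n_viruses", "host_name"], ascending=[False, True]).reset_index(drop=True)


def host_taxonomy(table: pd.DataFrame) -> dict[str, TaxonomyRecord]:
    """Extract one TaxonomyRecord per host from the lineage columns."""
    records = {}
    for host, group in table.groupby("host_name"):
        row = group.iloc[0]
        lineage = {r: row[f"host_{r}"] for r in RANKS if row[f"host_{r}"]}
        records[host] = TaxonomyRecord(species=host, lineage=lineage)
    return records


def _positives(table: pd.DataFrame, host: str) -> list[str]:
    return sorted(table.loc[table["host_name"] == host, "virus_id"].unique())


def _host_domain(table: pd.DataFrame, host: str) -> str:
    return table.loc[table["host_name"] == host, "host_domain"].iloc[0]


def _sample(pool: list[str], size: int, seed: int, what: str) -> list[str]:
    if len(pool) < size:
        raise InsufficientNegativesError(
            f"{what}: candidate pool has {len(pool)} viruses, need {size}"
        )
    rng = np.random.default_rng(seed)
    return sorted(rng.choice(sorted(pool), size=size, replace=False).tolist())


def sample_negatives_strategy1(host: str, table: pd.DataFrame, seed: int,
                               exclude_by: str = "virus_genus") -> list[str]:
    """Negatives from viruses in genera absent from the positive set.

    The pool is restricted to the focal host's domain (prokaryote or
    eukaryote) and excludes every virus associated with the host. With the
    default ``exclude_by='virus_genus'`` any virus whose genus occurs among
    the positives is also excluded; ``exclude_by='host_taxonomy'`` instead
    drops viruses whose hosts share the focal host's species, keeping only
    the no-association constraint.
    """
    pos = set(_positives(table, host))
    if not pos:
        raise ValueError(f"host {host!r} has no positive viruses")
    domain = _host_domain(table, host)
    dom = table[table["host_domain"] == domain]
    candidates = set(dom["virus_id"].unique()) - pos
    if exclude_by == "virus_genus":
        pos_genera = set(dom.loc[dom["virus_id"].isin(pos), "virus_genus"]) - {""}
        genus_of = dom.drop_duplicates("virus_id").set_index("virus_id")["virus_genus"]
        candidates = {v for v in candidates if genus_of[v] not in pos_genera}
    elif exclude_by != "host_taxonomy":
        raise ValueError(f"unknown exclusion mode {exclude_by!r}")
    return _sample(sorted(candidates), len(pos), seed, f"strategy1 for {host!r}")


def strategy2_pool(host: str, table: pd.DataFrame, rank: str) -> list[str]:
    """Candidate negatives: viruses of other hosts sharing the focal taxon at ``rank``."""
    if rank not in RANKS[:-1]:
        raise ValueError(f"rank must be one of {RANKS[:-1]}, got {rank!r}")
    col = f"host_{rank}"
    focal_rows = table[table["host_name"] == host]
    if focal_rows.empty:
        raise ValueError(f"host {host!r} not in table")
    taxon = focal_rows[col].iloc[0]
    if not taxon:
        raise ValueError(f"host {host!r} has no {rank} in its lineage")
    pos = set(focal_rows["virus_id"])
    related = table[(table[col] == taxon) & (table["host_name"] != host)]
    return sorted(set(related["virus_id"]) - pos)


def sample_negatives_strategy2(host: str, table: pd.DataFrame, rank: str,
                               seed: int) -> list[str]:
    """Negatives from viruses infecting related hosts at the given rank.

    The closer the rank (genus < family < ... < phylum), the more similar
    the negative viruses are to the positives, making classification
    harder. Fails when the related-host pool cannot fill a balanced set.
    """
    pos = _positives(table, host)
    pool = strategy2_pool(host, table, rank)
    return _sample(pool, len(pos), seed, f"strategy2({rank}) for {host!r}")


def build_binary_dataset(host: str, table: pd.DataFrame, strategy: str,
                         seed: int, rank: str | None = None) -> HostDataset:
    """Build one balanced binary dataset under strategy 1 or 2."""
    pos = _positives(table, host)
    if strategy == "strategy1":
        neg = sample_negatives_strategy1(host, table, seed)
        tag = "strategy1"
    elif strategy == "strategy2":
        if rank is None:
            raise ValueError("strategy2 requires a rank")
        neg = sample_negatives_strategy2(host, table, rank, seed)
        tag = f"strategy2({rank})"
    else:
        raise ValueError(f"unknown strategy {strategy!r}")
    return HostDataset(host=host, positives=pos, negatives=neg, strategy=tag, seed=seed)


def build_multiclass(table: pd.DataFrame, min_viruses: int) -> MulticlassDataset:
    """One class per host with >= ``min_viruses`` viruses.

    A virus associated with several eligible hosts contributes one labelled
    copy per association row; users may deduplicate downstream.
    """
    elig = eligible_hosts(table, min_viruses)
    classes = sorted(elig["host_name"].tolist())
    if len(classes) < 2:
        raise ValueError(
            f"only {len(classes)} hosts have >= {min_viruses} viruses; "
            "need at least 2 classes"
        )
    class_index = {h: i for i, h in enumerate(classes)}
    rows = table[table["host_name"].isin(class_index)][["virus_id", "host_name"]].copy()
    rows = rows.drop_duplicates()
    rows["class_index"] = rows["host_name"].map(class_index)
    rows = rows.rename(columns={"host_name": "host"}).reset_index(drop=True)
    return MulticlassDataset(classes=classes, labels=rows)
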