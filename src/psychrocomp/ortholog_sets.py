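"""Reciprocal-best-hit orthology and the nested core/accessory partition.

Two distinct homology rules coexist, as in the underlying methodology:

* set construction (core and nested subsets) uses reciprocal best hits
  (mutual first hit in both search directions at the E-value cutoff);
* "conserved in" accounting uses one-way presence: a gene is present in a
  target genome iff it has >= 1 hit at the cutoff, absent otherwise.

The partition is per focal genome: CDS_c (reciprocal partner in every other
genome of the full panel), then one label per nested hierarchy level by
sequential deduction, then the strain-specific remainder CDS_1.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .genome_io import GenomeCollection, HitRecord
from .similarity import hit_sort_key

__all__ = [
    "RBHPairSet",
    "PartitionTable",
    "reciprocal_best_hits",
    "presence_absence",
    "conservation_percent",
    "conservation_table",
    "core_set",
    "nested_partition",
    "partition_summary_from_shared_counts",
]


def _best_map(hits: list[HitRecord]) -> dict[str, str]:
    """query id -> best subject id under (E asc, bitscore desc, id asc)."""
    per_query: dict[str, HitRecord] = {}
    for h in hits:
        cur = per_query.get(h.query_id)
        if cur is None or hit_sort_key(h) < hit_sort_key(cur):
            per_query[h.query_id] = h
    return {q: h.subject_id for q, h in per_query.items()}


@dataclass(frozen=True)
class RBHPairSet:
    """One-to-one reciprocal-best-hit pairs for an ordered genome pair."""

    genome_a: str
    genome_b: str
    pairs: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        a_ids = [a for a, _ in self.pairs]
        b_ids = [b for _, b in self.pairs]
        if len(set(a_ids)) != len(a_ids) or len(set(b_ids)) != len(b_ids):
            raise ValueError("RBH pairs must be one-to-one")

    def a_to_b(self) -> dict[str, str]:
        return dict(self.pairs)

    def a_ids(self) -> frozenset[str]:
        return frozenset(a for a, _ in self.pairs)


def reciprocal_best_hits(
    hits_ab: list[HitRecord],
    hits_ba: list[HitRecord],
    genome_a: str = "A",
    genome_b: str = "B",
    ids_a: set[str] | None = None,
    ids_b: set[str] | None = None,
) -> RBHPairSet:
    """Mutual-first-hit pairs from the two directional hit lists.

    A pair (a, b) is included iff a's best hit over genome B is b AND b's
    best hit over genome A is a. Mutual-best pairs are one-to-one by
    construction. If id universes are supplied, hits referencing unknown ids
    are an error.
    """
    if ids_a is not None or ids_b is not None:
        for h in hits_ab:
            if ids_a is not None and h.query_id not in ids_a:
                raise ValueError(f"hit references unknown query id {h.query_id!r}")
            if ids_b is not None and h.subject_id not in ids_b:
                raise ValueError(f"hit references unknown subject id {h.subject_id!r}")
        for h in hits_ba:
            if ids_b is not None and h.query_id not in ids_b:
                raise ValueError(f"hit references unknown query id {h.query_id!r}")
            if ids_a is not None and h.subject_id not in ids_a:
                raise ValueError(f"hit references unknown subject id {h.subject_id!r}")
    fwd = _best_map(hits_ab)
    rev = _best_map(hits_ba)
    pairs = frozenset(
        (a, b) for a, b in sorted(fwd.items()) if rev.get(b) == a
    )
    return RBHPairSet(genome_a=genome_a, genome_b=genome_b, pairs=pairs)


def presence_absence(
    query_cds_ids: list[str], hits_ab: list[HitRecord], cutoff: float = 1e-20
) -> dict[str, bool]:
    """One-way presence: True iff the query CDS has >= 1 hit at the cutoff."""
    present = {q: False for q in query_cds_ids}
    for h in hits_ab:
        if h.evalue <= cutoff and h.query_id in present:
            present[h.query_id] = True
    return present


def conservation_percent(count: int, total: int) -> float:
    """Table-cell percentage: 100 * count / total, one decimal."""
    if total <= 0:
        raise ValueError("total must be positive")
    return round(100.0 * count / total, 1)


def conservation_table(
    collection: GenomeCollection,
    hits: dict[tuple[str, str], list[HitRecord]],
    genome_ids: list[str] | None = None,
    cutoff: float = 1e-20,
) -> pd.DataFrame:
    """Counts (and percentages) of query-genome CDS conserved in each target.

    Cell (row = target genome T, column = query genome Q) counts Q's CDS
    with >= 1 hit in T at the cutoff; the diagonal is Q's total CDS (100%).
    ``hits`` maps ordered pairs (query_genome, target_genome) to hit lists.
    """
    if genome_ids is None:
        genome_ids = collection.genome_ids()
    totals = {g: len(collection.cds_of(g)) for g in genome_ids}
    rows = []
    for target in genome_ids:
        row: dict[str, object] = {"target": target}
        for query in genome_ids:
            if query == target:
                count = totals[query]
            else:
                key = (query, target)
                if key not in hits:
                    raise KeyError(f"missing hit table for pair {key}")
                ids = [c.cds_id for c in collection.cds_of(query)]
                count = sum(presence_absence(ids, hits[key], cutoff).values())
            pct = conservation_percent(count, totals[query])
            row[f"{query}_count"] = count
            row[f"{query}_pct"] = pct
        rows.append(row)
    return pd.DataFrame(rows)


def core_set(
    collection: GenomeCollection,
    rbh_by_genome: dict[str, RBHPairSet],
    focal: str,
) -> frozenset[str]:
    """Focal-genome CDS with a reciprocal partner in EVERY other genome of
    the outermost hierarchy set."""
    if not collection.hierarchy:
        raise ValueError("collection has no hierarchy")
    others = sorted(collection.hierarchy[0] - {focal})
    missing = [g for g in others if g not in rbh_by_genome]
    if missing:
        raise ValueError(f"missing RBH tables for pairs with {missing}")
    sets = [rbh_by_genome[g].a_ids() for g in others]
    return frozenset.intersection(*sets) if sets else frozenset()


@dataclass
class PartitionTable:
    """Nested-set labels for every CDS of the focal genome.

    Labels partition the focal CDS set: CDS_c (core), one label per inner
    hierarchy level (e.g. CDS_4, CDS_2), and CDS_1 for the remainder.
    """

    focal: str
    labels: dict[str, str]
    level_names: list[str] = field(default_factory=list)

    def counts(self) -> dict[str, int]:
        out: dict[str, int] = {name: 0 for name in self.level_names}
        for lab in self.labels.values():
            out[lab] = out.get(lab, 0) + 1
        return out

    @property
    def total(self) -> int:
        return len(self.labels)

    def summary(self) -> pd.DataFrame:
        counts = self.counts()
        total = self.total
        core = counts.get("CDS_c", 0)
        rows = [
            {"set": "total", "count": total, "of_total_pct": 100.0},
            {"set": "CDS_c", "count": core, "of_total_pct": conservation_percent(core, total)},
            {"set": "CDS_nc", "count": total - core,
             "of_total_pct": conservation_percent(total - core, total)},
        ]
        for name in self.level_names:
            if name == "CDS_c":
                continue
            rows.append(
                {"set": name, "count": counts.get(name, 0),
                 "of_total_pct": conservation_percent(counts.get(name, 0), total)}
            )
        return pd.DataFrame(rows)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"cds_id": list(self.labels), "label": list(self.labels.values())}
        ).sort_values("cds_id", ignore_index=True)


def nested_partition(
    collection: GenomeCollection,
    rbh_by_genome: dict[str, RBHPairSet],
    focal: str,
) -> PartitionTable:
    """Sequential-deduction labelling over the nested hierarchy.

    Level 0 (outermost, the full panel) yields CDS_c; each inner level k
    yields the CDS with reciprocal partners in every other genome of that
    level's set, minus everything labelled at outer levels; the leftover is
    CDS_1.
    """
    if not collection.hierarchy:
        raise ValueError("collection has no hierarchy")
    for level in collection.hierarchy:
        if focal not in level:
            raise ValueError(f"focal genome {focal} missing from a hierarchy level")
    focal_ids = [c.cds_id for c in collection.cds_of(focal)]
    labels: dict[str, str] = {}
    level_names: list[str] = []
    for k, level in enumerate(collection.hierarchy):
        others = sorted(level - {focal})
        missing = [g for g in others if g not in rbh_by_genome]
        if missing:
            raise ValueError(f"missing RBH tables for pairs with {missing}")
        shared = (
            frozenset.intersection(*[rbh_by_genome[g].a_ids() for g in others])
            if others
            else frozenset(focal_ids)
        )
        name = "CDS_c" if k == 0 else f"CDS_{len(level)}"
        level_names.append(name)
        for cds_id in shared:
            if cds_id not in labels:
                labels[cds_id] = name
    level_names.append("CDS_1")
    for cds_id in focal_ids:
        labels.setdefault(cds_id, "CDS_1")
    # restrict to focal CDS only (shared sets are focal-side ids already)
    labels = {cid: labels[cid] for cid in focal_ids}
    return PartitionTable(focal=focal, labels=labels, level_names=level_names)


def partition_summary_from_shared_counts(
    total: int, shared_counts: list[int]
) -> dict[str, int]:
    """Set sizes by sequential deduction from raw shared-ortholog counts.

    ``shared_counts`` are the total ortholog counts at each hierarchy level,
    outermost (full panel -> core) first, e.g. [core, shared-among-four,
    shared-with-partner]. Returns sizes for CDS_c, CDS_nc, each deducted
    level, and the CDS_1 remainder; sizes sum to the total by construction.
    """
    if not shared_counts:
        raise ValueError("need at least the core count")
    if any(c < 0 for c in shared_counts) or total < 0:
        raise ValueError("counts must be non-negative")
    core = shared_counts[0]
    out = {"CDS_c": core, "CDS_nc": total - core}
    consumed = core
    for k, cnt in enumerate(shared_counts[1:], start=1):
        size = cnt - consumed
        if size < 0:
            raise ValueError("shared counts must be non-decreasing inward")
        out[f"level_{k}"] = size
        consumed = cnt
    out["CDS_1"] = total - consumed
    return out
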