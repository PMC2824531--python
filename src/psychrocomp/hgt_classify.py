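"""Lateral-gene-transfer calling from top-hit taxonomy.

A gene is called laterally transferred when, after excluding a configured
set of close relatives from its hit list, the best-matching genome falls
outside an expected lineage scope. Several exclusion cases are evaluated in
order (e.g. exclude the closest relative and require the top match to stay
within the genus; exclude the whole genus and require it to stay within
marine gamma-proteobacteria); ANY case escaping its scope triggers a lateral
call. Lineage membership is resolved via the ``lineage_tags`` of genome
metadata, never by parsing taxon names.

Genes with no panel hit at all are reported as ``no_hit`` and are never
counted as lateral.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

import pandas as pd

from .genome_io import GenomeMeta, HitRecord
from .similarity import hit_sort_key

__all__ = [
    "ExclusionCase",
    "ExclusionConfig",
    "OriginCall",
    "top_match",
    "classify_lateral",
    "classify_collection",
    "donor_summary",
    "habitat_marginals",
]


@dataclass(frozen=True)
class ExclusionCase:
    """One exclusion rule: genomes/tags removed before taking the top match,
    and the lineage scope whose escape triggers a lateral call."""

    name: str
    exclude: frozenset[str]  # genome ids and/or lineage tags
    scope_tags: frozenset[str]  # top match is native iff it carries any of these

    def __post_init__(self) -> None:
        object.__setattr__(self, "exclude", frozenset(self.exclude))
        object.__setattr__(self, "scope_tags", frozenset(self.scope_tags))


@dataclass(frozen=True)
class ExclusionConfig:
    cases: tuple[ExclusionCase, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "cases", tuple(self.cases))

    def validate(self, panel: dict[str, GenomeMeta]) -> None:
        known_ids = set(panel)
        known_tags = {t for m in panel.values() for t in m.lineage_tags}
        for case in self.cases:
            unknown = case.exclude - known_ids - known_tags
            if unknown:
                raise ValueError(
                    f"exclusion case {case.name!r}: unresolvable ids/tags {sorted(unknown)}"
                )


@dataclass(frozen=True)
class OriginCall:
    """Per-CDS origin: native, lateral (with donor), or no_hit."""

    cds_id: str
    label: str  # native | lateral | no_hit
    case: str | None = None
    donor_genome: str | None = None
    donor_taxon: str | None = None

    def __post_init__(self) -> None:
        if self.label == "lateral" and self.donor_genome is None:
            raise ValueError("lateral calls must carry a donor")
        if self.label == "no_hit" and (self.donor_genome or self.case):
            raise ValueError("no_hit calls carry neither case nor donor")


def _resolve_exclusions(
    exclude: frozenset[str], panel: dict[str, GenomeMeta]
) -> set[str]:
    """Expand lineage tags into genome ids; ids pass through."""
    known_tags = {t for m in panel.values() for t in m.lineage_tags}
    out: set[str] = set()
    for item in exclude:
        if item in panel:
            out.add(item)
        elif item in known_tags:
            out.update(g for g, m in panel.items() if item in m.lineage_tags)
        else:
            raise ValueError(f"unknown excluded id/tag {item!r}")
    return out


def top_match(
    hits: list[HitRecord],
    subject_genome: dict[str, str],
    excluded_genomes: set[str],
    panel: dict[str, GenomeMeta],
) -> tuple[str, str] | None:
    """Best surviving (genome id, taxon) after removing excluded genomes.

    ``subject_genome`` maps subject cds ids to their genome of origin. The
    best-hit rule (E, then bitscore, then subject id) applies to what
    survives; None if nothing does.
    """
    unknown = excluded_genomes - set(panel)
    if unknown:
        raise ValueError(f"unknown excluded genome ids {sorted(unknown)}")
    surviving = [
        h for h in hits if subject_genome[h.subject_id] not in excluded_genomes
    ]
    if not surviving:
        return None
    best = min(surviving, key=hit_sort_key)
    genome = subject_genome[best.subject_id]
    return genome, panel[genome].taxon_label


def classify_lateral(
    cds_id: str,
    hits: list[HitRecord],
    subject_genome: dict[str, str],
    config: ExclusionConfig,
    panel: dict[str, GenomeMeta],
) -> OriginCall:
    """Evaluate the exclusion cases in order; lateral if ANY case's top match
    escapes that case's lineage scope."""
    config.validate(panel)
    if not hits:
        return OriginCall(cds_id=cds_id, label="no_hit")
    for case in config.cases:
        excluded = _resolve_exclusions(case.exclude, panel)
        match = top_match(hits, subject_genome, excluded, panel)
        if match is None:
            continue  # exclusions emptied the list: this case cannot trigger
        genome, taxon = match
        if not (set(panel[genome].lineage_tags) & case.scope_tags):
            return OriginCall(
                cds_id=cds_id,
                label="lateral",
                case=case.name,
                donor_genome=genome,
                donor_taxon=taxon,
            )
    return OriginCall(cds_id=cds_id, label="native")


def classify_collection(
    cds_ids: list[str],
    panel_hits: list[HitRecord],
    subject_genome: dict[str, str],
    config: ExclusionConfig,
    panel: dict[str, GenomeMeta],
) -> list[OriginCall]:
    """Classify every CDS of a focal genome from one pooled panel hit list."""
    config.validate(panel)
    by_query: dict[str, list[HitRecord]] = defaultdict(list)
    for h in panel_hits:
        by_query[h.query_id].append(h)
    return [
        classify_lateral(cid, by_query.get(cid, []), subject_genome, config, panel)
        for cid in cds_ids
    ]


def donor_summary(
    calls: list[OriginCall], panel: dict[str, GenomeMeta]
) -> pd.DataFrame:
    """Lateral-call counts per donor taxon, with cold/warm marginal totals."""
    counts: dict[tuple[str, str], int] = defaultdict(int)
    for call in calls:
        if call.label != "lateral":
            continue
        habitat = panel[call.donor_genome].habitat
        counts[(call.donor_taxon, habitat)] += 1
    rows = [
        {"donor_taxon": taxon, "habitat": habitat, "count": n}
        for (taxon, habitat), n in sorted(counts.items())
    ]
    df = pd.DataFrame(rows, columns=["donor_taxon", "habitat", "count"])
    return df


def habitat_marginals(summary: pd.DataFrame) -> dict[str, int]:
    totals = {"cold": 0, "warm": 0, "unlabeled": 0}
    for row in summary.itertuples(index=False):
        totals[row.habitat] += row.count
    return totals
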