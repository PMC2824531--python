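"""Proteome amino-acid composition, GC/AG content, and group contrasts.

Average amino-acid composition (ACAA) is the pooled percentage of each
residue over all residues of all proteins in a set — not the mean of
per-protein percentages. X and other non-canonical symbols (B, Z, U, J, O,
stops) are excluded from numerator and denominator alike. Nucleotide content
pools all CDS bases, excluding N.

Group contrasts (cold vs warm habitats) use a two-sided Welch t-test with
the genome as the sampling unit — proteins are never treated as independent
samples. No multiple-testing correction is applied by default (per-feature
raw p-values are reported); Benjamini–Hochberg is available behind a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genome_io import GenomeCollection

__all__ = [
    "AA_ORDER",
    "CompositionVector",
    "NucleotideContent",
    "aa_composition",
    "nt_content",
    "composition_table",
    "deviation_profile",
    "welch_t",
    "group_compare",
    "gc_aa_correlation",
    "cumulative_composition_by_gc",
]

AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AA_ORDER)

AA_NAMES = {
    "A": "Ala", "C": "Cys", "D": "Asp", "E": "Glu", "F": "Phe",
    "G": "Gly", "H": "His", "I": "Ile", "K": "Lys", "L": "Leu",
    "M": "Met", "N": "Asn", "P": "Pro", "Q": "Gln", "R": "Arg",
    "S": "Ser", "T": "Thr", "V": "Val", "W": "Trp", "Y": "Tyr",
}


@dataclass(frozen=True)
class CompositionVector:
    """Percentages of the 20 canonical residues; sums to 100."""

    values: tuple[float, ...]  # ordered by AA_ORDER
    total: int  # counted (canonical) residues

    def __getitem__(self, aa: str) -> float:
        return self.values[AA_ORDER.index(aa)]

    def as_dict(self) -> dict[str, float]:
        return dict(zip(AA_ORDER, self.values))


@dataclass(frozen=True)
class NucleotideContent:
    gc_percent: float
    ag_percent: float
    total: int


def aa_composition(proteins: list[str]) -> CompositionVector:
    """Pooled residue percentages over a protein set (ACAA)."""
    counts = {aa: 0 for aa in AA_ORDER}
    total = 0
    for seq in proteins:
        for c in seq.upper():
            if c in _AA_SET:
                counts[c] += 1
                total += 1
    if total == 0:
        raise ValueError("no canonical residues in protein set")
    values = tuple(100.0 * counts[aa] / total for aa in AA_ORDER)
    return CompositionVector(values=values, total=total)


def nt_content(cds_seqs: list[str]) -> NucleotideContent:
    """Pooled G+C and A+G percentages over concatenated CDS; N excluded."""
    gc = ag = total = 0
    for seq in cds_seqs:
        for c in seq.upper():
            if c in "ACGT":
                total += 1
                if c in "GC":
                    gc += 1
                if c in "AG":
                    ag += 1
    if total == 0:
        raise ValueError("no counted bases in CDS set")
    return NucleotideContent(
        gc_percent=100.0 * gc / total, ag_percent=100.0 * ag / total, total=total
    )


FEATURES = list(AA_ORDER) + ["GC", "AG"]


def composition_table(
    collection: GenomeCollection,
    cds_subset: dict[str, set[str]] | None = None,
) -> pd.DataFrame:
    """Per-genome feature matrix: 20 amino-acid percentages + GC + AG.

    ``cds_subset`` optionally restricts each genome to a named CDS-id set
    (e.g. the core projection); genomes absent from it use all their CDS.
    """
    rows = []
    for g in collection.genome_ids():
        records = collection.cds_of(g)
        if cds_subset is not None and g in cds_subset:
            keep = cds_subset[g]
            records = [c for c in records if c.cds_id in keep]
        if not records:
            raise ValueError(f"genome {g}: empty CDS set")
        comp = aa_composition([c.aa_seq for c in records])
        nt = nt_content([c.nt_seq for c in records if c.nt_seq])
        row = {"genome_id": g, **comp.as_dict(), "GC": nt.gc_percent, "AG": nt.ag_percent}
        rows.append(row)
    return pd.DataFrame(rows).set_index("genome_id")


def deviation_profile(table: pd.DataFrame) -> pd.DataFrame:
    """Entity-minus-unweighted-mean deviations, per feature.

    Rows are entities (genomes or CDS sets), columns features; each column
    of the result sums to zero.
    """
    if len(table) < 2:
        raise ValueError("deviation profile needs >= 2 entities")
    return table - table.mean(axis=0)


def welch_t(x, y) -> tuple[float, float, float]:
    """Two-sided unequal-variance t-test; returns (delta, t, p).

    delta = mean(x) - mean(y). Degenerate zero-variance groups: identical
    means give (0, 0, 1); distinct means give t = +/-inf, p = 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs >= 2 values")
    delta = float(x.mean() - y.mean())
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0:
        if delta == 0.0:
            return 0.0, 0.0, 1.0
        return delta, float(np.sign(delta)) * float("inf"), 0.0
    t, p = stats.ttest_ind(x, y, equal_var=False)
    return delta, float(t), float(p)


def group_compare(
    collection: GenomeCollection,
    scope: str = "total",
    core_map: dict[str, set[str]] | None = None,
    bh_correct: bool = False,
) -> pd.DataFrame:
    """Cold-vs-warm contrast over per-genome composition features.

    scope="total" uses whole proteomes; scope="core" restricts each genome
    to its core CDS via ``core_map`` (genome id -> core cds ids). Returns a
    table with mean_cold, mean_warm, delta (cold - warm), t and p per
    feature (20 amino acids + GC + AG).
    """
    if scope not in ("total", "core"):
        raise ValueError("scope must be 'total' or 'core'")
    if scope == "core" and core_map is None:
        raise ValueError("scope='core' requires a core_map")
    cold = [m.genome_id for m in collection.metas if m.habitat == "cold"]
    warm = [m.genome_id for m in collection.metas if m.habitat == "warm"]
    unlabeled = [m.genome_id for m in collection.metas if m.habitat == "unlabeled"]
    if unlabeled:
        raise ValueError(f"genomes missing habitat labels: {unlabeled}")
    if len(cold) < 2 or len(warm) < 2:
        raise ValueError("need >= 2 genomes in each habitat group")
    table = composition_table(
        collection, cds_subset=core_map if scope == "core" else None
    )
    rows = []
    for feat in FEATURES:
        x = table.loc[cold, feat].to_numpy()
        y = table.loc[warm, feat].to_numpy()
        delta, t, p = welch_t(x, y)
        rows.append(
            {
                "feature": feat,
                "mean_cold": float(np.mean(x)),
                "mean_warm": float(np.mean(y)),
                "delta": delta,
                "t": t,
                "p": p,
            }
        )
    df = pd.DataFrame(rows)
    if bh_correct:
        df["p_adj"] = _benjamini_hochberg(df["p"].to_numpy())
    return df


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n - 1, -1, -1):
        idx = order[rank]
        running = min(running, p[idx] * n / (rank + 1))
        adj[idx] = running
    return adj


def gc_aa_correlation(collection: GenomeCollection) -> pd.DataFrame:
    """Per-amino-acid Pearson correlation and least-squares slope of
    composition against genome GC percent, across genomes."""
    table = composition_table(collection)
    if len(table) < 3:
        raise ValueError("need >= 3 genomes")
    gc = table["GC"].to_numpy()
    if np.var(gc) < 1e-12:
        raise ValueError("zero variance in genome GC content")
    rows = []
    for aa in AA_ORDER:
        y = table[aa].to_numpy()
        if np.var(y) < 1e-12:
            r = 0.0
        else:
            r = float(stats.pearsonr(gc, y).statistic)
        slope = float(np.polyfit(gc, y, 1)[0])
        rows.append({"aa": aa, "name": AA_NAMES[aa], "r": r, "slope": slope})
    return pd.DataFrame(rows)


def cumulative_composition_by_gc(collection: GenomeCollection) -> pd.DataFrame:
    """Genomes ordered by GC with cumulative amino-acid composition — the
    stacked-profile view of the GC/composition relationship."""
    table = composition_table(collection).sort_values("GC")
    cum = table[list(AA_ORDER)].cumsum(axis=1)
    cum.insert(0, "GC", table["GC"])
    return cum
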