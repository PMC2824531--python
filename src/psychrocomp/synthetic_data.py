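"""Seeded generator of genome collections with planted ground truth.

The generator emulates the statistical structure the analysis chain assumes:

* gene families shared at nested clade levels (core / clade / pair /
  strain-private), driving the orthology partition;
* a GC3 gradient across genomes, realized through synonymous codon choice;
* habitat-linked amino-acid composition shifts in cold-labelled genomes;
* laterally transferred genes copied from a labelled foreign donor panel,
  with donor divergence well below within-family divergence so truth is
  unambiguous.

Simulation is protein-level with reverse translation (rather than
codon-level mutation): every downstream statistic consumes proteins or
pooled GC, and this keeps the amino-acid signal and the GC signal
independently controllable. Replacement residues during mutation are drawn
from a genome-level target frequency vector — the uniform-codon-usage
marginal of the standard genetic code, tilted by the habitat shift for cold
genomes — so the realized cold-warm composition delta equals the configured
shift in expectation.

With ``gc_coupled_composition=True`` each genome's proteins are drawn
directly from the amino-acid marginal of a codon model weighted by the
genome's GC target, which reproduces the canonical GC-composition sign
pattern (Arg/Pro/Ala/Gly up, Ile/Lys/Asn/Tyr down) as a pure consequence of
codon structure. That mode models composition, not orthology.

Everything is deterministic for a fixed seed: identical configs give
byte-identical FASTA output.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .genome_io import (
    CDSRecord,
    GenomeCollection,
    GenomeMeta,
    CODON_TO_AA,
)
from .composition_stats import AA_ORDER

__all__ = [
    "DonorSpec",
    "SimConfig",
    "TruthTables",
    "baseline_aa_frequencies",
    "codon_model_aa_frequencies",
    "reverse_translate",
    "mutate_family",
    "simulate_collection",
    "write_collection",
]

_AA_TO_CODONS: dict[str, list[str]] = defaultdict(list)
for codon, aa in sorted(CODON_TO_AA.items()):
    _AA_TO_CODONS[aa].append(codon)

NATIVE_TAGS = ("Shewanella", "marine-gamma", "gamma")


@dataclass(frozen=True)
class DonorSpec:
    """One foreign-panel genome: its taxon, lineage tags, habitat label."""

    genome_id: str
    taxon_label: str
    lineage_tags: tuple[str, ...]
    habitat: str


DEFAULT_DONORS = (
    DonorSpec("D_firmi_cold", "Bacillus frigoris", ("firmicute",), "cold"),
    DonorSpec("D_firmi_warm", "Clostridium calidum", ("firmicute",), "warm"),
    DonorSpec("D_alpha_cold", "Rhodospirillum gelidum", ("alpha",), "cold"),
    DonorSpec("D_beta_warm", "Burkholderia tepida", ("beta",), "warm"),
)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one simulated collection.

    ``hierarchy_sizes`` are nested genome counts, outermost first (default
    17 strains / 4-strain clade / focal pair); ``families_per_level`` are the
    gene-family counts planted at each level; every genome additionally gets
    ``private_families`` unique families and ``n_hgt`` genes copied from the
    donor panel. ``aa_shift`` is in percentage points of composition for
    cold genomes and is compensated across the unlisted amino acids so the
    target frequencies stay on the simplex.
    """

    seed: int = 0
    hierarchy_sizes: tuple[int, ...] = (17, 4, 2)
    families_per_level: tuple[int, ...] = (200, 100, 80)
    private_families: int = 50
    mean_protein_len: int = 150
    min_protein_len: int = 100
    gc3_range: tuple[float, float] = (0.35, 0.65)
    gc3_targets: tuple[float, ...] | None = None
    cold_genomes: tuple[str, ...] | None = None  # default: the first inner clade
    aa_shift: dict[str, float] = field(
        default_factory=lambda: {"A": -0.8, "P": -0.3, "R": -0.5, "I": 0.6, "K": 0.4, "N": 0.4}
    )
    divergence: float = 0.15
    n_hgt: int = 10
    hgt_divergence: float = 0.05
    donors: tuple[DonorSpec, ...] = DEFAULT_DONORS
    gc_coupled_composition: bool = False

    def __post_init__(self) -> None:
        if len(self.families_per_level) != len(self.hierarchy_sizes):
            raise ValueError("families_per_level must match hierarchy_sizes")
        if any(f < 0 for f in self.families_per_level) or self.private_families < 0:
            raise ValueError("family counts must be >= 0")
        sizes = self.hierarchy_sizes
        if any(b >= a for a, b in zip(sizes, sizes[1:])) or any(s < 1 for s in sizes):
            raise ValueError("hierarchy sizes must be strictly decreasing and >= 1")
        if not (0.0 <= self.divergence < 1.0 and 0.0 <= self.hgt_divergence < 1.0):
            raise ValueError("divergences must be in [0, 1)")
        if self.n_hgt > 0 and not self.donors:
            raise ValueError("HGT genes require a donor panel")

    def genome_ids(self) -> list[str]:
        return [f"G{i + 1:02d}" for i in range(self.hierarchy_sizes[0])]


@dataclass
class TruthTables:
    """Planted ground truth covering every emitted CDS."""

    partition: dict[str, str]  # cds_id -> CDS_c / CDS_<k> / CDS_1 (native genomes)
    origin: dict[str, tuple[str, str | None]]  # cds_id -> (vertical|hgt, donor id)
    genome_gc3: dict[str, float]
    habitat: dict[str, str]


def baseline_aa_frequencies() -> dict[str, float]:
    """Uniform-codon-usage expectation of the standard code: n_codons / 61."""
    total = sum(len(_AA_TO_CODONS[aa]) for aa in AA_ORDER)
    return {aa: len(_AA_TO_CODONS[aa]) / total for aa in AA_ORDER}


def codon_model_aa_frequencies(gc_weight: float) -> dict[str, float]:
    """Amino-acid marginal of a codon model where each codon's probability
    is proportional to g^(#GC bases) * (1-g)^(#AT bases)."""
    if not (0.0 < gc_weight < 1.0):
        raise ValueError("gc_weight must be in (0, 1)")
    g = gc_weight
    weights = {
        aa: sum(
            np.prod([g if b in "GC" else 1.0 - g for b in codon])
            for codon in _AA_TO_CODONS[aa]
        )
        for aa in AA_ORDER
    }
    total = sum(weights.values())
    return {aa: w / total for aa, w in weights.items()}


def _shifted_frequencies(
    baseline: dict[str, float], shift_pp: dict[str, float], divergence: float
) -> dict[str, float]:
    """Replacement frequencies whose expected composition delta at the given
    divergence equals the configured shift (percentage points)."""
    unknown = set(shift_pp) - set(AA_ORDER)
    if unknown:
        raise ValueError(f"shift vector names unknown residues {sorted(unknown)}")
    if divergence <= 0:
        raise ValueError("a composition shift requires divergence > 0")
    q = dict(baseline)
    imbalance = sum(shift_pp.values()) / 100.0
    others = [aa for aa in AA_ORDER if aa not in shift_pp]
    other_mass = sum(baseline[aa] for aa in others)
    for aa in AA_ORDER:
        delta = shift_pp.get(aa, 0.0) / 100.0
        if aa in others and other_mass > 0:
            delta = -imbalance * baseline[aa] / other_mass
        q[aa] = baseline[aa] + delta / divergence
        if q[aa] < 0:
            raise ValueError(
                f"shift for {aa} drives replacement frequency negative "
                f"({q[aa]:.4f}); reduce the shift or raise divergence"
            )
    total = sum(q.values())
    return {aa: v / total for aa, v in q.items()}


def _freq_array(freqs: dict[str, float]) -> np.ndarray:
    arr = np.array([freqs[aa] for aa in AA_ORDER], dtype=float)
    return arr / arr.sum()


def _sample_protein(length: int, freqs: np.ndarray, rng: np.random.Generator) -> str:
    idx = rng.choice(len(AA_ORDER), size=length, p=freqs)
    return "".join(AA_ORDER[i] for i in idx)


def mutate_family(
    ancestor: str,
    divergence: float,
    target_freqs: dict[str, float],
    rng: np.random.Generator,
) -> str:
    """Substitute an expected fraction ``divergence`` of sites, drawing
    replacements from the target frequency vector (which may, by chance,
    re-draw the original residue)."""
    if not (0.0 <= divergence < 1.0):
        raise ValueError("divergence must be in [0, 1)")
    if divergence == 0.0:
        return ancestor
    arr = np.array(list(ancestor))
    mask = rng.random(len(arr)) < divergence
    n = int(mask.sum())
    if n:
        freqs = _freq_array(target_freqs)
        repl = rng.choice(len(AA_ORDER), size=n, p=freqs)
        arr[mask] = [AA_ORDER[i] for i in repl]
    return "".join(arr)


def reverse_translate(
    aa_seq: str, gc3_target: float, rng: np.random.Generator, stop: str = "TAA"
) -> str:
    """Pick synonymous codons with third positions weighted toward G/C (or
    A/T) to meet the GC3 target in expectation; appends a stop codon.

    ``translate_cds`` inverts the coding part exactly. Residues whose codon
    set has no third-position choice (Met, Trp) are emitted verbatim.
    """
    if not (0.0 <= gc3_target <= 1.0):
        raise ValueError("gc3_target must be in [0, 1]")
    bad = sorted(set(aa_seq) - set(AA_ORDER))
    if bad:
        raise ValueError(f"non-canonical residue(s) {''.join(bad)!r}")
    g = gc3_target
    arr = np.array(list(aa_seq))
    codons = np.empty(len(arr), dtype=object)
    for aa in set(aa_seq):
        options = _AA_TO_CODONS[aa]
        w = np.array([g if c[2] in "GC" else 1.0 - g for c in options])
        if w.sum() == 0.0:
            w = np.ones(len(options))
        w = w / w.sum()
        pos = np.flatnonzero(arr == aa)
        picks = rng.choice(len(options), size=len(pos), p=w)
        for p, k in zip(pos, picks):
            codons[p] = options[k]
    return "".join(codons) + stop


def simulate_collection(config: SimConfig) -> tuple[GenomeCollection, TruthTables]:
    """Generate a genome collection plus truth tables for the planted
    families, origins, GC targets and habitats. Deterministic per seed."""
    rng = np.random.default_rng(config.seed)
    genome_ids = config.genome_ids()
    n_genomes = len(genome_ids)

    if config.gc3_targets is not None:
        if len(config.gc3_targets) != n_genomes:
            raise ValueError("gc3_targets must have one value per genome")
        gc3 = list(config.gc3_targets)
    else:
        lo, hi = config.gc3_range
        gc3 = list(np.linspace(lo, hi, n_genomes)) if n_genomes > 1 else [(lo + hi) / 2]

    if config.cold_genomes is not None:
        cold = set(config.cold_genomes)
        unknown = cold - set(genome_ids)
        if unknown:
            raise ValueError(f"unknown cold genomes {sorted(unknown)}")
    elif len(config.hierarchy_sizes) > 1:
        cold = set(genome_ids[: config.hierarchy_sizes[1]])
    else:
        cold = set()

    baseline = baseline_aa_frequencies()
    warm_q = baseline
    if config.aa_shift and config.divergence > 0:
        cold_q = _shifted_frequencies(baseline, config.aa_shift, config.divergence)
    else:
        cold_q = baseline

    def genome_target(g: str) -> dict[str, float]:
        if config.gc_coupled_composition:
            return codon_model_aa_frequencies(gc3[genome_ids.index(g)])
        return cold_q if g in cold else warm_q

    def draw_length() -> int:
        # Narrow length spread with a hard floor: at a strict E-value cutoff,
        # very short proteins are undetectable regardless of conservation, so
        # a generator whose planted truth must be identifiable avoids them.
        mean = config.mean_protein_len
        length = int(round(rng.normal(mean, mean / 8.0)))
        return max(config.min_protein_len, length)

    baseline_arr = _freq_array(baseline)

    # planted family layout: (family id, member genome ids, truth label)
    hierarchy = [frozenset(genome_ids[:size]) for size in config.hierarchy_sizes]
    families: list[tuple[str, list[str], str]] = []
    for k, (level, n_fam) in enumerate(zip(hierarchy, config.families_per_level)):
        label = "CDS_c" if k == 0 else f"CDS_{len(level)}"
        members = sorted(level)
        for i in range(n_fam):
            families.append((f"fam_L{k}_{i:04d}", members, label))
    for g in genome_ids:
        for i in range(config.private_families):
            families.append((f"fam_P_{g}_{i:03d}", [g], "CDS_1"))

    cds: list[CDSRecord] = []
    partition_truth: dict[str, str] = {}
    origin_truth: dict[str, tuple[str, str | None]] = {}

    per_genome: dict[str, list[CDSRecord]] = {g: [] for g in genome_ids}
    for fam_id, members, label in families:
        length = draw_length()
        ancestor = _sample_protein(length, baseline_arr, rng)
        for g in members:
            if config.gc_coupled_composition:
                aa = _sample_protein(length, _freq_array(genome_target(g)), rng)
            else:
                aa = mutate_family(ancestor, config.divergence, genome_target(g), rng)
            nt = reverse_translate(aa, gc3[genome_ids.index(g)], rng)
            cid = f"{g}|{fam_id}"
            per_genome[g].append(CDSRecord(cds_id=cid, genome_id=g, nt_seq=nt, aa_seq=aa))
            partition_truth[cid] = label
            origin_truth[cid] = ("vertical", None)

    # foreign donors and planted transfers
    donor_cds: dict[str, list[CDSRecord]] = {d.genome_id: [] for d in config.donors}
    for g in genome_ids:
        for i in range(config.n_hgt):
            donor = config.donors[i % len(config.donors)]
            fam_id = f"fam_H_{g}_{i:03d}"
            length = draw_length()
            donor_ancestor = _sample_protein(length, baseline_arr, rng)
            donor_aa = mutate_family(donor_ancestor, config.hgt_divergence, baseline, rng)
            donor_nt = reverse_translate(donor_aa, 0.5, rng)
            did = f"{donor.genome_id}|{fam_id}"
            donor_cds[donor.genome_id].append(
                CDSRecord(cds_id=did, genome_id=donor.genome_id, nt_seq=donor_nt, aa_seq=donor_aa)
            )
            origin_truth[did] = ("vertical", None)
            recipient_aa = mutate_family(donor_ancestor, config.hgt_divergence, baseline, rng)
            recipient_nt = reverse_translate(recipient_aa, gc3[genome_ids.index(g)], rng)
            cid = f"{g}|{fam_id}"
            per_genome[g].append(
                CDSRecord(cds_id=cid, genome_id=g, nt_seq=recipient_nt, aa_seq=recipient_aa)
            )
            partition_truth[cid] = "CDS_1"
            origin_truth[cid] = ("hgt", donor.genome_id)

    metas = [
        GenomeMeta(
            genome_id=g,
            taxon_label=f"Strain {g}",
            habitat="cold" if g in cold else "warm",
            lineage_tags=NATIVE_TAGS,
            groups=tuple(f"level{k}" for k, level in enumerate(hierarchy) if g in level),
        )
        for g in genome_ids
    ]
    if config.n_hgt > 0:
        metas += [
            GenomeMeta(
                genome_id=d.genome_id,
                taxon_label=d.taxon_label,
                habitat=d.habitat,
                lineage_tags=d.lineage_tags,
                groups=("donor_panel",),
            )
            for d in config.donors
        ]

    for g in genome_ids:
        cds.extend(per_genome[g])
    if config.n_hgt > 0:
        for d in config.donors:
            cds.extend(donor_cds[d.genome_id])

    collection = GenomeCollection(metas=metas, cds=cds, hierarchy=list(hierarchy))
    truth = TruthTables(
        partition=partition_truth,
        origin=origin_truth,
        genome_gc3={g: gc3[genome_ids.index(g)] for g in genome_ids},
        habitat={m.genome_id: m.habitat for m in metas},
    )
    return collection, truth


def write_collection(
    collection: GenomeCollection, truth: TruthTables, outdir
) -> None:
    """Emit per-genome protein and CDS FASTA, the metadata table, and the
    truth tables, all as plain text."""
    from pathlib import Path

    from . import genome_io

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for g in collection.genome_ids():
        records = collection.cds_of(g)
        genome_io.write_fasta([(c.cds_id, c.aa_seq) for c in records], out / f"{g}.faa")
        genome_io.write_fasta([(c.cds_id, c.nt_seq) for c in records], out / f"{g}.fna")
    genome_io.write_metadata(collection.metas, out / "metadata.tsv")
    pd.DataFrame(
        {
            "cds_id": list(truth.partition),
            "label": list(truth.partition.values()),
        }
    ).to_csv(out / "truth_partition.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "cds_id": list(truth.origin),
            "origin": [o for o, _ in truth.origin.values()],
            "donor": [d if d else "" for _, d in truth.origin.values()],
        }
    ).to_csv(out / "truth_origin.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "genome_id": list(truth.genome_gc3),
            "gc3_target": list(truth.genome_gc3.values()),
            "habitat": [truth.habitat[g] for g in truth.genome_gc3],
        }
    ).to_csv(out / "truth_genomes.tsv", sep="\t", index=False)
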