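"""End-to-end orchestration: simulate/load -> hits -> RBH -> partition ->
HGT -> composition -> contrasts (-> phylogeny), driven by one structured
config with a single seed.

Stage outputs are pure functions of declared inputs plus config: a rerun
with the same config writes byte-identical reports. Hit tables are computed
for the focal genome against every other genome in the collection (the
per-focal-genome design of the underlying methodology); externally supplied
hit tables bypass the built-in aligner entirely.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import genome_io
from .genome_io import GenomeCollection, HitRecord
from .similarity import EvalueParams, all_vs_all_pair
from .ortholog_sets import (
    conservation_table,
    nested_partition,
    reciprocal_best_hits,
)
from .hgt_classify import (
    ExclusionCase,
    ExclusionConfig,
    classify_collection,
    donor_summary,
)
from .composition_stats import composition_table, group_compare, gc_aa_correlation
from .phylo import bootstrap_support
from .synthetic_data import SimConfig, simulate_collection, write_collection

__all__ = [
    "ConfigError",
    "PipelineConfig",
    "default_exclusion_cases",
    "load_collection",
    "compute_pair_hits",
    "run_pipeline",
]

log = logging.getLogger("psychrocomp")


class ConfigError(ValueError):
    """Invalid pipeline configuration (exit code 1 in the CLI)."""


@dataclass
class PipelineConfig:
    """All knobs for one pipeline run.

    Exactly one of ``simulate`` (a SimConfig) or ``input_dir`` (a directory
    holding metadata.tsv plus per-genome .faa/.fna) must be set; likewise the
    built-in aligner parameters are ignored when ``external_hits_dir`` is
    given.
    """

    workdir: str = "pipeline_out"
    seed: int = 0
    simulate: SimConfig | None = None
    input_dir: str | None = None
    hierarchy: list[list[str]] | None = None  # required when loading from files
    focal: str | None = None  # default: first genome of the innermost level
    cutoff: float = 1e-20
    aligner: EvalueParams = field(default_factory=EvalueParams)
    external_hits_dir: str | None = None
    genus_tag: str = "Shewanella"
    outer_scope_tags: tuple[str, ...] = ("marine-gamma", "gamma")
    exclusion_cases: list[ExclusionCase] | None = None
    contrast_scope: str | None = "total"  # None disables the group contrast
    gc_correlation: bool = False
    conservation: str = "none"  # none | inner
    phylo_alignment: str | None = None
    bootstrap_reps: int = 100
    run_hgt: bool = True

    def validate(self) -> None:
        if (self.simulate is None) == (self.input_dir is None):
            raise ConfigError("exactly one of simulate/input_dir must be set")
        if self.cutoff <= 0:
            raise ConfigError("cutoff must be positive")
        if self.input_dir is not None and not self.hierarchy:
            raise ConfigError("hierarchy is required when loading from files")
        if self.contrast_scope not in (None, "total", "core"):
            raise ConfigError("contrast_scope must be null, 'total' or 'core'")
        if self.conservation not in ("none", "inner"):
            raise ConfigError("conservation must be 'none' or 'inner'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        if "simulate" in raw and raw["simulate"] is not None:
            sim = dict(raw["simulate"])
            for key in ("hierarchy_sizes", "families_per_level", "gc3_targets",
                        "cold_genomes"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(sim[key])
            raw["simulate"] = SimConfig(**sim)
        if "aligner" in raw and raw["aligner"] is not None:
            raw["aligner"] = EvalueParams(**raw["aligner"])
        if "outer_scope_tags" in raw:
            raw["outer_scope_tags"] = tuple(raw["outer_scope_tags"])
        if "exclusion_cases" in raw and raw["exclusion_cases"] is not None:
            raw["exclusion_cases"] = [
                ExclusionCase(
                    name=c["name"],
                    exclude=frozenset(c["exclude"]),
                    scope_tags=frozenset(c["scope_tags"]),
                )
                for c in raw["exclusion_cases"]
            ]
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc


def default_exclusion_cases(
    collection: GenomeCollection,
    focal: str,
    genus_tag: str,
    outer_scope_tags: tuple[str, ...],
) -> ExclusionConfig:
    """The two-case lateral-transfer rule, derived from the hierarchy.

    Case-1 sub-variants exclude progressively larger sets of close relatives
    (each inner hierarchy level minus the focal genome) and ask whether the
    top match stays within the genus; case 2 excludes the whole genus and
    asks whether the top match stays within the broader marine lineage. The
    focal genome itself is always excluded.
    """
    cases: list[ExclusionCase] = []
    inner_levels = list(collection.hierarchy[1:])[::-1]  # innermost first
    for idx, level in enumerate(inner_levels, start=1):
        cases.append(
            ExclusionCase(
                name=f"case1{chr(96 + idx)}",
                exclude=frozenset((level - {focal}) | {focal}),
                scope_tags=frozenset([genus_tag]),
            )
        )
    cases.append(
        ExclusionCase(
            name="case2",
            exclude=frozenset([genus_tag]),
            scope_tags=frozenset(outer_scope_tags),
        )
    )
    return ExclusionConfig(cases=tuple(cases))


def load_collection(
    input_dir: str | Path, hierarchy: list[list[str]]
) -> GenomeCollection:
    """Read metadata.tsv and per-genome <id>.faa / <id>.fna FASTA files."""
    indir = Path(input_dir)
    metas = genome_io.read_metadata(indir / "metadata.tsv")
    cds: list[genome_io.CDSRecord] = []
    for m in metas:
        faa = indir / f"{m.genome_id}.faa"
        fna = indir / f"{m.genome_id}.fna"
        proteins = dict(genome_io.read_fasta(faa, kind="protein"))
        nts = dict(genome_io.read_fasta(fna, kind="dna")) if fna.exists() else {}
        for cid, aa in proteins.items():
            cds.append(
                genome_io.CDSRecord(
                    cds_id=cid, genome_id=m.genome_id,
                    nt_seq=nts.get(cid, ""), aa_seq=aa,
                )
            )
    return GenomeCollection(
        metas=metas, cds=cds, hierarchy=[frozenset(h) for h in hierarchy]
    )


def _hit_path(workdir: Path, a: str, b: str) -> Path:
    return workdir / "hits" / f"{a}__{b}.tsv"


def compute_pair_hits(
    collection: GenomeCollection,
    pairs: list[tuple[str, str]],
    config: PipelineConfig,
    workdir: Path,
) -> dict[tuple[str, str], list[HitRecord]]:
    """Hit tables for the given unordered genome pairs (both directions),
    from the built-in aligner or an external hit directory."""
    (workdir / "hits").mkdir(parents=True, exist_ok=True)
    hits: dict[tuple[str, str], list[HitRecord]] = {}
    for a, b in pairs:
        if config.external_hits_dir is not None:
            ext = Path(config.external_hits_dir)
            hits[(a, b)] = genome_io.read_hit_table(ext / f"{a}__{b}.tsv")
            hits[(b, a)] = genome_io.read_hit_table(ext / f"{b}__{a}.tsv")
        else:
            ab, ba = all_vs_all_pair(
                collection.cds_of(a), collection.cds_of(b),
                params=config.aligner, cutoff=config.cutoff,
            )
            hits[(a, b)] = ab
            hits[(b, a)] = ba
        genome_io.write_hit_table(hits[(a, b)], _hit_path(workdir, a, b))
        genome_io.write_hit_table(hits[(b, a)], _hit_path(workdir, b, a))
        log.info("hits %s~%s: %d / %d", a, b, len(hits[(a, b)]), len(hits[(b, a)]))
    return hits


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns the in-memory report bundle.

    Writes, under the workdir: the simulated inputs (when simulating), all
    hit tables, the partition and its summary, origin calls and donor
    summary, composition and contrast tables, the conservation matrix and
    the bootstrap tree when requested, plus a run log with per-stage counts.
    """
    config.validate()
    workdir = Path(config.workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(workdir / "pipeline.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    results: dict = {}
    try:
        log.info("seed=%d cutoff=%g", config.seed, config.cutoff)

        # --- stage: inputs
        if config.simulate is not None:
            sim = config.simulate
            if sim.seed != config.seed:
                sim = dataclasses.replace(sim, seed=config.seed)
            collection, truth = simulate_collection(sim)
            write_collection(collection, truth, workdir / "inputs")
            results["truth"] = truth
        else:
            collection = load_collection(config.input_dir, config.hierarchy)
        results["collection"] = collection
        log.info("collection: %d genomes, %d CDS",
                 len(collection.metas), len(collection.cds))

        focal = config.focal or sorted(collection.hierarchy[-1])[0]
        if focal not in {m.genome_id for m in collection.metas}:
            raise ConfigError(f"unknown focal genome {focal!r}")
        results["focal"] = focal

        # --- stage: hits (focal against every other genome, both directions)
        others = [g for g in collection.genome_ids() if g != focal]
        hits = compute_pair_hits(
            collection, [(focal, g) for g in others], config, workdir
        )

        # --- stage: RBH + partition
        panel_genomes = collection.hierarchy[0]
        rbh = {
            g: reciprocal_best_hits(
                hits[(focal, g)], hits[(g, focal)], genome_a=focal, genome_b=g
            )
            for g in sorted(panel_genomes - {focal})
        }
        partition = nested_partition(collection, rbh, focal)
        results["partition"] = partition
        genome_io.write_report_table(partition.to_frame(), workdir / "partition.tsv")
        genome_io.write_report_table(partition.summary(), workdir / "partition_summary.tsv")
        log.info("partition: %s", partition.counts())

        # --- stage: conservation matrix (optional)
        if config.conservation == "inner":
            inner = sorted(
                collection.hierarchy[1]
                if len(collection.hierarchy) > 1
                else collection.hierarchy[0]
            )
            need = [
                (a, b)
                for i, a in enumerate(inner)
                for b in inner[i + 1 :]
                if focal not in (a, b)
            ]
            hits.update(compute_pair_hits(collection, need, config, workdir))
            cons = conservation_table(collection, hits, genome_ids=inner,
                                      cutoff=config.cutoff)
            results["conservation"] = cons
            genome_io.write_report_table(cons, workdir / "conservation.tsv")

        # --- stage: HGT classification
        if config.run_hgt:
            panel = {m.genome_id: m for m in collection.metas}
            subject_genome = {c.cds_id: c.genome_id for c in collection.cds}
            exclusions = (
                ExclusionConfig(cases=tuple(config.exclusion_cases))
                if config.exclusion_cases
                else default_exclusion_cases(
                    collection, focal, config.genus_tag, config.outer_scope_tags
                )
            )
            pooled = [h for g in others for h in hits[(focal, g)]]
            calls = classify_collection(
                [c.cds_id for c in collection.cds_of(focal)],
                pooled, subject_genome, exclusions, panel,
            )
            results["origin_calls"] = calls
            calls_df = pd.DataFrame(
                [
                    {
                        "cds_id": c.cds_id, "label": c.label,
                        "case": c.case or "", "donor_genome": c.donor_genome or "",
                        "donor_taxon": c.donor_taxon or "",
                    }
                    for c in calls
                ]
            )
            genome_io.write_report_table(calls_df, workdir / "origin_calls.tsv")
            donors = donor_summary(calls, panel)
            results["donor_summary"] = donors
            genome_io.write_report_table(donors, workdir / "donor_summary.tsv")
            n_lateral = sum(1 for c in calls if c.label == "lateral")
            log.info("origin calls: %d lateral of %d", n_lateral, len(calls))

        # --- stage: composition and contrasts (hierarchy genomes only)
        natives = collection.hierarchy[0]
        sub = GenomeCollection(
            metas=[m for m in collection.metas if m.genome_id in natives],
            cds=[c for c in collection.cds if c.genome_id in natives],
            hierarchy=list(collection.hierarchy),
        )
        compo = composition_table(sub)
        results["composition"] = compo
        genome_io.write_report_table(compo.reset_index(), workdir / "composition.tsv")
        if config.contrast_scope is not None:
            core_map = None
            if config.contrast_scope == "core":
                core_ids = {c for c, lab in partition.labels.items() if lab == "CDS_c"}
                core_map = {focal: set(core_ids)}
                for g, pairset in rbh.items():
                    fwd = pairset.a_to_b()
                    core_map[g] = {fwd[c] for c in core_ids if c in fwd}
            contrast = group_compare(
                sub, scope="total" if config.contrast_scope == "total" else "core",
                core_map=core_map,
            )
            results["contrast"] = contrast
            genome_io.write_report_table(contrast, workdir / "contrast.tsv")
        if config.gc_correlation:
            corr = gc_aa_correlation(sub)
            results["gc_correlation"] = corr
            genome_io.write_report_table(corr, workdir / "gc_correlation.tsv")

        # --- stage: phylogeny (optional)
        if config.phylo_alignment is not None:
            seqs = dict(genome_io.read_fasta(config.phylo_alignment, kind="dna-aligned"))
            tree = bootstrap_support(
                seqs, n_reps=config.bootstrap_reps, seed=config.seed
            )
            results["tree"] = tree
            (workdir / "tree.nwk").write_text(tree.newick(include_support=True) + "\n")

        log.info("pipeline complete")
        return results
    finally:
        log.removeHandler(handler)
        handler.close()
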