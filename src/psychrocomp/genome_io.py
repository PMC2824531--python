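"""On-disk artifacts: FASTA, metadata tables, 12-column hit tables, report tables.

All tabular interchange is tab-separated text. Coordinates in hit records are
1-based inclusive (the tabular-search convention); everything in memory is
0-based half-open.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio.Data import CodonTable

__all__ = [
    "CDSRecord",
    "GenomeMeta",
    "GenomeCollection",
    "HitRecord",
    "FastaParseError",
    "TranslationError",
    "read_fasta",
    "write_fasta",
    "translate_cds",
    "read_hit_table",
    "write_hit_table",
    "read_metadata",
    "write_metadata",
    "read_report_table",
    "write_report_table",
]

DNA_ALPHABET = frozenset("ACGTN")
ALIGNED_DNA_ALPHABET = DNA_ALPHABET | {"-"}
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")

_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_STANDARD_TABLE.forward_table)
STOP_CODONS: frozenset[str] = frozenset(_STANDARD_TABLE.stop_codons)


class FastaParseError(ValueError):
    pass


class TranslationError(ValueError):
    pass


@dataclass(frozen=True)
class CDSRecord:
    """One protein-coding gene: nucleotide span and its protein product."""

    cds_id: str
    genome_id: str
    nt_seq: str = ""
    aa_seq: str = ""

    def __post_init__(self) -> None:
        if self.nt_seq and self.aa_seq:
            n, m = len(self.nt_seq), len(self.aa_seq)
            if n not in (3 * m, 3 * (m + 1)):
                raise ValueError(
                    f"{self.cds_id}: nt length {n} inconsistent with aa length {m} "
                    "(expected 3*aa or 3*(aa+1))"
                )


@dataclass(frozen=True)
class GenomeMeta:
    """Strain-level metadata driving grouping, lineage scoping and contrasts.

    ``lineage_tags`` are free-form lineage memberships (e.g. "Shewanella",
    "marine-gamma", "gamma"); HGT scoping resolves against these, never
    against taxon-name parsing.
    """

    genome_id: str
    taxon_label: str = ""
    habitat: str = "unlabeled"  # cold | warm | unlabeled
    lineage_tags: tuple[str, ...] = ()
    groups: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.habitat not in ("cold", "warm", "unlabeled"):
            raise ValueError(f"invalid habitat {self.habitat!r}")
        object.__setattr__(self, "lineage_tags", tuple(self.lineage_tags))
        object.__setattr__(self, "groups", tuple(self.groups))


@dataclass
class GenomeCollection:
    """Genomes + metadata + proteomes: the universal pipeline input.

    ``hierarchy`` is an ordered list of genome-id sets, outermost first
    (e.g. [all strains, the obligate-marine four, the focal pair]); each set
    must be a strict subset of the previous one.
    """

    metas: list[GenomeMeta]
    cds: list[CDSRecord]
    hierarchy: list[frozenset[str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        known = {m.genome_id for m in self.metas}
        if len(known) != len(self.metas):
            raise ValueError("duplicate genome_id in metas")
        seen: set[str] = set()
        for rec in self.cds:
            if rec.genome_id not in known:
                raise ValueError(f"CDS {rec.cds_id} references unknown genome {rec.genome_id}")
            if rec.cds_id in seen:
                raise ValueError(f"duplicate cds_id {rec.cds_id}")
            seen.add(rec.cds_id)
        self.hierarchy = [frozenset(s) for s in self.hierarchy]
        prev: frozenset[str] | None = None
        for level in self.hierarchy:
            if not level <= known:
                raise ValueError("hierarchy set contains unknown genome ids")
            if prev is not None and not (level < prev):
                raise ValueError("hierarchy sets must be strictly nested")
            prev = level

    def meta(self, genome_id: str) -> GenomeMeta:
        for m in self.metas:
            if m.genome_id == genome_id:
                return m
        raise KeyError(genome_id)

    def genome_ids(self) -> list[str]:
        return [m.genome_id for m in self.metas]

    def cds_of(self, genome_id: str) -> list[CDSRecord]:
        return [c for c in self.cds if c.genome_id == genome_id]

    def cds_by_id(self) -> dict[str, CDSRecord]:
        return {c.cds_id: c for c in self.cds}


@dataclass(frozen=True)
class HitRecord:
    """One protein similarity match in the 12-column tabular dialect."""

    query_id: str
    subject_id: str
    pident: float
    aln_len: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if self.evalue < 0:
            raise ValueError("evalue must be non-negative")
        if self.qstart > self.qend or self.sstart > self.send:
            raise ValueError("alignment spans must satisfy start <= end")
        if not math.isfinite(self.bitscore):
            raise ValueError("bitscore must be finite")


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str | Path, kind: str) -> list[tuple[str, str]]:
    """Read a FASTA file, returning ``[(id, seq), ...]`` in file order.

    Ids are the first whitespace token of each header; sequences are
    uppercased and validated against the declared alphabet (``dna``,
    ``dna-aligned`` which additionally allows gaps, or ``protein``).
    Duplicate ids are a hard error: the partition logic
    requires global uniqueness and silent de-duplication corrupts set sizes.
    """
    alphabets = {
        "dna": DNA_ALPHABET,
        "dna-aligned": ALIGNED_DNA_ALPHABET,
        "protein": PROTEIN_ALPHABET,
    }
    if kind not in alphabets:
        raise ValueError(f"kind must be one of {sorted(alphabets)}, got {kind!r}")
    alphabet = alphabets[kind]
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    current_id: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if current_id is not None:
            records.append((current_id, "".join(chunks)))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                header = line[1:].strip()
                if not header:
                    raise FastaParseError(f"{path}: empty header at line {lineno}")
                current_id = header.split()[0]
                if current_id in seen:
                    raise FastaParseError(
                        f"{path}: duplicate id {current_id!r} at line {lineno}"
                    )
                seen.add(current_id)
                chunks = []
            else:
                if current_id is None:
                    raise FastaParseError(
                        f"{path}: sequence before first header at line {lineno}"
                    )
                seq = line.upper()
                bad = sorted(set(seq) - alphabet)
                if bad:
                    raise FastaParseError(
                        f"{path}: illegal {kind} residue(s) {''.join(bad)!r} at line {lineno}"
                    )
                chunks.append(seq)
    flush()
    return records


def write_fasta(records: list[tuple[str, str]], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Translation


def translate_cds(nt_seq: str) -> str:
    """Plain codon translation under the standard genetic code.

    No alternative-start handling; a trailing stop codon is stripped; an
    internal stop codon is an error; any codon containing N translates to X.
    """
    n = len(nt_seq)
    if n % 3 != 0:
        raise TranslationError(f"sequence length {n} not divisible by 3")
    seq = nt_seq.upper()
    bad = sorted(set(seq) - DNA_ALPHABET)
    if bad:
        raise TranslationError(f"illegal nucleotide(s) {''.join(bad)!r}")
    ncodons = n // 3
    out: list[str] = []
    for i in range(ncodons):
        codon = seq[3 * i : 3 * i + 3]
        if "N" in codon:
            out.append("X")
        elif codon in STOP_CODONS:
            if i == ncodons - 1:
                break  # terminal stop stripped
            raise TranslationError(f"internal stop codon {codon} at codon index {i}")
        else:
            out.append(CODON_TO_AA[codon])
    return "".join(out)


# ---------------------------------------------------------------------------
# 12-column hit tables (qseqid sseqid pident length mismatch gapopen
#                       qstart qend sstart send evalue bitscore)

_HIT_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


def read_hit_table(path: str | Path) -> list[HitRecord]:
    """Parse a 12-column tab-separated hit file; '#' comment lines allowed.

    Extra or missing columns are rejected (not ignored) to catch format drift.
    """
    hits: list[HitRecord] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} columns, expected 12"
                )
            try:
                hits.append(
                    HitRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        pident=float(fields[2]),
                        aln_len=int(fields[3]),
                        mismatches=int(fields[4]),
                        gap_opens=int(fields[5]),
                        qstart=int(fields[6]),
                        qend=int(fields[7]),
                        sstart=int(fields[8]),
                        send=int(fields[9]),
                        evalue=float(fields[10]),
                        bitscore=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def write_hit_table(hits: list[HitRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.pident:.2f}",
                        str(h.aln_len),
                        str(h.mismatches),
                        str(h.gap_opens),
                        str(h.qstart),
                        str(h.qend),
                        str(h.sstart),
                        str(h.send),
                        f"{h.evalue:.2e}",
                        f"{h.bitscore:.1f}",
                    ]
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Metadata tables


def read_metadata(path: str | Path) -> list[GenomeMeta]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = ["genome_id", "taxon_label", "habitat", "lineage_tags", "groups"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata columns {missing}")
    metas = []
    for row in df.itertuples(index=False):
        metas.append(
            GenomeMeta(
                genome_id=row.genome_id,
                taxon_label=row.taxon_label,
                habitat=row.habitat or "unlabeled",
                lineage_tags=tuple(t for t in row.lineage_tags.split(",") if t),
                groups=tuple(g for g in row.groups.split(",") if g),
            )
        )
    return metas


def write_metadata(metas: list[GenomeMeta], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "genome_id": [m.genome_id for m in metas],
            "taxon_label": [m.taxon_label for m in metas],
            "habitat": [m.habitat for m in metas],
            "lineage_tags": [",".join(m.lineage_tags) for m in metas],
            "groups": [",".join(m.groups) for m in metas],
        }
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Report tables

def _format_value(col: str, value) -> str:
    name = str(col).lower()
    if isinstance(value, float):
        if "evalue" in name:
            return f"{value:.2e}"
        if name == "p" or name.endswith("_p") or name.startswith("p_"):
            return f"{value:.2f}"
        if "percent" in name or "pct" in name:
            return f"{value:.1f}"
        return repr(value)
    return str(value)


def write_report_table(table: pd.DataFrame, path: str | Path) -> None:
    """Write a named-column table as TSV with fixed printed precision.

    Percentages render with 1 decimal, p-values with 2, E-values in
    scientific notation; other floats round-trip exactly (repr). The output
    is readable back with :func:`read_report_table`.
    """
    if table.columns.isnull().any():
        raise ValueError("report table must have named columns")
    with open(path, "w") as fh:
        fh.write("\t".join(str(c) for c in table.columns) + "\n")
        for row in table.itertuples(index=False):
            fh.write(
                "\t".join(_format_value(col, v) for col, v in zip(table.columns, row))
                + "\n"
            )


def read_report_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
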