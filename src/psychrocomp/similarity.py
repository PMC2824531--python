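"""All-vs-all protein similarity at desk scale.

A dynamic-programming local aligner (affine gaps over BLOSUM62) with a
Karlin–Altschul E-value model, producing the same 12-column hit records an
external search tool would. Externally supplied hit tables bypass this module
entirely; the pipeline never mixes the two for one genome pair.

The E-value uses the ungapped-style constants K and lambda applied to gapped
scores — a documented approximation; only the thresholding behaviour at the
configured cutoff matters downstream, not calibrated E-values.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices
from numba import njit

from .genome_io import CDSRecord, HitRecord

__all__ = [
    "AlignmentResult",
    "EvalueParams",
    "DEFAULT_PARAMS",
    "local_align",
    "evalue",
    "all_vs_all",
    "best_hit",
    "hit_sort_key",
]

# Aligner alphabet: 20 canonical residues + X. X scores as the worst-case
# substitution (column minimum), so it can never create spurious similarity.
ALPHABET = "ACDEFGHIKLMNPQRSTVWYX"
_AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}


@dataclass(frozen=True)
class EvalueParams:
    """Score model: substitution matrix, affine gap costs, K and lambda.

    A gap of length k costs ``gap_open + k * gap_extend`` (the convention of
    the common search tools). ``lam`` is in nats per raw-score unit.
    """

    K: float = 0.041
    lam: float = 0.267
    gap_open: int = 11
    gap_extend: int = 1
    matrix_name: str = "BLOSUM62"

    def __post_init__(self) -> None:
        if self.K <= 0 or self.lam <= 0:
            raise ValueError("K and lambda must be positive")
        if self.gap_open <= 0 or self.gap_extend <= 0:
            raise ValueError("gap penalties must be positive integers")


DEFAULT_PARAMS = EvalueParams()


@dataclass(frozen=True)
class AlignmentResult:
    """Optimal local alignment: raw score, normalized score, identity, spans.

    Spans are 1-based inclusive; a score-0 alignment has empty spans
    (qstart == qend + 1 convention is avoided by reporting zeros).
    """

    raw_score: int
    bitscore: float
    pident: float
    aln_len: int
    matches: int
    mismatches: int
    gap_opens: int
    qstart: int
    qend: int
    sstart: int
    send: int


@lru_cache(maxsize=4)
def score_matrix(matrix_name: str = "BLOSUM62") -> np.ndarray:
    """Integer substitution matrix over ALPHABET; X = column-wise worst case."""
    blosum = substitution_matrices.load(matrix_name)
    n = len(ALPHABET)
    mat = np.zeros((n, n), dtype=np.int32)
    canonical = ALPHABET[:-1]
    for i, a in enumerate(canonical):
        for j, b in enumerate(canonical):
            mat[i, j] = int(blosum[a, b])
    worst = mat[: n - 1, : n - 1].min(axis=0)
    mat[n - 1, : n - 1] = worst
    mat[: n - 1, n - 1] = worst
    mat[n - 1, n - 1] = mat[: n - 1, : n - 1].min()
    return mat


def encode(seq: str) -> np.ndarray:
    try:
        return np.fromiter((_AA_INDEX[c] for c in seq), dtype=np.int8, count=len(seq))
    except KeyError as exc:
        raise ValueError(f"non-alignable residue {exc.args[0]!r}") from exc


@njit(cache=True)
def _sw_score(a, b, mat, gap_open, gap_extend):  # pragma: no cover - numba
    """Score-only affine Smith–Waterman; returns the optimal local score."""
    m, n = a.shape[0], b.shape[0]
    H = np.zeros(n + 1, dtype=np.int32)
    E = np.zeros(n + 1, dtype=np.int32)
    best = 0
    for i in range(1, m + 1):
        diag = 0  # H[i-1, j-1]
        F = 0
        ai = a[i - 1]
        for j in range(1, n + 1):
            up = H[j]
            e = E[j] - gap_extend
            t = up - gap_open - gap_extend
            if t > e:
                e = t
            E[j] = e
            f = F - gap_extend
            t = H[j - 1] - gap_open - gap_extend
            if t > f:
                f = t
            F = f
            h = diag + mat[ai, b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            diag = up
            H[j] = h
            if h > best:
                best = h
    return best


@njit(cache=True)
def _sw_full(a, b, mat, gap_open, gap_extend):  # pragma: no cover - numba
    """Full affine Smith–Waterman with deterministic traceback.

    Tie rule: the alignment endpoint is the cell with maximal score and
    smallest (i, j); during traceback, diagonal beats gap-in-query beats
    gap-in-subject. Returns
    (score, qstart, qend, sstart, send, matches, mismatches, gap_opens, aln_len)
    with 1-based inclusive spans (zeros for an empty alignment).
    """
    m, n = a.shape[0], b.shape[0]
    H = np.zeros((m + 1, n + 1), dtype=np.int32)
    E = np.zeros((m + 1, n + 1), dtype=np.int32)
    F = np.zeros((m + 1, n + 1), dtype=np.int32)
    best = 0
    bi = 0
    bj = 0
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e = E[i - 1, j] - gap_extend
            t = H[i - 1, j] - gap_open - gap_extend
            if t > e:
                e = t
            E[i, j] = e
            f = F[i, j - 1] - gap_extend
            t = H[i, j - 1] - gap_open - gap_extend
            if t > f:
                f = t
            F[i, j] = f
            h = H[i - 1, j - 1] + mat[a[i - 1], b[j - 1]]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0:
                h = 0
            H[i, j] = h
            if h > best:
                best = h
                bi = i
                bj = j
    if best == 0:
        return 0, 0, 0, 0, 0, 0, 0, 0, 0
    # traceback
    i, j = bi, bj
    matches = 0
    mismatches = 0
    gap_opens = 0
    aln_len = 0
    state = 0  # 0 = in H, 1 = in E (gap in subject / up), 2 = in F (gap in query / left)
    while H[i, j] != 0 or state != 0:
        if state == 0:
            h = H[i, j]
            diag = H[i - 1, j - 1] + mat[a[i - 1], b[j - 1]]
            if h == diag:
                aln_len += 1
                if a[i - 1] == b[j - 1]:
                    matches += 1
                else:
                    mismatches += 1
                i -= 1
                j -= 1
            elif h == E[i, j]:
                state = 1
            else:
                state = 2
        elif state == 1:
            aln_len += 1
            if E[i, j] == H[i - 1, j] - gap_open - gap_extend:
                gap_opens += 1
                state = 0
            elif E[i, j] == E[i - 1, j] - gap_extend:
                pass
            else:
                gap_opens += 1
                state = 0
            i -= 1
        else:
            aln_len += 1
            if F[i, j] == H[i, j - 1] - gap_open - gap_extend:
                gap_opens += 1
                state = 0
            elif F[i, j] == F[i, j - 1] - gap_extend:
                pass
            else:
                gap_opens += 1
                state = 0
            j -= 1
    return best, i + 1, bi, j + 1, bj, matches, mismatches, gap_opens, aln_len


@njit(cache=True)
def _sw_score_block(qcat, qoff, scat, soff, mat, gap_open, gap_extend):  # pragma: no cover
    """Score every query against every subject; sequences are concatenated
    with offset arrays (CSR style). Returns an int32 (nq, ns) score matrix."""
    nq = qoff.shape[0] - 1
    ns = soff.shape[0] - 1
    out = np.zeros((nq, ns), dtype=np.int32)
    for qi in range(nq):
        a = qcat[qoff[qi] : qoff[qi + 1]]
        for si in range(ns):
            b = scat[soff[si] : soff[si + 1]]
            out[qi, si] = _sw_score(a, b, mat, gap_open, gap_extend)
    return out


def local_align(a: str, b: str, params: EvalueParams = DEFAULT_PARAMS) -> AlignmentResult:
    """Optimal local alignment of two protein sequences.

    Deterministic: ties in endpoint choice and traceback are broken by a
    fixed rule (smallest endpoint, diagonal-first), so repeated runs give
    byte-identical output.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    mat = score_matrix(params.matrix_name)
    ea, eb = encode(a), encode(b)
    (score, qs, qe, ss, se, matches, mismatches, gap_opens, aln_len) = _sw_full(
        ea, eb, mat, params.gap_open, params.gap_extend
    )
    pident = 100.0 * matches / aln_len if aln_len else 0.0
    return AlignmentResult(
        raw_score=int(score),
        bitscore=bitscore(int(score), params),
        pident=pident,
        aln_len=int(aln_len),
        matches=int(matches),
        mismatches=int(mismatches),
        gap_opens=int(gap_opens),
        qstart=int(qs),
        qend=int(qe),
        sstart=int(ss),
        send=int(se),
    )


def bitscore(raw_score: int, params: EvalueParams = DEFAULT_PARAMS) -> float:
    return (params.lam * raw_score - np.log(params.K)) / np.log(2.0)


def evalue(
    raw_score: int, m: int, n: int, params: EvalueParams = DEFAULT_PARAMS
) -> float:
    """Karlin–Altschul expectation: E = K * m * n * exp(-lambda * S)."""
    if m < 1 or n < 1:
        raise ValueError("m and n must be >= 1")
    return float(params.K * m * n * np.exp(-params.lam * raw_score))


def hit_sort_key(h: HitRecord) -> tuple:
    """Canonical hit ordering: ascending E, then descending bitscore, then id."""
    return (h.evalue, -h.bitscore, h.subject_id)


def all_vs_all(
    queries: list[CDSRecord],
    subjects: list[CDSRecord],
    params: EvalueParams = DEFAULT_PARAMS,
    cutoff: float = 1e-20,
) -> list[HitRecord]:
    """Align every query protein against every subject protein.

    Returns one HitRecord per pair with E <= cutoff; self-pairs (identical
    cds_id) are excluded. Hits are grouped by query in input order and sorted
    per query by ascending E, then descending bitscore, then subject id.

    Scores are computed in a vectorized scan; the full traceback (identity,
    spans) is only run for the pairs that pass the cutoff.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not queries or not subjects:
        return []
    mat = score_matrix(params.matrix_name)
    qseqs = [encode(c.aa_seq) for c in queries]
    sseqs = [encode(c.aa_seq) for c in subjects]
    qcat = np.concatenate(qseqs) if qseqs else np.empty(0, dtype=np.int8)
    scat = np.concatenate(sseqs) if sseqs else np.empty(0, dtype=np.int8)
    qoff = np.zeros(len(qseqs) + 1, dtype=np.int64)
    np.cumsum([len(s) for s in qseqs], out=qoff[1:])
    soff = np.zeros(len(sseqs) + 1, dtype=np.int64)
    np.cumsum([len(s) for s in sseqs], out=soff[1:])
    scores = _sw_score_block(qcat, qoff, scat, soff, mat, params.gap_open, params.gap_extend)

    n_total = int(soff[-1])  # search-space size: all subject residues
    hits: list[HitRecord] = []
    for qi, q in enumerate(queries):
        m = len(q.aa_seq)
        row: list[HitRecord] = []
        for si, s in enumerate(subjects):
            if q.cds_id == s.cds_id:
                continue
            e = evalue(int(scores[qi, si]), m, n_total, params)
            if e > cutoff:
                continue
            res = local_align(q.aa_seq, s.aa_seq, params)
            row.append(
                HitRecord(
                    query_id=q.cds_id,
                    subject_id=s.cds_id,
                    pident=res.pident,
                    aln_len=res.aln_len,
                    mismatches=res.mismatches,
                    gap_opens=res.gap_opens,
                    qstart=res.qstart,
                    qend=res.qend,
                    sstart=res.sstart,
                    send=res.send,
                    evalue=e,
                    bitscore=res.bitscore,
                )
            )
        row.sort(key=hit_sort_key)
        hits.extend(row)
    return hits


def all_vs_all_pair(
    genome_a: list[CDSRecord],
    genome_b: list[CDSRecord],
    params: EvalueParams = DEFAULT_PARAMS,
    cutoff: float = 1e-20,
) -> tuple[list[HitRecord], list[HitRecord]]:
    """Hits in both search directions for one genome pair.

    Local-alignment scores are symmetric, so the score matrix is computed
    once and E-values are derived per direction (the search-space size n
    differs). Results are identical to ``all_vs_all(a, b)`` and
    ``all_vs_all(b, a)`` run separately, at half the cost.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if not genome_a or not genome_b:
        return [], []
    mat = score_matrix(params.matrix_name)
    aseqs = [encode(c.aa_seq) for c in genome_a]
    bseqs = [encode(c.aa_seq) for c in genome_b]
    acat = np.concatenate(aseqs)
    bcat = np.concatenate(bseqs)
    aoff = np.zeros(len(aseqs) + 1, dtype=np.int64)
    np.cumsum([len(s) for s in aseqs], out=aoff[1:])
    boff = np.zeros(len(bseqs) + 1, dtype=np.int64)
    np.cumsum([len(s) for s in bseqs], out=boff[1:])
    scores = _sw_score_block(acat, aoff, bcat, boff, mat, params.gap_open, params.gap_extend)
    n_a = int(aoff[-1])
    n_b = int(boff[-1])

    hits_ab: list[list[HitRecord]] = [[] for _ in genome_a]
    hits_ba: list[list[HitRecord]] = [[] for _ in genome_b]
    for ai, a in enumerate(genome_a):
        for bi, b in enumerate(genome_b):
            if a.cds_id == b.cds_id:
                continue
            s = int(scores[ai, bi])
            e_ab = evalue(s, len(a.aa_seq), n_b, params)
            e_ba = evalue(s, len(b.aa_seq), n_a, params)
            if e_ab > cutoff and e_ba > cutoff:
                continue
            res = local_align(a.aa_seq, b.aa_seq, params)
            if e_ab <= cutoff:
                hits_ab[ai].append(
                    HitRecord(
                        query_id=a.cds_id,
                        subject_id=b.cds_id,
                        pident=res.pident,
                        aln_len=res.aln_len,
                        mismatches=res.mismatches,
                        gap_opens=res.gap_opens,
                        qstart=res.qstart,
                        qend=res.qend,
                        sstart=res.sstart,
                        send=res.send,
                        evalue=e_ab,
                        bitscore=res.bitscore,
                    )
                )
            if e_ba <= cutoff:
                hits_ba[bi].append(
                    HitRecord(
                        query_id=b.cds_id,
                        subject_id=a.cds_id,
                        pident=res.pident,
                        aln_len=res.aln_len,
                        mismatches=res.mismatches,
                        gap_opens=res.gap_opens,
                        qstart=res.sstart,
                        qend=res.send,
                        sstart=res.qstart,
                        send=res.qend,
                        evalue=e_ba,
                        bitscore=res.bitscore,
                    )
                )
    out_ab: list[HitRecord] = []
    for row in hits_ab:
        row.sort(key=hit_sort_key)
        out_ab.extend(row)
    out_ba: list[HitRecord] = []
    for row in hits_ba:
        row.sort(key=hit_sort_key)
        out_ba.extend(row)
    return out_ab, out_ba


def best_hit(hits: list[HitRecord]) -> str | None:
    """Best subject for a single query: minimal E, then higher bitscore, then
    lexicographically smallest subject id; None for an empty list."""
    if not hits:
        return None
    queries = {h.query_id for h in hits}
    if len(queries) > 1:
        raise ValueError(f"best_hit expects a single query, got {sorted(queries)}")
    return min(hits, key=hit_sort_key).subject_id
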