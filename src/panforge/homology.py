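"""All-vs-all protein similarity search with an affine-gap local aligner.

The aligner is a full Smith–Waterman (Gotoh three-state) dynamic program;
seeding only decides which pairs get aligned, never changes a reported
alignment. E-values use the Karlin–Altschul formula with published ungapped
BLOSUM62 constants, so they are approximate calibrations of exact scores —
thresholds, not absolute calibration, drive the downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio.Align import substitution_matrices

from .proteome import StrainProteome

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ALPHABET)}
_X_INDEX = len(AA_ALPHABET)  # X and any unknown letter: scored 0 vs everything

_NEG = np.int64(-(2**40))


def _blosum62_matrix() -> np.ndarray:
    """21×21 integer score matrix: 20 amino acids + X (scored 0)."""
    blosum = substitution_matrices.load("BLOSUM62")
    n = len(AA_ALPHABET) + 1
    mat = np.zeros((n, n), dtype=np.int64)
    for i, a in enumerate(AA_ALPHABET):
        for j, b in enumerate(AA_ALPHABET):
            mat[i, j] = int(blosum[a, b])
    return mat


@dataclass(frozen=True)
class ScoringScheme:
    """Protein scoring: BLOSUM62 substitution scores, affine gap costs and
    Karlin–Altschul constants (published ungapped BLOSUM62 defaults)."""

    matrix: np.ndarray = field(default_factory=_blosum62_matrix)
    gap_open: int = -11  # cost of the first residue of a gap
    gap_extend: int = -1
    karlin_lambda: float = 0.3176
    karlin_k: float = 0.134

    def __post_init__(self):
        if not (self.gap_open <= self.gap_extend < 0):
            raise ValueError("require gap_open <= gap_extend < 0")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("substitution matrix must be symmetric")

    def encode(self, seq: str) -> np.ndarray:
        return np.array([_AA_INDEX.get(c, _X_INDEX) for c in seq.upper()], dtype=np.intp)


@dataclass(frozen=True)
class LocalAlignment:
    """One optimal Smith–Waterman local alignment (0-based half-open ranges)."""

    score: int
    a_start: int
    a_end: int
    b_start: int
    b_end: int
    aligned_a: str
    aligned_b: str

    @property
    def identity_pct(self) -> float:
        """% identical residue pairs over aligned columns excluding gap columns."""
        pairs = [
            (x, y)
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x != "-" and y != "-"
        ]
        if not pairs:
            return 0.0
        return 100.0 * sum(x == y for x, y in pairs) / len(pairs)

    @property
    def n_gap_opens(self) -> int:
        opens = 0
        for row in (self.aligned_a, self.aligned_b):
            in_gap = False
            for c in row:
                if c == "-" and not in_gap:
                    opens += 1
                in_gap = c == "-"
        return opens

    @property
    def n_mismatches(self) -> int:
        return sum(
            x != y
            for x, y in zip(self.aligned_a, self.aligned_b)
            if x != "-" and y != "-"
        )


@dataclass(frozen=True)
class SimilarityHit:
    query_id: str
    subject_id: str
    raw_score: int
    bit_score: float
    e_value: float
    identity_pct: float
    query_coverage_pct: float
    query_range: tuple[int, int]  # 0-based half-open
    subject_range: tuple[int, int]
    alignment: LocalAlignment | None = None


def local_align(a: str, b: str, scheme: ScoringScheme | None = None) -> LocalAlignment:
    """Best-scoring Smith–Waterman local alignment with affine gaps.

    Ties on the optimal score are broken by the earliest end cell in
    row-major order; the traceback prefers diagonal, then a gap in ``b``
    (vertical), then a gap in ``a``.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    scheme = scheme or ScoringScheme()
    ea, eb = scheme.encode(a), scheme.encode(b)
    m, n = len(ea), len(eb)
    go, ge = np.int64(scheme.gap_open), np.int64(scheme.gap_extend)

    H = np.zeros((m + 1, n + 1), dtype=np.int64)
    E = np.full((m + 1, n + 1), _NEG, dtype=np.int64)  # gap in a (consumes b)
    F = np.full((m + 1, n + 1), _NEG, dtype=np.int64)  # gap in b (consumes a)
    sub = scheme.matrix[ea][:, eb]  # m×n substitution scores

    # anti-diagonal sweep: E,F at (i,j) depend on (i,j-1)/(i-1,j), both on the
    # previous anti-diagonal, so each diagonal vectorizes.
    for d in range(2, m + n + 1):
        lo = max(1, d - n)
        hi = min(m, d - 1)
        if lo > hi:
            continue
        i = np.arange(lo, hi + 1)
        j = d - i
        e = np.maximum(H[i, j - 1] + go, E[i, j - 1] + ge)
        f = np.maximum(H[i - 1, j] + go, F[i - 1, j] + ge)
        h = np.maximum(H[i - 1, j - 1] + sub[i - 1, j - 1], 0)
        h = np.maximum(h, np.maximum(e, f))
        E[i, j], F[i, j], H[i, j] = e, f, h

    flat_best = int(np.argmax(H))  # first maximum in row-major order
    i, j = divmod(flat_best, n + 1)
    score = int(H[i, j])
    if score == 0:
        return LocalAlignment(0, 0, 0, 0, 0, "", "")

    # traceback
    rows_a: list[str] = []
    rows_b: list[str] = []
    state = "H"
    end_i, end_j = i, j
    while True:
        if state == "H":
            if H[i, j] == 0:
                break
            if H[i, j] == H[i - 1, j - 1] + sub[i - 1, j - 1]:
                rows_a.append(a[i - 1])
                rows_b.append(b[j - 1])
                i, j = i - 1, j - 1
            elif H[i, j] == F[i, j]:
                state = "F"
            else:
                state = "E"
        elif state == "F":  # gap in b, consume a[i-1]
            rows_a.append(a[i - 1])
            rows_b.append("-")
            opened = F[i, j] == H[i - 1, j] + go
            i -= 1
            state = "H" if opened else "F"
        else:  # E: gap in a, consume b[j-1]
            rows_a.append("-")
            rows_b.append(b[j - 1])
            opened = E[i, j] == H[i, j - 1] + go
            j -= 1
            state = "H" if opened else "E"
    return LocalAlignment(
        score, i, end_i, j, end_j, "".join(reversed(rows_a)), "".join(reversed(rows_b))
    )


def evalue_from_score(
    raw_score: float, query_len: int, db_len: int, scheme: ScoringScheme | None = None
) -> float:
    """Karlin–Altschul expectation E = K·m·n·exp(−λ·S)."""
    if query_len <= 0 or db_len <= 0:
        raise ValueError("lengths must be positive")
    scheme = scheme or ScoringScheme()
    return float(
        scheme.karlin_k
        * query_len
        * db_len
        * np.exp(-scheme.karlin_lambda * raw_score)
    )


def bitscore_from_score(raw_score: float, scheme: ScoringScheme | None = None) -> float:
    scheme = scheme or ScoringScheme()
    return float(
        (scheme.karlin_lambda * raw_score - np.log(scheme.karlin_k)) / np.log(2.0)
    )


def _kmer_set(seq: str, k: int) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def all_vs_all(
    strains: Sequence[StrainProteome],
    scheme: ScoringScheme | None = None,
    min_bitscore_prefilter: float = 20.0,
    seed_k: int = 4,
    keep_alignments: bool = False,
) -> list[SimilarityHit]:
    """Align every ordered pair of genes sharing an exact k-mer seed.

    Self-hits (same gene id) are excluded; hits below the bit-score prefilter
    are dropped. Output is sorted by (query id, e-value). Seeding is an exact
    k-mer match (default k=4): unrelated short proteins that share no 4-mer
    are never aligned, which keeps the desk-scale search exact on any pair it
    does align.
    """
    if not strains:
        raise ValueError("at least one strain required")
    scheme = scheme or ScoringScheme()

    seqs: dict[str, str] = {}
    for strain in strains:
        for rec in strain:
            if rec.gene_id in seqs:
                raise ValueError(f"duplicate gene id across strains: {rec.gene_id}")
            seqs[rec.gene_id] = rec.protein
    db_len = sum(len(s) for s in seqs.values())

    kmer_index: dict[str, list[str]] = {}
    gene_kmers = {gid: _kmer_set(s, seed_k) for gid, s in seqs.items()}
    for gid, kmers in gene_kmers.items():
        for kmer in kmers:
            kmer_index.setdefault(kmer, []).append(gid)

    candidates: dict[str, set[str]] = {gid: set() for gid in seqs}
    for members in kmer_index.values():
        if len(members) < 2:
            continue
        for q in members:
            candidates[q].update(members)

    hits: list[SimilarityHit] = []
    aln_cache: dict[tuple[str, str], LocalAlignment] = {}
    for q in sorted(seqs):
        for s in sorted(candidates[q]):
            if s == q:
                continue
            key = (q, s) if q <= s else (s, q)
            aln = aln_cache.get(key)
            if aln is None:
                aln = local_align(seqs[key[0]], seqs[key[1]], scheme)
                aln_cache[key] = aln
            if key != (q, s):  # swap roles: score/identity symmetric
                aln = LocalAlignment(
                    aln.score,
                    aln.b_start,
                    aln.b_end,
                    aln.a_start,
                    aln.a_end,
                    aln.aligned_b,
                    aln.aligned_a,
                )
            bit = bitscore_from_score(aln.score, scheme)
            if bit < min_bitscore_prefilter:
                continue
            cov = 100.0 * (aln.a_end - aln.a_start) / len(seqs[q])
            hits.append(
                SimilarityHit(
                    query_id=q,
                    subject_id=s,
                    raw_score=aln.score,
                    bit_score=bit,
                    e_value=evalue_from_score(aln.score, len(seqs[q]), db_len, scheme),
                    identity_pct=aln.identity_pct,
                    query_coverage_pct=cov,
                    query_range=(aln.a_start, aln.a_end),
                    subject_range=(aln.b_start, aln.b_end),
                    alignment=aln if keep_alignments else None,
                )
            )
    hits.sort(key=lambda h: (h.query_id, h.e_value, h.subject_id))
    return hits


_TSV_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]


def write_hits_tsv(hits: Iterable[SimilarityHit], path: str | Path) -> None:
    """12-column tabular format (1-based inclusive coordinates)."""
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_TSV_COLUMNS) + "\n")
        for h in hits:
            aln_len = (
                len(h.alignment.aligned_a)
                if h.alignment is not None
                else h.query_range[1] - h.query_range[0]
            )
            mism = h.alignment.n_mismatches if h.alignment is not None else 0
            gaps = h.alignment.n_gap_opens if h.alignment is not None else 0
            fh.write(
                "\t".join(
                    [
                        h.query_id,
                        h.subject_id,
                        f"{h.identity_pct:.2f}",
                        str(aln_len),
                        str(mism),
                        str(gaps),
                        str(h.query_range[0] + 1),
                        str(h.query_range[1]),
                        str(h.subject_range[0] + 1),
                        str(h.subject_range[1]),
                        f"{h.e_value:.3g}",
                        f"{h.bit_score:.1f}",
                    ]
                )
                + "\n"
            )


def read_hits_tsv(path: str | Path) -> list[SimilarityHit]:
    hits = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            f = line.rstrip("\n").split("\t")
            hits.append(
                SimilarityHit(
                    query_id=f[0],
                    subject_id=f[1],
                    identity_pct=float(f[2]),
                    raw_score=0,
                    bit_score=float(f[11]),
                    e_value=float(f[10]),
                    query_coverage_pct=0.0,
                    query_range=(int(f[6]) - 1, int(f[7])),
                    subject_range=(int(f[8]) - 1, int(f[9])),
                )
            )
    return hits
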