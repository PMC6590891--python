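"""Affine-gap global alignment, similarity statistics and progressive MSA.

The pairwise aligner is a Needleman-Wunsch-Gotoh dynamic program with an
affine gap model in which a gap of length k costs
``gap_open + (k - 1) * gap_extend``. Traceback ties are broken
diagonal > up > left so alignments are bit-reproducible. The progressive
MSA builds a UPGMA guide tree from fractional-common-k-mer distances and
aligns profiles with sum-of-pairs column scoring (gaps score 0 against
anything).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio import SeqIO
from Bio.Align import substitution_matrices
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import squareform

from .seqio import SequenceRecord

NEG_INF = float("-inf")


class SubstitutionMatrix:
    """Symmetric residue substitution scores (default BLOSUM62, with X)."""

    def __init__(self, name: str, scores: dict):
        self.name = name
        self._scores = scores

    @classmethod
    def load(cls, name: str = "BLOSUM62") -> "SubstitutionMatrix":
        arr = substitution_matrices.load(name)
        scores = {}
        for a in arr.alphabet:
            for b in arr.alphabet:
                scores[(a, b)] = float(arr[a, b])
        return cls(name, scores)

    def score(self, a: str, b: str) -> float:
        try:
            return self._scores[(a, b)]
        except KeyError:
            raise KeyError(f"no substitution score for pair ({a!r}, {b!r})")

    @property
    def alphabet(self) -> str:
        return "".join(sorted({a for a, _ in self._scores}))


_DEFAULT_MATRIX: SubstitutionMatrix | None = None


def default_matrix() -> SubstitutionMatrix:
    global _DEFAULT_MATRIX
    if _DEFAULT_MATRIX is None:
        _DEFAULT_MATRIX = SubstitutionMatrix.load("BLOSUM62")
    return _DEFAULT_MATRIX


@dataclass(frozen=True)
class PairwiseAlignment:
    a_id: str
    b_id: str
    a_aln: str
    b_aln: str
    score: float
    gap_open: float
    gap_extend: float

    def __post_init__(self) -> None:
        if len(self.a_aln) != len(self.b_aln):
            raise ValueError("aligned strings differ in length")
        if any(x == "-" and y == "-" for x, y in zip(self.a_aln, self.b_aln)):
            raise ValueError("column with two gaps")

    @property
    def n_columns(self) -> int:
        return len(self.a_aln)

    def degapped(self) -> tuple[str, str]:
        return self.a_aln.replace("-", ""), self.b_aln.replace("-", "")


@dataclass(frozen=True)
class SimilarityStats:
    pct_identity: float
    pct_similarity: float
    n_columns_scored: int


@dataclass(frozen=True)
class MultipleAlignment:
    """Ordered gapped rows of equal length; de-gapping recovers inputs."""

    ids: tuple
    rows: tuple  # gapped strings

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids/rows length mismatch")
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate ids in alignment")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]

    def column(self, j: int) -> str:
        """0-based column as a string of residues/gaps."""
        return "".join(r[j] for r in self.rows)

    def to_fasta(self, path, width: int = 70) -> None:
        with open(path, "w") as fh:
            for rid, row in zip(self.ids, self.rows):
                fh.write(f">{rid}\n")
                for i in range(0, len(row), width):
                    fh.write(row[i : i + width] + "\n")

    @classmethod
    def from_fasta(cls, path) -> "MultipleAlignment":
        ids, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            ids.append(rec.id)
            rows.append(str(rec.seq).upper())
        if not ids:
            raise ValueError(f"no records in {path}")
        return cls(ids=tuple(ids), rows=tuple(rows))

    @classmethod
    def from_records(cls, records) -> "MultipleAlignment":
        return cls(
            ids=tuple(r.id for r in records),
            rows=tuple(r.residues for r in records),
        )


# states: 0 = M (diagonal), 1 = X (up: consume A, gap in B), 2 = Y (left)
def _gotoh(n: int, m: int, sub, gap_open: float, gap_extend: float):
    """Core affine-gap DP over abstract items; ``sub(i, j)`` scores item i of
    A against item j of B (1-based). Returns (score, path) where path is a
    list of (i, j) with 0 marking a gap."""
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    X = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Y = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - (i - 1) * gap_extend
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - (j - 1) * gap_extend
    for i in range(1, n + 1):
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Mp, Xp, Yp = M[i - 1], X[i - 1], Y[i - 1]
        for j in range(1, m + 1):
            s = sub(i, j)
            Mi[j] = s + max(Mp[j - 1], Xp[j - 1], Yp[j - 1])
            Xi[j] = max(Mp[j] - gap_open, Xp[j] - gap_extend, Yp[j] - gap_open)
            Yi[j] = max(Mi[j - 1] - gap_open, Xi[j - 1] - gap_open,
                        Yi[j - 1] - gap_extend)
    # end state: tie order diagonal > up > left
    end_vals = (M[n][m], X[n][m], Y[n][m])
    score = max(end_vals)
    state = end_vals.index(score)  # prefers M, then X, then Y on ties
    path = []
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            path.append((i, j))
            cands = (M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1])
            i, j = i - 1, j - 1
        elif state == 1:
            path.append((i, 0))
            cands = (M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                     Y[i - 1][j] - gap_open)
            i = i - 1
        else:
            path.append((0, j))
            cands = (M[i][j - 1] - gap_open, X[i][j - 1] - gap_open,
                     Y[i][j - 1] - gap_extend)
            j = j - 1
        if i == 0 and j == 0:
            break
        if i == 0:
            state = 2
        elif j == 0:
            state = 1
        else:
            state = cands.index(max(cands))
    path.reverse()
    return score, path


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> PairwiseAlignment:
    """Optimal affine-gap global alignment (Gotoh) of two protein records."""
    if gap_open <= 0 or gap_extend <= 0:
        raise ValueError("gap penalties must be positive")
    if len(a.residues) == 0 or len(b.residues) == 0:
        raise ValueError("cannot align empty sequences")
    matrix = matrix or default_matrix()
    ra, rb = a.residues, b.residues
    score, path = _gotoh(
        len(ra), len(rb),
        lambda i, j: matrix.score(ra[i - 1], rb[j - 1]),
        gap_open, gap_extend,
    )
    a_aln = "".join(ra[i - 1] if i else "-" for i, _ in path)
    b_aln = "".join(rb[j - 1] if j else "-" for _, j in path)
    return PairwiseAlignment(
        a_id=a.id, b_id=b.id, a_aln=a_aln, b_aln=b_aln,
        score=score, gap_open=gap_open, gap_extend=gap_extend,
    )


def similarity_stats(
    aln: PairwiseAlignment,
    matrix: SubstitutionMatrix | None = None,
    denominator: str = "aligned_columns",
) -> SimilarityStats:
    """Percent identity and percent positive-scoring similarity.

    Identity counts columns with identical residues; similarity counts
    columns whose residue pair is identical or has a positive substitution
    score. Gap columns never count as matches. The denominator is
    configurable because percent-identity conventions differ:
    ``aligned_columns`` (both residues present), ``shorter_seq`` or
    ``all_columns``.
    """
    matrix = matrix or default_matrix()
    n_ident = n_sim = n_aligned = 0
    for x, y in zip(aln.a_aln, aln.b_aln):
        if x == "-" or y == "-":
            continue
        n_aligned += 1
        if x == y:
            n_ident += 1
            n_sim += 1
        elif matrix.score(x, y) > 0:
            n_sim += 1
    if denominator == "aligned_columns":
        denom = n_aligned
    elif denominator == "shorter_seq":
        denom = min(len(s) for s in aln.degapped())
    elif denominator == "all_columns":
        denom = aln.n_columns
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    if denom == 0:
        raise ValueError("zero denominator: no columns to score")
    return SimilarityStats(
        pct_identity=100.0 * n_ident / denom,
        pct_similarity=100.0 * n_sim / denom,
        n_columns_scored=denom,
    )


def _kmer_set(seq: str, k: int) -> set:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def kmer_distance_matrix(seqs, k: int = 3) -> np.ndarray:
    """1 - (shared distinct k-mers / smaller distinct-k-mer count)."""
    k = min(k, min(len(s) for s in seqs))
    sets = [_kmer_set(s, k) for s in seqs]
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            frac = len(sets[i] & sets[j]) / min(len(sets[i]), len(sets[j]))
            d[i, j] = d[j, i] = 1.0 - frac
    return d


def _profile_column_scorer(rows_a, rows_b, matrix):
    score = matrix.score

    def sub(i: int, j: int) -> float:
        total = 0.0
        for ra in rows_a:
            x = ra[i - 1]
            if x == "-":
                continue
            for rb in rows_b:
                y = rb[j - 1]
                if y != "-":
                    total += score(x, y)
        return total

    return sub


def _align_profiles(rows_a, rows_b, matrix, gap_open, gap_extend):
    sub = _profile_column_scorer(rows_a, rows_b, matrix)
    _, path = _gotoh(len(rows_a[0]), len(rows_b[0]), sub, gap_open, gap_extend)
    new_a = ["".join(r[i - 1] if i else "-" for i, _ in path) for r in rows_a]
    new_b = ["".join(r[j - 1] if j else "-" for _, j in path) for r in rows_b]
    return new_a, new_b


def progressive_msa(
    seqs,
    matrix: SubstitutionMatrix | None = None,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> MultipleAlignment:
    """Progressive multiple alignment: k-mer distances -> UPGMA guide tree ->
    profile-profile Gotoh at internal nodes. Deterministic given input
    order; output rows keep the input order."""
    seqs = list(seqs)
    if len(seqs) < 2:
        raise ValueError("progressive_msa needs at least 2 sequences")
    ids = [s.id for s in seqs]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate sequence ids")
    matrix = matrix or default_matrix()
    if len(seqs) == 2:
        pa = global_align(seqs[0], seqs[1], matrix, gap_open, gap_extend)
        return MultipleAlignment(ids=tuple(ids), rows=(pa.a_aln, pa.b_aln))
    d = kmer_distance_matrix([s.residues for s in seqs])
    Z = linkage(squareform(d, checks=False), method="average")
    # clusters[c] = (member indices, gapped rows) in input order
    clusters: dict[int, tuple[list, list]] = {
        i: ([i], [seqs[i].residues]) for i in range(len(seqs))
    }
    nxt = len(seqs)
    for a, b, _, _ in Z:
        ia, ib = clusters.pop(int(a)), clusters.pop(int(b))
        rows_a, rows_b = _align_profiles(ia[1], ib[1], matrix, gap_open, gap_extend)
        clusters[nxt] = (ia[0] + ib[0], rows_a + rows_b)
        nxt += 1
    members, rows = clusters.popitem()[1]
    order = np.argsort(members)
    return MultipleAlignment(
        ids=tuple(ids[members[k]] for k in order),
        rows=tuple(rows[k] for k in order),
    )


def column_occupancy(msa: MultipleAlignment) -> np.ndarray:
    """Fraction of non-gap residues per column."""
    arr = np.frombuffer(
        "".join(msa.rows).encode(), dtype="S1"
    ).reshape(msa.n_rows, msa.n_columns)
    return (arr != b"-").mean(axis=0)


def trim_termini(
    msa: MultipleAlignment, min_occupancy: float = 0.5
) -> MultipleAlignment:
    """Remove ragged alignment termini.

    Leading and trailing columns with non-gap occupancy below
    ``min_occupancy`` are dropped, up to the first/last column that passes;
    interior columns are untouched.
    """
    occ = column_occupancy(msa)
    passing = np.nonzero(occ >= min_occupancy)[0]
    if len(passing) == 0:
        raise ValueError("trimming would remove every column")
    lo, hi = int(passing[0]), int(passing[-1])
    return MultipleAlignment(
        ids=msa.ids, rows=tuple(r[lo : hi + 1] for r in msa.rows)
    )


def pairwise_from_msa(msa: MultipleAlignment, a_id: str, b_id: str) -> PairwiseAlignment:
    """Extract two rows of an MSA as a PairwiseAlignment (shared gap columns
    dropped), e.g. to compute identity statistics between MSA members."""
    ra, rb = msa.row(a_id), msa.row(b_id)
    cols = [(x, y) for x, y in zip(ra, rb) if not (x == "-" and y == "-")]
    return PairwiseAlignment(
        a_id=a_id, b_id=b_id,
        a_aln="".join(x for x, _ in cols),
        b_aln="".join(y for _, y in cols),
        score=float("nan"), gap_open=10.0, gap_extend=0.5,
    )
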