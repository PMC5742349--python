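"""Progressive multiple alignment and per-column conservation profiling.

The aligner is a deterministic progressive scheme: a k-mer distance matrix
feeds a UPGMA guide tree (ties in joins broken by smallest member accession)
and profiles are merged by global profile-profile alignment under BLOSUM62
with affine gaps (a gap of length g costs ``gap_open + g * gap_extend``).

Conservation of a column is the sum over all sequence pairs of the min-max
normalised substitution score of their residues, weighted by sequence
weights; the profile is rescaled so the best-scoring column reads exactly
100, mirroring the convention of reporting the highest conserved amino acid
as 100. Columns that are mostly gaps still get a score but are excluded
from the normalisation maximum, so alignment artifacts cannot claim the
100 anchor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .records import AMINO_ACIDS, ProteinRecord

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

LOG2_20 = float(np.log2(20.0))


def _blosum62() -> np.ndarray:
    m = substitution_matrices.load("BLOSUM62")
    out = np.zeros((20, 20))
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            out[i, j] = m[a, b]
    return out


_B62 = _blosum62()
#: BLOSUM62 min-max normalised to [0, 1]; used by the conservation score.
_B62_NORM = (_B62 - _B62.min()) / (_B62.max() - _B62.min())


@dataclass
class MSA:
    """Aligned sequences: equal-length rows over the alphabet plus '-'."""

    accessions: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.accessions) != len(self.rows):
            raise ValueError("accessions and rows must have equal length")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("all MSA rows must have the same length")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, accession: str) -> str:
        return self.rows[self.accessions.index(accession)]

    def ungapped(self, accession: str) -> str:
        return self.row(accession).replace("-", "")

    def to_fasta(self, path) -> None:
        recs = [
            SeqRecord(Seq(row), id=acc, description="")
            for acc, row in zip(self.accessions, self.rows)
        ]
        with open(path, "w") as handle:
            writer = SeqIO.FastaIO.FastaWriter(handle, wrap=60)
            writer.write_file(recs)

    @classmethod
    def from_fasta(cls, path) -> "MSA":
        accs, rows = [], []
        for rec in SeqIO.parse(str(path), "fasta"):
            accs.append(rec.id)
            rows.append(str(rec.seq).upper())
        return cls(accessions=accs, rows=rows)

    def column_matrix(self) -> np.ndarray:
        """Integer matrix (n_rows x n_columns): residue index, -1 for gap/X."""
        out = np.full((self.n_rows, self.n_columns), -1, dtype=np.int8)
        for i, row in enumerate(self.rows):
            for j, c in enumerate(row):
                out[i, j] = _AA_INDEX.get(c, -1)
        return out


# ---------------------------------------------------------------------------
# Guide tree
# ---------------------------------------------------------------------------

def kmer_distance(a: str, b: str, k: int = 3) -> float:
    """1 - (shared k-mers / k-mers of the shorter sequence), multiset counts."""
    def counts(s: str) -> dict[str, int]:
        d: dict[str, int] = {}
        for i in range(len(s) - k + 1):
            kmer = s[i : i + k]
            d[kmer] = d.get(kmer, 0) + 1
        return d

    ca, cb = counts(a), counts(b)
    shared = sum(min(n, cb.get(kmer, 0)) for kmer, n in ca.items())
    denom = min(len(a), len(b)) - k + 1
    if denom <= 0:
        return 1.0
    return 1.0 - shared / denom


def _upgma_join_order(
    labels: list[str], dist: np.ndarray
) -> list[tuple[int, int]]:
    """UPGMA agglomeration order over cluster indices.

    Returns joins as (i, j) into a growing cluster list whose first
    ``len(labels)`` entries are the leaves. Ties in the minimum distance are
    broken by the smallest member accession of each cluster.
    """
    n = len(labels)
    active: dict[int, tuple[float, str]] = {
        i: (1.0, labels[i]) for i in range(n)
    }  # idx -> (size, min accession)
    d = {
        (i, j): float(dist[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    sizes = {i: 1 for i in range(n)}
    joins: list[tuple[int, int]] = []
    next_idx = n
    while len(active) > 1:
        best = None
        for (i, j), dij in d.items():
            if i not in active or j not in active:
                continue
            key = (dij, min(active[i][1], active[j][1]), max(active[i][1], active[j][1]))
            if best is None or key < best[0]:
                best = (key, i, j)
        _, i, j = best
        joins.append((i, j))
        new_min = min(active[i][1], active[j][1])
        si, sj = sizes[i], sizes[j]
        for k in list(active):
            if k in (i, j):
                continue
            dik = d[(min(i, k), max(i, k))]
            djk = d[(min(j, k), max(j, k))]
            d[(min(next_idx, k), max(next_idx, k))] = (si * dik + sj * djk) / (si + sj)
        del active[i], active[j]
        active[next_idx] = (si + sj, new_min)
        sizes[next_idx] = si + sj
        next_idx += 1
    return joins


# ---------------------------------------------------------------------------
# Profile-profile alignment
# ---------------------------------------------------------------------------

def _profile(rows: list[str]) -> np.ndarray:
    """Column frequency matrix (L x 20); gaps and X contribute nothing."""
    L = len(rows[0])
    out = np.zeros((L, 20))
    for row in rows:
        for j, c in enumerate(row):
            idx = _AA_INDEX.get(c)
            if idx is not None:
                out[j, idx] += 1.0
    return out / len(rows)


def _profile_align(
    rows_a: list[str],
    rows_b: list[str],
    gap_open: float,
    gap_extend: float,
) -> tuple[float, list[str]]:
    """Global affine-gap profile-profile alignment (Gotoh).

    Returns the optimal score and the merged traceback as a list of steps
    'D' (consume both), 'A' (consume a column of A only), 'B' (B only).
    Tie preference at every cell: diagonal, then gap-in-B, then gap-in-A.
    """
    fa, fb = _profile(rows_a), _profile(rows_b)
    la, lb = fa.shape[0], fb.shape[0]
    S = (fa @ _B62 @ fb.T).tolist()
    neg = float("-inf")
    oe = gap_open + gap_extend
    # list-of-lists DP (scalar indexing dominates; lists beat numpy here)
    M = [[neg] * (lb + 1) for _ in range(la + 1)]
    X = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in B (consumes A)
    Y = [[neg] * (lb + 1) for _ in range(la + 1)]  # gap in A (consumes B)
    M[0][0] = 0.0
    for i in range(1, la + 1):
        X[i][0] = -gap_open - i * gap_extend
    for j in range(1, lb + 1):
        Y[0][j] = -gap_open - j * gap_extend
    for i in range(1, la + 1):
        Mi1, Xi1, Yi1 = M[i - 1], X[i - 1], Y[i - 1]
        Mi, Xi, Yi = M[i], X[i], Y[i]
        Si = S[i - 1]
        for j in range(1, lb + 1):
            j1 = j - 1
            Mi[j] = Si[j1] + max(Mi1[j1], Xi1[j1], Yi1[j1])
            Xi[j] = max(Mi1[j] - oe, Yi1[j] - oe, Xi1[j] - gap_extend)
            Yi[j] = max(Mi[j1] - oe, Xi[j1] - oe, Yi[j1] - gap_extend)
    M, X, Y = np.array(M), np.array(X), np.array(Y)
    score = max(M[la, lb], X[la, lb], Y[la, lb])

    # traceback; invalid predecessors hold -inf, so argmax (with the fixed
    # M > X > Y preference) never leaves the valid path
    steps: list[str] = []
    i, j = la, lb
    state = ["M", "X", "Y"][int(np.argmax([M[la, lb], X[la, lb], Y[la, lb]]))]
    while i > 0 or j > 0:
        if state == "M":
            steps.append("D")
            prev = [M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1]]
            names = ["M", "X", "Y"]
            i, j = i - 1, j - 1
        elif state == "X":
            steps.append("A")
            prev = [M[i - 1, j] - oe, Y[i - 1, j] - oe, X[i - 1, j] - gap_extend]
            names = ["M", "Y", "X"]
            i -= 1
        else:  # Y
            steps.append("B")
            prev = [M[i, j - 1] - oe, X[i, j - 1] - oe, Y[i, j - 1] - gap_extend]
            names = ["M", "X", "Y"]
            j -= 1
        state = names[int(np.argmax(prev))]
    steps.reverse()
    return float(score), steps


def _merge(rows_a: list[str], rows_b: list[str], steps: list[str]) -> tuple[list[str], list[str]]:
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    ia = ib = 0
    for step in steps:
        if step in ("D", "A"):
            for r, row in zip(out_a, rows_a):
                r.append(row[ia])
            ia += 1
        else:
            for r in out_a:
                r.append("-")
        if step in ("D", "B"):
            for r, row in zip(out_b, rows_b):
                r.append(row[ib])
            ib += 1
        else:
            for r in out_b:
                r.append("-")
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def global_alignment_score(
    a: str, b: str, gap_open: float = 10.0, gap_extend: float = 0.5
) -> float:
    """Optimal global (Needleman-Wunsch, affine) score of two sequences under
    BLOSUM62 with the aligner's gap convention. Exposed for oracle checks."""
    score, _ = _profile_align([a], [b], gap_open, gap_extend)
    return score


def align(
    records: Sequence[ProteinRecord],
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
    kmer: int = 3,
) -> MSA:
    """Progressive multiple alignment of the records.

    Deterministic: guide-tree ties are broken by smallest accession and DP
    tie preference is fixed. Ungapping any output row reproduces its input
    sequence exactly. A single record is returned as its own trivial MSA
    with a warning.
    """
    if not records:
        raise ValueError("align requires at least one record")
    if len(records) == 1:
        warnings.warn("align called with a single record; returning trivial MSA")
        return MSA(accessions=[records[0].accession], rows=[records[0].sequence])
    labels = [r.accession for r in records]
    n = len(records)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = kmer_distance(
                records[i].sequence, records[j].sequence, k=kmer
            )
    joins = _upgma_join_order(labels, dist)
    clusters: list[tuple[list[str], list[str]]] = [
        ([r.accession], [r.sequence]) for r in records
    ]
    for i, j in joins:
        accs_a, rows_a = clusters[i]
        accs_b, rows_b = clusters[j]
        _, steps = _profile_align(rows_a, rows_b, gap_open, gap_extend)
        new_a, new_b = _merge(rows_a, rows_b, steps)
        clusters.append((accs_a + accs_b, new_a + new_b))
    accs, rows = clusters[-1]
    order = sorted(range(len(accs)), key=lambda k: labels.index(accs[k]))
    return MSA(accessions=[accs[k] for k in order], rows=[rows[k] for k in order])


# ---------------------------------------------------------------------------
# Conservation, logo, reference map
# ---------------------------------------------------------------------------

def sequence_weights(msa: MSA, weighting: str = "none", identity: float = 0.62) -> np.ndarray:
    """Uniform weights, or inverse-cluster-size weights after single-linkage
    clustering of rows at ``identity`` fraction identical (pairwise over
    columns where neither row is gapped)."""
    if weighting == "none":
        return np.ones(msa.n_rows)
    if weighting != "identity_cluster":
        raise ValueError(f"unknown weighting {weighting!r}")
    cm = msa.column_matrix()
    n = msa.n_rows
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            both = (cm[i] >= 0) & (cm[j] >= 0)
            tot = int(both.sum())
            if tot == 0:
                continue
            ident = int((cm[i][both] == cm[j][both]).sum()) / tot
            if ident >= identity:
                parent[find(i)] = find(j)
    sizes: dict[int, int] = {}
    for i in range(n):
        sizes[find(i)] = sizes.get(find(i), 0) + 1
    return np.array([1.0 / sizes[find(i)] for i in range(n)])


@dataclass
class ConservationProfile:
    """Per-column conservation table plus residue frequency matrix.

    ``frame`` columns: column (1-based), raw_score, relative_score,
    gap_fraction, information_bits. ``frequencies`` is (n_columns x 20),
    rows summing to 1 over non-gap symbols (0 for all-gap columns).
    """

    frame: pd.DataFrame
    frequencies: np.ndarray

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        for i, a in enumerate(AMINO_ACIDS):
            out[f"freq_{a}"] = self.frequencies[:, i]
        out.to_csv(path, sep="\t", index=False)


def conservation(
    msa: MSA,
    weighting: str = "none",
    max_gap_fraction: float = 0.5,
) -> ConservationProfile:
    """Sum-of-normalised-pairs conservation, rescaled so the top column is 100.

    raw(c) = sum_{i<j} w_i w_j s_norm(a_i, a_j) over rows without a gap in c,
    with s_norm the min-max normalised BLOSUM62. relative(c) = 100 * raw(c) /
    max raw over columns whose gap fraction is <= ``max_gap_fraction``;
    gap-heavy columns are scored but cannot set the maximum.
    """
    if msa.n_rows == 0:
        raise ValueError("conservation requires a non-empty MSA")
    w = sequence_weights(msa, weighting)
    cm = msa.column_matrix()
    n_cols = msa.n_columns
    raw = np.zeros(n_cols)
    gap_fraction = np.zeros(n_cols)
    freqs = np.zeros((n_cols, 20))
    bits = np.zeros(n_cols)
    for c in range(n_cols):
        col = cm[:, c]
        ok = col >= 0
        gap_fraction[c] = 1.0 - ok.sum() / msa.n_rows
        if not ok.any():
            continue
        W = np.zeros(20)   # sum of weights per residue
        V = np.zeros(20)   # sum of squared weights per residue
        np.add.at(W, col[ok], w[ok])
        np.add.at(V, col[ok], w[ok] ** 2)
        raw[c] = 0.5 * (W @ _B62_NORM @ W - float(np.sum(V * np.diag(_B62_NORM))))
        counts = np.zeros(20)
        np.add.at(counts, col[ok], 1.0)
        f = counts / counts.sum()
        freqs[c] = f
        nz = f > 0
        bits[c] = LOG2_20 - float(-(f[nz] * np.log2(f[nz])).sum())
    eligible = gap_fraction <= max_gap_fraction
    peak = raw[eligible].max() if eligible.any() else 0.0
    if peak <= 0:
        peak = raw.max()
    relative = 100.0 * raw / peak if peak > 0 else np.zeros(n_cols)
    frame = pd.DataFrame(
        {
            "column": np.arange(1, n_cols + 1),
            "raw_score": raw,
            "relative_score": relative,
            "gap_fraction": gap_fraction,
            "information_bits": bits,
        }
    )
    return ConservationProfile(frame=frame, frequencies=freqs)


def logo_matrix(msa: MSA) -> pd.DataFrame:
    """Sequence-logo matrix: per column, information content in bits
    (log2 20 - Shannon entropy of non-gap frequencies, no small-sample
    correction) and per-residue heights f_a * bits."""
    prof = conservation(msa)
    out = pd.DataFrame(
        {
            "column": prof.frame["column"],
            "information_bits": prof.frame["information_bits"],
        }
    )
    heights = prof.frequencies * prof.frame["information_bits"].to_numpy()[:, None]
    for i, a in enumerate(AMINO_ACIDS):
        out[f"height_{a}"] = heights[:, i]
    return out


@dataclass(frozen=True)
class ReferenceMap:
    """Alignment column <-> reference residue number (both 1-based)."""

    reference: str
    column_to_residue: dict[int, int]
    residue_to_column: dict[int, int]


def map_reference(msa: MSA, reference_accession: str) -> ReferenceMap:
    if reference_accession not in msa.accessions:
        raise ValueError(f"reference accession {reference_accession!r} not in MSA")
    row = msa.row(reference_accession)
    col_to_res: dict[int, int] = {}
    res = 0
    for c, ch in enumerate(row, start=1):
        if ch != "-":
            res += 1
            col_to_res[c] = res
    return ReferenceMap(
        reference=reference_accession,
        column_to_residue=col_to_res,
        residue_to_column={r: c for c, r in col_to_res.items()},
    )
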