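"""Multiple alignment of barcode sequences and coordinate mapping.

The aligner is a classic progressive scheme: affine-gap global pairwise
alignment (Gotoh dynamic programming), a UPGMA guide tree on k-mer
distances, and profile-profile merges in guide-tree order.  For the
near-identical spacer haplotypes this package targets, the method places
the characteristic short indels (1/1/9 nt in this genus) as contiguous gap
blocks.  A pre-computed alignment can be injected instead via
:func:`read_alignment` (e.g. an alignment produced by an external tool).

Coordinates: alignment columns are 1-based and inclusive throughout, and
:func:`map_position` / :func:`unmap_position` convert between a row's
ungapped residue numbering and alignment columns.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple, Union

import numpy as np
from numba import njit

from .seqio import GAP, IUPAC_SETS, SeqRecord, parse_fasta_raw, write_fasta

_SYMBOLS = "ACGTRYSWKMBDHVN" + GAP
_INDEX = {c: i for i, c in enumerate(_SYMBOLS)}
_GAP_IDX = _INDEX[GAP]
_ENC = np.full(256, -1, dtype=np.int64)
for _c, _i in _INDEX.items():
    _ENC[ord(_c)] = _i


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scores: match/mismatch and affine gap penalties.

    Defaults (+2/-1, open -5, extend -1) make short isolated indels align
    as single contiguous gap blocks, which is what the spacer haplotypes
    require.  With ``ambiguity_is_match`` IUPAC codes whose base sets
    intersect score as a match, so a hybrid's K/M columns pair cleanly
    with either parent.
    """

    match: float = 2.0
    mismatch: float = -1.0
    gap_open: float = -5.0
    gap_extend: float = -1.0
    ambiguity_is_match: bool = True

    def __post_init__(self) -> None:
        if not (self.gap_open <= self.gap_extend <= 0):
            raise ValueError("require gap_open <= gap_extend <= 0")
        if not self.match > self.mismatch:
            raise ValueError("require match > mismatch")


class Alignment:
    """Equal-length gapped rows with 1-based column coordinates."""

    def __init__(self, ids: Sequence[str], rows: Sequence[str]):
        ids = list(ids)
        rows = [r.upper() for r in rows]
        if len(ids) != len(rows):
            raise ValueError("ids and rows length mismatch")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate row ids in alignment")
        if rows:
            L = len(rows[0])
            for rid, r in zip(ids, rows):
                if len(r) != L:
                    raise ValueError(
                        f"row {rid!r} has length {len(r)}, expected {L}"
                    )
        self.ids = ids
        self.rows = rows
        self._col_cache: dict = {}

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def nrows(self) -> int:
        return len(self.rows)

    def row(self, row_id: str) -> str:
        try:
            return self.rows[self.ids.index(row_id)]
        except ValueError:
            raise KeyError(f"no row {row_id!r} in alignment") from None

    def degapped(self, row_id: str) -> str:
        return self.row(row_id).replace(GAP, "")

    def _nongap_cols(self, row_id: str) -> list:
        if row_id not in self._col_cache:
            self._col_cache[row_id] = [
                k for k, c in enumerate(self.row(row_id)) if c != GAP
            ]
        return self._col_cache[row_id]

    def pair(self, id_a: str, id_b: str) -> "Alignment":
        """Two-row slice with columns gapped in both rows dropped."""
        ra, rb = self.row(id_a), self.row(id_b)
        keep = [k for k in range(len(ra)) if ra[k] != GAP or rb[k] != GAP]
        return Alignment(
            [id_a, id_b],
            ["".join(ra[k] for k in keep), "".join(rb[k] for k in keep)],
        )

    def to_fasta(self, path: Union[str, Path], wrap_width: int = 70) -> Path:
        return write_fasta(
            list(zip(self.ids, self.rows)), path,
            wrap_width=wrap_width, aligned=True,
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Alignment)
            and self.ids == other.ids
            and self.rows == other.rows
        )


def read_alignment(path: Union[str, Path]) -> Alignment:
    """Read an aligned FASTA file; all-gap columns are dropped with a warning."""
    triples = parse_fasta_raw(path)
    ids = [t[0] for t in triples]
    rows = [t[2] for t in triples]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path}: rows have unequal lengths {sorted(lengths)}")
    for rid, r in zip(ids, rows):
        bad = set(r) - set(_SYMBOLS)
        if bad:
            raise ValueError(f"{path}: row {rid!r}: illegal characters {sorted(bad)}")
    L = lengths.pop()
    keep = [k for k in range(L) if any(r[k] != GAP for r in rows)]
    if len(keep) != L:
        warnings.warn(f"{path}: dropped {L - len(keep)} all-gap columns", stacklevel=2)
        rows = ["".join(r[k] for k in keep) for r in rows]
    return Alignment(ids, rows)


def map_position(aln: Alignment, row_id: str, index: int) -> int:
    """Map a 1-based ungapped residue index of a row to its alignment column."""
    cols = aln._nongap_cols(row_id)
    if not 1 <= index <= len(cols):
        raise IndexError(
            f"residue index {index} out of range 1..{len(cols)} "
            f"for row {row_id!r}"
        )
    return cols[index - 1] + 1


def unmap_position(aln: Alignment, row_id: str, column: int) -> int:
    """Inverse of :func:`map_position`; the column must hold a residue."""
    if not 1 <= column <= aln.length:
        raise IndexError(f"column {column} out of range 1..{aln.length}")
    row = aln.row(row_id)
    if row[column - 1] == GAP:
        raise ValueError(f"column {column} is a gap in row {row_id!r}")
    return column - row[:column].count(GAP)


# --------------------------------------------------------------------------
# Affine-gap DP kernel (Gotoh).  Works on a pre-computed column-vs-column
# score matrix so the same kernel serves residue-residue and
# profile-profile alignment.  Traceback tie-break: diagonal > up > left,
# encoded by candidate evaluation order with strict improvement.


@njit(cache=True)
def _gotoh_kernel(S, gap_open, gap_extend):  # pragma: no cover - numba
    n, m = S.shape
    NEG = -1e30
    M = np.full((n + 1, m + 1), NEG)
    X = np.full((n + 1, m + 1), NEG)  # gap in second profile (vertical)
    Y = np.full((n + 1, m + 1), NEG)  # gap in first profile (horizontal)
    pM = np.zeros((n + 1, m + 1), dtype=np.int8)
    pX = np.zeros((n + 1, m + 1), dtype=np.int8)
    pY = np.zeros((n + 1, m + 1), dtype=np.int8)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + (i - 1) * gap_extend
        pX[i, 0] = 0 if i == 1 else 1
    for j in range(1, m + 1):
        Y[0, j] = gap_open + (j - 1) * gap_extend
        pY[0, j] = 0 if j == 1 else 2
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            b = M[i - 1, j - 1]
            p = 0
            if X[i - 1, j - 1] > b:
                b = X[i - 1, j - 1]
                p = 1
            if Y[i - 1, j - 1] > b:
                b = Y[i - 1, j - 1]
                p = 2
            M[i, j] = b + S[i - 1, j - 1]
            pM[i, j] = p

            b = M[i - 1, j] + gap_open
            p = 0
            if X[i - 1, j] + gap_extend > b:
                b = X[i - 1, j] + gap_extend
                p = 1
            if Y[i - 1, j] + gap_open > b:
                b = Y[i - 1, j] + gap_open
                p = 2
            X[i, j] = b
            pX[i, j] = p

            b = M[i, j - 1] + gap_open
            p = 0
            if X[i, j - 1] + gap_open > b:
                b = X[i, j - 1] + gap_open
                p = 1
            if Y[i, j - 1] + gap_extend > b:
                b = Y[i, j - 1] + gap_extend
                p = 2
            Y[i, j] = b
            pY[i, j] = p
    score = M[n, m]
    state = 0
    if X[n, m] > score:
        score = X[n, m]
        state = 1
    if Y[n, m] > score:
        score = Y[n, m]
        state = 2
    return score, state, pM, pX, pY


def _traceback(pM, pX, pY, state, n, m):
    ops = []  # (consume_first, consume_second)
    i, j = n, m
    while i > 0 or j > 0:
        if state == 0:
            nxt = pM[i, j]
            ops.append((True, True))
            i -= 1
            j -= 1
        elif state == 1:
            nxt = pX[i, j]
            ops.append((True, False))
            i -= 1
        else:
            nxt = pY[i, j]
            ops.append((False, True))
            j -= 1
        state = nxt
    ops.reverse()
    return ops


def _score_matrix(scheme: ScoringScheme) -> np.ndarray:
    SM = np.zeros((16, 16))
    for a, i in _INDEX.items():
        for b, j in _INDEX.items():
            if a == GAP or b == GAP:
                continue  # gap-vs-anything scores 0 inside a profile column
            if scheme.ambiguity_is_match:
                hit = bool(IUPAC_SETS[a] & IUPAC_SETS[b])
            else:
                hit = a == b
            SM[i, j] = scheme.match if hit else scheme.mismatch
    return SM


def _encode(seq: str) -> np.ndarray:
    v = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (v < 0).any():
        bad = seq[int(np.argmax(v < 0))]
        raise ValueError(f"illegal alignment character {bad!r}")
    return v


def pairwise_global(
    a: SeqRecord,
    b: SeqRecord,
    scheme: Optional[ScoringScheme] = None,
) -> Tuple[Alignment, float]:
    """Optimal global alignment of two sequences under the affine scheme.

    Deterministic: traceback ties resolve diagonal > up > left everywhere.
    """
    scheme = scheme or ScoringScheme()
    if not a.residues or not b.residues:
        raise ValueError("sequences must be non-empty")
    SM = _score_matrix(scheme)
    ia, ib = _encode(a.residues), _encode(b.residues)
    S = SM[ia][:, ib]
    score, state, pM, pX, pY = _gotoh_kernel(S, scheme.gap_open, scheme.gap_extend)
    ops = _traceback(pM, pX, pY, state, len(ia), len(ib))
    ra, rb = [], []
    i = j = 0
    for ca, cb in ops:
        ra.append(a.residues[i] if ca else GAP)
        rb.append(b.residues[j] if cb else GAP)
        i += ca
        j += cb
    return Alignment([a.id, b.id], ["".join(ra), "".join(rb)]), float(score)


# --------------------------------------------------------------------------
# Progressive MSA


def _profile_counts(rows: Sequence[str]) -> np.ndarray:
    M = np.stack([_encode(r) for r in rows])
    C = np.zeros((M.shape[1], 16))
    for s in range(16):
        C[:, s] = (M == s).sum(axis=0)
    return C


def _merge_profiles(ids_a, rows_a, ids_b, rows_b, scheme, SM):
    Ca = _profile_counts(rows_a)
    Cb = _profile_counts(rows_b)
    S = (Ca @ SM @ Cb.T) / (len(rows_a) * len(rows_b))
    score, state, pM, pX, pY = _gotoh_kernel(S, scheme.gap_open, scheme.gap_extend)
    ops = _traceback(pM, pX, pY, state, len(rows_a[0]), len(rows_b[0]))
    out_a = [[] for _ in rows_a]
    out_b = [[] for _ in rows_b]
    i = j = 0
    for ca, cb in ops:
        for r, buf in zip(rows_a, out_a):
            buf.append(r[i] if ca else GAP)
        for r, buf in zip(rows_b, out_b):
            buf.append(r[j] if cb else GAP)
        i += ca
        j += cb
    return (
        ids_a + ids_b,
        ["".join(buf) for buf in out_a] + ["".join(buf) for buf in out_b],
    )


def kmer_distance(s1: str, s2: str, k: int = 3) -> float:
    """Fractional common k-mer distance between two ungapped sequences."""
    c1 = Counter(s1[i:i + k] for i in range(len(s1) - k + 1))
    c2 = Counter(s2[i:i + k] for i in range(len(s2) - k + 1))
    shared = sum(min(n, c2[w]) for w, n in c1.items())
    denom = min(len(s1), len(s2)) - k + 1
    if denom <= 0:
        return 1.0
    return 1.0 - shared / denom


def _upgma_merge_order(ids, dist):
    """UPGMA joins with a canonical tie-break (distance, then the sorted
    pair of lexicographically smallest member labels), so the merge order
    does not depend on input order."""
    members = {i: frozenset([i]) for i in ids}
    rep = {i: i for i in ids}  # cluster key -> min label
    size = {i: 1 for i in ids}
    d = dict(dist)  # keys: frozenset({ka, kb}) over cluster keys
    active = set(ids)
    merges = []
    while len(active) > 1:
        best = None
        for ka in active:
            for kb in active:
                if rep[ka] < rep[kb]:
                    key = (round(d[frozenset([ka, kb])], 10), rep[ka], rep[kb])
                    if best is None or key < best[0]:
                        best = (key, ka, kb)
        _, ka, kb = best
        left, right = (ka, kb) if rep[ka] < rep[kb] else (kb, ka)
        new = min(rep[ka], rep[kb])
        merges.append((left, right, new))
        for kc in active:
            if kc in (ka, kb):
                continue
            dn = (
                size[ka] * d[frozenset([ka, kc])]
                + size[kb] * d[frozenset([kb, kc])]
            ) / (size[ka] + size[kb])
            d[frozenset([new, kc])] = dn
        active -= {ka, kb}
        members[new] = members[ka] | members[kb]
        size[new] = size[ka] + size[kb]
        rep[new] = new
        active.add(new)
    return merges


def progressive_msa(
    records: Sequence[SeqRecord],
    scheme: Optional[ScoringScheme] = None,
) -> Alignment:
    """Progressive multiple alignment (UPGMA guide tree on 3-mer distances).

    Deterministic and independent of input order up to row order: guide-tree
    ties break on sorted cluster labels, and output rows are returned in
    input order.
    """
    if len(records) < 2:
        raise ValueError("progressive_msa needs at least 2 records")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids")
    scheme = scheme or ScoringScheme()
    SM = _score_matrix(scheme)
    seqs = {r.id: r.residues for r in records}
    dist = {}
    sorted_ids = sorted(ids)
    for x, ida in enumerate(sorted_ids):
        for idb in sorted_ids[x + 1:]:
            dist[frozenset([ida, idb])] = kmer_distance(seqs[ida], seqs[idb])
    profiles = {i: ([i], [seqs[i]]) for i in ids}
    for left, right, new in _upgma_merge_order(ids, dist):
        la, ra_ = profiles.pop(left)
        lb, rb_ = profiles.pop(right)
        profiles[new] = _merge_profiles(la, ra_, lb, rb_, scheme, SM)
    (_, (out_ids, out_rows)), = profiles.items()
    order = {rid: k for k, rid in enumerate(out_ids)}
    rows = [out_rows[order[rid]] for rid in ids]
    aln = Alignment(ids, rows)
    # progressive merging never emits an all-gap column, but enforce it
    for k in range(aln.length):
        if all(r[k] == GAP for r in aln.rows):
            raise AssertionError(f"all-gap column {k + 1} in progressive MSA")
    return aln
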