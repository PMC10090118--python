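"""Distance matrices and bootstrap-supported neighbor-joining trees.

Two pairwise distances are provided: the uncorrected p-distance (share of
differing sites among compared sites) and the Tamura-Nei 1993 correction,
which allows unequal base frequencies and distinct rates for the two
transition classes (A<->G and C<->T).  Base frequencies for TN93 are
empirical, estimated per pair from the columns actually compared.

Columns holding a gap or an IUPAC ambiguity code in either member of a
pair are excluded for that pair ("pairwise deletion", the default): this
preserves information across the long 9-nt indel of the locus, and keeps
hybrid additivity codes from inflating distances.  "complete" deletion
(drop a column if any row is gapped/ambiguous) is available.

Trees are built by neighbor-joining, which recovers additive distances
exactly; node support comes from column-resampling bootstrap (share of
replicate trees containing each bipartition of the point-estimate tree).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Tuple, Union

import numpy as np
import pandas as pd

from .msa import Alignment

_ENC4 = np.full(256, -1, dtype=np.int8)
for _i, _c in enumerate("ACGT"):
    _ENC4[ord(_c)] = _i


class UndefinedDistanceError(ValueError):
    """A pair of rows shares no comparable columns."""


@dataclass
class DistanceMatrix:
    """Labelled symmetric distance matrix; flagged entries are NaN.

    ``flags`` maps an (label_a, label_b) pair to a short code explaining
    why its entry is undefined (e.g. TN93 saturation).
    """

    labels: Tuple[str, ...]
    values: np.ndarray
    flags: Dict[Tuple[str, str], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        v = np.asarray(self.values, dtype=float)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(np.nan_to_num(v), np.nan_to_num(v.T)):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(v), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        with np.errstate(invalid="ignore"):
            if np.nanmin(v) < -1e-12:
                raise ValueError("distances must be non-negative")
        self.values = v

    def __getitem__(self, pair: Tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: Union[str, Path]) -> Path:
        path = Path(path)
        self.to_dataframe().to_csv(path, float_format="%.6f")
        return path


# --------------------------------------------------------------------------
# per-pair column statistics
#
# For every unordered row pair we record, per alignment column: whether the
# column is comparable (both rows unambiguous bases), A<->G and C<->T
# transition indicators, transversion indicator, and the pooled base counts.
# All distances (and every bootstrap replicate, via column weights) are
# linear in these statistics, which turns resampling into one matmul.

_NSTAT = 8  # valid, ts1, ts2, tv, nA, nC, nG, nT


def _encode_alignment(aln: Alignment) -> np.ndarray:
    out = np.empty((aln.nrows, aln.length), dtype=np.int8)
    for r, row in enumerate(aln.rows):
        out[r] = _ENC4[np.frombuffer(row.encode("ascii"), dtype=np.uint8)]
    return out


def _pair_stats(enc: np.ndarray) -> Tuple[np.ndarray, List[Tuple[int, int]]]:
    n, L = enc.shape
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    A = np.zeros((L, len(pairs) * _NSTAT))
    for p, (i, j) in enumerate(pairs):
        ei, ej = enc[i], enc[j]
        valid = (ei >= 0) & (ej >= 0)
        ts1 = valid & (((ei == 0) & (ej == 2)) | ((ei == 2) & (ej == 0)))
        ts2 = valid & (((ei == 1) & (ej == 3)) | ((ei == 3) & (ej == 1)))
        diff = valid & (ei != ej)
        tv = diff & ~ts1 & ~ts2
        base = p * _NSTAT
        A[:, base + 0] = valid
        A[:, base + 1] = ts1
        A[:, base + 2] = ts2
        A[:, base + 3] = tv
        for b in range(4):
            A[:, base + 4 + b] = valid * ((ei == b).astype(float) + (ej == b))
    return A, pairs


def _p_from_counts(c: np.ndarray) -> np.ndarray:
    v = c[..., 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        return (c[..., 1] + c[..., 2] + c[..., 3]) / v


def _tn93_from_counts(c: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """TN93 distances from pair statistics; returns (d, flagged mask)."""
    v = c[..., 0]
    with np.errstate(divide="ignore", invalid="ignore"):
        P1 = c[..., 1] / v
        P2 = c[..., 2] / v
        Q = c[..., 3] / v
        gA = c[..., 4] / (2 * v)
        gC = c[..., 5] / (2 * v)
        gG = c[..., 6] / (2 * v)
        gT = c[..., 7] / (2 * v)
        gR = gA + gG
        gY = gC + gT
        k1 = 2 * gA * gG / gR
        k2 = 2 * gT * gC / gY
        k3 = 2 * (gR * gY - gA * gG * gY / gR - gT * gC * gR / gY)
        a1 = 1 - P1 / k1 - Q / (2 * gR)
        a2 = 1 - P2 / k2 - Q / (2 * gY)
        a3 = 1 - Q / (2 * gR * gY)
        t1 = -k1 * np.log(a1)
        t2 = -k2 * np.log(a2)
        t3 = -k3 * np.log(a3)
        # A transition class absent from the data contributes 0 in the limit
        t1 = np.where((c[..., 1] == 0) & ~np.isfinite(t1), 0.0, t1)
        t2 = np.where((c[..., 2] == 0) & ~np.isfinite(t2), 0.0, t2)
        t3 = np.where((c[..., 3] == 0) & ~np.isfinite(t3), 0.0, t3)
        d = t1 + t2 + t3
    flagged = ~np.isfinite(d) | (v == 0)
    return np.where(flagged, np.nan, d), flagged


def _complete_mask(enc: np.ndarray) -> np.ndarray:
    return (enc >= 0).all(axis=0)


def _counts(aln: Alignment, deletion: str) -> Tuple[np.ndarray, list]:
    if deletion not in ("pairwise", "complete"):
        raise ValueError("deletion policy must be 'pairwise' or 'complete'")
    enc = _encode_alignment(aln)
    if deletion == "complete":
        enc = enc[:, _complete_mask(enc)]
    A, pairs = _pair_stats(enc)
    counts = A.sum(axis=0).reshape(len(pairs), _NSTAT)
    return counts, pairs


def _square(labels, pairs, vec) -> np.ndarray:
    n = len(labels)
    M = np.zeros((n, n))
    for p, (i, j) in enumerate(pairs):
        M[i, j] = M[j, i] = vec[p]
    return M


def p_distance_matrix(aln: Alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """Uncorrected p-distance matrix (mismatches / compared columns)."""
    if aln.nrows < 2:
        raise ValueError("need at least 2 rows")
    counts, pairs = _counts(aln, deletion)
    for p, (i, j) in enumerate(pairs):
        if counts[p, 0] == 0:
            raise UndefinedDistanceError(
                f"no comparable columns between {aln.ids[i]!r} and {aln.ids[j]!r}"
            )
    return DistanceMatrix(tuple(aln.ids), _square(aln.ids, pairs, _p_from_counts(counts)))


def tn93_distance_matrix(aln: Alignment, deletion: str = "pairwise") -> DistanceMatrix:
    """Tamura-Nei (1993) distance matrix with per-pair empirical frequencies.

    Saturated or frequency-degenerate pairs get a NaN entry plus a flag
    code instead of a number.
    """
    if aln.nrows < 2:
        raise ValueError("need at least 2 rows")
    counts, pairs = _counts(aln, deletion)
    for p, (i, j) in enumerate(pairs):
        if counts[p, 0] == 0:
            raise UndefinedDistanceError(
                f"no comparable columns between {aln.ids[i]!r} and {aln.ids[j]!r}"
            )
    d, flagged = _tn93_from_counts(counts)
    flags = {}
    for p, (i, j) in enumerate(pairs):
        if flagged[p]:
            flags[(aln.ids[i], aln.ids[j])] = "saturation-or-degenerate-frequencies"
    return DistanceMatrix(tuple(aln.ids), _square(aln.ids, pairs, d), flags)


# --------------------------------------------------------------------------
# trees


class TreeNode:
    """Minimal phylogenetic tree node: children, branch length, support."""

    __slots__ = ("name", "length", "support", "children")

    def __init__(self, name=None, length=0.0, support=None, children=None):
        self.name = name
        self.length = float(length)
        self.support = support
        self.children = children if children is not None else []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> List["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def leaf_names(self) -> frozenset:
        return frozenset(l.name for l in self.leaves())

    def walk(self) -> Iterable["TreeNode"]:
        yield self
        for c in self.children:
            yield from c.walk()


def nj_tree(d: DistanceMatrix) -> TreeNode:
    """Neighbor-joining tree from a distance matrix.

    Negative branch-length estimates are clamped to zero with the deficit
    moved to the sister branch.  Ties in the Q criterion resolve to the
    smallest pair in label order (each cluster keyed by the
    lexicographically smallest leaf it contains), so the result is
    deterministic and independent of input row order.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("neighbor-joining needs at least 3 labels")
    if np.isnan(d.values).any():
        raise ValueError("distance matrix contains undefined (flagged) entries")
    D = d.values.copy()
    nodes = [TreeNode(name=lab) for lab in d.labels]
    keys = [str(lab) for lab in d.labels]
    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        iu = np.triu_indices(m, k=1)
        flat = np.full((m, m), np.inf)
        flat[iu] = Q[iu]
        cands = np.argwhere(flat == flat.min())
        i, j = min(
            (tuple(c) for c in cands),
            key=lambda ij: tuple(sorted((keys[ij[0]], keys[ij[1]]))),
        )
        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        if li < 0:
            lj -= li
            li = 0.0
        if lj < 0:
            li -= lj
            lj = 0.0
        ni, nj_ = nodes[i], nodes[j]
        ni.length, nj_.length = max(li, 0.0), max(lj, 0.0)
        new = TreeNode(children=[ni, nj_])
        dn = 0.5 * (D[i] + D[j] - D[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = np.maximum(dn[keep], 0.0)
        D2[-1, -1] = 0.0
        D = D2
        nodes = [nodes[k] for k in keep] + [new]
        keys = [keys[k] for k in keep] + [min(keys[i], keys[j])]
    a, b, c = nodes
    d01, d02, d12 = D[0, 1], D[0, 2], D[1, 2]
    la = 0.5 * (d01 + d02 - d12)
    lb = 0.5 * (d01 + d12 - d02)
    lc = 0.5 * (d02 + d12 - d01)
    a.length, b.length, c.length = (max(x, 0.0) for x in (la, lb, lc))
    root = TreeNode(children=[a, b, c])
    _collapse_zero_edges(root)
    return root


def _collapse_zero_edges(node: TreeNode, tol: float = 1e-10) -> None:
    """Collapse internal edges of ~zero length into polytomies.

    Zero-length internal edges carry no signal (they are tie-break
    artifacts on indistinguishable sequences); collapsing them keeps such
    resolutions out of the bipartition set, so identical sequences yield a
    star-like tree and earn no bootstrap support.
    """
    new_children = []
    for c in node.children:
        _collapse_zero_edges(c, tol)
        if not c.is_leaf and c.length <= tol:
            new_children.extend(c.children)
        else:
            new_children.append(c)
    node.children = new_children


def bipartitions(tree: TreeNode) -> Dict[frozenset, TreeNode]:
    """Non-trivial bipartitions of an unrooted tree, canonicalized to the
    side not containing the lexicographically smallest leaf."""
    all_leaves = tree.leaf_names()
    ref = min(all_leaves)
    out = {}
    for node in tree.walk():
        if node is tree or node.is_leaf:
            continue
        side = node.leaf_names()
        if ref in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out[frozenset(side)] = node
    return out


def _dist_square_from_counts(labels, pairs, counts, distance):
    if distance == "tn93":
        d, flagged = _tn93_from_counts(counts)
        # undefined TN93 entries (rare, resampled replicates) fall back to
        # the p-distance of the same pair so every replicate yields a tree
        p = _p_from_counts(counts)
        d = np.where(np.isnan(d), p, d)
    elif distance == "p":
        d = _p_from_counts(counts)
    else:
        raise ValueError("distance must be 'p' or 'tn93'")
    d = np.where(np.isnan(d), 0.0, d)
    return DistanceMatrix(tuple(labels), _square(labels, pairs, d))


def bootstrap_support(
    aln: Alignment,
    replicates: int = 1000,
    seed: int = 42,
    distance: str = "tn93",
    deletion: str = "pairwise",
) -> TreeNode:
    """NJ point-estimate tree with bootstrap support percentages.

    Columns are resampled with replacement ``replicates`` times; the
    support of each internal edge of the point tree is the percentage of
    replicate trees containing the same bipartition.  Reproducible given
    ``seed``.
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    enc = _encode_alignment(aln)
    if deletion == "complete":
        enc = enc[:, _complete_mask(enc)]
    L = enc.shape[1]
    A, pairs = _pair_stats(enc)
    counts = A.sum(axis=0).reshape(len(pairs), _NSTAT)
    point = nj_tree(_dist_square_from_counts(aln.ids, pairs, counts, distance))
    parts = bipartitions(point)
    hits = {side: 0 for side in parts}
    rng = np.random.default_rng(seed)
    W = np.zeros((replicates, L))
    for r in range(replicates):
        W[r] = np.bincount(rng.integers(0, L, size=L), minlength=L)
    rep_counts = (W @ A).reshape(replicates, len(pairs), _NSTAT)
    for r in range(replicates):
        t = nj_tree(_dist_square_from_counts(aln.ids, pairs, rep_counts[r], distance))
        rep_parts = bipartitions(t)
        for side in hits:
            if side in rep_parts:
                hits[side] += 1
    for side, node in parts.items():
        node.support = 100.0 * hits[side] / replicates
    return point


def to_newick(tree: TreeNode, support_threshold: float = 50.0) -> str:
    """Newick string; internal-node supports are printed only when they
    exceed ``support_threshold`` (the conventional "shown only > 50%"
    display rule)."""

    def fmt(node: TreeNode, is_root: bool) -> str:
        if node.is_leaf:
            return f"{node.name}:{max(node.length, 0.0):.6f}"
        inner = ",".join(fmt(c, False) for c in node.children)
        label = ""
        if (
            not is_root
            and node.support is not None
            and node.support > support_threshold
        ):
            label = f"{node.support:.0f}"
        if is_root:
            return f"({inner}){label}"
        return f"({inner}){label}:{max(node.length, 0.0):.6f}"

    return fmt(tree, True) + ";"


def write_newick(
    tree: TreeNode, path: Union[str, Path], support_threshold: float = 50.0
) -> Path:
    path = Path(path)
    path.write_text(to_newick(tree, support_threshold) + "\n", encoding="utf-8")
    return path
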