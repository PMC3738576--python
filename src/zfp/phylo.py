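"""Anchored domain alignment, NJ trees, bootstrap supports and group calls.

The family's members are aligned without an optimizer: both zinc fingers have
fixed-spacing blocks interrupted by three variable-length gaps (the BZF
inter-pair spacer and RING-H2 gaps 2 and 6), so each variable gap is simply
right-padded with '-' to the corpus maximum and the BZF block is concatenated
with the RING-H2 block.  The twelve ligand columns act as alignment anchors.

Distances are p-distances over shared non-gap columns, optionally Poisson
corrected (d = -ln(1 - p)); this deliberately simplifies the JTT+Gamma
distances used with optimizer-based alignments.  Trees are built by
Saitou-Nei neighbor joining with deterministic tie-breaking, supports come
from column-bootstrap replicates, and groups are maximal surviving clades of
the support-collapsed tree that mix monocot and eudicot members.
"""
from __future__ import annotations

import logging
import string
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import numpy as np
from skbio import TreeNode

from .zf_grammar import ZnMatch

logger = logging.getLogger(__name__)

UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class AnchoredAlignment:
    """Fixed-anchor alignment of concatenated BZF + RING-H2 blocks.

    All rows have equal length; ``anchor_columns`` are the 0-based columns of
    the 12 ligand residues (4 BZF + 8 RING-H2), which hold the required C/H
    in every row by construction.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    anchor_columns: tuple[int, ...]
    anchor_classes: tuple[str, ...]

    def __post_init__(self) -> None:
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("alignment rows differ in length")
        for row_id, row in zip(self.ids, self.rows):
            for col, cls in zip(self.anchor_columns, self.anchor_classes):
                if row[col] != "-" and row[col] != cls:
                    raise ValueError(
                        f"{row_id}: anchor column {col} holds {row[col]!r}, "
                        f"expected {cls!r}"
                    )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple[str, ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(m, m.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if (m < -1e-12).any() or not np.isfinite(m).all():
            raise ValueError("distances must be finite and non-negative")
        object.__setattr__(self, "matrix", m)


def _segment(sequence: str, start: int, end: int) -> str:
    """1-based inclusive slice."""
    return sequence[start - 1 : end]


def build_anchored_alignment(
    entries: Iterable[tuple[str, str, ZnMatch | None, ZnMatch | None]],
) -> AnchoredAlignment:
    """Assemble the anchored alignment from per-sequence finger matches.

    ``entries`` yields ``(sequence_id, sequence, bzf_match, ring_match)``.
    Sequences missing either match are excluded with a logged warning.
    Variable gaps (BZF spacer, RING gaps 2 and 6) are right-padded to the
    corpus maximum; fixed gaps are copied verbatim.
    """
    kept: list[tuple[str, str, ZnMatch, ZnMatch]] = []
    for seq_id, seq, bzf, ring in entries:
        if bzf is None or ring is None:
            missing = "BZF" if bzf is None else "RING-H2"
            logger.warning("excluding %s from alignment: missing %s match", seq_id, missing)
            continue
        kept.append((seq_id, seq, bzf, ring))
    if not kept:
        raise ValueError("no sequences with both finger matches")

    spacer_max = max(m[2].gap_signature[1] for m in kept)
    g2_max = max(m[3].gap_signature[1] for m in kept)
    g6_max = max(m[3].gap_signature[5] for m in kept)

    ids, rows = [], []
    for seq_id, seq, bzf, ring in kept:
        b = bzf.ligand_positions
        r = ring.ligand_positions
        spacer = _segment(seq, b[1] + 1, b[2] - 1)
        g2 = _segment(seq, r[1] + 1, r[2] - 1)
        g6 = _segment(seq, r[5] + 1, r[6] - 1)
        row = (
            _segment(seq, b[0], b[1])                 # C x x C
            + spacer.ljust(spacer_max, "-")
            + _segment(seq, b[2], b[3])               # C x x C
            + _segment(seq, r[0], r[1])               # C x x C
            + g2.ljust(g2_max, "-")
            + _segment(seq, r[2], r[5])               # C x H x x H x x C
            + g6.ljust(g6_max, "-")
            + _segment(seq, r[6], r[7])               # C x x C
        )
        ids.append(seq_id)
        rows.append(row)

    bzf_start = 0
    ring_start = 8 + spacer_max
    anchors = (
        bzf_start,
        bzf_start + 3,
        bzf_start + 4 + spacer_max,
        bzf_start + 7 + spacer_max,
        ring_start,
        ring_start + 3,
        ring_start + 4 + g2_max,
        ring_start + 4 + g2_max + 2,
        ring_start + 4 + g2_max + 5,
        ring_start + 4 + g2_max + 8,
        ring_start + 4 + g2_max + 9 + g6_max,
        ring_start + 4 + g2_max + 12 + g6_max,
    )
    classes = ("C", "C", "C", "C", "C", "C", "C", "H", "H", "C", "C", "C")
    return AnchoredAlignment(
        ids=tuple(ids),
        rows=tuple(rows),
        anchor_columns=anchors,
        anchor_classes=classes,
    )


def _char_matrix(aln: AnchoredAlignment) -> np.ndarray:
    return np.array([list(row) for row in aln.rows])


def filtered_columns(aln: AnchoredAlignment, max_gap_fraction: float = 0.5) -> np.ndarray:
    """Character matrix restricted to columns with <= 50% gaps."""
    chars = _char_matrix(aln)
    keep = (chars == "-").mean(axis=0) <= max_gap_fraction
    return chars[:, keep]


def _distances_from_chars(
    chars: np.ndarray, ids: Sequence[str], correction: str
) -> DistanceMatrix:
    if correction not in ("p", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    n = chars.shape[0]
    gaps = chars == "-"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gaps[i] & ~gaps[j]
            n_shared = int(shared.sum())
            if n_shared == 0:
                raise ValueError(
                    f"no shared non-gap columns between {ids[i]} and {ids[j]}"
                )
            p = float((chars[i, shared] != chars[j, shared]).mean())
            if correction == "poisson":
                p = min(p, 0.95)
                d[i, j] = d[j, i] = -np.log1p(-p)
            else:
                d[i, j] = d[j, i] = p
    return DistanceMatrix(ids=tuple(ids), matrix=d)


def distances(aln: AnchoredAlignment, correction: str = "poisson") -> DistanceMatrix:
    """Pairwise distances over >50%-gap-filtered columns.

    p = mismatches / shared non-gap columns; the Poisson correction is
    d = -ln(1 - p) with p capped at 0.95.
    """
    if len(aln.ids) < 3:
        raise ValueError("need at least 3 sequences")
    return _distances_from_chars(filtered_columns(aln), aln.ids, correction)


# ---------------------------------------------------------------------------
# Neighbor joining


def _clamp_pair(li: float, lj: float) -> tuple[float, float]:
    """Clamp negative branch lengths to 0, transferring the deficit to the
    sister edge so the path length between the joined taxa is conserved."""
    if li < 0:
        lj += li
        li = 0.0
    if lj < 0:
        li += lj
        lj = 0.0
    return max(li, 0.0), max(lj, 0.0)


def neighbor_joining(dm: DistanceMatrix) -> TreeNode:
    """Saitou-Nei agglomeration with deterministic tie-breaks.

    Ties on the Q criterion are broken by the smallest (i, j) index pair of
    the current working matrix.  The returned tree is unrooted, represented
    with a trifurcating root.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    D = dm.matrix.copy()
    nodes = [TreeNode(name=name) for name in dm.ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = D.sum(axis=1)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(Q <= qmin + 1e-12)
        i, j = min((int(a), int(b)) for a, b in ties if a < b)

        li = 0.5 * D[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = D[i, j] - li
        li, lj = _clamp_pair(li, lj)
        parent = TreeNode()
        child_i, child_j = nodes[i], nodes[j]
        child_i.length = float(li)
        child_j.length = float(lj)
        parent.extend([child_i, child_j])

        new_row = 0.5 * (D[i, :] + D[j, :] - D[i, j])
        new_row = np.maximum(new_row, 0.0)
        keep = [k for k in range(m) if k not in (i, j)]
        D_new = np.empty((m - 1, m - 1))
        D_new[: m - 2, : m - 2] = D[np.ix_(keep, keep)]
        D_new[: m - 2, m - 2] = new_row[keep]
        D_new[m - 2, : m - 2] = new_row[keep]
        D_new[m - 2, m - 2] = 0.0
        D = D_new
        nodes = [nodes[k] for k in keep] + [parent]

    la = 0.5 * (D[0, 1] + D[0, 2] - D[1, 2])
    lb = 0.5 * (D[0, 1] + D[1, 2] - D[0, 2])
    lc = 0.5 * (D[0, 2] + D[1, 2] - D[0, 1])
    root = TreeNode()
    for node, length in zip(nodes, (la, lb, lc)):
        node.length = float(max(length, 0.0))
        root.append(node)
    return root


# ---------------------------------------------------------------------------
# Bootstrap supports


def _bipartitions(tree: TreeNode, reference: str) -> dict[int, frozenset[str]]:
    """Map id(node) -> canonical bipartition side (the side NOT containing
    ``reference``) for every internal non-root node."""
    all_leaves = frozenset(leaf.name for leaf in tree.tips())
    out: dict[int, frozenset[str]] = {}
    for node in tree.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips())
        if reference in side:
            side = all_leaves - side
        if 2 <= len(side) <= len(all_leaves) - 2:
            out[id(node)] = side
    return out


def bootstrap_supports(
    aln: AnchoredAlignment,
    n_reps: int = 200,
    seed: int = 0,
    correction: str = "poisson",
) -> TreeNode:
    """NJ tree on the full alignment with bootstrap supports on internal edges.

    Columns of the gap-filtered alignment are resampled with replacement;
    the support of an internal edge is the fraction of replicate NJ trees
    containing the same bipartition.  Seeded and reproducible.  Replicate
    pairs with no shared non-gap column fall back to the capped maximum
    distance instead of failing.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    chars = filtered_columns(aln)
    reference = aln.ids[0]
    tree = neighbor_joining(_distances_from_chars(chars, aln.ids, correction))
    parts = _bipartitions(tree, reference)

    counts: dict[frozenset[str], int] = {side: 0 for side in parts.values()}
    rng = np.random.default_rng(seed)
    k = chars.shape[1]
    for _ in range(n_reps):
        cols = rng.integers(0, k, size=k)
        sub = chars[:, cols]
        try:
            dm = _distances_from_chars(sub, aln.ids, correction)
        except ValueError:
            cap = -np.log1p(-0.95) if correction == "poisson" else 0.95
            dm = _robust_distances(sub, aln.ids, correction, cap)
        rep_tree = neighbor_joining(dm)
        rep_parts = set(_bipartitions(rep_tree, reference).values())
        for side in counts:
            if side in rep_parts:
                counts[side] += 1

    for node in tree.non_tips(include_self=False):
        side = parts.get(id(node))
        node.support = counts[side] / n_reps if side is not None else None
    return tree


def _robust_distances(
    chars: np.ndarray, ids: Sequence[str], correction: str, cap: float
) -> DistanceMatrix:
    n = chars.shape[0]
    gaps = chars == "-"
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            shared = ~gaps[i] & ~gaps[j]
            if not shared.any():
                d[i, j] = d[j, i] = cap
                continue
            p = float((chars[i, shared] != chars[j, shared]).mean())
            if correction == "poisson":
                d[i, j] = d[j, i] = -np.log1p(-min(p, 0.95))
            else:
                d[i, j] = d[j, i] = p
    return DistanceMatrix(ids=tuple(ids), matrix=d)


def collapse_tree(tree: TreeNode, threshold: float) -> TreeNode:
    """Contract every internal edge whose support is < ``threshold``
    (strict); children of a contracted node reattach to its parent."""
    collapsed = tree.copy()
    for node in list(collapsed.non_tips(include_self=False)):
        support = getattr(node, "support", None)
        if support is not None and support < threshold:
            parent = node.parent
            children = list(node.children)
            parent.remove(node)
            parent.extend(children)
    return collapsed


def write_newick(tree: TreeNode, path) -> None:
    """Write newick; supports become internal node labels."""
    out = tree.copy()
    for node in out.non_tips(include_self=False):
        if getattr(node, "support", None) is not None:
            node.name = None  # let the writer emit the support as the label
    out.write(str(path), format="newick")


# ---------------------------------------------------------------------------
# Grouping


def _group_labels(count: int) -> list[str]:
    letters = string.ascii_uppercase
    labels = list(letters)
    while len(labels) < count:
        labels += [a + b for a in letters for b in letters]
    return labels[:count]


def collapse_and_group(
    tree: TreeNode,
    threshold: float,
    clade_labels: Mapping[str, str],
    outgroup_ids: Iterable[str] | None = None,
) -> dict[str, str]:
    """Collapse weakly supported edges and call monocot+eudicot groups.

    Candidate clades are the leaf sets defined by surviving internal edges,
    projected onto the ingroup (outgroup ids are dropped from both
    bipartition sides, so the outgroup's attachment point cannot turn
    "everything else" into a clade) and oriented as the smaller projected
    side.  A clade qualifies when it contains at least one monocot and one
    eudicot leaf; groups are the maximal qualifying clades (not nested
    inside another), labelled A, B, ... by decreasing size with ties broken
    by the lexicographically smallest member.  Outgroup leaves and leaves
    outside every group map to ``"unclassified"``.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must be in (0, 1]")
    collapsed = collapse_tree(tree, threshold)
    all_leaves = frozenset(leaf.name for leaf in collapsed.tips())
    outgroup = frozenset(outgroup_ids or ()) & all_leaves
    ingroup = all_leaves - outgroup

    candidates: set[frozenset[str]] = set()
    for node in collapsed.non_tips(include_self=False):
        side = frozenset(leaf.name for leaf in node.tips()) - outgroup
        other = ingroup - side
        if not side or not other:
            continue
        cand = min(side, other, key=lambda s: (len(s), sorted(s)))
        candidates.add(cand)

    def mixed(clade: frozenset[str]) -> bool:
        kinds = {clade_labels.get(leaf) for leaf in clade}
        return "monocot" in kinds and "eudicot" in kinds

    qualifying = [c for c in candidates if mixed(c)]
    maximal = [
        c
        for c in qualifying
        if not any(c < other for other in qualifying)
    ]
    maximal.sort(key=lambda c: (-len(c), min(c)))

    assignment = {leaf: UNCLASSIFIED for leaf in all_leaves}
    for label, clade in zip(_group_labels(len(maximal)), maximal):
        for leaf in clade:
            assignment[leaf] = label
    return assignment
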