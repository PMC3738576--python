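"""Shared test utilities: independent oracles and small generators."""
from __future__ import annotations

import numpy as np

from zfp import phylo, synthetic, zf_grammar as zg

AA = "ACDEFGHIKLMNPQRSTVWY"


# ---------------------------------------------------------------------------
# Brute-force scanner oracle (independent of zfp.zf_grammar.scan)


def oracle_placements(seq: str, pattern) -> list[tuple[int, ...]]:
    """Every ligand placement (0-based) by exhaustive per-class enumeration."""
    pos_by_class = {
        c: [i for i, ch in enumerate(seq) if ch == c] for c in set(pattern.ligands)
    }
    out: list[tuple[int, ...]] = []

    def rec(k: int, chosen: list[int]) -> None:
        if k == len(pattern.ligands):
            out.append(tuple(chosen))
            return
        for p in pos_by_class[pattern.ligands[k]]:
            if not chosen:
                rec(k + 1, [p])
            else:
                gap = p - chosen[-1] - 1
                lo, hi = pattern.gap_bounds[k - 1]
                if lo <= gap <= hi:
                    rec(k + 1, chosen + [p])

    rec(0, [])
    return out


def oracle_scan(seq: str, pattern) -> list[tuple[int, ...]]:
    """Selected 1-based placements under the documented overlap contract:
    greedy by (leftmost start, smallest total gap sum), non-overlapping."""
    cands = []
    for placement in oracle_placements(seq, pattern):
        positions = tuple(p + 1 for p in placement)
        gap_sum = positions[-1] - positions[0] - (len(positions) - 1)
        cands.append((positions[0], gap_sum, positions))
    picked: list[tuple[int, ...]] = []
    for _, _, positions in sorted(cands):
        lo, hi = positions[0], positions[-1]
        if all(hi < p[0] or lo > p[-1] for p in picked):
            picked.append(positions)
    return sorted(picked)


# ---------------------------------------------------------------------------
# Random additive trees (for NJ exactness)


def random_additive_tree(rng: np.random.Generator, n: int):
    """Random unrooted binary tree with branch lengths in [0.1, 1.1];
    returns (leaf names, distance matrix, bipartition set)."""
    names = [f"t{i}" for i in range(n)]
    # start from a 3-star, attach remaining leaves to random edges
    dist = {name: {} for name in names}
    # represent tree as adjacency with lengths on a node graph
    import itertools

    next_internal = [0]

    def new_internal():
        next_internal[0] += 1
        return f"I{next_internal[0]}"

    adj: dict[str, dict[str, float]] = {}

    def link(a, b, w):
        adj.setdefault(a, {})[b] = w
        adj.setdefault(b, {})[a] = w

    def unlink(a, b):
        del adj[a][b]
        del adj[b][a]

    center = new_internal()
    for name in names[:3]:
        link(center, name, float(rng.uniform(0.1, 1.1)))
    for name in names[3:]:
        edges = [(a, b) for a in adj for b in adj[a] if a < b]
        a, b = edges[int(rng.integers(len(edges)))]
        w = adj[a][b]
        mid = new_internal()
        split = float(rng.uniform(0.25, 0.75))
        unlink(a, b)
        link(a, mid, w * split)
        link(mid, b, w * (1 - split))
        link(mid, name, float(rng.uniform(0.1, 1.1)))

    # path distances by BFS
    mat = np.zeros((n, n))
    for i, src in enumerate(names):
        seen = {src: 0.0}
        stack = [src]
        while stack:
            u = stack.pop()
            for v, w in adj[u].items():
                if v not in seen:
                    seen[v] = seen[u] + w
                    stack.append(v)
        for j, dst in enumerate(names):
            mat[i, j] = seen[dst]

    # bipartitions of internal edges
    parts = set()
    internals = [x for x in adj if x.startswith("I")]
    for a in internals:
        for b in adj[a]:
            if not b.startswith("I") or a > b:
                continue
            # leaves on a's side when edge (a,b) removed
            seen = {a}
            stack = [a]
            while stack:
                u = stack.pop()
                for v in adj[u]:
                    if v == b and u == a:
                        continue
                    if v not in seen and not (u == a and v == b):
                        seen.add(v)
                        stack.append(v)
            side = frozenset(x for x in seen if not x.startswith("I"))
            if 2 <= len(side) <= n - 2:
                parts.add(min(side, frozenset(names) - side, key=sorted))
    return names, mat, parts


def tree_bipartitions(tree, names):
    """Canonical bipartition set of an unrooted skbio tree."""
    full = frozenset(names)
    parts = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if 2 <= len(side) <= len(full) - 2:
            parts.add(min(side, full - side, key=sorted))
    return parts


def tree_path_distances(tree, names):
    """Leaf-to-leaf path lengths of an skbio tree as an (n, n) array."""
    n = len(names)
    mat = np.zeros((n, n))
    tips = {t.name: t for t in tree.tips()}
    for i in range(n):
        for j in range(i + 1, n):
            d = tips[names[i]].distance(tips[names[j]])
            mat[i, j] = mat[j, i] = d
    return mat


# ---------------------------------------------------------------------------
# Pipeline-style scanning of a simulated family


def scan_entries(result: synthetic.SimulationResult):
    """(id, seq, bzf, ring) tuples for every simulated protein."""
    ring_pat = zg.make_btl_ring_pattern()
    bzf_pat = zg.make_bzf_pattern()
    entries = []
    for pid, seq in result.proteins.items():
        rings = zg.scan(seq, ring_pat, sequence_id=pid)
        ring = rings[0] if rings else None
        bzf = None
        if ring is not None:
            for cand in zg.scan(seq, bzf_pat, sequence_id=pid):
                if cand.end < ring.start:
                    bzf = cand
                    break
        entries.append((pid, seq, bzf, ring))
    return entries


def recover_group_count(result: synthetic.SimulationResult, seed: int,
                        n_reps: int = 200, threshold: float = 0.80) -> int:
    """Full grouping chain on a simulated family; returns the group count."""
    aln = phylo.build_anchored_alignment(scan_entries(result))
    tree = phylo.bootstrap_supports(aln, n_reps=n_reps, seed=seed)
    outgroup = [
        i for i, c in result.clades.items() if c not in ("monocot", "eudicot")
    ]
    groups = phylo.collapse_and_group(tree, threshold, result.clades, outgroup)
    return len({g for g in groups.values() if g != phylo.UNCLASSIFIED})
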