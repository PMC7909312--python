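"""Alignment-based classification of T2 RNase family members.

The classification stage places each candidate into one of the three
T2 RNase classes (all known S-RNases fall in class III) by nearest
labeled reference under p-distance, builds a neighbor-joining tree for
reporting, and flags low-polymorphic subclusters (LPSCs) within class
III — groups of near-identical sequences that lack the allelic diversity
expected of an S determinant.

A maximum-likelihood tree with bootstrap is deliberately not computed:
the screen needs class membership and subcluster identity, not branch
support, so neighbor-joining plus nearest-reference labeling stands in
(this deviation is stamped on every report header).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .align import align_with_matrix, global_align
from .io import SequenceRecord

CLASS_ORDER = ("I", "II", "III")


# ---------------------------------------------------------------------------
# Multiple alignment
# ---------------------------------------------------------------------------

@dataclass
class Msa:
    """A multiple sequence alignment: parallel rows of equal width."""

    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        widths = {len(r) for r in self.rows}
        if len(widths) > 1:
            raise ValueError(f"unequal row widths: {sorted(widths)}")

    @property
    def width(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def row(self, seq_id: str) -> str:
        return self.rows[self.ids.index(seq_id)]

    def subset(self, ids: list[str]) -> "Msa":
        return Msa(list(ids), [self.row(i) for i in ids])


_AA = "ACDEFGHIKLMNPQRSTVWY"
_SYM = _AA + "-X"
_SYM_INDEX = {c: i for i, c in enumerate(_SYM)}


def _profile_freqs(rows: list[str]) -> np.ndarray:
    """Column symbol frequencies over the 20 aa + gap + other alphabet."""
    width = len(rows[0])
    freq = np.zeros((width, len(_SYM)))
    for row in rows:
        for j, c in enumerate(row.upper()):
            freq[j, _SYM_INDEX.get(c, _SYM_INDEX["X"])] += 1
    return freq / len(rows)


def _sym_score(match: float, mismatch: float, gap: float) -> np.ndarray:
    S = np.full((len(_SYM), len(_SYM)), mismatch)
    np.fill_diagonal(S, match)
    g = _SYM_INDEX["-"]
    S[g, :] = gap
    S[:, g] = gap
    S[g, g] = 0.0
    return S


def _merge_profiles(a_rows: list[str], b_rows: list[str], S: np.ndarray,
                    gap: float) -> tuple[list[str], list[str]]:
    sub = _profile_freqs(a_rows) @ S @ _profile_freqs(b_rows).T
    ops, _ = align_with_matrix(sub, gap)
    out_a = [[] for _ in a_rows]
    out_b = [[] for _ in b_rows]
    i = j = 0
    for op in ops:
        if op in "DU":
            for k, row in enumerate(a_rows):
                out_a[k].append(row[i])
            i += 1
        else:
            for col in out_a:
                col.append("-")
        if op in "DL":
            for k, row in enumerate(b_rows):
                out_b[k].append(row[j])
            j += 1
        else:
            for col in out_b:
                col.append("-")
    return ["".join(r) for r in out_a], ["".join(r) for r in out_b]


def progressive_msa(seqs: list[SequenceRecord], match: float = 1.0,
                    mismatch: float = 0.0, gap: float = -1.0,
                    profile_mismatch: float = -1.0,
                    profile_gap: float = -2.0) -> Msa:
    """Progressive multiple alignment along a neighbor-joining guide tree.

    Pairwise p-distances from global alignments (scored with ``match``/
    ``mismatch``/``gap``) feed NJ; profiles are then merged child-wise
    in post-order.  Columns are never reordered, and ungapping any row
    recovers its input sequence.

    Profile merging scores mismatches at ``profile_mismatch`` and gaps
    at ``profile_gap``: with a zero mismatch cost, deep merges between
    divergent groups can profitably shift low-identity segments onto
    chance matches, shredding columns that are homologous across the
    whole family.  A real mismatch penalty keeps the columnar
    alignment optimal whenever homologous positions agree better than
    chance.
    """
    if not seqs:
        raise ValueError("no sequences to align")
    if len(seqs) == 1:
        return Msa([seqs[0].id], [seqs[0].residues])
    n = len(seqs)
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        aln = global_align(seqs[i].residues, seqs[j].residues,
                           match, mismatch, gap)
        D[i, j] = D[j, i] = 1.0 - aln.identity(exclude_terminal_gaps=False)
    S = _sym_score(match, profile_mismatch, profile_gap)

    if n == 2:
        order: list[tuple[int, int]] = [(0, 1)]
    else:
        tree = nj_tree(DistanceMatrix([s.id for s in seqs], D))
        order = tree.merge_order({s.id: k for k, s in enumerate(seqs)})

    profiles: dict[int, tuple[list[int], list[str]]] = {
        k: ([k], [seqs[k].residues]) for k in range(n)}
    for k, (a, b) in enumerate(order):
        ia, ra = profiles.pop(a)
        ib, rb = profiles.pop(b)
        ra2, rb2 = _merge_profiles(ra, rb, S, profile_gap)
        profiles[n + k] = (ia + ib, ra2 + rb2)
    (idx, rows), = profiles.values()
    # restore input order
    pos = {seq_idx: row for seq_idx, row in zip(idx, rows)}
    return Msa([s.id for s in seqs], [pos[k] for k in range(n)])


# ---------------------------------------------------------------------------
# Distances
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    """Symmetric pairwise p-distance matrix with taxon ids."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        if self.d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")


def p_distance(msa: Msa, i: int, j: int,
               gap_policy: str = "pairwise_deletion") -> float:
    """Proportion of differing sites between two alignment rows.

    Columns gapped in either of the two rows (``pairwise_deletion``) or
    in any row (``complete_deletion``) are excluded from the comparison.
    """
    a, b = msa.rows[i].upper(), msa.rows[j].upper()
    if gap_policy == "pairwise_deletion":
        keep = [k for k in range(len(a)) if a[k] != "-" and b[k] != "-"]
    elif gap_policy == "complete_deletion":
        keep = [k for k in range(msa.width)
                if all(row[k] != "-" for row in msa.rows)]
    else:
        raise ValueError(f"unknown gap_policy {gap_policy!r}")
    if not keep:
        raise ValueError("no overlap: zero compared sites")
    diff = sum(1 for k in keep if a[k] != b[k])
    return diff / len(keep)


def p_distance_matrix(msa: Msa, gap_policy: str = "pairwise_deletion"
                      ) -> DistanceMatrix:
    n = len(msa.ids)
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        d[i, j] = d[j, i] = p_distance(msa, i, j, gap_policy)
    return DistanceMatrix(list(msa.ids), d)


def mean_pairwise_identity(msa: Msa, member_ids: list[str] | None = None,
                           gap_policy: str = "pairwise_deletion") -> float:
    """Mean of (1 − p-distance) over all unordered member pairs."""
    ids = list(member_ids) if member_ids is not None else list(msa.ids)
    if len(ids) < 2:
        raise ValueError("mean pairwise identity needs >= 2 members")
    idx = [msa.ids.index(i) for i in ids]
    vals = [1.0 - p_distance(msa, i, j, gap_policy)
            for i, j in itertools.combinations(idx, 2)]
    return sum(vals) / len(vals)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    """An unrooted tree represented with an arbitrary internal root."""

    root: TreeNode
    negative_branches_clamped: int = 0

    def leaf_names(self) -> list[str]:
        out: list[str] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf():
                out.append(node.name)
            for child, _ in node.children:
                walk(child)

        walk(self.root)
        return out

    def to_newick(self) -> str:
        def render(node: TreeNode) -> str:
            if node.is_leaf():
                return node.name
            inner = ",".join(f"{render(c)}:{bl:.10g}" for c, bl in node.children)
            return f"({inner})"

        return render(self.root) + ";"

    def leaf_distance_matrix(self) -> DistanceMatrix:
        """Patristic (path-length) distances between all leaf pairs."""
        # ancestor depths along each root-to-leaf path; LCA depth is the
        # deepest node the two paths share
        paths: dict[str, dict[int, float]] = {}

        def walk(node: TreeNode, depth: float,
                 ancestors: dict[int, float]) -> None:
            ancestors = {**ancestors, id(node): depth}
            if node.is_leaf():
                paths[node.name] = ancestors
                return
            for child, bl in node.children:
                walk(child, depth + bl, ancestors)

        walk(self.root, 0.0, {})
        names = sorted(paths)
        n = len(names)
        d = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            pi, pj = paths[names[i]], paths[names[j]]
            lca_depth = max(pi[a] for a in set(pi) & set(pj))
            dist = max(pi.values()) + max(pj.values()) - 2 * lca_depth
            d[i, j] = d[j, i] = dist
        return DistanceMatrix(names, d)

    def merge_order(self, leaf_index: dict[str, int]) -> list[tuple[int, int]]:
        """Post-order pairwise merge schedule for progressive alignment.

        Returns pairs of working-profile keys; multifurcations at the
        root are merged left to right.
        """
        order: list[tuple[int, int]] = []
        counter = [max(leaf_index.values()) + 1]

        def walk(node: TreeNode) -> int:
            if node.is_leaf():
                return leaf_index[node.name]
            keys = [walk(c) for c, _ in node.children]
            cur = keys[0]
            for k in keys[1:]:
                order.append((cur, k))
                cur = counter[0]
                counter[0] += 1
            return cur

        walk(self.root)
        # renumber internal results to sequential merge outputs
        return order


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou–Nei neighbor joining.

    On an additive distance matrix this recovers the generating topology
    and branch lengths exactly.  Negative branch-length estimates are
    clamped to zero and counted on the returned tree.
    """
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    D = dm.d.copy()
    nodes: list[TreeNode] = [TreeNode(name=i) for i in dm.ids]
    active = list(range(n))
    clamped = 0

    def clamp(x: float) -> float:
        nonlocal clamped
        if x < 0.0:
            clamped += 1
            return 0.0
        return x

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = divmod(int(np.argmin(Q)), m)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = clamp(0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2)))
        lj = clamp(dij - (0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))))
        new = TreeNode(children=[(nodes[i], li), (nodes[j], lj)])
        newdist = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.pad(D, ((0, 1), (0, 1)))
        D[-1, :-1] = newdist
        D[:-1, -1] = newdist
        D[-1, -1] = 0.0
        nodes.append(new)
        active = [a for a in active if a not in (i, j)] + [len(nodes) - 1]

    a, b, c = active
    la = clamp(0.5 * (D[a, b] + D[a, c] - D[b, c]))
    lb = clamp(0.5 * (D[a, b] + D[b, c] - D[a, c]))
    lc = clamp(0.5 * (D[a, c] + D[b, c] - D[a, b]))
    root = TreeNode(children=[(nodes[a], la), (nodes[b], lb), (nodes[c], lc)])
    return Tree(root, negative_branches_clamped=clamped)


# ---------------------------------------------------------------------------
# Class assignment and LPSC detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassAssignment:
    """Class label with nearest-reference support for one query."""

    id: str
    label: str  # "I", "II", "III" or "unclassified"
    support: float  # identity to the nearest labeled reference
    lpsc: bool = False


def assign_class(queries: list[str], reference_labels: dict[str, str],
                 msa: Msa, floor: float = 0.30,
                 gap_policy: str = "pairwise_deletion"
                 ) -> dict[str, ClassAssignment]:
    """Label each query with the class of its nearest labeled reference.

    Support is the identity (1 − p-distance) to that reference; queries
    below ``floor`` are 'unclassified'.  Ties go to the lowest class
    index (I < II < III).
    """
    if not reference_labels:
        raise ValueError("no labeled references")
    bad = set(reference_labels.values()) - set(CLASS_ORDER)
    if bad:
        raise ValueError(f"unknown class labels {bad}")
    ref_idx = {rid: msa.ids.index(rid) for rid in reference_labels}
    out: dict[str, ClassAssignment] = {}
    for q in queries:
        qi = msa.ids.index(q)
        best_ident, best_label = -1.0, None
        for rid, ri in ref_idx.items():
            ident = 1.0 - p_distance(msa, qi, ri, gap_policy)
            label = reference_labels[rid]
            rank = CLASS_ORDER.index(label)
            key = (ident, -rank)
            if best_label is None or key > (best_ident,
                                            -CLASS_ORDER.index(best_label)):
                best_ident, best_label = ident, label
        if best_ident < floor:
            out[q] = ClassAssignment(q, "unclassified", best_ident)
        else:
            out[q] = ClassAssignment(q, best_label, best_ident)
    return out


def detect_lpsc(class3_ids: list[str], msa: Msa, identity_floor: float = 0.85,
                min_size: int = 3,
                gap_policy: str = "pairwise_deletion") -> list[list[str]]:
    """Flag low-polymorphic subclusters within class III.

    Single-linkage groups at pairwise identity >= ``identity_floor``;
    a group is an LPSC when it has >= ``min_size`` members and its mean
    pairwise identity is also >= the floor.
    """
    ids = list(class3_ids)
    if len(ids) < min_size:
        return []
    idx = {i: msa.ids.index(i) for i in ids}
    parent = {i: i for i in ids}

    def find(x: str) -> str:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in itertools.combinations(ids, 2):
        if 1.0 - p_distance(msa, idx[a], idx[b], gap_policy) >= identity_floor:
            parent[find(a)] = find(b)
    groups: dict[str, list[str]] = {}
    for i in ids:
        groups.setdefault(find(i), []).append(i)
    flagged = []
    for members in groups.values():
        if (len(members) >= min_size
                and mean_pairwise_identity(msa, members, gap_policy)
                >= identity_floor):
            flagged.append(sorted(members))
    flagged.sort()
    return flagged
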