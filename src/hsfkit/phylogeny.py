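"""Neighbor–Joining classification of Hsf proteins.

Classification uses the N-proximal region of each protein — from the start
of the DNA-binding domain to the end of the HR-A/B oligomerization region.
Pairwise evolutionary distances are Poisson-corrected proportions of
differing sites computed with pairwise deletion (only site pairs where
neither row is gapped are compared):

    p = differing comparable sites / comparable sites,   d = −ln(1 − p)

Trees are built with the Saitou–Nei Neighbor–Joining agglomeration.  Ties
in the Q criterion are broken by the lowest (row, col) index pair, and
negative branch lengths are clamped to zero with the event logged — both
are conventions this package documents because the method leaves them open.
Column-bootstrap supports (percentage of replicates containing each
internal bipartition of the full-data tree) can be annotated on the tree.

Query proteins whose region aligns are placed on a joint tree with
labelled references and assigned the majority subclass of the smallest
clade containing the query and at least one reference (falling back to the
nearest reference by patristic distance).  Queries lacking the region are
assigned by highest full-length sequence identity to a reference
(homology fallback).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from skbio import TreeNode

__all__ = [
    "MultipleAlignment",
    "DistanceMatrix",
    "PhyloTree",
    "SubclassAssignment",
    "poisson_distance",
    "build_nj",
    "bootstrap_supports",
    "assign_subclass",
    "center_star_align",
]

GAP = "-"


@dataclass(frozen=True)
class MultipleAlignment:
    """Equal-length gapped protein rows with ids."""

    ids: tuple
    rows: tuple

    def __post_init__(self):
        if len(self.rows) < 2:
            raise ValueError("alignment needs at least 2 rows")
        if len({len(r) for r in self.rows}) != 1:
            raise ValueError("alignment rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate row ids")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])

    def resample_columns(self, rng: np.random.Generator) -> "MultipleAlignment":
        cols = rng.integers(0, self.n_columns, size=self.n_columns)
        rows = tuple("".join(r[c] for c in cols) for r in self.rows)
        return MultipleAlignment(self.ids, rows)


@dataclass(frozen=True)
class DistanceMatrix:
    ids: tuple
    values: np.ndarray
    undefined_pairs: tuple = ()   # zero comparable sites
    infinite_pairs: tuple = ()    # p >= 1

    def __post_init__(self):
        v = self.values
        if v.shape != (len(self.ids), len(self.ids)):
            raise ValueError("distance matrix shape mismatch")

    @property
    def is_clean(self) -> bool:
        return not self.undefined_pairs and not self.infinite_pairs


@dataclass
class PhyloTree:
    """Unrooted NJ tree (held as a trifurcating-rooted skbio TreeNode)."""

    tree: TreeNode
    clamped_edges: tuple = ()

    def newick(self) -> str:
        return str(self.tree).strip()

    def tip_names(self) -> set:
        return {t.name for t in self.tree.tips()}


def poisson_distance(alignment: MultipleAlignment) -> DistanceMatrix:
    """Poisson-corrected distances with pairwise deletion of gapped sites."""
    n = len(alignment.rows)
    arr = np.array([list(r) for r in alignment.rows])
    gaps = arr == GAP
    d = np.zeros((n, n))
    undefined, infinite = [], []
    for i in range(n):
        for j in range(i + 1, n):
            usable = ~(gaps[i] | gaps[j])
            m = int(usable.sum())
            if m == 0:
                undefined.append((alignment.ids[i], alignment.ids[j]))
                d[i, j] = d[j, i] = np.nan
                continue
            p = float((arr[i, usable] != arr[j, usable]).sum()) / m
            if p >= 1.0:
                infinite.append((alignment.ids[i], alignment.ids[j]))
                d[i, j] = d[j, i] = np.inf
            else:
                d[i, j] = d[j, i] = -math.log(1.0 - p)
    return DistanceMatrix(alignment.ids, d, tuple(undefined), tuple(infinite))


def build_nj(matrix: DistanceMatrix) -> PhyloTree:
    """Saitou–Nei Neighbor–Joining over a clean distance matrix.

    Q-criterion ties break on the lowest (row, col) index pair; negative
    branch lengths are clamped to 0 and the clamping events recorded.
    """
    if len(matrix.ids) < 3:
        raise ValueError("NJ requires at least 3 taxa")
    if matrix.undefined_pairs or matrix.infinite_pairs:
        raise ValueError(
            "undefined/infinite distances for pairs: "
            f"{list(matrix.undefined_pairs) + list(matrix.infinite_pairs)}"
        )
    if np.any(matrix.values < 0):
        raise ValueError("negative distances in matrix")

    d = matrix.values.astype(float).copy()
    nodes = [TreeNode(name=name) for name in matrix.ids]
    clamped: list[tuple] = []

    def _clamp(length: float, label: str) -> float:
        if length < 0:
            clamped.append((label, length))
            return 0.0
        return length

    join_counter = 0
    while len(nodes) > 3:
        n = len(nodes)
        totals = d.sum(axis=1)
        # Q matrix; select min with lowest (i, j) tie-break
        best = None
        for i in range(n):
            for j in range(i + 1, n):
                q = (n - 2) * d[i, j] - totals[i] - totals[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (totals[i] - totals[j]) / (2.0 * (n - 2))
        lj = d[i, j] - li
        li = _clamp(li, nodes[i].name or f"node{join_counter}")
        lj = _clamp(lj, nodes[j].name or f"node{join_counter}")
        child_i, child_j = nodes[i], nodes[j]
        child_i.length, child_j.length = li, lj
        parent = TreeNode(children=[child_i, child_j])
        join_counter += 1
        new_d = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(n) if k not in (i, j)]
        d = np.vstack([d[keep][:, keep], new_d[keep][None, :]])
        d = np.hstack([d, np.append(new_d[keep], 0.0)[:, None]])
        nodes = [nodes[k] for k in keep] + [parent]

    # terminal trifurcation
    a, b, c = nodes
    dab, dac, dbc = d[0, 1], d[0, 2], d[1, 2]
    la = _clamp(0.5 * (dab + dac - dbc), a.name or "a")
    lb = _clamp(0.5 * (dab + dbc - dac), b.name or "b")
    lc = _clamp(0.5 * (dac + dbc - dab), c.name or "c")
    a.length, b.length, c.length = la, lb, lc
    root = TreeNode(children=[a, b, c])
    return PhyloTree(tree=root, clamped_edges=tuple(clamped))


def _bipartitions(tree: TreeNode) -> set:
    """Canonical internal bipartitions (unordered pair of tip-name sets)."""
    all_tips = frozenset(t.name for t in tree.tips())
    out = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        other = all_tips - side
        if len(side) >= 2 and len(other) >= 2:
            out.add(frozenset((side, other)))
    return out


def bootstrap_supports(
    alignment: MultipleAlignment,
    reps: int = 1000,
    seed: int = 0,
) -> PhyloTree:
    """Column-bootstrap supports on the full-data NJ tree.

    Supports (0–100, % of replicates containing the bipartition) are stored
    on internal nodes as ``node.support`` and mirrored into node names for
    newick output.  Deterministic given (alignment, reps, seed).
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = np.random.default_rng(seed)
    full = build_nj(poisson_distance(alignment))
    counts: dict[frozenset, int] = {bp: 0 for bp in _bipartitions(full.tree)}
    for _ in range(reps):
        rep_aln = alignment.resample_columns(rng)
        dm = poisson_distance(rep_aln)
        if not dm.is_clean:
            continue
        rep_tree = build_nj(dm)
        rep_bps = _bipartitions(rep_tree.tree)
        for bp in counts:
            if bp in rep_bps:
                counts[bp] += 1
    all_tips = frozenset(full.tip_names())
    for node in full.tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        bp = frozenset((side, all_tips - side))
        if bp in counts:
            support = 100.0 * counts[bp] / reps
            node.bootstrap_support = support
            node.name = f"{support:g}"
    return full


# ---------------------------------------------------------------------------
# Progressive (center-star) alignment
# ---------------------------------------------------------------------------

def _kmer_distance(a: str, b: str, k: int = 3) -> float:
    ka = {a[i : i + k] for i in range(len(a) - k + 1)}
    kb = {b[i : i + k] for i in range(len(b) - k + 1)}
    if not ka or not kb:
        return 1.0
    return 1.0 - len(ka & kb) / min(len(ka), len(kb))


def _global_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    aligner.open_end_gap_score = -5.0
    aligner.extend_end_gap_score = -0.5
    return aligner


def _gapped_pair(aln) -> tuple[str, str]:
    a_row, b_row = [], []
    coords = aln.coordinates
    a, b = aln.sequences
    for k in range(coords.shape[1] - 1):
        a0, a1 = int(coords[0, k]), int(coords[0, k + 1])
        b0, b1 = int(coords[1, k]), int(coords[1, k + 1])
        if a1 > a0 and b1 > b0:
            a_row.append(str(a[a0:a1]))
            b_row.append(str(b[b0:b1]))
        elif a1 > a0:
            a_row.append(str(a[a0:a1]))
            b_row.append(GAP * (a1 - a0))
        else:
            a_row.append(GAP * (b1 - b0))
            b_row.append(str(b[b0:b1]))
    return "".join(a_row), "".join(b_row)


def center_star_align(ids: Sequence[str], seqs: Sequence[str]) -> MultipleAlignment:
    """Progressive multiple alignment by the center-star heuristic.

    The center sequence minimizes the sum of k-mer distances to all
    others (a ClustalW-style guide heuristic); every other sequence is
    globally aligned to the center and the pairwise gap patterns are
    merged.  Adequate for the closely related within-family regions this
    package aligns; where exactness matters the caller supplies a fixed
    alignment instead.
    """
    if len(seqs) < 2:
        raise ValueError("need at least 2 sequences")
    n = len(seqs)
    dist_sum = [sum(_kmer_distance(seqs[i], seqs[j]) for j in range(n) if j != i) for i in range(n)]
    center = min(range(n), key=lambda i: (dist_sum[i], ids[i]))
    aligner = _global_aligner()

    center_seq = seqs[center]
    others = [i for i in range(n) if i != center]
    pair_rows = {}
    ins_before = np.zeros(len(center_seq) + 1, dtype=int)
    per_aln_ins = {}
    for i in others:
        aln = aligner.align(center_seq, seqs[i])[0]
        c_row, s_row = _gapped_pair(aln)
        pair_rows[i] = (c_row, s_row)
        # insertions relative to center, keyed by center position they precede
        ins = np.zeros(len(center_seq) + 1, dtype=int)
        cpos = 0
        run = 0
        for cc in c_row:
            if cc == GAP:
                run += 1
            else:
                ins[cpos] = max(ins[cpos], run)
                run = 0
                cpos += 1
        ins[len(center_seq)] = max(ins[len(center_seq)], run)
        per_aln_ins[i] = ins
        ins_before = np.maximum(ins_before, ins)

    def _project(c_row: str, s_row: str) -> str:
        out = []
        cpos = 0
        pending = []
        for cc, sc in zip(c_row, s_row):
            if cc == GAP:
                pending.append(sc)
            else:
                out.append(GAP * (ins_before[cpos] - len(pending)) + "".join(pending))
                out.append(sc)
                pending = []
                cpos += 1
        out.append(GAP * (ins_before[len(center_seq)] - len(pending)) + "".join(pending))
        return "".join(out)

    rows = [None] * n
    center_row = []
    for p, ch in enumerate(center_seq):
        center_row.append(GAP * ins_before[p] + ch)
    center_row.append(GAP * ins_before[len(center_seq)])
    rows[center] = "".join(center_row)
    for i in others:
        rows[i] = _project(*pair_rows[i])
    return MultipleAlignment(tuple(ids), tuple(rows))


# ---------------------------------------------------------------------------
# Subclass assignment
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SubclassAssignment:
    query_id: str
    subclass: Optional[str]
    method: str          # clade-majority | nearest-reference | homology-fallback | unclassified
    confidence: float


def _global_identity(a: str, b: str, aligner) -> float:
    aln = aligner.align(a, b)[0]
    counts = aln.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    return counts.identities / columns if columns else 0.0


def assign_subclass(
    query_regions: dict,
    ref_regions: dict,
    ref_labels: dict,
    query_full: Optional[dict] = None,
    ref_full: Optional[dict] = None,
    alignment: Optional[MultipleAlignment] = None,
) -> list[SubclassAssignment]:
    """Assign subclass labels to queries from labelled references.

    ``query_regions`` maps query id → DBD-to-HR-A/B region sequence, or
    ``None`` for queries lacking the region; those are classified by
    highest full-length identity to a reference (homology fallback) using
    ``query_full``/``ref_full``.  Tree-based queries take the majority
    label of the smallest clade containing the query and ≥1 reference;
    label ties break lexicographically; a clade-less query falls back to
    the nearest reference by patristic distance.  Pass ``alignment`` to
    use a fixed joint alignment instead of the built-in aligner.
    """
    assignments: list[SubclassAssignment] = []
    treeable = {q: s for q, s in query_regions.items() if s}
    fallback = [q for q, s in query_regions.items() if not s]

    if treeable:
        ids = list(ref_regions) + list(treeable)
        seqs = [ref_regions[r] for r in ref_regions] + [treeable[q] for q in treeable]
        if alignment is None:
            alignment = center_star_align(ids, seqs)
        dm = poisson_distance(alignment)
        if not dm.is_clean:
            raise ValueError(f"distances undefined for pairs {dm.undefined_pairs + dm.infinite_pairs}")
        ptree = build_nj(dm)
        tree = ptree.tree
        tip_index = {t.name: t for t in tree.tips()}
        ref_ids = set(ref_regions)
        tipdists = tree.tip_tip_distances()
        for q in treeable:
            node = tip_index[q].parent
            label = None
            conf = 0.0
            while node is not None:
                clade_refs = [t.name for t in node.tips() if t.name in ref_ids]
                if clade_refs:
                    votes: dict[str, int] = {}
                    for r in clade_refs:
                        votes[ref_labels[r]] = votes.get(ref_labels[r], 0) + 1
                    top = max(votes.values())
                    tied = sorted(l for l, v in votes.items() if v == top)
                    if len(tied) == 1:
                        label = tied[0]
                        conf = top / len(clade_refs)
                    else:
                        # vote tie: nearest reference (patristic) decides,
                        # confidence reflects that proximity
                        nearest = min(
                            (r for r in clade_refs if ref_labels[r] in tied),
                            key=lambda r: (tipdists[q, r], ref_labels[r], r),
                        )
                        label = ref_labels[nearest]
                        conf = 1.0 / (1.0 + tipdists[q, nearest])
                    break
                node = node.parent
            if label is not None:
                assignments.append(SubclassAssignment(q, label, "clade-majority", conf))
            else:  # pragma: no cover - a tree always contains the references
                nearest = min(ref_ids, key=lambda r: tipdists[q, r])
                assignments.append(
                    SubclassAssignment(q, ref_labels[nearest], "nearest-reference",
                                       1.0 / (1.0 + tipdists[q, nearest]))
                )

    if fallback:
        aligner = _global_aligner()
        q_full = query_full or {}
        r_full = ref_full or {r: s for r, s in ref_regions.items()}
        for q in fallback:
            seq = q_full.get(q)
            if not seq:
                assignments.append(SubclassAssignment(q, None, "unclassified", 0.0))
                continue
            best_ref, best_ident = None, -1.0
            for r, rseq in sorted(r_full.items()):
                ident = _global_identity(seq, rseq, aligner)
                if ident > best_ident:
                    best_ref, best_ident = r, ident
            if best_ref is None or best_ident <= 0.0:
                assignments.append(SubclassAssignment(q, None, "unclassified", 0.0))
            else:
                assignments.append(
                    SubclassAssignment(q, ref_labels[best_ref], "homology-fallback", best_ident)
                )
    order = list(query_regions)
    assignments.sort(key=lambda a: order.index(a.query_id))
    return assignments
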