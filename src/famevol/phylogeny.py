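"""Neighbor-joining phylogeny, bootstrap support, subfamily assignment.

Distances between aligned proteins use the Poisson correction
d = -ln(1 - p) with pairwise deletion of gapped columns (the common default
for protein NJ).  The NJ join order is the Saitou–Nei Q-criterion with a
deterministic lexicographic tie-break, so trees are reproducible.
Subfamilies are transferred from reference anchor leaves: a query takes the
label of the smallest clade that contains it together with at least one
anchor, provided those anchors agree.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import dendropy
import numpy as np

SUBFAMILIES = ("GT-1", "GT-2", "GT-gamma", "SIP1", "SH4")

GAP_CHARS = set("-.")


class PhyloError(ValueError):
    pass


@dataclass
class DistanceMatrix:
    labels: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise PhyloError("matrix shape does not match labels")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-12):
            raise PhyloError("matrix not symmetric")
        if np.any(np.diag(self.matrix) != 0):
            raise PhyloError("diagonal must be zero")
        if np.any(self.matrix < 0):
            raise PhyloError("negative distances")


def protein_distance(msa: dict[str, str],
                     saturation_cap: float = 20.0) -> DistanceMatrix:
    """Poisson-corrected pairwise distances with pairwise gap deletion.

    ``p`` is the mismatch fraction over columns where neither sequence has
    a gap; distances at or beyond saturation (p >= 1 - e^-cap) are capped
    at ``saturation_cap`` substitutions per site.
    """
    labels = list(msa)
    if len({len(s) for s in msa.values()}) > 1:
        raise PhyloError("aligned sequences must have equal length")
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = msa[labels[i]], msa[labels[j]]
            shared = [(x, y) for x, y in zip(a, b)
                      if x not in GAP_CHARS and y not in GAP_CHARS]
            if not shared:
                raise PhyloError(
                    f"no shared columns for {labels[i]} / {labels[j]}")
            p = sum(1 for x, y in shared if x != y) / len(shared)
            if p >= 1.0 - math.exp(-saturation_cap):
                d = saturation_cap
            else:
                d = -math.log(1.0 - p)
            D[i, j] = D[j, i] = d
    return DistanceMatrix(labels, D)


# ---------------------------------------------------------------------------
# Neighbor joining

def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou–Nei neighbor joining with deterministic tie-breaking.

    Ties in the Q-criterion resolve to the lexicographically smallest pair
    of cluster representatives (each cluster is represented by its smallest
    leaf label).  Negative branch lengths are clamped to zero.
    """
    n = len(dm.labels)
    if n < 3:
        raise PhyloError("need at least 3 taxa")
    ns = dendropy.TaxonNamespace(dm.labels)
    nodes: dict[str, dendropy.Node] = {}
    for lbl in dm.labels:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(lbl)
        nodes[lbl] = node
    # active clusters keyed by representative (smallest member leaf label)
    reps = sorted(dm.labels)
    D = {(a, b): dm.matrix[dm.labels.index(a)][dm.labels.index(b)]
         for a in dm.labels for b in dm.labels}

    def dist(a: str, b: str) -> float:
        return D[(a, b)]

    while len(reps) > 2:
        m = len(reps)
        r = {a: sum(dist(a, b) for b in reps if b != a) for a in reps}
        best = None
        for i, a in enumerate(reps):
            for b in reps[i + 1:]:
                q = (m - 2) * dist(a, b) - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
        _, a, b = best
        dab = dist(a, b)
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        la, lb = max(la, 0.0), max(lb, 0.0)
        parent = dendropy.Node()
        parent.add_child(nodes[a])
        parent.add_child(nodes[b])
        nodes[a].edge.length = la
        nodes[b].edge.length = lb
        rep = min(a, b)
        for c in reps:
            if c in (a, b):
                continue
            d_new = 0.5 * (dist(a, c) + dist(b, c) - dab)
            D[(rep, c)] = D[(c, rep)] = d_new
        reps = sorted(set(reps) - {a, b} | {rep})
        nodes[rep] = parent
    a, b = reps
    root = dendropy.Node()
    root.add_child(nodes[a])
    root.add_child(nodes[b])
    half = dist(a, b) / 2.0
    nodes[a].edge.length = half
    nodes[b].edge.length = half
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return tree


# ---------------------------------------------------------------------------
# Bootstrap

def _splits(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Non-trivial bipartitions as canonical leaf-label sets."""
    labels = sorted(t.label for t in tree.taxon_namespace)
    ref = labels[0]
    n = len(labels)
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if len(side) < 2 or len(side) > n - 2:
            continue
        if ref in side:
            side = frozenset(labels) - side
        out.add(side)
    return out


def bootstrap_support(msa: dict[str, str], n_reps: int = 100,
                      seed: int = 0) -> dendropy.Tree:
    """NJ point-estimate tree with column-bootstrap support percentages.

    Support (percent of replicate trees containing each internal
    bipartition) is written to the internal node labels of the returned
    tree.
    """
    if n_reps < 1:
        raise PhyloError("n_reps must be >= 1")
    point = neighbor_joining(protein_distance(msa))
    target = _splits(point)
    counts = {s: 0 for s in target}
    ncol = len(next(iter(msa.values())))
    rng = np.random.default_rng(seed)
    ids = list(msa)
    for _ in range(n_reps):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = {i: "".join(msa[i][c] for c in cols) for i in ids}
        rep_tree = neighbor_joining(protein_distance(resampled))
        for s in _splits(rep_tree) & target:
            counts[s] += 1
    for node in point.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        labels = sorted(t.label for t in point.taxon_namespace)
        if labels[0] in side:
            side = frozenset(labels) - side
        if side in counts:
            node.label = str(round(100.0 * counts[side] / n_reps))
    return point


# ---------------------------------------------------------------------------
# Subfamily assignment

@dataclass
class SubfamilyAssignment:
    assignments: dict[str, str]          # leaf -> subfamily ("" = unassigned)
    diagnostics: dict[str, str]


def assign_subfamilies(tree: dendropy.Tree, anchors: dict[str, str],
                       required: tuple[str, ...] | None = None
                       ) -> SubfamilyAssignment:
    """Label query leaves from the smallest anchored clade containing them.

    ``anchors`` maps reference leaf labels to subfamily names; every
    subfamily in ``required`` (default: the set present in ``anchors``)
    must have at least one anchor.  A query whose smallest anchored clade
    mixes subfamilies stays unassigned with a diagnostic.

    Clades are read in the unrooted sense — every edge bipartition defines
    two candidate clades — so the arbitrary root placement of an NJ tree
    cannot split a subfamily.
    """
    present = set(anchors.values())
    for fam in (required or sorted(present)):
        if fam not in present:
            raise PhyloError(f"no anchor for subfamily {fam!r}")
    leaf_labels = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = set(anchors) - leaf_labels
    if missing:
        raise PhyloError(f"anchor leaves absent from tree: {sorted(missing)}")
    # every edge splits the leaves in two; both sides are candidate clades
    all_leaves = frozenset(leaf_labels)
    sides: list[frozenset[str]] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        below = frozenset(lf.taxon.label for lf in node.leaf_iter())
        sides.append(below)
        sides.append(all_leaves - below)
    anchor_set = set(anchors)
    out: dict[str, str] = {}
    diag: dict[str, str] = {}
    for lbl in sorted(leaf_labels):
        if lbl in anchors:
            out[lbl] = anchors[lbl]
            continue
        candidates = [s for s in sides if lbl in s and s & anchor_set]
        smallest = min(candidates, key=lambda s: (len(s), sorted(s)))
        fams = {anchors[a] for a in smallest & anchor_set}
        if len(fams) == 1:
            out[lbl] = next(iter(fams))
        else:
            out[lbl] = ""
            diag[lbl] = ("smallest anchored clade mixes "
                         + "/".join(sorted(fams)))
    return SubfamilyAssignment(out, diag)


def subfamily_percentages(assignment: SubfamilyAssignment,
                          species_of: dict[str, str]):
    """Per-subfamily composition across species, percentages summing to 100."""
    import pandas as pd
    rows = [(species_of[g], fam) for g, fam in assignment.assignments.items()
            if fam and g in species_of]
    df = pd.DataFrame(rows, columns=["species", "subfamily"])
    counts = df.value_counts(["subfamily", "species"]).unstack(fill_value=0)
    pct = counts.div(counts.sum(axis=1), axis=0) * 100.0
    return pct.round(2)
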