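"""Distance-based phylogenetics: NJ trees, bootstrap, clade assignment.

Neighbor-joining (Q-criterion) over p- or Poisson-corrected MSA distances,
with column-resampling bootstrap supports, bipartition-based monophyly
testing, and assignment of candidate proteins to clades defined by reference
anchors (e.g. CLSY1-2 / CLSY3-4 / DRD1 reference proteins). Trees are
dendropy objects; Newick and relaxed-PHYLIP output are provided so an
external maximum-likelihood program can be run on the same alignment when
desired.

NJ tie-breaks (lowest index pair in the Q matrix) are fixed so the topology
is reproducible; negative NJ branch lengths are clamped to zero and the tree
is midpoint-rooted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import dendropy
import numpy as np

from .align import Msa


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative distances (substitutions per site)."""

    ids: tuple[str, ...]
    d: np.ndarray

    def __post_init__(self):
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")
        if not np.all(np.isfinite(self.d)) or np.any(self.d < 0):
            raise ValueError("distances must be finite and nonnegative")


def msa_distances(msa: Msa, correction: str = "poisson") -> DistanceMatrix:
    """Pairwise distances over columns where neither row has a gap.

    correction="p": mismatch fraction; "poisson": -ln(1 - p).
    """
    if len(msa.rows) < 2:
        raise ValueError("need at least two rows")
    if correction not in ("p", "poisson"):
        raise ValueError(f"unknown correction {correction!r}")
    seqs = [np.frombuffer(seq.encode(), dtype="S1") for _, seq in msa.rows]
    gap = np.bytes_(b"-")
    n = len(seqs)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = (seqs[i] != gap) & (seqs[j] != gap)
            m = int(ok.sum())
            if m == 0:
                raise ValueError(
                    f"no comparable columns between {msa.rows[i][0]!r} "
                    f"and {msa.rows[j][0]!r}")
            p = float((seqs[i][ok] != seqs[j][ok]).sum()) / m
            if correction == "poisson":
                if p >= 1.0:
                    raise ValueError("saturated pair (p = 1) under poisson")
                dist = -np.log(1.0 - p)
            else:
                dist = p
            d[i, j] = d[j, i] = dist
    return DistanceMatrix(tuple(msa.ids), d)


def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree, negative branches clamped, midpoint-rooted."""
    n = len(dm.ids)
    if n < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace()
    nodes: list[dendropy.Node] = []
    for name in dm.ids:
        taxon = dendropy.Taxon(label=name)
        tns.add_taxon(taxon)
        node = dendropy.Node(taxon=taxon)
        nodes.append(node)
    D = dm.d.astype(float).copy()
    active = list(range(n))

    def set_len(node: dendropy.Node, length: float) -> None:
        node.edge.length = max(0.0, float(length))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        # lowest (i, j) among minima, i < j
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin))
        ii, jj = min((min(a, b), max(a, b)) for a, b in ties)
        i, j = active[ii], active[jj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ii] - r[jj]) / (2.0 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        set_len(nodes[i], li)
        set_len(nodes[j], lj)
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        # distances from the new node to the rest
        new_row = 0.5 * (D[i, :] + D[j, :] - dij)
        D[i, :] = new_row
        D[:, i] = new_row
        D[i, i] = 0.0
        nodes[i] = parent
        active.remove(j)

    a, b, c = active
    center = dendropy.Node()
    set_len(nodes[a], 0.5 * (D[a, b] + D[a, c] - D[b, c]))
    set_len(nodes[b], 0.5 * (D[a, b] + D[b, c] - D[a, c]))
    set_len(nodes[c], 0.5 * (D[a, c] + D[b, c] - D[a, b]))
    for k in (a, b, c):
        center.add_child(nodes[k])
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.reroot_at_midpoint(update_bipartitions=False)
    return tree


def leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {leaf.taxon.label for leaf in tree.leaf_node_iter()}


def bipartitions(tree: dendropy.Tree) -> set[frozenset[str]]:
    """Nontrivial unrooted bipartitions, canonicalized as the side not
    containing the lexicographically smallest taxon."""
    taxa = leaf_labels(tree)
    anchor = min(taxa)
    parts = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if len(side) <= 1 or len(side) >= len(taxa) - 1:
            continue
        if anchor in side:
            side = taxa - side
        parts.add(frozenset(side))
    return parts


def robinson_foulds(t1: dendropy.Tree, t2: dendropy.Tree) -> int:
    """Symmetric bipartition-set difference (explicit brute-force RF)."""
    if leaf_labels(t1) != leaf_labels(t2):
        raise ValueError("trees have different leaf sets")
    b1, b2 = bipartitions(t1), bipartitions(t2)
    return len(b1 ^ b2)


def bootstrap_support(msa: Msa, n_replicates: int, seed: int,
                      correction: str = "poisson") -> dendropy.Tree:
    """NJ tree with column-resampling bootstrap supports in [0, 100].

    Support of an internal edge = percent of replicate NJ trees containing
    the same bipartition; stored as the internal node's label and a
    ``support`` attribute.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    base = nj_tree(msa_distances(msa, correction))
    ncol = msa.column_count
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[str], int] = {}
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        rep_rows = tuple(
            (rid, "".join(seq[c] for c in cols)) for rid, seq in msa.rows
        )
        rep_tree = nj_tree(msa_distances(Msa(rep_rows), correction))
        for part in bipartitions(rep_tree):
            counts[part] = counts.get(part, 0) + 1
    taxa = leaf_labels(base)
    anchor = min(taxa)
    for node in base.preorder_node_iter():
        if node is base.seed_node or node.is_leaf():
            continue
        side = {leaf.taxon.label for leaf in node.leaf_iter()}
        if len(side) <= 1 or len(side) >= len(taxa) - 1:
            node.support = None
            continue
        key = frozenset(taxa - side if anchor in side else side)
        support = 100.0 * counts.get(key, 0) / n_replicates
        node.support = support
        node.label = f"{support:.0f}"
    return base


def is_monophyletic(tree: dendropy.Tree, leaf_set: set[str]) -> bool:
    """True iff leaf_set is exactly one side of an edge of the unrooted tree."""
    taxa = leaf_labels(tree)
    if not leaf_set:
        raise ValueError("leaf set must be nonempty")
    unknown = set(leaf_set) - taxa
    if unknown:
        raise ValueError(f"unknown leaves: {sorted(unknown)}")
    if len(leaf_set) in (1, len(taxa)) or len(leaf_set) == len(taxa) - 1:
        return True  # trivial splits always present in the unrooted tree
    anchor = min(taxa)
    query = frozenset(taxa - set(leaf_set) if anchor in leaf_set
                      else set(leaf_set))
    return query in bipartitions(tree)


def assign_clades(tree: dendropy.Tree,
                  anchors: dict[str, str]) -> dict[str, str]:
    """Label every leaf by the anchor clade whose smallest anchor-spanning
    subtree contains it; leaves outside all anchor clades become "outlier".

    ``anchors`` maps reference leaf id -> clade label. Anchors of different
    labels that fall inside each other's spanning subtrees make the reference
    set ambiguous and raise an error.
    """
    taxa = leaf_labels(tree)
    by_label: dict[str, list[str]] = {}
    for ref, label in anchors.items():
        if ref not in taxa:
            raise ValueError(f"anchor {ref!r} not in tree")
        by_label.setdefault(label, []).append(ref)
    if not by_label:
        raise ValueError("no anchors supplied")
    # candidate clades = both sides of every edge of the unrooted tree;
    # a label's clade is the smallest side containing all its anchors
    # (root placement therefore cannot affect the assignment)
    sides: list[frozenset[str]] = [frozenset(taxa)]
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            continue
        under = frozenset(leaf.taxon.label for leaf in node.leaf_iter())
        sides.append(under)
        sides.append(frozenset(taxa - under))
    members: dict[str, set[str]] = {}
    for label, refs in by_label.items():
        refset = set(refs)
        members[label] = set(min(
            (s for s in sides if refset <= s), key=len))
    for label_a, leaves_a in members.items():
        for label_b, leaves_b in members.items():
            if label_a >= label_b:
                continue
            a_in_b = any(r in leaves_b for r in by_label[label_a])
            b_in_a = any(r in leaves_a for r in by_label[label_b])
            if a_in_b and b_in_a:
                raise ValueError(
                    f"ambiguous reference set: anchor clades {label_a!r} "
                    f"and {label_b!r} are topologically inseparable")
    out: dict[str, str] = {}
    for leaf in sorted(taxa):
        if leaf in anchors:
            out[leaf] = anchors[leaf]
            continue
        containing = [(len(leaves), label) for label, leaves in members.items()
                      if leaf in leaves]
        out[leaf] = min(containing)[1] if containing else "outlier"
    return out


def select_spanning_anchors(tree: dendropy.Tree,
                            groups: dict[str, set[str]]) -> dict[str, str]:
    """Pick, per group, the two leaves at maximal path distance as anchors.

    For a group that is monophyletic in the tree the anchors are one leaf
    from each side of the group's root split, so their spanning subtree
    covers the whole group — the property anchor-based clade assignment
    relies on. Non-monophyletic groups fall back to the leaf-pair at
    maximal path length.
    """
    pdm = None
    tns = tree.taxon_namespace
    anchors: dict[str, str] = {}
    nodes_by_leafset = {
        frozenset(leaf.taxon.label for leaf in node.leaf_iter()): node
        for node in tree.preorder_node_iter()
    }
    for label, leaves in groups.items():
        members = sorted(leaves)
        if not members:
            raise ValueError(f"group {label!r} has no leaves")
        if len(members) == 1:
            anchors[members[0]] = label
            continue
        node = nodes_by_leafset.get(frozenset(members))
        if node is not None and len(node.child_nodes()) >= 2:
            for child in node.child_nodes()[:2]:
                anchors[min(l.taxon.label for l in child.leaf_iter())] = label
            continue
        if pdm is None:
            pdm = tree.phylogenetic_distance_matrix()
        best = max(
            ((pdm.path_edge_count(tns.get_taxon(a), tns.get_taxon(b)), a, b)
             for i, a in enumerate(members) for b in members[i + 1:]),
        )
        anchors[best[1]] = label
        anchors[best[2]] = label
    return anchors


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    Path(path).write_text(tree.as_string(schema="newick"))


def read_newick(path: str | Path) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")


def write_phylip(msa: Msa, path: str | Path) -> None:
    """Relaxed PHYLIP export for optional external ML tree inference."""
    lines = [f" {len(msa.rows)} {msa.column_count}"]
    for rid, seq in msa.rows:
        lines.append(f"{rid}  {seq}")
    Path(path).write_text("\n".join(lines) + "\n")
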