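"""Distance-based phylogenetics: NJ, bootstrap supports, rooting, clade calls.

The placement workflow is: multiple alignment -> pairwise distances
(p-distance or Poisson-corrected) -> neighbor joining -> nonparametric
bootstrap over alignment columns -> outgroup rooting -> subfamily cluster
assignment for a query leaf. Approximate-ML inference and
Shimodaira-Hasegawa local supports are deliberately not implemented: the
qualitative cluster structure of the SLC6 subfamilies (NAT vs the NTT
groups), not exact support values, is what this module is for, and
NJ + bootstrap is the documented stand-in.
"""

from __future__ import annotations

from dataclasses import dataclass
import dendropy
import numpy as np

from .align import MultipleAlignment


@dataclass(frozen=True)
class DistanceMatrix:
    taxa: tuple
    d: np.ndarray

    def __post_init__(self) -> None:
        n = len(self.taxa)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match taxa")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("matrix not symmetric")
        if not np.allclose(np.diag(self.d), 0):
            raise ValueError("nonzero diagonal")
        if (self.d < -1e-12).any():
            raise ValueError("negative distances")


class SupportedTree:
    """A dendropy tree plus bootstrap supports keyed by bipartition.

    Bipartitions are canonicalized as the frozenset of leaf labels on the
    side *not* containing the lexicographically smallest taxon, so they are
    invariant under rooting and taxon order.
    """

    def __init__(self, tree: dendropy.Tree, supports: dict | None = None):
        self.tree = tree
        self.supports = dict(supports or {})

    @property
    def taxa(self) -> tuple:
        return tuple(sorted(leaf.taxon.label for leaf in self.tree.leaf_node_iter()))

    def bipartitions(self) -> set:
        return internal_bipartitions(self.tree)

    def total_length(self) -> float:
        return sum(
            e.length or 0.0 for e in self.tree.preorder_edge_iter()
        )

    def newick(self) -> str:
        """Newick with branch lengths; supports (proportions, 2 decimals) as
        internal-node labels; labels containing spaces are quoted."""
        tree = self.tree.clone(depth=1)
        ref = min(self.taxa)
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None:
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            key = _canonical(side, frozenset(self.taxa), ref)
            if key in self.supports:
                node.label = f"{self.supports[key]:.2f}"
        return tree.as_string(
            schema="newick", suppress_rooting=True, preserve_spaces=True
        ).strip()

    @classmethod
    def from_newick(cls, text: str) -> "SupportedTree":
        tree = dendropy.Tree.get(data=text, schema="newick")
        st = cls(tree)
        ref = min(st.taxa)
        full = frozenset(st.taxa)
        supports = {}
        for node in tree.preorder_node_iter():
            if node.is_leaf() or node.parent_node is None or not node.label:
                continue
            try:
                val = float(node.label)
            except ValueError:
                continue
            side = frozenset(l.taxon.label for l in node.leaf_iter())
            supports[_canonical(side, full, ref)] = val
        st.supports = supports
        return st


def _canonical(side: frozenset, full: frozenset, ref: str) -> frozenset:
    return full - side if ref in side else side


def internal_bipartitions(tree: dendropy.Tree) -> set:
    """Canonical bipartitions of the internal edges (both sides >= 2)."""
    labels = sorted(leaf.taxon.label for leaf in tree.leaf_node_iter())
    full = frozenset(labels)
    ref = labels[0]
    out = set()
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(side) < 2 or len(full) - len(side) < 2:
            continue
        out.add(_canonical(side, full, ref))
    return out


def same_topology(a: SupportedTree, b: SupportedTree) -> bool:
    """Unrooted topology equality via bipartition sets."""
    if a.taxa != b.taxa:
        return False
    return internal_bipartitions(a.tree) == internal_bipartitions(b.tree)


def _msa_byte_matrix(msa: MultipleAlignment) -> np.ndarray:
    return np.frombuffer("".join(msa.rows).encode(), dtype=np.uint8).reshape(
        msa.n_rows, msa.n_columns
    )


_GAP = ord("-")


def _distances_from_bytes(arr: np.ndarray, model: str) -> np.ndarray:
    n = arr.shape[0]
    d = np.zeros((n, n))
    nongap = arr != _GAP
    for i in range(n):
        for j in range(i + 1, n):
            both = nongap[i] & nongap[j]
            overlap = int(both.sum())
            if overlap == 0:
                raise ValueError(
                    f"rows {i} and {j} share no aligned columns"
                )
            p = float(((arr[i] != arr[j]) & both).sum()) / overlap
            if model == "p_distance":
                dij = p
            elif model == "poisson_corrected":
                if p >= 1.0:
                    raise ValueError(
                        f"saturated pair (p=1) between rows {i} and {j} "
                        "under the Poisson correction"
                    )
                dij = -np.log(1.0 - p)
            else:
                raise ValueError(f"unknown distance model {model!r}")
            d[i, j] = d[j, i] = dij
    return d


def msa_distances(
    msa: MultipleAlignment, model: str = "poisson_corrected"
) -> DistanceMatrix:
    """Pairwise distances over both-non-gap columns.

    ``p_distance`` is the mismatch fraction; ``poisson_corrected`` is
    -ln(1 - p), the Poisson multiple-hit correction (errors on saturated
    pairs, p = 1).
    """
    if msa.n_rows < 2:
        raise ValueError("need at least 2 rows")
    arr = _msa_byte_matrix(msa)
    return DistanceMatrix(taxa=tuple(msa.ids), d=_distances_from_bytes(arr, model))


def nj(dm: DistanceMatrix) -> SupportedTree:
    """Saitou-Nei neighbor joining.

    Ties in the Q criterion break on the smallest (i, j) index pair in
    node-creation order; negative branch lengths are clamped to zero with
    the deficit moved onto the sibling edge. The result is unrooted
    (trifurcating seed node); supports are empty.
    """
    n = len(dm.taxa)
    if n < 3:
        raise ValueError("neighbor joining needs >= 3 taxa")
    tns = dendropy.TaxonNamespace([str(t) for t in dm.taxa])
    nodes = [
        dendropy.Node(taxon=tns.get_taxon(str(t))) for t in dm.taxa
    ]
    d = dm.d.astype(float).copy()
    active = list(range(n))  # indices into `nodes` in creation order
    dist = {  # condensed working distances keyed by creation index pairs
        (i, j): d[i, j] for i in range(n) for j in range(i + 1, n)
    }

    def get(i, j):
        return dist[(i, j) if i < j else (j, i)]

    while len(active) > 3:
        r = len(active)
        sums = {i: sum(get(i, k) for k in active if k != i) for i in active}
        best = None
        for ai in range(r):
            for aj in range(ai + 1, r):
                i, j = active[ai], active[aj]
                q = (r - 2) * get(i, j) - sums[i] - sums[j]
                key = (q, i, j)
                if best is None or key < best:
                    best = key
        _, i, j = best
        dij = get(i, j)
        vi = dij / 2.0 + (sums[i] - sums[j]) / (2.0 * (r - 2))
        vj = dij - vi
        if vi < 0:
            vj = max(0.0, vj + vi)
            vi = 0.0
        elif vj < 0:
            vi = max(0.0, vi + vj)
            vj = 0.0
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = vi
        nodes[j].edge.length = vj
        u = len(nodes)
        nodes.append(parent)
        for k in active:
            if k in (i, j):
                continue
            dist[(k, u) if k < u else (u, k)] = (get(i, k) + get(j, k) - dij) / 2.0
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    root = dendropy.Node()
    for a, b, c in ((i, j, k), (j, i, k), (k, i, j)):
        v = (get(a, b) + get(a, c) - get(b, c)) / 2.0
        root.add_child(nodes[a])
        nodes[a].edge.length = max(0.0, v)
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=root)
    tree.is_rooted = False
    return SupportedTree(tree)


def bootstrap_support(
    msa: MultipleAlignment,
    n_reps: int = 100,
    seed: int = 0,
    model: str = "poisson_corrected",
) -> SupportedTree:
    """NJ tree with nonparametric bootstrap supports.

    Alignment columns are resampled with replacement ``n_reps`` times; the
    support of an internal edge is the fraction of replicate NJ trees
    containing the same bipartition. Deterministic given ``seed``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    main = nj(msa_distances(msa, model))
    arr = _msa_byte_matrix(msa)
    L = arr.shape[1]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in main.bipartitions()}
    taxa = tuple(msa.ids)
    for _ in range(n_reps):
        idx = rng.integers(0, L, size=L)
        try:
            drep = _distances_from_bytes(arr[:, idx], model)
        except ValueError:
            continue  # saturated replicate carries no signal for any split
        rep = nj(DistanceMatrix(taxa=taxa, d=drep))
        for bp in rep.bipartitions():
            if bp in counts:
                counts[bp] += 1
    main.supports = {bp: c / n_reps for bp, c in counts.items()}
    return main


def root_by_outgroup(st: SupportedTree, outgroup_taxa) -> SupportedTree:
    """Root on the edge separating a (monophyletic) outgroup from the rest."""
    outgroup = frozenset(str(t) for t in outgroup_taxa)
    taxa = frozenset(st.taxa)
    if not outgroup or not outgroup <= taxa:
        raise ValueError("outgroup taxa absent from tree")
    if outgroup == taxa:
        raise ValueError("outgroup cannot be the whole taxon set")
    tree = st.tree.clone(depth=1)
    target = None
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        side = frozenset(l.taxon.label for l in node.leaf_iter())
        if side == outgroup or taxa - side == outgroup:
            target = node
            break
    if target is None:
        raise ValueError(
            f"outgroup {sorted(outgroup)} is not monophyletic: no edge "
            "separates it from the ingroup"
        )
    length = target.edge.length or 0.0
    tree.reroot_at_edge(target.edge, length1=length / 2.0, length2=length / 2.0)
    tree.is_rooted = True
    return SupportedTree(tree, dict(st.supports))


@dataclass(frozen=True)
class ClusterAssignment:
    query: str
    label: str
    sister_taxa: tuple
    is_nested: bool


def cluster_assignment(st: SupportedTree, labels: dict) -> ClusterAssignment:
    """Assign the query leaf to a subfamily cluster on a rooted tree.

    ``labels`` maps every leaf to a subfamily label, with exactly one leaf
    labelled ``query``. The smallest clade containing the query and at
    least one other labelled leaf is located; its majority label (ties
    alphabetical) is the assignment. ``is_nested`` is true when every
    non-query leaf in that clade carries the same label (the query sits
    inside a monophyletic single-label cluster).
    """
    leaf_labels = {l.taxon.label for l in st.tree.leaf_node_iter()}
    missing = leaf_labels - set(labels)
    if missing:
        raise ValueError(f"unlabelled leaves: {sorted(missing)}")
    queries = [t for t, lab in labels.items() if lab == "query" and t in leaf_labels]
    if len(queries) != 1:
        raise ValueError(f"expected exactly one query leaf, found {queries}")
    query = queries[0]
    node = next(
        l for l in st.tree.leaf_node_iter() if l.taxon.label == query
    )
    while node.parent_node is not None:
        node = node.parent_node
        others = [
            l.taxon.label
            for l in node.leaf_iter()
            if l.taxon.label != query
        ]
        if others:
            votes: dict[str, int] = {}
            for t in others:
                votes[labels[t]] = votes.get(labels[t], 0) + 1
            label = min(sorted(votes), key=lambda k: -votes[k])
            return ClusterAssignment(
                query=query,
                label=label,
                sister_taxa=tuple(sorted(others)),
                is_nested=len(votes) == 1,
            )
    raise ValueError("query leaf has no labelled relatives")


def read_label_map(path) -> dict:
    """Two-column TSV: taxon id <tab> subfamily label."""
    labels = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            taxon, label = line.split("\t")
            labels[taxon] = label
    return labels
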