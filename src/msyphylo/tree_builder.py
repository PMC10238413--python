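"""Perfect-phylogeny tree building on polarized binary characters.

Variants whose derived-sample sets are mutually compatible (rooted four-gamete
test) define a laminar family of clades; the tree is that family.  The rare
incompatible character is excluded from topology and placed afterwards by
small parsimony (:func:`place_homoplasic`), never altering the topology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .variant_matrix import MISSING, PolarizedMatrix

_LATIN = [chr(c) for c in range(ord("A"), ord("Z") + 1)]
_SUFFIXES = _LATIN + [a + b for a in _LATIN for b in _LATIN]
GREEK_POOL = tuple("αβγδεζηθικλμνξοπρστυφχψω")


class TreeNode:
    """A node of the haplotype tree.

    The branch *entering* the node carries ``branch_variants`` (its identifier
    variants).  Samples attach to tip nodes; a tip with an empty identifier set
    represents samples sitting on its parent's (internal) node.
    """

    __slots__ = ("children", "parent", "branch_variants", "samples", "label",
                 "haplotype_id", "_min_sample", "_n_tip_samples")

    def __init__(self) -> None:
        self.children: list[TreeNode] = []
        self.parent: TreeNode | None = None
        self.branch_variants: list[str] = []
        self.samples: list[str] = []
        self.label: str | None = None
        self.haplotype_id: str | None = None
        self._min_sample: str = "￿"
        self._n_tip_samples: int = 0

    # -- structure -----------------------------------------------------------

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_tip(self) -> bool:
        return not self.children

    def preorder(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self):
        out = list(self.preorder())
        return reversed(out)

    def ancestors(self, include_self: bool = False):
        node = self if include_self else self.parent
        while node is not None:
            yield node
            node = node.parent

    def subtree_samples(self) -> list[str]:
        out: list[str] = []
        for node in self.preorder():
            out.extend(node.samples)
        return out

    @property
    def n_mutations(self) -> int:
        return len(self.branch_variants)


@dataclass
class HomoplasyRecord:
    variant_id: str
    branches: list[int]  # indices into HaplotypeTree.nodes (branch = node entered)
    extra_steps: int


class HaplotypeTree:
    """Rooted haplotype tree with branch identifier sets and a homoplasy ledger."""

    def __init__(self, root: TreeNode, sort_children: bool = True) -> None:
        self.root = root
        self.homoplasy_ledger: list[HomoplasyRecord] = []
        self.uninformative_variants: list[str] = []
        self._sort_children = sort_children
        self._index()

    def _index(self) -> None:
        self.nodes: list[TreeNode] = list(self.root.preorder())
        self.node_id: dict[int, int] = {id(n): i for i, n in enumerate(self.nodes)}
        self.sample_node: dict[str, TreeNode] = {}
        self.variant_branch: dict[str, TreeNode] = {}
        for node in self.nodes:
            for s in node.samples:
                self.sample_node[s] = node
            for vid in node.branch_variants:
                self.variant_branch[vid] = node
        self._annotate()

    def _annotate(self) -> None:
        for node in self.root.postorder():
            node._n_tip_samples = len(node.samples) + sum(
                c._n_tip_samples for c in node.children
            )
            mins = [c._min_sample for c in node.children]
            if node.samples:
                mins.append(min(node.samples))
            node._min_sample = min(mins) if mins else "￿"
        # canonical child order: big clades first, then smallest sample id
        if self._sort_children:
            for node in self.nodes:
                node.children.sort(key=lambda c: (-c._n_tip_samples, c._min_sample))

    # -- queries -------------------------------------------------------------

    def depth(self, node: TreeNode) -> int:
        return sum(1 for _ in node.ancestors())

    def mrca(self, samples: list[str]) -> TreeNode:
        paths = []
        for s in samples:
            node = self.sample_node[s]
            paths.append(list(node.ancestors(include_self=True))[::-1])
        mrca = self.root
        for level in zip(*paths):
            if all(n is level[0] for n in level):
                mrca = level[0]
            else:
                break
        return mrca

    def clade_sets(self) -> set[frozenset[str]]:
        """Non-trivial sample clades, for topology comparison."""
        out = set()
        for node in self.nodes:
            samples = frozenset(node.subtree_samples())
            if samples:
                out.add(samples)
        return out

    def branch_path(self, node: TreeNode) -> list[TreeNode]:
        """Root -> node path (nodes whose entering branches lead to ``node``)."""
        return list(node.ancestors(include_self=True))[::-1]

    @property
    def total_branch_mutations(self) -> int:
        return sum(n.n_mutations for n in self.nodes)

    def haplotype_count(self) -> int:
        return sum(1 for n in self.nodes if n.samples)


@dataclass
class ConflictReport:
    """Four-gamete violations between variant pairs."""

    violations: list[tuple[str, str]] = field(default_factory=list)
    skipped_pairs: int = 0

    @property
    def is_compatible(self) -> bool:
        return not self.violations


def _pattern_counts(states: np.ndarray):
    """Joint pattern count matrices over all variant pairs.

    Returns (C11, Cda) where ``C11[i, j]`` counts samples derived at both and
    ``Cda[i, j]`` counts samples derived at i but ancestral at j.
    """
    D = (states == 1).astype(np.int32)
    Z = (states == 0).astype(np.int32)
    C11 = D.T @ D
    Cda = D.T @ Z
    return C11, Cda


def four_gamete_check(matrix: PolarizedMatrix, min_joint: int = 2) -> ConflictReport:
    """Pairwise rooted compatibility: a pair fails iff patterns (1,0), (0,1)
    and (1,1) all occur among jointly non-missing samples."""
    S = matrix.states
    C11, Cda = _pattern_counts(S)
    obs = (S != MISSING).astype(np.int32)
    joint = obs.T @ obs
    bad = (C11 > 0) & (Cda > 0) & (Cda.T > 0)
    report = ConflictReport()
    ids = [v.id for v in matrix.variants]
    iu, ju = np.triu_indices(len(ids), k=1)
    for i, j in zip(iu, ju):
        if joint[i, j] < min_joint:
            report.skipped_pairs += 1
        elif bad[i, j]:
            report.violations.append((ids[i], ids[j]))
    return report


# ---------------------------------------------------------------------------
# Tree construction
# ---------------------------------------------------------------------------


def _variant_clusters(states: np.ndarray, cols: np.ndarray) -> list[list[int]]:
    """Group variant columns into putative same-branch clusters.

    Two variants join when their observed joint patterns never disagree
    ({0,1} or {1,0}) and they share at least one derived sample.  Components
    are then split until *pure*: no sample may be observed derived at one
    member and ancestral at another (such a sample distinguishes two true
    branches).  Variants masked at the splitting sample follow the side they
    share more no-disagreement links with.
    """
    sub = states[:, cols]
    D = sub == 1
    Z = sub == 0
    C11, Cda = _pattern_counts(sub)
    same = (Cda == 0) & (Cda.T == 0) & (C11 > 0)

    k = len(cols)
    parent = list(range(k))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a in range(k):
        for b in np.flatnonzero(same[a, a + 1:]) + a + 1:
            ra, rb = find(a), find(int(b))
            if ra != rb:
                parent[rb] = ra
    comps: dict[int, list[int]] = {}
    for a in range(k):
        comps.setdefault(find(a), []).append(a)

    final: list[list[int]] = []
    stack = [sorted(g) for g in comps.values()]
    while stack:
        g = stack.pop()
        if len(g) == 1:
            final.append(g)
            continue
        Dg = D[:, g]
        Zg = Z[:, g]
        impure = np.flatnonzero(Dg.any(axis=1) & Zg.any(axis=1))
        if impure.size == 0:
            final.append(g)
            continue
        s = int(impure[0])
        side_a = [v for v in g if D[s, v]]
        side_b = [v for v in g if Z[s, v]]
        undecided = [v for v in g if sub[s, v] == MISSING]
        for v in undecided:
            la = int(same[v, side_a].sum()) if side_a else 0
            lb = int(same[v, side_b].sum()) if side_b else 0
            (side_a if la >= lb else side_b).append(v)
        for side in (sorted(side_a), sorted(side_b)):
            if side:
                stack.append(side)
    return sorted(final)


def _cluster_memberships(
    states: np.ndarray, cols: np.ndarray, clusters: list[list[int]]
) -> list[np.ndarray]:
    """Consensus derived-sample set per cluster, with cluster-level routing.

    A sample observed derived at any member is in; observed ancestral at any
    member is out; a sample masked at every member is routed in iff it is a
    member of some cluster lying weakly below this one.
    """
    sub = states[:, cols]
    D = sub == 1
    Z = sub == 0
    member = [D[:, g].any(axis=1) for g in clusters]
    excluded = [Z[:, g].any(axis=1) for g in clusters]
    routed = [m.copy() for m in member]
    for gi, g in enumerate(clusters):
        unknown = ~member[gi] & ~excluded[gi]
        if not unknown.any():
            continue
        for hj, h in enumerate(clusters):
            if hj == gi:
                continue
            # h weakly below g: h's members never observed outside g
            if (member[hj] & excluded[gi]).any():
                continue
            if not (member[hj] & member[gi]).any():
                continue
            routed[gi] |= member[hj] & unknown
    return routed


def build_tree(
    matrix: PolarizedMatrix, nomenclature: "Nomenclature | None" = None
) -> HaplotypeTree:
    """Construct the perfect phylogeny of all mutually compatible variants.

    Columns are taken in order of descending derived count (ties by coordinate
    then id); a variant incompatible with an earlier-accepted one is excluded
    from topology and afterwards placed by :func:`place_homoplasic`.  Identical
    sample rows collapse to a single tip haplotype.  Multifurcations are kept.
    """
    S = matrix.states
    n, m = S.shape
    polarized = np.array([v.ancestral != "unknown" for v in matrix.variants])
    dcount = (S == 1).sum(axis=0)
    if not polarized.any():
        raise ValueError("matrix contains no polarized variants")

    informative = polarized & (dcount > 0)
    uninformative = [matrix.variants[j].id for j in np.flatnonzero(polarized & (dcount == 0))]

    order = sorted(
        np.flatnonzero(informative),
        key=lambda j: (-int(dcount[j]), matrix.variants[j].pos, matrix.variants[j].id),
    )
    C11, Cda = _pattern_counts(S)
    conflict = (C11 > 0) & (Cda > 0) & (Cda.T > 0)

    accepted: list[int] = []
    homoplasic: list[int] = []
    for j in order:
        if accepted and conflict[j, accepted].any():
            homoplasic.append(j)
        else:
            accepted.append(j)

    cols = np.array(accepted, dtype=int)
    D = S == 1
    if cols.size:
        clusters = _variant_clusters(S, cols)
        memberships = _cluster_memberships(S, cols, clusters)
    else:
        clusters, memberships = [], []

    # enforce laminarity: a set crossing an accepted one is repaired using its
    # certain (observed-derived) members; only genuine conflicts are demoted
    order2 = sorted(
        range(len(clusters)),
        key=lambda gi: (-int(memberships[gi].sum()),
                        min(matrix.variants[cols[v]].pos for v in clusters[gi])),
    )
    groups: dict[bytes, list[int]] = {}
    accepted_sets: list[tuple[bytes, np.ndarray]] = []
    for gi in order2:
        a = memberships[gi].copy()
        certain = D[:, cols[clusters[gi]]].any(axis=1)
        variant_cols = [int(cols[v]) for v in clusters[gi]]
        demote = False
        changed = True
        while changed and not demote:
            changed = False
            for _, b in accepted_sets:
                if (a & b).any() and (a & ~b).any() and (b & ~a).any():
                    if not (certain & ~b).any():
                        a &= b  # routed members outside b were spurious
                        changed = True
                    elif not (certain & b).any():
                        a &= ~b
                        changed = True
                    else:
                        demote = True
                    break
        if demote or not a.any():
            homoplasic.extend(variant_cols)
            continue
        key = np.packbits(a).tobytes()
        if key in groups:
            groups[key].extend(variant_cols)
        else:
            groups[key] = variant_cols
            accepted_sets.append((key, a))
    group_sets = dict(accepted_sets)

    # build nodes from the laminar family (processed large -> small)
    root = TreeNode()
    universal = np.ones(n, dtype=bool)
    node_of: list[tuple[np.ndarray, TreeNode]] = [(universal, root)]
    for key, a in accepted_sets:
        if a.all():
            root.branch_variants.extend(
                sorted((matrix.variants[j].id for j in groups[key]))
            )
            continue
        parent = root
        best = n + 1
        for bset, bnode in node_of[1:]:
            if not (a & ~bset).any():  # a subset of bset
                size = int(bset.sum())
                if size < best:
                    best, parent = size, bnode
        node = parent.add_child(TreeNode())
        node.branch_variants = sorted(matrix.variants[j].id for j in groups[key])
        node_of.append((a, node))

    # attach samples at their smallest containing clade
    sample_home: list[TreeNode] = [root] * n
    best_size = [n + 1] * n
    for bset, bnode in node_of[1:]:
        size = int(bset.sum())
        for i in np.flatnonzero(bset):
            if size < best_size[i]:
                best_size[i] = size
                sample_home[i] = bnode

    # collapse identical rows to tip haplotypes (full row incl. homoplasic, STR)
    hom_cols = np.array(sorted(homoplasic), dtype=int)
    str_ids = sorted(matrix.str_alleles)
    memb = (np.column_stack([a for _, a in accepted_sets])
            if accepted_sets else np.zeros((n, 0), bool))
    by_node: dict[int, dict[tuple, list[str]]] = {}
    for i, s in enumerate(matrix.samples):
        node = sample_home[i]
        sig = (
            tuple(memb[i, :]),
            tuple(S[i, hom_cols]) if hom_cols.size else (),
            tuple(int(matrix.str_alleles[x][i]) for x in str_ids),
        )
        by_node.setdefault(id(node), {}).setdefault(sig, []).append(s)
    for bset, bnode in node_of:
        buckets = by_node.get(id(bnode))
        if not buckets:
            continue
        for sig in sorted(buckets, key=lambda t: min(buckets[t])):
            tip = bnode.add_child(TreeNode())
            tip.samples = sorted(buckets[sig])

    tree = HaplotypeTree(root)
    tree.uninformative_variants = uninformative

    # haplotype ids in canonical traversal order
    k = 0
    for node in tree.root.preorder():
        if node.samples:
            k += 1
            node.haplotype_id = f"HT{k:04d}"
    tree._index()

    for j in sorted(set(homoplasic),
                    key=lambda j: (-int(dcount[j]), matrix.variants[j].pos)):
        place_homoplasic(tree, matrix.variants[j].id, matrix)

    if nomenclature is not None:
        name_haplogroups(tree, nomenclature)
    return tree


# ---------------------------------------------------------------------------
# Small parsimony for incompatible characters
# ---------------------------------------------------------------------------


def place_homoplasic(
    tree: HaplotypeTree, variant_id: str, matrix: PolarizedMatrix
) -> HomoplasyRecord:
    """Minimal-change branch assignment of one binary character on the fixed tree.

    One post-order (cost) and one pre-order (backtrack) pass; the root state is
    fixed ancestral.  Missing calls are free in both states.  Ties resolve to
    the parent's state, so a compatible character degenerates to its single
    origin branch.  The result is appended to the tree's homoplasy ledger.
    """
    j = matrix.variant_index(variant_id)
    state_of = {s: int(matrix.states[i, j]) for i, s in enumerate(matrix.samples)}

    INF = 10**9
    cost: dict[int, list[int]] = {}
    for node in tree.root.postorder():
        c = [0, 0]
        for s in node.samples:
            st = state_of.get(s, MISSING)
            if st != MISSING:
                c[1 - st] += 1
        for child in node.children:
            cc = cost[id(child)]
            c[0] += min(cc[0], cc[1] + 1)
            c[1] += min(cc[1], cc[0] + 1)
        c[0] = min(c[0], INF)
        c[1] = min(c[1], INF)
        cost[id(node)] = c

    branches: list[int] = []
    score = cost[id(tree.root)][0]
    assign: dict[int, int] = {}
    for node in tree.root.preorder():
        parent_state = 0 if node.parent is None else assign[id(node.parent)]
        c = cost[id(node)]
        keep = c[parent_state]
        flip = c[1 - parent_state] + 1
        state = parent_state if keep <= flip else 1 - parent_state
        assign[id(node)] = state
        if state != parent_state:
            branches.append(tree.node_id[id(node)])
        # changes on zero-length sample pendants count and land on this node
        for s in node.samples:
            st = state_of.get(s, MISSING)
            if st != MISSING and st != state:
                branches.append(tree.node_id[id(node)])

    record = HomoplasyRecord(
        variant_id=variant_id, branches=sorted(set(branches)),
        extra_steps=max(0, score - 1)
    )
    tree.homoplasy_ledger.append(record)
    return record


def parsimony_scores(tree: HaplotypeTree, samples: list[str],
                     chars: np.ndarray) -> np.ndarray:
    """Minimum change counts for many binary characters at once.

    ``chars`` is a (n_characters x len(samples)) 0/1/-1 array; the root state
    is fixed ancestral.  Same recurrence as :func:`place_homoplasic`, evaluated
    column-wise over all characters.
    """
    chars = np.asarray(chars)
    col = {s: k for k, s in enumerate(samples)}
    nc = chars.shape[0]
    cost: dict[int, np.ndarray] = {}
    for node in tree.root.postorder():
        c = np.zeros((2, nc), dtype=np.int32)
        for s in node.samples:
            k = col.get(s)
            if k is None:
                continue
            st = chars[:, k]
            c[0] += st == 1
            c[1] += st == 0
        for child in node.children:
            cc = cost[id(child)]
            c[0] += np.minimum(cc[0], cc[1] + 1)
            c[1] += np.minimum(cc[1], cc[0] + 1)
        cost[id(node)] = c
    return cost[id(tree.root)][0].copy()


def parsimony_score(tree: HaplotypeTree, state_of: dict[str, int]) -> int:
    """Minimum number of state changes for a binary character (root ancestral)."""
    cost: dict[int, list[int]] = {}
    for node in tree.root.postorder():
        c = [0, 0]
        for s in node.samples:
            st = state_of.get(s, MISSING)
            if st != MISSING:
                c[1 - st] += 1
        for child in node.children:
            cc = cost[id(child)]
            c[0] += min(cc[0], cc[1] + 1)
            c[1] += min(cc[1], cc[0] + 1)
        cost[id(node)] = c
    return cost[id(tree.root)][0]


# ---------------------------------------------------------------------------
# Haplogroup nomenclature
# ---------------------------------------------------------------------------


@dataclass
class Nomenclature:
    """Deterministic haplogroup naming.

    ``anchors`` maps a backbone label (e.g. "p", "db", "da1", "daC") to sample
    ids; the label lands on the MRCA of those samples.  Unanchored internal
    nodes get ``<parent>_<letter>`` with children ordered canonically; tips
    whose identifier set is empty (samples sitting on an internal node) get
    ``<parent>*``.  Nodes whose subtrees hold only ancient samples draw from a
    Greek-letter pool in pre-order.
    """

    anchors: dict[str, list[str]] = field(default_factory=dict)
    root_label: str = "Y"
    ancient_samples: frozenset[str] = frozenset()
    greek_pool: tuple[str, ...] = GREEK_POOL


def name_haplogroups(tree: HaplotypeTree, nomenclature: Nomenclature) -> dict[int, str]:
    """Label every node; returns node index -> label (also set on the nodes)."""
    missing_anchor_samples = [
        s
        for samples in nomenclature.anchors.values()
        for s in samples
        if s not in tree.sample_node
    ]
    if missing_anchor_samples:
        raise KeyError(f"anchor samples absent from tree: {sorted(missing_anchor_samples)}")

    anchored: dict[int, str] = {}
    for label, samples in nomenclature.anchors.items():
        node = tree.mrca(samples)
        anchored[id(node)] = label

    greek = iter(nomenclature.greek_pool)
    ancient = nomenclature.ancient_samples
    labels: dict[int, str] = {}
    for node in tree.root.preorder():
        if node.parent is None:
            label = anchored.get(id(node), nomenclature.root_label)
        elif id(node) in anchored:
            label = anchored[id(node)]
        else:
            parent_label = node.parent.label or nomenclature.root_label
            subtree = node.subtree_samples()
            if ancient and subtree and all(s in ancient for s in subtree):
                label = f"{next(greek)}*"
            elif node.is_tip and not node.branch_variants:
                label = f"{parent_label}*"
            else:
                label = _child_label(node, parent_label, anchored)
        node.label = label
        labels[tree.node_id[id(node)]] = label
    return labels


def _child_label(node: TreeNode, parent_label: str, anchored: dict[int, str]) -> str:
    siblings = [
        c
        for c in node.parent.children
        if id(c) not in anchored and not (c.is_tip and not c.branch_variants)
    ]
    k = siblings.index(node)
    return f"{parent_label}_{_SUFFIXES[k]}"


# ---------------------------------------------------------------------------
# Newick round-trip
# ---------------------------------------------------------------------------


def to_newick(tree: HaplotypeTree, with_branch_mutations: bool = False) -> str:
    """Canonical Newick string; branch lengths = mutation counts when requested."""

    def fmt(node: TreeNode) -> str:
        name = (node.haplotype_id or node.label or "") if node.is_tip \
            else (node.label or "")
        if node.children:
            inner = ",".join(fmt(c) for c in node.children)
            s = f"({inner}){name}"
        else:
            s = name
        if with_branch_mutations and node.parent is not None:
            s += f":{node.n_mutations}"
        return s

    return fmt(tree.root) + ";"


def from_newick(newick: str) -> HaplotypeTree:
    """Parse a Newick string (via dendropy) back into a bare HaplotypeTree."""
    import dendropy

    dtree = dendropy.Tree.get(data=newick, schema="newick",
                              suppress_internal_node_taxa=False,
                              preserve_underscores=True)

    def convert(dnode) -> TreeNode:
        node = TreeNode()
        name = None
        if dnode.taxon is not None:
            name = dnode.taxon.label
        elif dnode.label:
            name = dnode.label
        if name:
            if name.startswith("HT"):
                node.haplotype_id = name
                node.samples = [name]
            else:
                node.label = name
        if dnode.edge.length is not None:
            # preserve mutation counts through the round-trip
            node.branch_variants = [f"?{k}" for k in range(int(dnode.edge.length))]
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    return HaplotypeTree(root, sort_children=False)
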