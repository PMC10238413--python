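"""Independent oracle helpers shared across test modules."""

from __future__ import annotations

import numpy as np

from msyphylo.simulate import SimDataset
from msyphylo.variant_matrix import PolarizedMatrix, Variant


def make_variants(n: int, ancestral: str = "ref") -> list[Variant]:
    return [
        Variant(id=f"v{j:03d}", contig="Y", pos=10 * (j + 1), ref_allele="A",
                alt_allele="G", ancestral=ancestral)
        for j in range(n)
    ]


def make_matrix(rows: list[list[int]], sample_prefix: str = "S",
                variants: list[Variant] | None = None) -> PolarizedMatrix:
    """Matrix from literal rows; -1 marks missing cells."""
    arr = np.asarray(rows, dtype=np.int8)
    samples = [f"{sample_prefix}{i + 1}" for i in range(arr.shape[0])]
    return PolarizedMatrix(
        samples=samples,
        variants=variants or make_variants(arr.shape[1]),
        states=arr,
    )


def mutated_truth_clades(ds: SimDataset) -> set[frozenset[str]]:
    """Truth clades identifiable from data: subtended by >=1 mutation."""
    mutated = {id(b) for b in ds.truth.variant_branch.values()}
    out = set()
    for node in ds.truth.tree.preorder():
        if node.parent is not None and id(node) in mutated:
            out.add(frozenset(t.name for t in node.tips()))
    return out


def reconstructed_clades(tree) -> set[frozenset[str]]:
    return {
        frozenset(n.subtree_samples())
        for n in tree.nodes
        if n.branch_variants and n.parent is not None
    }


def true_backbone_path(ds: SimDataset, sample: str) -> list[str]:
    """Backbone branches (p, d, db, da1) on the sample's true root path."""
    node = ds.truth.sample_node[sample]
    path_ids = {id(n) for n in node.path_from_root()}
    return [
        name for name in ("p", "d", "db", "da1")
        if name in ds.truth.backbone_nodes
        and id(ds.truth.backbone_nodes[name]) in path_ids
    ]


def brute_force_parsimony(tree, state_of: dict[str, int]) -> int:
    """Exhaustive minimum-change score for a binary character (root ancestral).

    Enumerates every 0/1 assignment to non-root nodes and counts edge changes
    plus mismatches against sample states attached to nodes (missing = free).
    Independent of the package's dynamic-programming implementation.
    """
    nodes = [n for n in tree.root.preorder() if n.parent is not None]
    best = 10**9
    for bits in range(2 ** len(nodes)):
        states = {id(tree.root): 0}
        for k, node in enumerate(nodes):
            states[id(node)] = (bits >> k) & 1
        cost = 0
        for node in nodes:
            cost += states[id(node)] != states[id(node.parent)]
        for node in tree.nodes:
            for s in node.samples:
                st = state_of.get(s, -1)
                if st != -1:
                    cost += states[id(node)] != st
        best = min(best, cost)
    return best
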