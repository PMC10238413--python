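"""Tree-guided imputation of missing genotypes.

A missing cell is filled from the sample's placement on the haplotype tree:
derived if the variant's branch lies on the sample's root path, ancestral if
the sample demonstrably diverged elsewhere — in both cases only when at least
one observed identifier corroborates the decision.  Observed cells are never
touched, and a second pass imputes nothing (idempotence).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tree_builder import HaplotypeTree, TreeNode
from .variant_matrix import MISSING, PolarizedMatrix


@dataclass
class ImputationReport:
    imputed: int = 0
    unresolved: int = 0
    per_sample: dict[str, int] = field(default_factory=dict)
    per_variant: dict[str, int] = field(default_factory=dict)

    def check(self, input_missing: int) -> None:
        if self.imputed + self.unresolved != input_missing:
            raise AssertionError("imputation counts do not reconcile")

    def to_frame(self) -> pd.DataFrame:
        rows = [("__total_imputed__", self.imputed),
                ("__total_unresolved__", self.unresolved)]
        rows += sorted(self.per_sample.items())
        return pd.DataFrame(rows, columns=["key", "imputed_cells"])


def impute_missing(
    matrix: PolarizedMatrix, tree: HaplotypeTree
) -> tuple[PolarizedMatrix, ImputationReport, np.ndarray]:
    """Fill missing cells from tree placement.

    Returns ``(imputed matrix, report, mask)`` where ``mask[i, j]`` is True for
    cells set by imputation.  Rules for a missing cell (sample s, variant v on
    branch b):

    * another identifier of b observed in s -> copy the majority observed state;
    * b on s's root path with an observed derived identifier at or below b -> 1;
    * b diverging from s's path above s's deepest observed derived branch -> 0;
    * otherwise the cell stays missing.
    """
    for s in matrix.samples:
        if s not in tree.sample_node:
            raise KeyError(f"sample {s!r} not placed on the tree")

    S = matrix.states.copy()
    n, m = S.shape
    report = ImputationReport()
    input_missing = int((S == MISSING).sum())

    branch_of: list[TreeNode | None] = [
        tree.variant_branch.get(v.id) for v in matrix.variants
    ]
    # variants with no observed derived call sit on no branch: every sample
    # with at least one observed call elsewhere is imputed ancestral
    derived_free = set(tree.uninformative_variants)
    free_cols = [j for j, v in enumerate(matrix.variants) if v.id in derived_free]
    depth = {id(node): tree.depth(node) for node in tree.nodes}
    var_cols_of_branch: dict[int, list[int]] = {}
    for j, b in enumerate(branch_of):
        if b is not None:
            var_cols_of_branch.setdefault(id(b), []).append(j)

    for i, sample in enumerate(matrix.samples):
        row = S[i, :]
        n_observed = int((row != MISSING).sum())
        free_filled = 0
        if n_observed:
            for j in free_cols:
                if row[j] == MISSING:
                    S[i, j] = 0
                    free_filled += 1
        missing_cols = [j for j in np.flatnonzero(row == MISSING)
                        if branch_of[j] is not None]
        if not missing_cols and not free_filled:
            continue
        # deepest branch with an observed derived identifier defines the path
        derived_branches = [
            branch_of[j] for j in np.flatnonzero(row == 1) if branch_of[j] is not None
        ]
        if derived_branches:
            deepest = max(derived_branches, key=lambda b: depth[id(b)])
            path = {id(a) for a in deepest.ancestors(include_self=True)}
            deepest_depth = depth[id(deepest)]
        else:
            deepest = tree.root
            path = {id(tree.root)}
            deepest_depth = 0

        count = free_filled
        for j in sorted(missing_cols, key=lambda j: depth[id(branch_of[j])]):
            b = branch_of[j]
            value = MISSING
            # same-branch corroboration first: identifiers of one branch agree
            sibs = [k for k in var_cols_of_branch[id(b)] if k != j and row[k] != MISSING]
            if sibs:
                votes = row[sibs]
                value = 1 if (votes == 1).sum() * 2 > len(sibs) else (
                    0 if (votes == 0).sum() * 2 > len(sibs) else MISSING)
            elif id(b) in path:
                below = any(
                    id(b) in {id(a) for a in db.ancestors(include_self=True)}
                    for db in derived_branches
                )
                if below:
                    value = 1
            else:
                # divergence point of b from the sample's path
                anc = b
                while id(anc) not in path:
                    anc = anc.parent
                if deepest_depth > depth[id(anc)]:
                    value = 0
            if value != MISSING:
                S[i, j] = value
                count += 1
        if count:
            report.per_sample[sample] = count
            report.imputed += count
            for j in missing_cols:
                if S[i, j] != MISSING:
                    vid = matrix.variants[j].id
                    report.per_variant[vid] = report.per_variant.get(vid, 0) + 1

    report.unresolved = int((S == MISSING).sum())
    report.check(input_missing)

    out = PolarizedMatrix(
        samples=list(matrix.samples),
        variants=list(matrix.variants),
        states=S,
        str_alleles=dict(matrix.str_alleles),
        groups=dict(matrix.groups),
    )
    mask = (matrix.states == MISSING) & (S != MISSING)
    return out, report, mask
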