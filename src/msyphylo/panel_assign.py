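"""Major-haplogroup assignment from a small diagnostic marker panel.

The panel is a tree of branches, each tagged by one or more markers with known
ancestral/derived alleles.  A sample is assigned by walking the branch tree
root-to-tip along derived calls; samples derived along a path prefix but
ancestral at every genotyped marker immediately below land on the inner node
(label suffixed with ``*``).  Contradictory call patterns are reported as
"inconsistent", never dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

NA = "NA"


@dataclass(frozen=True)
class Marker:
    id: str
    branch: str
    ancestral_allele: str
    derived_allele: str


@dataclass
class MarkerPanel:
    """Ordered markers plus the branch partial order (a tree)."""

    name: str
    markers: list[Marker]
    branch_parent: dict[str, str | None]  # branch -> parent branch (None = root child)

    def __post_init__(self) -> None:
        branches = set(self.branch_parent)
        for m in self.markers:
            if m.branch not in branches:
                raise ValueError(f"marker {m.id} maps to unknown branch {m.branch}")
        for b, p in self.branch_parent.items():
            if p is not None and p not in branches:
                raise ValueError(f"branch {b} has unknown parent {p}")
            # tree order: walking up must terminate without cycles
            seen = {b}
            cur = p
            while cur is not None:
                if cur in seen:
                    raise ValueError(f"cycle in branch order at {cur}")
                seen.add(cur)
                cur = self.branch_parent[cur]

    @property
    def branches(self) -> list[str]:
        return list(self.branch_parent)

    def children(self, branch: str | None) -> list[str]:
        return sorted(b for b, p in self.branch_parent.items() if p == branch)

    def markers_of(self, branch: str) -> list[Marker]:
        return [m for m in self.markers if m.branch == branch]

    def is_leaf(self, branch: str) -> bool:
        return not self.children(branch)

    def ancestors(self, branch: str) -> list[str]:
        out = []
        cur = self.branch_parent[branch]
        while cur is not None:
            out.append(cur)
            cur = self.branch_parent[cur]
        return out

    def to_tsv(self, path) -> None:
        rows = [
            (m.id, m.branch, self.branch_parent[m.branch] or "", m.ancestral_allele,
             m.derived_allele)
            for m in self.markers
        ]
        pd.DataFrame(
            rows,
            columns=["marker", "branch", "parent_branch", "ancestral_allele",
                     "derived_allele"],
        ).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path, name: str | None = None) -> "MarkerPanel":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        markers = [
            Marker(r.marker, r.branch, r.ancestral_allele, r.derived_allele)
            for r in df.itertuples()
        ]
        parent = {r.branch: (r.parent_branch or None) for r in df.itertuples()}
        return cls(name=name or str(path), markers=markers, branch_parent=parent)


@dataclass
class Assignment:
    sample: str
    label: str  # mjHG, "<branch>*", "inconsistent" or "unassigned"
    call_string: str = ""
    conflicts: list[str] = field(default_factory=list)
    flags: list[str] = field(default_factory=list)


def _branch_states(panel: MarkerPanel, calls: dict[str, str]) -> dict[str, str]:
    """Aggregate marker calls into per-branch derived/ancestral/NA states."""
    states: dict[str, str] = {}
    for b in panel.branches:
        obs = []
        for m in panel.markers_of(b):
            allele = calls.get(m.id, NA)
            if allele in (NA, "", None):
                continue
            if allele == m.derived_allele:
                obs.append("derived")
            elif allele == m.ancestral_allele:
                obs.append("ancestral")
            else:
                raise ValueError(
                    f"call {allele!r} for marker {m.id} is neither ancestral "
                    f"({m.ancestral_allele}) nor derived ({m.derived_allele})"
                )
        if not obs:
            states[b] = NA
        elif all(o == "derived" for o in obs):
            states[b] = "derived"
        elif all(o == "ancestral" for o in obs):
            states[b] = "ancestral"
        else:
            states[b] = "conflict"
    return states


def assign_sample(panel: MarkerPanel, sample: str, calls: dict[str, str]) -> Assignment:
    """Assign one sample from its marker calls.

    Missing markers on the path are treated as unobserved, not ancestral: the
    walk continues through an NA marker when a deeper marker on the same path
    is derived (flagged ``path-gap``).
    """
    states = _branch_states(panel, calls)
    call_string = "".join(
        "N" if calls.get(m.id, NA) in (NA, "", None)
        else ("1" if calls[m.id] == m.derived_allele else "0")
        for m in panel.markers
    )
    asg = Assignment(sample=sample, label="unassigned", call_string=call_string)

    conflict_branches = [b for b, s in states.items() if s == "conflict"]
    if conflict_branches:
        asg.label = "inconsistent"
        asg.conflicts = [f"mixed marker calls on branch {b}" for b in conflict_branches]
        return asg

    derived = [b for b, s in states.items() if s == "derived"]
    if not derived:
        if all(states[b] == NA for b in panel.branches):
            asg.flags.append("all markers missing")
        else:
            asg.flags.append("no derived markers")
        return asg

    # all derived branches must lie on a single root path
    for b in derived:
        anc = set(panel.ancestors(b))
        for other in derived:
            if other != b and other not in anc and b not in set(panel.ancestors(other)):
                asg.label = "inconsistent"
                asg.conflicts.append(
                    f"derived at disjoint branches {b} and {other}"
                )
                return asg

    deepest = max(derived, key=lambda b: len(panel.ancestors(b)))
    for anc in panel.ancestors(deepest):
        if states[anc] == "ancestral":
            asg.label = "inconsistent"
            asg.conflicts.append(
                f"derived at {deepest} but ancestral at its ancestor {anc}"
            )
            return asg
        if states[anc] == NA:
            asg.flags.append(f"path-gap at {anc}")

    if panel.is_leaf(deepest):
        asg.label = deepest
    else:
        below = [c for c in panel.children(deepest) if states[c] != NA]
        asg.label = f"{deepest}*"
        if not below:
            asg.flags.append("no genotyped markers below")
    return asg


def assign_all(panel: MarkerPanel, calls_by_sample: dict[str, dict[str, str]]
               ) -> list[Assignment]:
    return [assign_sample(panel, s, c) for s, c in calls_by_sample.items()]


def summarize_frequencies(
    assignments: list[Assignment], groups: dict[str, str]
) -> pd.DataFrame:
    """Per-group label counts and proportions (proportions sum to 1 per group)."""
    missing = [a.sample for a in assignments if a.sample not in groups]
    if missing:
        raise KeyError(f"samples without a group: {sorted(missing)}")
    df = pd.DataFrame(
        [(groups[a.sample], a.label) for a in sorted(assignments, key=lambda a: a.sample)],
        columns=["group", "label"],
    )
    counts = df.groupby(["group", "label"]).size().rename("n").reset_index()
    counts["proportion"] = counts["n"] / counts.groupby("group")["n"].transform("sum")
    return counts.sort_values(["group", "label"]).reset_index(drop=True)


def refine_panel(
    extension: MarkerPanel,
    parent_label: str,
    assignments: list[Assignment],
    calls_by_sample: dict[str, dict[str, str]],
) -> list[Assignment]:
    """Re-assign samples carrying ``parent_label`` using a nested extension panel.

    Extension branches must nest under a single root (the prior label's
    subtree).  Samples whose prior label differs are returned untouched; a
    sample ancestral at every extension tip keeps a basal ``<parent_label>*``
    style label.
    """
    if not extension.children(None):
        raise ValueError("extension panel has no root branches to nest under "
                         f"{parent_label!r}")
    out: list[Assignment] = []
    for a in assignments:
        if a.label != parent_label:
            out.append(a)
            continue
        sub = assign_sample(extension, a.sample, calls_by_sample.get(a.sample, {}))
        if sub.label == "inconsistent":
            refined = sub
        elif sub.label == "unassigned":
            refined = Assignment(sample=a.sample, label=f"{parent_label}*",
                                 call_string=sub.call_string,
                                 flags=sub.flags + ["basal within " + parent_label])
        else:
            refined = sub
        out.append(refined)
    return out
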