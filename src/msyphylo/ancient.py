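"""Placement of low-coverage ancient samples on the modern backbone.

Each backbone branch carries a disjoint set of identifier variants.  For every
branch the derived (D) and ancestral (A) counts over the sample's genotyped
identifiers are tallied; a branch "passes" when at least half (configurable)
of its genotyped identifiers are derived and none is ancestral.  The walk
descends through passing branches; a branch showing both derived and
ancestral states stops the walk at its own internal branching point (Greek
letter / '*' nodes seen only in ancient samples).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

_GREEK_CHAR = {"a": "α", "b": "β", "c": "γ", "d": "δ", "p": "ρ", "q": "κ",
               "s": "σ", "C": "γ"}


def greek_label(branch: str) -> str:
    """Transliterated Greek name for an ancient-only internal node, e.g. db -> δβ*."""
    return "".join(_GREEK_CHAR.get(c, c) for c in branch) + "*"


@dataclass
class BranchIdentifierSet:
    branch: str
    identifiers: frozenset[str]
    coordinates: dict[str, dict[str, int]] = field(default_factory=dict)  # ref -> vid -> pos


@dataclass
class Backbone:
    """Ordered backbone branches (a small tree) with identifier sets."""

    branch_parent: dict[str, str | None]
    identifier_sets: dict[str, BranchIdentifierSet]
    group_under: dict[str, str] = field(default_factory=dict)  # branch -> clade label

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for b, ids in self.identifier_sets.items():
            if b not in self.branch_parent:
                raise ValueError(f"identifier set for unknown branch {b}")
            overlap = seen & ids.identifiers
            if overlap:
                raise ValueError(
                    f"identifiers {sorted(overlap)} appear on more than one branch"
                )
            seen |= ids.identifiers
        for b in self.branch_parent:
            self.group_under.setdefault(b, b)

    @property
    def panel_variants(self) -> frozenset[str]:
        out: set[str] = set()
        for ids in self.identifier_sets.values():
            out |= ids.identifiers
        return frozenset(out)

    def children(self, branch: str | None) -> list[str]:
        return sorted(b for b, p in self.branch_parent.items() if p == branch)

    def path(self, branch: str) -> list[str]:
        out = [branch]
        cur = self.branch_parent[branch]
        while cur is not None:
            out.append(cur)
            cur = self.branch_parent[cur]
        return out[::-1]

    def to_tsv(self, path) -> None:
        rows = []
        for b in self.branch_parent:
            ids = self.identifier_sets.get(b)
            for vid in sorted(ids.identifiers) if ids else []:
                rows.append((b, self.branch_parent[b] or "", vid))
        pd.DataFrame(rows, columns=["branch", "parent", "variant_id"]).to_csv(
            path, sep="\t", index=False
        )

    @classmethod
    def from_tsv(cls, path) -> "Backbone":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        parent: dict[str, str | None] = {}
        ids: dict[str, set[str]] = {}
        for r in df.itertuples():
            parent[r.branch] = r.parent or None
            ids.setdefault(r.branch, set()).add(r.variant_id)
        return cls(
            branch_parent=parent,
            identifier_sets={
                b: BranchIdentifierSet(branch=b, identifiers=frozenset(v))
                for b, v in ids.items()
            },
        )


@dataclass
class AncientCalls:
    """Pseudo-haploid calls of one sample at identifier positions."""

    sample: str
    states: dict[str, int]  # variant id -> 0 (ancestral) / 1 (derived)
    metadata: dict[str, object] = field(default_factory=dict)

    @property
    def covered(self) -> int:
        return len(self.states)


@dataclass
class BranchTally:
    genotyped: int
    derived: int
    ancestral: int


@dataclass
class Placement:
    sample: str
    placement_class: str  # "clade", "internal", "unassigned", "ineligible"
    branch: str | None = None
    label: str | None = None
    tallies: dict[str, BranchTally] = field(default_factory=dict)
    eligible: bool = True
    flags: list[str] = field(default_factory=list)


def eligibility(calls: AncientCalls, panel_size: int, min_fraction: float = 0.5) -> bool:
    """True iff the sample covers at least ceil(min_fraction * panel_size) sites."""
    if not 0.0 < min_fraction <= 1.0:
        raise ValueError("min_fraction must be in (0, 1]")
    return calls.covered >= math.ceil(min_fraction * panel_size)


def _tally(calls: AncientCalls, identifiers: frozenset[str]) -> BranchTally:
    derived = sum(1 for v in identifiers if calls.states.get(v) == 1)
    ancestral = sum(1 for v in identifiers if calls.states.get(v) == 0)
    return BranchTally(genotyped=derived + ancestral, derived=derived,
                       ancestral=ancestral)


def place_backbone(
    calls: AncientCalls,
    backbone: Backbone,
    min_derived_fraction: float = 0.5,
    max_ancestral: int = 0,
) -> Placement:
    """Walk the backbone; assign to the group under the deepest passed branch.

    A branch passes iff ``D >= ceil(min_derived_fraction * G)`` and
    ``A <= max_ancestral`` (0 by default: a single ancestral call blocks the
    branch).  When no child passes but one shows both derived and ancestral
    states, the sample lands on that branch's internal node.
    """
    placement = Placement(sample=calls.sample, placement_class="unassigned")
    current: str | None = None
    deepest_passed: str | None = None

    while True:
        children = backbone.children(current)
        if not children:
            break
        tallies = {}
        for b in children:
            t = _tally(calls, backbone.identifier_sets[b].identifiers)
            tallies[b] = t
            placement.tallies[b] = t
        if all(t.genotyped == 0 for t in tallies.values()):
            placement.flags.append(f"uninformative-path below {current or 'root'}")
            break
        passed = [
            b for b, t in tallies.items()
            if t.genotyped > 0
            and t.derived >= math.ceil(min_derived_fraction * t.genotyped)
            and t.ancestral <= max_ancestral
        ]
        if passed:
            best = max(passed, key=lambda b: (tallies[b].derived / tallies[b].genotyped,
                                              tallies[b].derived, b))
            if len(passed) > 1:
                placement.flags.append(
                    f"multiple passing branches {sorted(passed)}; descended {best}"
                )
            deepest_passed = best
            current = best
            continue
        mixed = [b for b, t in tallies.items()
                 if t.derived >= 1 and t.ancestral >= 1]
        if mixed:
            best = max(mixed, key=lambda b: (tallies[b].derived, b))
            placement.placement_class = "internal"
            placement.branch = best
            placement.label = greek_label(best)
            return placement
        break

    if deepest_passed is not None:
        placement.placement_class = "clade"
        placement.branch = deepest_passed
        placement.label = backbone.group_under[deepest_passed]
    return placement


def refine_da1(
    calls: AncientCalls,
    mjhg_backbone: Backbone,
    min_derived_fraction: float = 0.5,
) -> str:
    """Refine a clade(da1) sample over da1's child mjHG branches.

    Returns the mjHG label, an internal-node label, or ``"basal da1"`` when no
    child branch passes (flagged uninformative when nothing was genotyped).
    """
    sub = place_backbone(calls, mjhg_backbone, min_derived_fraction)
    if sub.placement_class == "clade":
        return sub.label
    if sub.placement_class == "internal":
        return sub.label
    return "basal da1"


def detect_identifier(calls: AncientCalls, variant_id: str,
                      known_variants: frozenset[str] | None = None) -> str:
    """Tri-state lookup of one diagnostic identifier: present/absent/uncalled."""
    if known_variants is not None and variant_id not in known_variants:
        raise KeyError(f"unknown identifier variant {variant_id!r}")
    state = calls.states.get(variant_id)
    if state is None:
        return "uncalled"
    return "present" if state == 1 else "absent"


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------


def read_ancient_calls(path) -> dict[str, AncientCalls]:
    """Read a calls TSV with columns sample, variant_id, state (0/1)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample": str, "variant_id": str})
    out: dict[str, AncientCalls] = {}
    for r in df.itertuples():
        out.setdefault(r.sample, AncientCalls(sample=r.sample, states={})).states[
            r.variant_id
        ] = int(r.state)
    return out


def write_ancient_calls(calls: dict[str, AncientCalls], path) -> None:
    rows = [
        (s, vid, st)
        for s in sorted(calls)
        for vid, st in sorted(calls[s].states.items())
    ]
    pd.DataFrame(rows, columns=["sample", "variant_id", "state"]).to_csv(
        path, sep="\t", index=False
    )


def placements_frame(placements: list[Placement], backbone: Backbone) -> pd.DataFrame:
    """Audit table with per-branch derived/ancestral counts."""
    branches = list(backbone.branch_parent)
    rows = []
    for p in placements:
        row = {
            "sample": p.sample,
            "class": p.placement_class,
            "branch": p.branch or "",
            "label": p.label or "",
            "eligible": p.eligible,
            "flags": ";".join(p.flags),
        }
        for b in branches:
            t = p.tallies.get(b)
            row[f"D_{b}"] = t.derived if t else 0
            row[f"A_{b}"] = t.ancestral if t else 0
        rows.append(row)
    return pd.DataFrame(rows)
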