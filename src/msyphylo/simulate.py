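"""Synthetic datasets with known truth for every pipeline stage.

Trees carry branch lengths in years; mutations drop as Poisson(mu * L * years)
per branch under infinite sites, so every emitted variant has a single origin
branch and the matrix always admits a perfect phylogeny before masking.
Ancient samples may attach mid-branch (extinct lineages) and are observed
through a per-sample callability and an optional per-call error rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .ancient import AncientCalls, Backbone, BranchIdentifierSet
from .panel_assign import Marker, MarkerPanel
from .variant_matrix import MISSING, PolarizedMatrix, Variant


@dataclass
class SimConfig:
    seed: int
    n_modern: int = 60
    n_ancient: int = 40
    mode: str = "backbone"  # "backbone" | "yule"
    mu: float = 1.69e-9
    length_bp: int = 5_063_000
    modern_missingness: float = 0.0
    ancient_error: float = 0.0
    ancient_error_mode: str = "symmetric"  # or "no_false_derived"
    callability_beta: tuple[float, float] = (2.0, 2.0)
    callability_range: tuple[float, float] = (0.2, 1.0)
    ancient_internal_fraction: float = 0.2
    ancient_max_age: float = 3000.0
    # backbone split times, years before present
    root_split: float = 15_000.0
    d_split: float = 5_500.0
    da1_age: float = 4_000.0
    crown_age: float = 1_500.0
    yule_birth_rate: float = 2.5e-4
    yule_duration: float = 8_000.0
    str_mutation_rate: float = 0.0
    crown_scale: float = 1.0  # shrinks within-clade coalescent depth (< 1 makes
    # trees backbone-heavy: shorter pendant branches, fewer singletons)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name in ("modern_missingness", "ancient_error",
                     "ancient_internal_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("root_split", "d_split", "da1_age", "crown_age"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


class SimNode:
    """Node of the true tree; ``time`` is years before present."""

    __slots__ = ("name", "time", "children", "parent")

    def __init__(self, name: str, time: float) -> None:
        self.name = name
        self.time = time
        self.children: list[SimNode] = []
        self.parent: SimNode | None = None

    def add_child(self, node: "SimNode") -> "SimNode":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def branch_years(self) -> float:
        return 0.0 if self.parent is None else self.parent.time - self.time

    def preorder(self):
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def tips(self) -> list["SimNode"]:
        return [n for n in self.preorder() if not n.children]

    def path_from_root(self) -> list["SimNode"]:
        out = []
        node = self
        while node is not None:
            out.append(node)
            node = node.parent
        return out[::-1]


@dataclass
class Truth:
    tree: SimNode
    variant_branch: dict[str, SimNode] = field(default_factory=dict)
    variant_age: dict[str, float] = field(default_factory=dict)
    sample_node: dict[str, SimNode] = field(default_factory=dict)
    sample_age: dict[str, float] = field(default_factory=dict)
    clade_of_sample: dict[str, str] = field(default_factory=dict)
    backbone_nodes: dict[str, SimNode] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Tree simulation
# ---------------------------------------------------------------------------


def _coalescent_subtree(name: str, k: int, crown_age: float,
                        rng: np.random.Generator) -> SimNode:
    """Random bifurcating subtree with MRCA exactly at ``crown_age``."""
    tips = [SimNode(f"{name}.t{i}", 0.0) for i in range(k)]
    if k == 1:
        return tips[0]
    inner = sorted(rng.uniform(0.05 * crown_age, 0.95 * crown_age, size=k - 2))
    times = list(inner) + [crown_age]
    lineages = tips
    for t in times:
        i, j = sorted(rng.choice(len(lineages), size=2, replace=False))
        node = SimNode(f"{name}.n{t:.1f}", t)
        node.add_child(lineages[i])
        node.add_child(lineages[j])
        lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
        lineages.append(node)
    return lineages[0]


def _allocate(n: int, weights: dict[str, float]) -> dict[str, int]:
    """Largest-remainder allocation with at least one tip per clade when possible."""
    names = list(weights)
    if n < len(names):
        return {name: (1 if i < n else 0) for i, name in enumerate(names)}
    raw = {c: n * w / sum(weights.values()) for c, w in weights.items()}
    out = {c: max(1, int(raw[c])) for c in names}
    while sum(out.values()) > n:
        c = max(names, key=lambda c: (out[c] - raw[c], c))
        out[c] -= 1
    remainders = sorted(names, key=lambda c: (-(raw[c] - out[c]), c))
    i = 0
    while sum(out.values()) < n:
        out[remainders[i % len(names)]] += 1
        i += 1
    return out


def simulate_tree(config: SimConfig) -> Truth:
    """Sample the true genealogy (deterministic given the config seed)."""
    rng = np.random.default_rng(config.seed)
    if config.mode == "yule":
        return Truth(tree=_yule_tree(config, rng))
    if config.mode != "backbone":
        raise ValueError(f"unknown tree mode {config.mode!r}")

    weights = {"p": 0.08, "db": 0.10, "da1_A": 0.18, "da1_B": 0.14,
               "da1_C": 0.12, "daC": 0.38}
    alloc = _allocate(config.n_modern, weights)

    root = SimNode("root", config.root_split)
    truth = Truth(tree=root)
    s = config.crown_scale
    crown = {"p": s * min(2_500.0, 0.5 * config.root_split), "db": s * 3_000.0,
             "da1_A": s * 3_200.0, "da1_B": s * 2_800.0, "da1_C": s * 2_400.0,
             "daC": s * config.crown_age}

    def attach(parent: SimNode, clade: str) -> None:
        k = alloc.get(clade, 0)
        if k == 0:
            return
        sub = _coalescent_subtree(clade, k, crown[clade], rng)
        parent.add_child(sub)
        truth.backbone_nodes[clade] = sub

    attach(root, "p")
    da1_clades = ("da1_A", "da1_B", "da1_C", "daC")
    if any(alloc.get(c, 0) for c in ("db",) + da1_clades):
        d = root.add_child(SimNode("d", config.d_split))
        truth.backbone_nodes["d"] = d
        attach(d, "db")
        if any(alloc.get(c, 0) for c in da1_clades):
            da1 = d.add_child(SimNode("da1", config.da1_age))
            truth.backbone_nodes["da1"] = da1
            for clade in da1_clades:
                attach(da1, clade)

    # name modern tips deterministically and record their clades
    for i, tip in enumerate(root.tips()):
        clade = tip.name.split(".")[0]
        tip.name = f"M{i + 1:03d}"
        truth.sample_node[tip.name] = tip
        truth.sample_age[tip.name] = 0.0
        truth.clade_of_sample[tip.name] = clade
    return truth


def _yule_tree(config: SimConfig, rng: np.random.Generator) -> SimNode:
    """Forward-time pure-birth tree run for a fixed duration.

    The expected tip count is exp(birth_rate * duration).
    """
    lam, T = config.yule_birth_rate, config.yule_duration
    counter = [0]

    def grow(birth_time: float) -> SimNode:
        t_split = birth_time - rng.exponential(1.0 / lam)
        if t_split <= 0:
            counter[0] += 1
            return SimNode(f"M{counter[0]:03d}", 0.0)
        node = SimNode(f"y@{t_split:.2f}", t_split)
        node.add_child(grow(t_split))
        node.add_child(grow(t_split))
        return node

    root = SimNode("root", T)
    root.add_child(grow(T))
    return root


# ---------------------------------------------------------------------------
# Mutations
# ---------------------------------------------------------------------------

_BASES = "ACGT"


def drop_mutations(
    truth: Truth, mu: float, length_bp: int, seed: int,
) -> list[Variant]:
    """Poisson mutations per branch under infinite sites; updates ``truth``."""
    rng = np.random.default_rng(seed)
    branches = [n for n in truth.tree.preorder() if n.parent is not None]
    counts = rng.poisson(mu * length_bp * np.array([b.branch_years for b in branches]))
    total = int(counts.sum())
    if total > length_bp:
        raise ValueError("more mutations than sites; lower mu or raise length_bp")
    positions = rng.choice(length_bp, size=total, replace=False) + 1
    variants: list[Variant] = []
    k = 0
    for b, c in zip(branches, counts):
        for _ in range(int(c)):
            pos = int(positions[k])
            ref = _BASES[pos % 4]
            alt = _BASES[(pos + 1 + int(rng.integers(3))) % 4]
            if alt == ref:
                alt = _BASES[(pos + 2) % 4]
            vid = f"eS{k + 1:05d}"
            variants.append(
                Variant(id=vid, contig="Y", pos=pos, ref_allele=ref, alt_allele=alt,
                        vclass="SNP", ancestral="ref", provenance="e")
            )
            truth.variant_branch[vid] = b
            truth.variant_age[vid] = float(rng.uniform(b.time, b.parent.time))
            k += 1
    return variants


# ---------------------------------------------------------------------------
# Modern samples
# ---------------------------------------------------------------------------


def _haplotype(truth: Truth, variants: list[Variant], node: SimNode,
               age: float = 0.0) -> np.ndarray:
    path = {id(n) for n in node.path_from_root()}
    out = np.zeros(len(variants), dtype=np.int8)
    for j, v in enumerate(variants):
        b = truth.variant_branch[v.id]
        if id(b) in path and (b is not node or truth.variant_age[v.id] >= age):
            out[j] = 1
    return out


def sample_modern(
    truth: Truth,
    variants: list[Variant],
    missingness: float,
    seed: int,
) -> tuple[PolarizedMatrix, PolarizedMatrix]:
    """Observed (masked) and complete modern matrices, in tip order."""
    rng = np.random.default_rng(seed)
    tips = [n for n in truth.tree.tips()]
    samples = [t.name for t in tips]
    full = np.stack([_haplotype(truth, variants, t) for t in tips])
    states = full.copy()
    if missingness > 0:
        mask = rng.random(states.shape) < missingness
        states[mask] = MISSING
    groups = {s: truth.clade_of_sample.get(s, "sim") for s in samples}
    observed = PolarizedMatrix(samples=samples, variants=list(variants),
                               states=states, groups=groups)
    complete = PolarizedMatrix(samples=list(samples), variants=list(variants),
                               states=full, groups=dict(groups))
    return observed, complete


# ---------------------------------------------------------------------------
# Ancient samples
# ---------------------------------------------------------------------------


def sample_ancient(
    truth: Truth,
    variants: list[Variant],
    config: SimConfig,
    seed: int,
    panel_variants: frozenset[str] | None = None,
) -> dict[str, AncientCalls]:
    """Pseudo-haploid calls at panel sites with callability and error noise.

    Ancient samples attach either to a modern tip lineage or (with probability
    ``ancient_internal_fraction``) mid-branch, emulating extinct side lineages.
    Truth records the attachment node, age and clade.
    """
    rng = np.random.default_rng(seed)
    byid = {v.id: v for v in variants}
    panel = sorted(panel_variants) if panel_variants is not None else sorted(byid)
    tips = truth.tree.tips()
    internal = [n for n in truth.tree.preorder()
                if n.parent is not None and n.children and n.branch_years > 0]
    lo, hi = config.callability_range
    a, b = config.callability_beta

    out: dict[str, AncientCalls] = {}
    for i in range(config.n_ancient):
        name = f"A{i + 1:03d}"
        if internal and rng.random() < config.ancient_internal_fraction:
            node = internal[int(rng.integers(len(internal)))]
            age = float(rng.uniform(node.time, node.parent.time))
        else:
            node = tips[int(rng.integers(len(tips)))]
            age = float(rng.uniform(0.0, config.ancient_max_age))
            age = min(age, node.parent.time * 0.99)
        truth.sample_node[name] = node
        truth.sample_age[name] = age
        truth.clade_of_sample[name] = _clade_at(truth, node)

        hap = _haplotype(truth, [byid[v] for v in panel], node, age)
        call = rng.random(len(panel)) < (lo + (hi - lo) * rng.beta(a, b))
        states: dict[str, int] = {}
        for j, vid in enumerate(panel):
            if not call[j]:
                continue
            st = int(hap[j])
            if config.ancient_error > 0 and rng.random() < config.ancient_error:
                if config.ancient_error_mode == "symmetric":
                    st = 1 - st
                elif st == 1:  # no_false_derived: only derived -> ancestral flips
                    st = 0
            states[vid] = st
        out[name] = AncientCalls(sample=name, states=states,
                                 metadata={"age_bp": age, "true_node": node.name})
    return out


def _clade_at(truth: Truth, node: SimNode) -> str:
    names = {id(n): c for c, n in truth.backbone_nodes.items()}
    best = "root"
    for n in node.path_from_root():
        if id(n) in names:
            best = names[id(n)]
    return best


# ---------------------------------------------------------------------------
# Backbone / panel extraction from truth
# ---------------------------------------------------------------------------

BACKBONE_PARENT: dict[str, str | None] = {"p": None, "d": None, "db": "d", "da1": "d"}
MJHG_PARENT: dict[str, str | None] = {"da1_A": None, "da1_B": None, "da1_C": None,
                                      "daC": None}


def backbone_from_truth(truth: Truth, variants: list[Variant]) -> Backbone:
    """Fig-4-style backbone (p, d, db, da1) with true identifier sets."""
    return _backbone(truth, variants, BACKBONE_PARENT)


def mjhg_backbone_from_truth(truth: Truth, variants: list[Variant]) -> Backbone:
    """da1's child mjHG branches, for the refinement step."""
    return _backbone(truth, variants, MJHG_PARENT)


def _backbone(truth: Truth, variants: list[Variant],
              parent: dict[str, str | None]) -> Backbone:
    sets = {}
    for branch in parent:
        node = truth.backbone_nodes.get(branch)
        ids = frozenset(
            v.id for v in variants
            if node is not None and truth.variant_branch[v.id] is node
        )
        sets[branch] = BranchIdentifierSet(branch=branch, identifiers=ids)
    return Backbone(branch_parent=dict(parent), identifier_sets=sets)


def marker_panel_from_truth(
    truth: Truth, variants: list[Variant], matrix: PolarizedMatrix
) -> tuple[MarkerPanel, dict[str, dict[str, str]]]:
    """A small diagnostic panel (one marker per backbone branch) plus calls.

    Marker calls are read off the modern matrix; missing cells become NA.
    """
    byid = {v.id: v for v in variants}
    parent = {"p": None, "d": None, "db": "d", "da1": "d",
              "da1_A": "da1", "da1_B": "da1", "da1_C": "da1", "daC": "da1"}
    markers: list[Marker] = []
    for branch in parent:
        node = truth.backbone_nodes.get(branch)
        if node is None:
            continue
        on_branch = sorted(
            v for v, b in truth.variant_branch.items() if b is node
        )
        if not on_branch:
            continue
        v = byid[on_branch[0]]
        markers.append(Marker(id=v.id, branch=branch,
                              ancestral_allele=v.ancestral_allele,
                              derived_allele=v.derived_allele))
    panel = MarkerPanel(
        name="sim-panel",
        markers=markers,
        branch_parent={b: p for b, p in parent.items()
                       if b in {m.branch for m in markers}
                       and (p is None or p in {m.branch for m in markers})},
    )
    calls: dict[str, dict[str, str]] = {}
    for i, s in enumerate(matrix.samples):
        row = {}
        for m in markers:
            j = matrix.variant_index(m.id)
            st = matrix.states[i, j]
            if st == MISSING:
                row[m.id] = "NA"
            else:
                row[m.id] = m.derived_allele if st == 1 else m.ancestral_allele
        calls[s] = row
    return panel, calls


# ---------------------------------------------------------------------------
# One-call dataset
# ---------------------------------------------------------------------------


@dataclass
class SimDataset:
    config: SimConfig
    truth: Truth
    variants: list[Variant]
    matrix: PolarizedMatrix  # observed (masked)
    complete: PolarizedMatrix  # pre-mask truth matrix
    ancient: dict[str, AncientCalls]
    backbone: Backbone
    mjhg_backbone: Backbone


def simulate_dataset(config: SimConfig) -> SimDataset:
    """Simulate tree, mutations, modern matrix, ancient calls and backbone."""
    truth = simulate_tree(config)
    variants = drop_mutations(truth, config.mu, config.length_bp, config.seed + 1)
    matrix, complete = sample_modern(truth, variants, config.modern_missingness,
                                     config.seed + 2)
    backbone = backbone_from_truth(truth, variants)
    mjhg = mjhg_backbone_from_truth(truth, variants)
    panel = backbone.panel_variants | mjhg.panel_variants
    ancient = sample_ancient(truth, variants, config, config.seed + 3,
                             panel_variants=frozenset(panel))
    return SimDataset(config=config, truth=truth, variants=variants, matrix=matrix,
                      complete=complete, ancient=ancient, backbone=backbone,
                      mjhg_backbone=mjhg)
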