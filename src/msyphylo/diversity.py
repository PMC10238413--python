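"""Group-wise diversity summaries and molecular-clock node dating.

Watterson's theta is computed per site over a configurable surveyed length
(default 5,063,000 bp of single-copy Y sequence); mean pairwise differences
are per sequence with pairwise-complete handling of missing cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .variant_matrix import MISSING, PolarizedMatrix, haplotype_strings

DEFAULT_SURVEYED_BP = 5_063_000
DEFAULT_CLOCK_RATE = 1.69e-9  # mutations / site / year


@dataclass(frozen=True)
class ClockConfig:
    mu: float = DEFAULT_CLOCK_RATE
    length_bp: int = DEFAULT_SURVEYED_BP

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.length_bp <= 0:
            raise ValueError("mutation rate and length must be positive")


@dataclass
class DiversitySummary:
    group: str
    n: int
    n_mjhg: int | None
    unique_haplotypes: int
    segregating_sites: int
    mean_pairwise_diff: float
    sd_pairwise_diff: float
    watterson_theta: float
    surveyed_bp: int


def harmonic(n_minus_1: int) -> float:
    return float(np.sum(1.0 / np.arange(1, n_minus_1 + 1))) if n_minus_1 > 0 else 0.0


def watterson_theta(s: int, n: int, length_bp: int = DEFAULT_SURVEYED_BP) -> float:
    """Per-site Watterson estimator: S / (a_n * L), a_n = sum_{i<n} 1/i."""
    if n < 2:
        raise ValueError("Watterson's theta requires at least two sequences")
    if length_bp <= 0:
        raise ValueError("surveyed length must be positive")
    if s < 0:
        raise ValueError("segregating-site count cannot be negative")
    return s / (harmonic(n - 1) * length_bp)


def pairwise_differences(matrix: PolarizedMatrix) -> tuple[float, float]:
    """Mean and sample SD of pairwise difference counts over all sample pairs.

    Missing cells are handled pairwise-complete: a site enters a pair's count
    only when both samples are called there.
    """
    n = matrix.n_samples
    if n < 2:
        raise ValueError("pairwise differences require at least two samples")
    S = matrix.states
    obs = S != MISSING
    dists = []
    for i, j in combinations(range(n), 2):
        both = obs[i] & obs[j]
        dists.append(int(np.sum((S[i, both] != S[j, both]))))
    dists = np.asarray(dists, dtype=float)
    sd = float(dists.std(ddof=1)) if len(dists) > 1 else 0.0
    return float(dists.mean()), sd


def segregating_sites(matrix: PolarizedMatrix) -> int:
    S = matrix.states
    has0 = (S == 0).any(axis=0)
    has1 = (S == 1).any(axis=0)
    return int((has0 & has1).sum())


@dataclass
class SummaryConfig:
    surveyed_bp: int = DEFAULT_SURVEYED_BP
    # rows computed on a group minus one haplogroup, e.g. [("East Asia", "Pb_D")]
    exclusions: list[tuple[str, str]] = field(default_factory=list)
    include_total: bool = True


def region_summary(
    matrix: PolarizedMatrix,
    groups: dict[str, str],
    assignments: dict[str, str] | None = None,
    config: SummaryConfig | None = None,
) -> pd.DataFrame:
    """One diversity row per group (plus exclusion rows and a Total row)."""
    config = config or SummaryConfig()
    assignments = assignments or {}
    uncovered = [s for s in matrix.samples if s not in groups]
    if uncovered:
        raise KeyError(f"samples without a group: {sorted(uncovered)}")

    def one(label: str, samples: list[str]) -> DiversitySummary:
        sub = matrix.subset_samples(samples)
        s_count = segregating_sites(sub)
        if len(samples) >= 2:
            mean_pd, sd_pd = pairwise_differences(sub)
            theta = watterson_theta(s_count, len(samples), config.surveyed_bp)
        else:
            mean_pd = sd_pd = theta = float("nan")
        hts = haplotype_strings(sub)[1]
        labels = {assignments[s] for s in samples if s in assignments}
        return DiversitySummary(
            group=label, n=len(samples), n_mjhg=len(labels) or None,
            unique_haplotypes=hts, segregating_sites=s_count,
            mean_pairwise_diff=mean_pd, sd_pairwise_diff=sd_pd,
            watterson_theta=theta, surveyed_bp=config.surveyed_bp,
        )

    rows: list[DiversitySummary] = []
    by_group: dict[str, list[str]] = {}
    for s in matrix.samples:
        by_group.setdefault(groups[s], []).append(s)
    for g in sorted(by_group):
        rows.append(one(g, by_group[g]))
    for group, excluded_hg in config.exclusions:
        if excluded_hg not in set(assignments.values()):
            raise KeyError(f"exclusion haplogroup {excluded_hg!r} absent from assignments")
        samples = [s for s in by_group.get(group, [])
                   if assignments.get(s) != excluded_hg]
        rows.append(one(f"{group} wo {excluded_hg}", samples))
    if config.include_total:
        rows.append(one("Total", list(matrix.samples)))
    return pd.DataFrame(
        [
            (r.group, r.n, r.n_mjhg, r.unique_haplotypes, r.segregating_sites,
             r.mean_pairwise_diff, r.sd_pairwise_diff, r.watterson_theta,
             r.surveyed_bp)
            for r in rows
        ],
        columns=["group", "n", "mjHGs", "unique_HTs", "S", "mean_pairwise_diff",
                 "sd_pairwise_diff", "watterson_theta", "surveyed_bp"],
    )


def node_age(
    mutation_count: int, clock: ClockConfig | None = None, ci: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Date a node from its branch mutation count: age = k / (mu * L), years.

    The interval is the exact Poisson confidence interval on the count,
    divided by mu * L.
    """
    if mutation_count < 0:
        raise ValueError("mutation count cannot be negative")
    clock = clock or ClockConfig()
    rate = clock.mu * clock.length_bp
    alpha = 1.0 - ci
    k = mutation_count
    lo = stats.chi2.ppf(alpha / 2, 2 * k) / 2 if k > 0 else 0.0
    hi = stats.chi2.ppf(1 - alpha / 2, 2 * k + 2) / 2
    return k / rate, (lo / rate, hi / rate)
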