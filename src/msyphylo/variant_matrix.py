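"""Haploid genotype matrices: reading, polarization, filtering and haplotype strings.

The central object is :class:`PolarizedMatrix`, a samples x variants array over
``{0 = ancestral, 1 = derived, -1 = missing}``.  Variants are polarized against
an outgroup column (e.g. a donkey sample) before any downstream analysis.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

MISSING = -1

_VCLASSES = ("SNP", "INDEL", "STR")
_ANCESTRAL = ("ref", "alt", "unknown")
_PROVENANCE = ("r", "s", "f", "q", "e")


class VcfParseError(ValueError):
    """Raised when a VCF record cannot be interpreted."""


@dataclass(frozen=True)
class Variant:
    """A biallelic (or, for the STR, multi-state) variant on a haploid contig."""

    id: str
    contig: str
    pos: int  # 1-based, as in VCF
    ref_allele: str
    alt_allele: str
    vclass: str = "SNP"
    ancestral: str = "unknown"  # which allele is ancestral: "ref" | "alt" | "unknown"
    provenance: str = "e"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant {self.id}: pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"variant {self.id}: ref and alt alleles are identical")
        if self.vclass not in _VCLASSES:
            raise ValueError(f"variant {self.id}: unknown vclass {self.vclass!r}")
        if self.vclass == "SNP" and (
            len(self.ref_allele) != 1 or len(self.alt_allele) != 1
        ):
            raise ValueError(f"variant {self.id}: SNP alleles must have length 1")
        if self.ancestral not in _ANCESTRAL:
            raise ValueError(f"variant {self.id}: bad ancestral flag {self.ancestral!r}")
        if self.provenance not in _PROVENANCE:
            raise ValueError(f"variant {self.id}: bad provenance {self.provenance!r}")

    @property
    def derived_allele(self) -> str:
        if self.ancestral == "ref":
            return self.alt_allele
        if self.ancestral == "alt":
            return self.ref_allele
        raise ValueError(f"variant {self.id} is not polarized")

    @property
    def ancestral_allele(self) -> str:
        if self.ancestral == "ref":
            return self.ref_allele
        if self.ancestral == "alt":
            return self.alt_allele
        raise ValueError(f"variant {self.id} is not polarized")


@dataclass
class AlleleMatrix:
    """Raw ref/alt coded calls prior to polarization.

    ``calls[i, j]`` is 0 (ref), 1 (alt) or -1 (missing) for sample i, variant j.
    """

    samples: list[str]
    variants: list[Variant]
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=np.int8)
        if self.calls.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"calls shape {self.calls.shape} != "
                f"({len(self.samples)}, {len(self.variants)})"
            )


@dataclass
class PolarizedMatrix:
    """Samples x variants over {0 ancestral, 1 derived, -1 missing}.

    ``str_alleles`` carries per-sample repeat counts for STR variants, which are
    kept out of the binary state array (they only split terminal haplotypes).
    """

    samples: list[str]
    variants: list[Variant]
    states: np.ndarray
    str_alleles: dict[str, np.ndarray] = field(default_factory=dict)
    groups: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = np.asarray(self.states, dtype=np.int8)
        if self.states.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"states shape {self.states.shape} != "
                f"({len(self.samples)}, {len(self.variants)})"
            )
        bad = ~np.isin(self.states, (0, 1, MISSING))
        if bad.any():
            raise ValueError("states must be 0, 1 or -1 (missing)")

    # -- convenience ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_index(self, variant_id: str) -> int:
        for j, v in enumerate(self.variants):
            if v.id == variant_id:
                return j
        raise KeyError(variant_id)

    def sample_index(self, sample: str) -> int:
        try:
            return self.samples.index(sample)
        except ValueError:
            raise KeyError(sample) from None

    def subset_samples(self, keep: list[str]) -> "PolarizedMatrix":
        idx = [self.sample_index(s) for s in keep]
        return PolarizedMatrix(
            samples=list(keep),
            variants=list(self.variants),
            states=self.states[idx, :].copy(),
            str_alleles={k: v[idx].copy() for k, v in self.str_alleles.items()},
            groups={s: g for s, g in self.groups.items() if s in set(keep)},
        )

    def subset_variants(self, keep_idx: np.ndarray) -> "PolarizedMatrix":
        keep_idx = np.asarray(keep_idx)
        return PolarizedMatrix(
            samples=list(self.samples),
            variants=[self.variants[j] for j in keep_idx],
            states=self.states[:, keep_idx].copy(),
            str_alleles=dict(self.str_alleles),
            groups=dict(self.groups),
        )

    # -- I/O -----------------------------------------------------------------

    def to_tsv(self, path) -> None:
        """Write the 0/1/NA sample x variant table (header = variant ids)."""
        df = pd.DataFrame(
            self.states, index=self.samples, columns=[v.id for v in self.variants]
        ).astype(object)
        df[self.states == MISSING] = "NA"
        df.index.name = "sample"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path, variants: list[Variant] | None = None) -> "PolarizedMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
        states = df.replace("NA", str(MISSING)).astype(np.int8).to_numpy()
        if variants is None:
            variants = [
                Variant(id=c, contig="Y", pos=j + 1, ref_allele="A", alt_allele="G",
                        ancestral="ref")
                for j, c in enumerate(df.columns)
            ]
        else:
            byid = {v.id: v for v in variants}
            variants = [byid[c] for c in df.columns]
        return cls(samples=list(df.index), variants=variants, states=states)

    def write_variant_table(self, path) -> None:
        rows = [
            (v.id, v.contig, v.pos, v.ref_allele, v.alt_allele, v.vclass,
             v.ancestral, v.provenance)
            for v in self.variants
        ]
        pd.DataFrame(
            rows,
            columns=["id", "contig", "pos", "ref", "alt", "vclass", "ancestral",
                     "provenance"],
        ).to_csv(path, sep="\t", index=False)


def read_variant_table(path) -> list[Variant]:
    df = pd.read_csv(path, sep="\t", dtype={"contig": str})
    return [
        Variant(id=r.id, contig=str(r.contig), pos=int(r.pos), ref_allele=r.ref,
                alt_allele=r.alt, vclass=r.vclass, ancestral=r.ancestral,
                provenance=r.provenance)
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# VCF ingestion
# ---------------------------------------------------------------------------


def read_vcf(path, sample_subset: list[str] | None = None) -> AlleleMatrix:
    """Read a haploid (or diploid-encoded) VCF into an :class:`AlleleMatrix`.

    Diploid heterozygous genotypes are converted to missing (the chromosome is
    haploid; a het call flags a mapping artefact).  Multiallelic records are
    split into one biallelic variant per alternate allele; a sample carrying a
    different alternate allele is coded ref (it does not carry this one).
    """
    import pysam

    with pysam.VariantFile(str(path)) as vcf:
        all_samples = list(vcf.header.samples)
        if sample_subset is not None:
            missing = set(sample_subset) - set(all_samples)
            if missing:
                raise VcfParseError(f"samples not in VCF: {sorted(missing)}")
            samples = list(sample_subset)
        else:
            samples = all_samples
        if not samples:
            raise VcfParseError(f"no samples in VCF {path}")

        variants: list[Variant] = []
        columns: list[np.ndarray] = []
        n_het = 0
        for rec in vcf:
            if not rec.alts:
                continue
            haploid = np.full(len(samples), MISSING, dtype=np.int8)
            for i, s in enumerate(samples):
                gt = rec.samples[s].get("GT", (None,))
                alleles = [a for a in gt if a is not None]
                if not alleles:
                    continue
                if len(set(alleles)) > 1:  # diploid-encoded het on a haploid contig
                    n_het += 1
                    continue
                haploid[i] = alleles[0]
            for k, alt in enumerate(rec.alts, start=1):
                vclass = "SNP" if len(rec.ref) == 1 and len(alt) == 1 else "INDEL"
                vid = rec.id if rec.id and len(rec.alts) == 1 else (
                    f"{rec.id or rec.contig + '_' + str(rec.pos)}"
                    + (f".{k}" if len(rec.alts) > 1 else "")
                )
                variants.append(
                    Variant(id=vid, contig=rec.contig, pos=rec.pos, ref_allele=rec.ref,
                            alt_allele=alt, vclass=vclass)
                )
                col = np.where(
                    haploid == MISSING, MISSING, (haploid == k).astype(np.int8)
                ).astype(np.int8)
                columns.append(col)
        if n_het:
            log.warning("converted %d heterozygous calls to missing", n_het)
    if not variants:
        calls = np.zeros((len(samples), 0), dtype=np.int8)
    else:
        calls = np.column_stack(columns).astype(np.int8)
    return AlleleMatrix(samples=samples, variants=variants, calls=calls)


def write_vcf(matrix: PolarizedMatrix, path) -> None:
    """Write a haploid VCF (ref/alt coding recovered from polarization)."""
    import pysam

    header = pysam.VariantHeader()
    contigs = sorted({v.contig for v in matrix.variants}) or ["Y"]
    for c in contigs:
        header.contigs.add(c, length=2**29)
    header.add_line('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    header.add_line('##INFO=<ID=AA,Number=1,Type=String,Description="Ancestral allele">')
    for s in matrix.samples:
        header.add_sample(s)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for j in sorted(range(matrix.n_variants),
                        key=lambda j: (matrix.variants[j].contig, matrix.variants[j].pos)):
            v = matrix.variants[j]
            rec = out.new_record(contig=v.contig, start=v.pos - 1,
                                 alleles=(v.ref_allele, v.alt_allele), id=v.id)
            if v.ancestral != "unknown":
                rec.info["AA"] = v.ancestral_allele
            for i, s in enumerate(matrix.samples):
                st = matrix.states[i, j]
                if st == MISSING or v.ancestral == "unknown":
                    rec.samples[s]["GT"] = (None,)
                else:
                    derived_is_alt = v.ancestral == "ref"
                    allele = int(st) if derived_is_alt else 1 - int(st)
                    rec.samples[s]["GT"] = (allele,)
            out.write(rec)


# ---------------------------------------------------------------------------
# Polarization
# ---------------------------------------------------------------------------


def polarize(matrix: AlleleMatrix, outgroup_sample: str) -> PolarizedMatrix:
    """Orient alleles into ancestral/derived using the outgroup's calls.

    The outgroup's allele at a variant becomes the ancestral allele; variants
    where the outgroup is missing keep ``ancestral = "unknown"`` (they are
    flagged and dropped by :func:`filter_stringent`).  The outgroup row is
    removed from the returned matrix.  Applying polarize twice with the same
    outgroup is a no-op on states.
    """
    if outgroup_sample not in matrix.samples:
        raise KeyError(f"outgroup sample {outgroup_sample!r} not in matrix")
    og = matrix.samples.index(outgroup_sample)
    keep = [i for i in range(len(matrix.samples)) if i != og]
    og_calls = matrix.calls[og, :]
    states = matrix.calls[keep, :].astype(np.int8)

    variants: list[Variant] = []
    n_unpolarized = 0
    for j, v in enumerate(matrix.variants):
        c = og_calls[j]
        if c == MISSING:
            variants.append(replace(v, ancestral="unknown"))
            n_unpolarized += 1
        elif c == 0:
            variants.append(replace(v, ancestral="ref"))
        else:
            variants.append(replace(v, ancestral="alt"))
            col = states[:, j]
            states[:, j] = np.where(col == MISSING, MISSING, 1 - col)
    if n_unpolarized:
        log.info("%d variants left unpolarized (outgroup missing)", n_unpolarized)
    return PolarizedMatrix(
        samples=[matrix.samples[i] for i in keep], variants=variants, states=states
    )


# ---------------------------------------------------------------------------
# Filtering
# ---------------------------------------------------------------------------


@dataclass
class FilterConfig:
    max_site_missing: float = 0.2
    max_sample_missing: float = 0.3
    require_polarized: bool = True
    require_biallelic: bool = True
    flag_singletons: bool = True

    def __post_init__(self) -> None:
        for name in ("max_site_missing", "max_sample_missing"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class FilterReport:
    """Removal counts per rule, in application order."""

    input_variants: int = 0
    input_samples: int = 0
    removed_not_biallelic: int = 0
    removed_unpolarized: int = 0
    removed_site_missing: int = 0
    removed_samples: int = 0
    retained_variants: int = 0
    retained_samples: int = 0
    singleton_variant_ids: list[str] = field(default_factory=list)

    def check(self) -> None:
        v = (self.removed_not_biallelic + self.removed_unpolarized
             + self.removed_site_missing + self.retained_variants)
        if v != self.input_variants:
            raise AssertionError("variant counts do not reconcile")
        if self.removed_samples + self.retained_samples != self.input_samples:
            raise AssertionError("sample counts do not reconcile")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                ("input_variants", self.input_variants),
                ("removed_not_biallelic", self.removed_not_biallelic),
                ("removed_unpolarized", self.removed_unpolarized),
                ("removed_site_missing", self.removed_site_missing),
                ("retained_variants", self.retained_variants),
                ("input_samples", self.input_samples),
                ("removed_samples", self.removed_samples),
                ("retained_samples", self.retained_samples),
                ("singleton_variants", len(self.singleton_variant_ids)),
            ],
            columns=["rule", "count"],
        )


def filter_stringent(
    matrix: PolarizedMatrix, config: FilterConfig | None = None
) -> tuple[PolarizedMatrix, FilterReport]:
    """Apply the stringent site/sample filters in a fixed order.

    Order: (i) biallelic (the STR is moved to ``str_alleles``, not used as a
    binary character), (ii) polarized, (iii) site missingness, (iv) sample
    missingness.  Singletons are retained but listed in the report.
    """
    config = config or FilterConfig()
    rep = FilterReport(input_variants=matrix.n_variants,
                       input_samples=matrix.n_samples)

    keep = np.ones(matrix.n_variants, dtype=bool)
    if config.require_biallelic:
        # Multi-state characters (the STR) never enter the binary state array;
        # their repeat counts live in str_alleles and survive filtering there.
        for j, v in enumerate(matrix.variants):
            if v.vclass == "STR":
                keep[j] = False
                rep.removed_not_biallelic += 1
    if config.require_polarized:
        for j, v in enumerate(matrix.variants):
            if keep[j] and v.ancestral == "unknown":
                keep[j] = False
                rep.removed_unpolarized += 1
    miss_frac = (matrix.states == MISSING).mean(axis=0)
    for j in range(matrix.n_variants):
        if keep[j] and miss_frac[j] > config.max_site_missing:
            keep[j] = False
            rep.removed_site_missing += 1

    out = matrix.subset_variants(np.flatnonzero(keep))

    sample_miss = (out.states == MISSING).mean(axis=1) if out.n_variants else (
        np.zeros(out.n_samples))
    keep_samples = [s for i, s in enumerate(out.samples)
                    if sample_miss[i] <= config.max_sample_missing]
    rep.removed_samples = out.n_samples - len(keep_samples)
    if rep.removed_samples:
        out = out.subset_samples(keep_samples)

    if config.flag_singletons:
        derived_counts = (out.states == 1).sum(axis=0)
        rep.singleton_variant_ids = [
            out.variants[j].id for j in np.flatnonzero(derived_counts == 1)
        ]
    rep.retained_variants = out.n_variants
    rep.retained_samples = out.n_samples
    rep.check()
    return out, rep


# ---------------------------------------------------------------------------
# Haplotype strings
# ---------------------------------------------------------------------------


def haplotype_strings(
    matrix: PolarizedMatrix, impute_policy: str = "raw"
) -> tuple[dict[str, str], int]:
    """Concatenate per-sample states into haplotype strings.

    Returns ``(sample -> haplotype string, number of distinct haplotypes)``.
    Under ``impute_policy="require_complete"`` samples with any missing state
    are excluded.  STR repeat counts, when present, are appended as a final
    multi-state symbol so that the STR splits otherwise identical tips.
    """
    if impute_policy not in ("raw", "require_complete"):
        raise ValueError(f"unknown impute_policy {impute_policy!r}")
    symbols = np.array(["0", "1"])
    out: dict[str, str] = {}
    for i, s in enumerate(matrix.samples):
        row = matrix.states[i, :]
        if impute_policy == "require_complete" and (row == MISSING).any():
            continue
        chars = ["N" if x == MISSING else symbols[x] for x in row]
        for str_id in sorted(matrix.str_alleles):
            rep = matrix.str_alleles[str_id][i]
            chars.append(f"[{str_id}={'N' if rep == MISSING else int(rep)}]")
        out[s] = "".join(chars)
    return out, len(set(out.values()))
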