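# msyphylo

Tools for building and using haplotype phylogenies of the male-specific
region of the Y chromosome (MSY) from polarized binary variants:

* **variant_matrix** — haploid VCF / TSV ingestion, outgroup polarization,
  stringent site/sample filtering, haplotype-string construction.
* **tree_builder** — perfect-phylogeny reconstruction on compatible binary
  characters (four-gamete screened), diagnostic "identifier" variants placed
  on branches, small-parsimony placement of the rare homoplasic character,
  deterministic haplogroup nomenclature and Newick round-trips.
* **imputer** — tree-guided imputation of missing genotypes with an explicit
  corroboration rule; never alters observed cells, idempotent.
* **panel_assign** — major-haplogroup assignment from a small diagnostic
  marker panel, including inner-node (`*`) placements, inconsistency
  reporting, frequency tables, and nested panel refinement.
* **ancient** — placement of low-coverage pseudo-haploid samples on the
  modern backbone by derived/ancestral identifier counting, with eligibility
  thresholds, internal (Greek-letter) nodes, and da1 mjHG refinement.
* **diversity** — Watterson's theta, mean pairwise differences (pairwise
  complete), per-group summary tables, and Poisson molecular-clock node
  dating (default clock 1.69e-9 /site/year over 5.063 Mb).
* **simulate** — seeded synthetic datasets with full truth: backbone or Yule
  genealogies in years, Poisson infinite-sites mutations, modern missingness,
  and ancient samples with per-sample callability and call errors.

## Tests

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including an
exhaustive brute-force cross-check of the small-parsimony scorer over all
146,599 rooted binary trees with up to 8 tips and every binary character.
The full suite takes a few minutes on one CPU.

## CLI

```bash
# synthetic dataset with truth tables
msyphylo simulate --seed 1 --n-modern 60 --n-ancient 40 --out sim/

# modern workflow: filter -> tree -> impute -> haplotypes (+ diversity)
msyphylo modern --matrix sim/matrix.tsv --out modern/

# from a haploid VCF with an outgroup column for polarization
msyphylo modern --vcf calls.vcf --outgroup donkey --out modern/

# ancient workflow: eligibility -> backbone placement -> da1 refinement
msyphylo ancient --backbone sim/backbone.tsv \
    --mjhg-backbone sim/mjhg_backbone.tsv \
    --calls sim/ancient_calls.tsv --out ancient/
```

Every run echoes its configuration to `config.json` and logs stage counts to
`run.log` inside the output directory; reruns with the same inputs are
byte-identical.

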