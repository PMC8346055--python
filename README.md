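# cxvar

Domain enrichment, conservation and statistical-coupling analysis of
connexin missense variants.

Connexins form gap-junction channels; variants in the four disease-linked
α-connexin genes (*GJA1*/Cx43, *GJA3*/Cx46, *GJA5*/Cx40, *GJA8*/Cx50) are
found both in patients with Mendelian diseases (oculodentodigital
dysplasia, congenital cataracts, atrial fibrillation) and, without disease
linkage, in population references such as gnomAD. Where a missense variant
falls on the protein carries signal about its pathogenicity: the cryo-EM
gap-junction structure divides a connexin into structure-resolved domains
(NT, M1, E1, M2, M3, E2, M4 — the first four lining the channel pore) and
unresolved ones (the cytoplasmic loop CL and the carboxyl terminus CT).
`cxvar` provides a tested pipeline for asking, for any pair of variant
cohorts: are disease variants enriched on structured / pore / conserved /
co-evolving positions relative to population variants?

## What it computes

* **Variant catalog** — parses HGVS p. labels (three- or one-letter,
  `p.Asn220Asp`, `N220D`, `W4*`, `S251fs`, …), types them (missense,
  synonymous, stop gained/lost, start lost, frameshift, in-frame indel),
  deduplicates, tabulates per-gene/pooled percentages and computes the
  positional overlap between cohorts.
* **Domain map** — global pairwise alignment (BLOSUM62, affine gaps) of a
  query connexin onto a reference segmentation keyed to the sheep Cx46
  structure (shipped as an editable JSON config), per-residue domain labels
  and partition flags, per-region percent identity, and per-variant
  localization. Per-residue values can be written into PDB B-factors for
  molecular viewers.
* **Enrichment statistics** — 2×2 cohort-by-partition tables of unique
  variant counts; a two-sided Fisher exact test computed by
  point-probability ordering in log space,
  `p = Σ_{k : P(k) ≤ P(obs)} P(k)` over the hypergeometric support;
  in/out count ratios; length-normalized densities; and a Student
  pooled-variance unpaired t-test for conservation-score comparisons.
* **Conservation & coupling (SCA)** — from a multi-species MSA restricted
  to structured reference columns: redundancy weights
  `w_s = 1/|{s' : id(s,s') ≥ δ}|` and the effective sequence count
  `Meff = Σ w_s`; weighted amino-acid frequencies with background
  pseudocount; per-position conservation
  `D_i = Σ_a f_i^a ln(f_i^a / q_a)` (Kullback–Leibler relative entropy
  against a database background); the conservation-weighted co-variation
  matrix `C̃_ij = ‖φ_i^a φ_j^b (f_ij^ab − f_i^a f_j^b)‖_F` with
  `φ_i^a = ln[f_i^a(1−q_a)/((1−f_i^a)q_a)]`; eigenmode significance
  against a column-permutation null; independent-component rotation of the
  significant modes; top-5%-loading residue sets per IC; and grouping of
  ICs into protein sectors by their mutual coupling.
* **Synthetic data** — generators for MSAs with stated conservation and
  planted co-varying groups, and for variant cohorts with controlled
  per-partition enrichment, so every stage is testable end to end with
  known ground truth.

## Worked example

```python
import numpy as np
from cxvar.synthetic import CohortSpec, generate_cohorts
from cxvar.domains import align_query_to_reference, build_domain_map, \
    default_segmentation, locate_variants
from cxvar.enrichment import enrichment_test
from cxvar.variants import parse_variant_label, select_missense

rng = np.random.default_rng(1)
spec = CohortSpec()   # 60 disease-like vs 300 population-like variants
disease_df, population_df, truth = generate_cohorts(spec, rng)

records = [parse_variant_label(r.hgvs_p, r.gene, c)
           for df, c in ((disease_df, "disease"), (population_df, "population"))
           for r in df.itertuples()]
seq = truth["sequence"]
dmap = build_domain_map(align_query_to_reference(seq, seq), default_segmentation())
annotated = locate_variants(select_missense(records), dmap)
res = enrichment_test(annotated, "structured_vs_unstructured",
                      dmap.partition_lengths())
print(f"table={res.table.as_array().tolist()}  p={res.p_value:.3g}")
print(f"disease stru/unstru ratio={res.ratio_disease:.2f}  "
      f"population ratio={res.ratio_population:.2f}")
```

Output:

```
table=[[43, 8], [32, 158]]  p=2.99e-19
disease stru/unstru ratio=5.38  population ratio=0.20
```

The disease-like cohort piles onto the structured domains (ratio > 2), the
population-like cohort onto CL/CT (ratio < 0.5), and the Fisher test calls
the contrast at p ≪ 0.001 — the qualitative pattern the pipeline is built
to detect and quantify.

The same analysis is available from the shell:

```bash
cxvar simulate --out-dir fixtures --seed 1
cxvar map fixtures/disease_variants.tsv fixtures/protein.fasta \
      --segmentation fixtures/segmentation.json --out annotated.tsv
cxvar enrich annotated.tsv --partition structured_vs_unstructured
cxvar sca fixtures/msa.fasta --reference-id synthetic_ref --out-dir sca_out
```

## Documentation

`docs/methods.md` describes the models, parameter defaults, numerical
choices and known limitations in detail.
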