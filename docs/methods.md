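# Methods

## Problem setting

A connexin monomer threads the membrane four times; its topological
segments are NT, M1, E1, CL, M2, M3, E2, M4 and CT (N- to C-terminus).
In the reference cryo-EM gap-junction structure the NT, M1, E1, M2, M3,
E2 and M4 segments are resolved ("structured"); CL and CT are not
("unstructured"). Within the structured part, NT+M1+E1+M2 line the
channel pore and M3+E2+M4 face the lipid. The package quantifies whether
two cohorts of missense variants — one disease-linked, one drawn from a
population reference — distribute differently over these partitions,
over per-position conservation, and over co-evolving sectors.

## Variant catalog

Labels are accepted in HGVS p. notation or short form, three- or
one-letter, and normalized to one-letter internally. Typing is by
substitution pattern: aa→different aa missense, aa→same aa (or `=`)
synonymous, aa→Ter/"*" stop gained, Ter→aa stop lost, a disrupted
initiator Met start lost, an `fs` suffix frameshift, del/ins/dup without
`fs` in-frame indel. Nucleotide-level, intronic and UTR notation is
rejected. Numbering is 1-based on the protein including the initiator
Met. The unit of counting everywhere is the unique variant, keyed by
(gene, cohort, normalized label); multi-residue in-frame indels are
anchored at their first residue and flagged, and only missense variants
enter the positional analyses. Cohort overlap is keyed by (gene,
position) so multi-gene tables cannot collide across genes.

## Domain mapping

Query connexins are mapped onto the reference by global pairwise
alignment (BLOSUM62, gap open −11, gap extend −1, end gaps penalized).
At the 40–96% identity typical of α-connexin orthologs this mapping is
unambiguous; precomputed pairwise alignments can be supplied instead.
Each mapped query residue inherits the label of its aligned reference
residue. Gap-aligned query residues take the shared label of the two
flanking mapped residues when those agree, otherwise the label of the
nearest preceding mapped residue; residues before the first anchor are
NT and a C-terminal extension is CT. Percent identity is matches over
aligned columns excluding double gaps; region identity restricts the
columns to a reference-position mask (e.g. the structured segments), and
reference residues deleted from the query still count as columns.

The segment boundaries are data, not code: a JSON config in sheep Cx46
numbering ships with the package (NT 1–22, M1 23–45, E1 46–75, M2 76–96,
CL 97–136, M3 137–159, E2 160–191, M4 192–220, CT 221–440 — approximate
resolved-range/topology boundaries) and any alternative segmentation can
be passed in its place. Residue 1 is included in NT.

## Enrichment statistics

Counts of unique missense variants per cohort and partition form 2×2
tables; the pore/non-pore comparison is restricted to structured-domain
variants and CL/CT to unstructured ones. The two-sided Fisher exact
p-value is the sum of hypergeometric probabilities, over the support of
the fixed-margin family, of all tables at most as probable as the
observed one — the point-probability ordering used by the common
statistics packages. Probabilities are computed in log space from
log-gamma sums; a relative tolerance of 1e−7 absorbs floating-point ties
at the observed probability. The implementation is validated against
exact-rational enumeration for every table with total count ≤ 40.

Ratios are in-partition over out-partition counts per cohort (0 when the
numerator is empty; flagged infinite when the denominator is empty), and
densities divide counts by partition residue counts to control for
segment length. Conservation-score comparisons between cohorts use the
Student pooled-variance unpaired t-test (df = n1+n2−2; two groups with
zero variance and equal means return t = 0, p = 1); Welch's correction
is deliberately not applied, and can be obtained directly from scipy if
wanted. No multiple-testing correction is applied — each partition
comparison is reported at its own p-value, which mirrors how such
per-comparison results are conventionally reported and should be kept in
mind when many partitions are scanned.

## Conservation and coupling analysis

The MSA is first restricted to columns where the reference row is
non-gap and (optionally) maps to a structured segment. Sequences are
dropped when their gap fraction exceeds 0.4 or their fractional identity
to the reference falls outside [0.2, 0.85] (the reference itself is
kept); columns with more than 20% gaps are then dropped. The upper
identity bound of 0.85 keeps closely related paralogs apart from the
reference while discarding near-duplicates.

Redundancy weights are w_s = 1/|{s′ : id(s, s′) ≥ δ}| with δ = 0.8
(identity computed over the filtered columns; the neighbor set includes
the sequence itself), giving the effective sequence count Meff = Σ w_s ∈
[1, N]. Note that adding an exact duplicate leaves Meff unchanged only
when the duplicate's identity neighborhood is a clique; with
non-transitive neighborhoods (s′ near s but not near s″) Meff can shift
slightly, which is a property of threshold weighting itself, not of this
implementation.

Weighted frequencies use a background pseudocount:
f_i^a = (1−λ)·(Σ_s w_s 1[x_si = a]) / Meff_i + λ·q_a with λ = 0.03,
where Meff_i sums weights of sequences non-gapped at i — gaps are
excluded from the 20-state simplex rather than treated as a 21st state.
The background q is a standard database amino-acid composition shipped
with the package and overridable. Conservation is the relative entropy
D_i = Σ_a f_i^a ln(f_i^a/q_a) (natural log): 0 iff the column matches
the background, ln 20 ≈ 2.9957 for a fully conserved residue under a
uniform background.

The coupling matrix collapses the pair-covariance tensor
C_ij^ab = f_ij^ab − f_i^a f_j^b (pair frequencies from weighted pair
counts with per-pair effective counts, pseudocount λ·q_a·q_b) through
the conservation gradients φ_i^a = ln[f_i^a(1−q_a)/((1−f_i^a)q_a)]:
C̃_ij = ‖φ_i^a φ_j^b C_ij^ab‖_F. C̃ is symmetric and non-negative, and
its diagonal is retained.

Eigenmode significance is calibrated by a column-permutation null: each
column's residues are shuffled independently across sequences
(destroying inter-column correlation, preserving composition; the
original sequence weights are reused), C̃ is rebuilt, and its spectrum
recorded, for 10 trials. The significance threshold is the maximum
eigenvalue observed in any trial, with each trial's own first mode
excluded; k counts true eigenvalues above it, likewise excluding the
first mode. The first eigenmode of such matrices is dominated by overall
conservation and is shared by the null, so it is excluded by default
(`include_first_mode=False`). On small or strongly structured synthetic
alignments a planted block can outweigh the diffuse conservation signal
and claim the first mode; `include_first_mode=True` keeps it in the
analysis for such cases.

The k significant eigenvectors are rotated into independent components
by fixed-point ICA (logcosh contrast, tolerance 1e−8, at most 1000
iterations, seeded; non-convergence raises an error naming the seed).
Loadings are sign-oriented so each IC's largest-magnitude loading is
positive, making residue selection deterministic; each IC's residue set
is the top ⌈5%·L⌉ of its empirical loading distribution. ICs are grouped
into sectors by average-linkage clustering on their mean inter-set
coupling in C̃, cutting the dendrogram at the cluster count that
maximizes the within/between mean-coupling ratio; the count can be
forced (e.g. to two) and k = 1 trivially yields one sector. IC residue
sets may overlap; a sector's residue set is the union over its ICs.
Sector membership transfers to any query protein through the alignment
map, feeding the sector/non-sector enrichment test.

## Synthetic data

The MSA generator draws exchangeable sequences: uncoupled column i shows
its consensus residue with probability c_i and a background draw
otherwise. A planted coupled group is a set of clean two-state columns
(consensus/alternate, both states at frequency ½): per sequence, with
probability ρ the whole group adopts one shared Bernoulli(½) state, and
with probability 1−ρ each column switches independently, so ρ is exactly
the group's co-switching probability and produces a block in C̃. Gaps
are sprinkled uniformly at a configurable rate; the first row is the
ungapped all-consensus reference. Defaults (400 sequences, 200 columns,
c_i = 0.6) give reference identities ≈ 0.5 and pairwise identities
≈ 0.3–0.4, comfortably inside the filter bounds.

The cohort generator draws variant positions with per-partition
probability proportional to partition length × an odds multiplier
(defaults: 60 disease-like variants at structured:unstructured odds 6,
300 population-like variants at odds 1/3 — a contrast of the magnitude
the pipeline is designed to detect), substitutions uniform over the 19
alternatives, and a variant-type mixture (disease: 87% missense,
remainder truncating/indel; population: 59% missense, 35% synonymous,
6% other). Uniqueness is enforced by rejection; labels are emitted in
HGVS p. form and round-trip through the parser. Missense draws avoid
residue 1, where any substitution of the initiator Met is a start-loss.

What passing tests on these data do and do not show: the generators have
no phylogeny (sequences are exchangeable), no indel history beyond
uniform gaps, no mutational spectrum, and coupling is a single two-state
block mechanism. Recovery of planted sectors and calibrated nulls
therefore demonstrate the correctness and calibration of the machinery,
not biological claims about connexin evolution; real-alignment results
depend additionally on sampling depth and phylogenetic correlation that
the permutation null only partially absorbs.

## Problem sizes and reproducibility

The test suite and `scripts/acceptance.py` run the coupling analysis at
400 sequences × 200 columns (planted-sector recovery, ten seeds in the
suite), the permutation-null calibration at 150 × 80 over ten seeds, and
the cohort-null Fisher calibration over 5000 (suite) / 2000 (script)
replicates — sizes chosen to give stable statistics on a single CPU in
minutes. Every stochastic step consumes an explicit seeded generator;
pipeline re-runs with the same config are byte-identical apart from the
manifest, which records package version, seed and input checksums.

## Known limitations

* Segment boundaries ship as approximate structure-derived defaults;
  analyses near boundaries should use a segmentation config derived from
  the user's own reference annotation.
* The pairwise global aligner replaces a profile/multiple aligner for
  query→reference mapping; below ~30% identity the mapping (and hence
  domain transfer) becomes unreliable.
* Threshold redundancy weighting makes Meff only clique-stable under
  duplication (see above).
* The exact test treats variants as exchangeable units; allele
  frequencies, recurrence and ascertainment differences between cohorts
  are not modeled.
* Sector extraction inherits ICA's rotational stochasticity; seeds are
  exposed and logged, and the IC residue sets are stable across seeds in
  the tested regimes, but borderline modes near the null threshold can
  flip significance between seeds.
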