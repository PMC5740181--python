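# Methods

## The analysis

`poolscan` implements a pooled-sequencing bulked-segregant (BSA) scan for a
quantitative trait in a first backcross (BC1) population, followed by the
downstream screening stages that narrow a linkage signal to a candidate
gene, using silkworm cocoon shell weight (CSW) — the proxy for silk protein
synthesis — as the motivating trait.

Individuals from the phenotypic extremes of each family are combined into a
low pool (L) and a high pool (H) and sequenced. At every polymorphic marker
the read depth splits into an "aa" channel (homozygous for the recurrent,
low-phenotype parent) and an "ab" channel (heterozygous). The per-channel
SNP-index contrasts the pools:

    SNP_index(aa) = Maa / (Paa + Maa)
    SNP_index(ab) = Mab / (Pab + Mab)
    Δ = SNP_index(aa) − SNP_index(ab)

with `M` = L-pool depth and `P` = H-pool depth. At an unlinked marker both
indices hover near the pool depth ratio and Δ ≈ 0; at a trait-linked marker
selection enriches aa in the low pool and ab in the high pool, pushing Δ
positive. Δ is standardised against the genome-wide background,

    Z = (Δ − μ0) / (S / √n),

where μ0 and S are the mean and sample standard deviation (ddof = 1) of all
Δ values and n the number of tested markers, converted to a normal-tail
p-value, adjusted for multiple testing, and thresholded (adjusted value
< 0.05) to call linked markers.

Two documented quirks of this statistic are preserved deliberately,
because the package's worked example reproduces a published table computed
with them:

- **Scale.** The `S/√n` denominator is a standard-error form applied to
  individual observations; it inflates |Z| by √n relative to a classical
  z-score. Both are available (`scale="se"` verbatim, `scale="sd"`
  classical). All simulation-based inference in this package uses the
  classical scale, whose null calibration is testable (one-sided p is
  uniform under the null); the verbatim scale exists to reproduce the
  published arithmetic.
- **Sidedness.** The confirmation stage uses a two-sided p computed as
  `2·(1 − Φ(z))` on the *signed* z — not folded through |z| and not capped
  at 1, so negative z gives p > 1. The published table prints such values
  (1.2217, 1.8190), and only this convention reproduces them.

**Multiple testing.** The published protocol names Bonferroni, but its
printed calls (14 markers whose largest raw p is 7.03×10⁻⁵ among 9,143
tests, all called at 0.05) are consistent only with Benjamini–Hochberg
step-up: the rank-14 adjusted value is 7.02539×10⁻⁵ · 9143 / 14 ≈ 0.0459,
while the Bonferroni product is 0.64. The default is therefore BH with an
explicit `n_tests` (supporting p-value lists that are only the smallest of
a larger scan); Bonferroni remains available, and every scan report states
which method ran and why the two disagree here.

**Confirmation.** Pooled depths can misrepresent allele frequency
(unequal DNA contributions, depth sampling), so each putative marker is
re-tested on hard counts: a nearby indel (±15 kb window) genotyped
individual-by-individual in the pooled animals, with the same
index → Z → p machinery applied to individual counts. The verdict rule is
*positive iff p_indel < p_bsa* (strict); this is the only plain rule that
reproduces the published 8-positive/6-false-discovery split row by row.
The standardisation background for indel Z is configurable: over the
supplied indel set (default, matching the worked example's self-contained
table) or against an external null background of unlinked-marker deltas —
the latter is what the pipeline uses on synthetic data, because a set of
indels that all sit at putative QTLs carries the very signal under test
and cannot serve as its own background.

**Regions and gene screening.** BC1 gametes carry at most one recombination
per chromosome, so linkage disequilibrium around a confirmed marker is
long-range. Each confirmed marker anchors a ±150 kb window (300 kb total,
the genome's ≈300 kb per cM physical scale); windows overlapping or
touching merge. Genes overlapping a region by ≥1 bp are candidates if they
have EST evidence (count > 0) in *every* required tissue — by default the
5th-instar silk gland and the embryo, the two stages that determine silk
yield.

**Expression association.** Candidates are scored against (a) daily silk
gland growth: Pearson/Spearman correlation of 5th-instar expression with
daily volume increments `V_t − V_{t−1}` (and their negation, for genes
that fall as growth accelerates), and (b) strain CSW: Spearman correlation
across strains, or a median-split Welch-t contrast. With a dozen strains
and under ten days, inference is by seeded permutation tests (default
10,000 permutations); the classical statistics are reported alongside but
no distributional claim is made at these sample sizes.

**Gene clusters.** Given one position per differentially expressed gene
(midpoint of its span), adjacent intervals are computed per chromosome and
compared with the uniform expectation `genome_size / n_genes` (total
genome size, not per-chromosome). A cluster is a maximal run of ≥3
consecutive genes whose every adjacent interval is strictly below a
threshold. Two published threshold conventions exist — 30 kb absolute
(about the genome-average gene interval) and 10% of the expected
interval — and they need not agree; both are computed and reported side by
side with a disagreement flag rather than silently resolved. A permutation
null (uniform re-placement with per-chromosome counts fixed) gives an
empirical p for the observed cluster count and for the fraction of
intervals below the expectation.

## The simulator

The generator emulates the study design that motivates the package:

| parameter | default | rationale |
|---|---|---|
| families ("moth areas") | 7 | stated design |
| family size | 127–174 males | stated design |
| pool fraction | 10% per tail, per family | stated design ("about 10%"), exposed as a parameter |
| mean marker depth | 245× | stated sequencing depth |
| genome | 28 chromosomes × 51 cM | ≈432 Mb at 300 kb/cM, the silkworm karyotype and genome size |
| marker spacing | 1 cM | desk-scale map (~1,456 markers); the study's ~9,143 markers only multiply runtime |
| CSW baseline / noise SD | 0.25 g / 0.05 g | typical cocoon-shell masses; noise spans the observed strain range |
| QTL effect | 0.10 g per heterozygous QTL | 2 phenotype SD, the regime the method is meant for |
| read error | 0.005 | post-filter short-read error scale |

Gametes follow a two-state Markov chain along each chromosome with Haldane
recombination fractions r = ½(1 − e^(−2d/100)); no interference. BC1
genotypes are aa/ab with probability ½ at every locus. Phenotype =
baseline + Σ effects·1[QTL = ab] + Gaussian noise. Pool selection takes
the exact bottom/top ⌊f·n⌋ (minimum 1) per family, stably ordered by
(phenotype, index) so ties are deterministic.

Pooled depths are Poisson(mean_depth) per marker per pool. Read
assignment to channels follows the **allele-depth convention** by default:
a read carries the recurrent-parent allele with the pool's a-allele
frequency (2·n_aa + n_ab)/(2n), and a-alleles land in the "aa" channel —
only alleles are observable in a pool. Under perfect selection at a fully
linked marker (low pool all aa, high pool all ab) the low pool emits only
a-reads and the high pool splits evenly, giving SNP_index(aa) → D/(D+D/2)
= 2/3, SNP_index(ab) → 0, hence Δ → 2/3; the replicate studies confirm
this limit. A "genotype-dosage" convention (heterozygotes contribute half
their reads to each channel) is selectable; the two agree in expectation
and differ only in dispersion. Sequencing error flips a read's channel
with the error rate.

What the generator does **not** emulate: restriction-site marker ascertainment
(markers are an even cM grid, not SLAF fragments), depth overdispersion
beyond Poisson, pool construction biases (unequal DNA input per
individual), genotyping error in the confirmation counts, and any
non-additive QTL action. Passing tests therefore show the statistics
behave correctly under the design's idealised assumptions, not that the
pipeline is robust to those artefacts.

## Replicate studies and problem sizes

`poolscan.validation` runs the pipeline property studies at the full study
scale (28-chromosome map, ~1,000–1,200 males, 245×), which matters because
the Z score is standardised against the genome-wide Δ distribution — on a
small genome a planted QTL's linked markers contaminate their own
background and the scan loses calibration (this failure mode is visible if
the map is shrunk to a few chromosomes).

- **Type-I control:** 100 zero-effect replicates; the pipeline (scan at
  FDR 0.05, then confirmation) should confirm nothing in ≥95 of them.
  Observed: the BH stage alone already leaves ~96% of replicates with zero
  calls (its family-wise error under a global null), and confirmation
  removes the depth-noise survivors.
- **Recovery:** 50 replicates with one 2-SD QTL; the max-|Z| marker should
  fall within 5 cM of the truth in ≥90%.
- **Perfect-linkage limit:** mean Δ over 2,000 fully linked markers at
  245×, compared with 2/3.

These sizes run in well under a minute; they are the package's chosen
validation scale, stated here so results are interpreted at that scale.

## Numerical choices

- Φ is `scipy.special.ndtr`; tails are computed as `ndtr(−z)` so that
  deep-tail p-values do not round to zero prematurely. The test suite
  checks Φ against the C library's `erfc` to 10⁻¹².
- Printed-value comparison in the worked example allows one unit in the
  last printed digit: one published entry (1.221679211) is a truncation,
  not a rounding, of the computed 1.2216792116.
- Printed p-values of exactly 0 are treated as underflow at the table's
  precision (< 5×10⁻¹⁰); classifications use the computed float.
- BH adjusted values are not capped at 1 (they are compared against
  thresholds, never interpreted as probabilities); Bonferroni is the plain
  product p·n_tests.
- Markers with a zero-depth channel are excluded from the scan (counted
  and logged), never imputed. All-equal Δ (S = 0) is an error naming the
  degenerate input.
- Coordinates are 1-based inclusive throughout; BED import/export converts
  at the boundary.
- One master seed; stages derive child seeds via `numpy` `SeedSequence`.
  Pipeline reruns are byte-identical.

## Known limitations

- The published BSA p-value column is not a monotone function of its BSA Z
  column, so no single Z→p rule can reproduce it; only the confirmation
  (indel) p column is reproduced exactly. The BSA p values are therefore
  consumed as given when re-analysing the published table.
- The published genome-wide figures that depend on the study's
  supplementary DEG list and annotation build (the 77.8% / 25.64%
  interval fractions and the 114-cluster catalogue) are not reproducible
  without those inputs; the pipeline computes the same summaries for any
  user-supplied DEG list, and its cluster statistics are validated against
  closed-form and brute-force oracles instead.
- The region stage's EST screen passes annotation text through for human
  review; it does not attempt functional curation.
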