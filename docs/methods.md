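# Methods

## Scope and data model

`cellsplice` operates downstream of read alignment: its inputs are a
junction-count table (reads per splice junction per event per sample),
a gene × sample raw-count matrix with per-gene uniquely-mappable
lengths, and a sample sheet assigning each sample to a cell type and an
organ (`root` or `aerial`).  Each alternative-splicing event belongs to
one of four classes — intron retention (IR), exon skipping (EX),
alternative acceptor (ALTA) and alternative donor (ALTD) — which fixes
the junction roles that are legal for it.  Alignment, junction-library
construction and impact prediction are out of scope; predicted protein
impact is consumed as an annotation table.

## PSI estimation

For EX events the inclusion evidence is the mean of the two inclusion
junctions, I = (C1A + AC2)/2, and PSI = 100·I/(I + C1C2); IR events are
analogous with the two exon–intron junctions EI and IE against the
spliced junction EE.  ALTA/ALTD events report the focal variant's read
share.  Averaging the two inclusion junctions uses both boundary
measurements and keeps the estimator unbiased when each junction is
sequenced at the same rate as the exclusion junction.  A zero
denominator yields a missing value: absence of evidence is not evidence
of exclusion, and conflating the two would deflate PSI for poorly
covered events.

Stored PSI values carry two decimals and balance p-values six
significant digits — the same precision as the on-disk table dialect —
so a written table reads back bit-identically.

### Coverage tiers

The informative read total (⌊I + E⌋; half-counts from junction
averaging are floored for cross-platform determinism) maps to ordinal
tiers: N below 10 reads, then VLOW (≥10), LOW (≥15), OK (≥20), SOK
(≥100).  The tier names follow the splicing-table convention of
graded read-support labels; the numeric cutoffs are this package's
explicit defaults and are configurable (`RunConfig.tier_cutoffs`).
Downstream analyses use values at tier ≥ LOW by default.

### Intron-retention read balance

Genuine retained introns produce reads at both exon–intron boundaries
at similar rates; strong imbalance indicates mis-mapping or overlapping
features.  Per (event, sample), the EI read count is tested against
EI + IE trials at success probability ½ with an exact two-sided
binomial test; a cell fails when p < α (default 0.05).  No multiplicity
correction is applied: this is per-cell evidence screening, not
inference.  Two design points:

- Cells with **no** retention reads (EI = IE = 0 but EE > 0) are valid
  fully spliced observations (PSI = 0).  They make no retention claim,
  so the balance filter does not mask them; masking them would silently
  delete the low-PSI end of every IR event and bias cell-type means
  upward.  `ir_balance_test(0, 0)` itself reports "no evidence"
  (p = NaN, not passed) for callers that interrogate a junction
  directly.
- The production path uses a vectorized closed form of the two-sided
  exact test (valid because Binomial(n, ½) is symmetric); the scalar
  reference implementation wraps `scipy.stats.binomtest`, and the test
  suite asserts their equality exhaustively for n ≤ 60.

### Event filter

An event survives when ≥ `min_samples` (default 10) samples hold a
present PSI at tier ≥ LOW, counting IR cells only if their balance test
did not reject.

## Cell-type-specific splicing calls (DSE)

Organs are analyzed separately, since root and aerial samples differ
globally and pooling them would swamp within-organ specificity.  For a
target cell type, over covered values only:

- **ΔPSI_global**: target mean minus the mean of all other same-organ
  samples pooled.  Pooling weights samples, not cell types; a
  config switch is not offered for this because the pooled reading is
  the operative definition throughout ("PSI_target − PSI_average").
- **ΔPSI_min**: the per-cell-type mean difference of smallest
  magnitude against any other cell type with ≥ `min_replicates`
  covered values (sign preserved; ties resolved toward the smaller
  signed value).
- **PSI range**: max minus min of per-cell-type maximum replicate PSI
  across the organ — a guard that the event actually varies rather
  than sitting at a constant level with one noisy group.

A call requires |ΔPSI_global| > 25, |ΔPSI_min| > 15 and range ≥ 2, with
≥ 2 covered replicates in the target and ≥ 4 covered cell types in the
organ.  The two ΔPSI comparisons are strict by default (configurable via
`strict_dpsi`); the range rule is inclusive.  Direction is the sign of
ΔPSI_global.  Sign coherence between the two ΔPSI statistics is not
required by default (only magnitudes are thresholded); setting
`require_sign_coherence` enforces it.  An event may be called in more
than one cell type of an organ, necessarily in mixed directions.

## Expression quantification and DEG calls

cRPKM divides counts by uniquely mappable positions rather than
annotated length, so repetitive genes are not under-quantified; the
library size is the count-matrix column sum.  Size factors follow
median-of-ratios: per-gene geometric means over samples (genes with any
zero excluded), each sample's factor the median ratio to that
reference, with the lower-median convention on even counts for
determinism.  A single sample gets factor 1.  Note that per-column
rescaling of raw counts is absorbed by the factors only up to a global
constant c^(1/S) — the geometric-mean reference itself moves — so
normalized counts are defined up to scale, as with any
reference-relative normalization.

A gene enters the DEG analysis in an organ when its median cRPKM
reaches 5 in at least one cell type.  The call rules for a target cell
type: fold change ≥ 2 against every other cell-type median, fold
change ≥ 5 against the pooled median of all other samples, and an
absolute difference ≥ 2 cRPKM against every other cell-type median —
each fold change evaluated symmetrically (ratio ≥ t or ≤ 1/t) on the
linear scale with pseudocount 0.01, which keeps 0-vs-0 neutral and
0-vs-positive large.  Outputs report the global comparison as log2.
All DEG rules are inclusive (≥).  No p-values are attached: the
procedure is deliberately rule-based, and the replicate-median plus
four-rule structure is its robustness mechanism.

## Summaries, enrichment

Call sets reduce to: DEG/DSG overlap counts (a DSG is a gene owning ≥ 1
called event), exclusive upset intersection patterns of cell-type
membership, event-class proportions per direction, gene-set subsets
(e.g. an immunity list), predicted-impact breakdowns with an up/down
split within ORF-disrupting events, and a per-call join of ΔPSI with
the gene's log2 fold change in the same cell type, labeled by quadrant
at |ΔPSI| > 25 and |log2 FC| > 2 (both configurable).

Term enrichment uses the one-tailed hypergeometric tail
P(X ≥ k) and its EASE variant P(X ≥ k−1) (floored at 0), which
penalizes overlaps supported by a single gene (k = 1 scores 1.0) and is
always ≥ the Fisher tail.  The background should be the genes that
passed the same quality filters as the list under test; list and terms
are intersected with it before counting.  Benjamini–Hochberg-adjusted
EASE scores are appended; raw values are retained since the adjustment
convention varies across tools.  P-values are floored at 1e-300 to
respect the (0, 1] contract under floating-point underflow.

## The synthetic-data generator

The generator emulates the sorted-cell-type study design: 7 root + 4
aerial cell types (named after the reporter promoters of such designs,
pATHB8, pSCR, …, pML1, pREV, …), 3 replicates, 1000 events mixed 65%
IR / 17% ALTA / 10% EX / 8% ALTD (intron retention dominant, the plant
ranking), 2000 genes.  All knobs sit on `SimConfig`.

**Splicing.**  Each event draws a baseline PSI from Beta(0.3, 1.2)
× 100, clipped to [1, 99] — J-shaped toward low inclusion, the typical
profile of IR-dominated plant event sets.  A planted event (20% of
events by default) shifts its baseline by ±40 PSI points in exactly one
cell type, assigned round-robin so every cell type receives signal; the
baseline is redrawn (and the redraw logged) until the shifted value
fits in [1, 99].  Per sample, the realized PSI is Beta-distributed
around the cell-type truth with intra-class correlation ρ = 0.02
(a = μ(1−ρ)/ρ, b = (1−μ)(1−ρ)/ρ; ρ → 0 degenerates to the truth) —
one intuitive dispersion knob.  Junction reads are independent
Poisson: each inclusion junction at rate depth·ψ and the exclusion
junction at rate depth·(1−ψ), depth 100 by default.  This makes the
expected informative total equal the depth parameter, renders the PSI
estimator consistent in expectation (generator and estimator share the
junction model), and gives the IR junction pair a Binomial(n, ½) split
conditional on its sum — exactly the null of the balance test.
ALTA/ALTD events are simulated with two variants.

**Expression.**  Gene abundances are log-normal (median cRPKM ≈ 50,
log-sd 1, so ~1% of genes sit below the cRPKM-5 eligibility floor);
counts are gamma-Poisson (negative binomial, Var = μ + 0.1·μ²) around
abundance × library size (5e6 ± 5%); mappable lengths log-normal
around 2 kb.  Planted genes (10% by default) multiply or divide their
mean by 8 in one cell type.  Planted splicing and expression signals
occupy disjoint genes, so the two call sets are separable by
construction.

**What the generator does not emulate**: correlated dispersion across
events or genes, organ-level global expression shifts, coverage that
varies by event (depth is homogeneous), overlapping cell-type
identities (each planted signal is exactly one cell type), genomic
coordinates with real structure, or GC/length biases.  Passing the
recovery and null tests therefore demonstrates the correctness and
calibration of the calling logic under its own model assumptions — not
performance on real libraries, where coverage heterogeneity and shared
cell-type identity will lower recall for closely related populations.

## Verification and problem sizes

The suite checks, among others: exact agreement of both callers with
independently coded straight-line rule evaluators on 500 random
instances each; recovery on the default recovery study (one organ, 4
cell types × 3 replicates, 1000 events / 200 planted, 2000 genes / 200
planted) of ≥ 0.90 recall and precision with ≥ 0.99 direction accuracy;
≤ 1% call rates with nothing planted; balance-test rejection ≤ 6% on
10,000 balanced junctions at n = 50 with stochastically super-uniform
p-values; and PSI-estimator accuracy within 2 points of the generative
value for ≥ 95% of events at depth 1000.  The consistency study runs at
10,000 events rather than 1,000: the population value of the
within-2-points fraction is ≈ 0.956 (measured over independent seeds),
close enough to the 0.95 bound that the larger sample is needed for the
check to measure the property rather than seed noise.  Typical end-to-
end runtimes are a few seconds per study on one CPU.

## Degenerate inputs and tie-breaking

Missing PSI is distinct from 0 throughout ("NA" on disk).  Empty gene
lists warn rather than fail.  Events absent from the impact annotation
map to `unknown` and are excluded from impact fractions.  A cell type
whose organ has fewer than the minimum covered cell types contributes
no calls (logged).  ΔPSI_min ties prefer the smaller signed value;
medians over even counts use the lower median in size factors and the
interpolated median elsewhere (medians of cRPKM replicates), matching
each context's convention.  All pipeline outputs are byte-deterministic
for a fixed seed: stable sort orders, fixed float formats.
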