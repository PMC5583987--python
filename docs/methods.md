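# Methods

## Study design being modeled

Five developmental stages of the chicken liver around hatch: embryonic days
E18 and E20, posthatch days D0 (before first feeding), D1 and D3. mRNA
expression is profiled per bird (4 replicate libraries per stage); small-RNA
libraries are pooled across the 4 birds of a stage, so miRNA expression has
one library per stage and no within-stage replication. Pairwise stage
comparisons follow the developmental path (E18–E20, E20–D0, D0–D1, D1–D3)
plus the pre/post-switch endpoints E18–D3.

## Normalization and detection

CPM = count / library_size × 10⁶; RPKM = CPM / (length/10³). Detection keeps
features with CPM ≥ 30 (miRNA) or RPKM ≥ 30 (mRNA), threshold inclusive, in
**at least one** library by default. The per-library reading is used because
detection counts are reported per library; an `all`-samples rule is exposed
as a flag for the stricter interpretation, which the data do not
disambiguate.

## Differential expression

**Model.** Counts are negative binomial with mean μ and dispersion φ,
Var = μ + φμ² (φ = 0 is Poisson). This single parameterization is shared by
the simulator, the dispersion estimator and the test.

**Library equalization.** The exact test requires equal library sizes, so
counts are first quantile-adjusted to the geometric mean of the observed
library sizes by moment matching: pseudo = μ_out + (y − μ_in)·√(v_out/v_in)
with v = μ(1 + φμ). Equal input libraries are a fixed point, and rescaling
all library sizes by a constant leaves pseudo-counts unchanged (the
abundance estimate absorbs the scale).

**Common dispersion.** φ maximizes the summed per-feature conditional
log-likelihood of counts given their group sums (all-zero features
excluded), a 1-D bounded maximization over φ ∈ [10⁻⁶, 10] with tolerance
10⁻⁶ (scipy bounded Brent; deterministic, no seed). At least one group must
have ≥ 2 replicates; otherwise the caller must supply a fixed φ.

**Exact test.** Conditional on the total of the two group sums, the group-a
sum is beta-binomial with shapes n_a/φ and n_b/φ (binomial with success
probability n_a/(n_a+n_b) at φ = 0). The two-sided p-value sums the
probabilities of all splits whose probability is ≤ the observed one, with
relative tolerance 10⁻¹⁰ for ties (floating-point-safe "as or less
probable"). Probabilities are normalized over the integer grid 0..total;
non-integer pseudo-count sums are evaluated continuously against that grid.
p-values are floored at 10⁻³⁰⁰ to stay in (0, 1].

**Calls.** log2FC is computed on normalized group means with pseudo-count
0.5 (descriptive; p and q drive calls, finite FC for zero means). BH FDR is
applied within each pairwise comparison (per-comparison discovery counts are
the reporting unit). Significance ⇔ |log2FC| > 1 strictly AND q < 0.05.
Unreplicated (pooled-library) miRNA comparisons refuse to run without an
explicit fixed dispersion, and the output table carries a
`fixed_dispersion` column flagging the assumption; silently assuming a
variance for n=1 designs would make calls irreproducible. The run-all demo
uses 0.05.

## Target-site prediction

**Alignment.** Best local antiparallel duplex by affine-gap dynamic
programming (Gotoh) of the miRNA (5′→3′) against the reversed UTR window:
WC +5, G:U +2, mismatch −3, gap open −9, gap extend −4, with pair scores at
miRNA nt 2–8 scaled ×4. The tool and version the thresholds come from is
configurable only through these parameters, which are recorded in output
headers; the 130-score gate is evaluated on the scaled score. Ties prefer
the smaller UTR start, then fewer gaps. A perfect 22-nt duplex with this
scheme scores 7·5·4 + 15·5 = 215.

**Scanning.** Every class-A or class-B site must contain a 6-mer pairing
miRNA nt 2–7 (WC, or G:U where wobble is allowed), so candidate regions are
located by enumerating those seed anchors and aligning a window of
mirna_length + 8 nt around each; this is exhaustive with respect to the
reportable site classes and keeps 1000-UTR scans in seconds. Candidates must
pass score (strictly > 130), energy (strictly < −16 kcal/mol) and carry
seed class A or B — all gates conjunctive. Overlapping candidates are
resolved greedily by descending score; output is sorted by window start.

**Seed rules.** Class A: miRNA nt 2–8 all WC-paired, contiguous (UTR
positions consecutive), no gaps. Class B: nt 2–7 AND nt 13–16 paired with
WC or G:U, contiguous and gap-free per span; "and" is the adopted reading of
the two-segment rule. A takes precedence. By default wobble is tolerated in
both class-B spans (the tolerance attaches to the whole rule);
`wobble_scope="3p"` restricts it to nt 13–16.

**Duplex free energy.** Helix segments (maximal runs of paired columns) are
summed with nearest-neighbor stacking ΔG°37: the exact 10-parameter
Watson–Crick table (Xia/Turner), duplex initiation +4.09 kcal/mol, +0.45
per helix end closed by A:U or G:U, and +3.0 per internal interruption
(each maximal mismatch/gap run). Stacks involving G:U wobbles use a
simplified 3-level approximation (−1.5 next to G:C, −1.0 next to A:U, −0.5
for tandem wobbles): qualitatively correct (weaker than WC, still
stabilizing), chosen over a full wobble table that could not be sourced
reliably. The model has no loop thermodynamics and is approximate relative
to partition-function tools; the −16 kcal/mol gate is defined **on this
model**. No quantity reported by the package depends on exact wobble stack
values.

## Network integration

An edge miRNA → gene for one comparison requires: both features significant
(the 2-fold + FDR 0.05 call, not raw p), opposite log2FC signs, and ≥ 1
passing site (sites unioned over the gene's transcripts via a two-column
transcript→gene map). Edges are ranked by
rank_score = w₁·minmax(−ΔG) + w₂·|gene log2FC| + w₃·n_sites + w₄·annotation,
weights default 1 — the selection criteria are qualitative, so the
combination is an explicit pipeline convention, recorded in output. The
annotation flag comes from a user-supplied metabolic gene list; no pathway
database is bundled. Reporter helpers implement Renilla/firefly
normalization and a two-group one-way ANOVA (equivalent to the two-sided
t-test) with a direction gate: repression requires p < 0.05 AND a lower
miRNA-condition mean.

## Synthetic data generator

The generator is first-class, tested code; every downstream stage is
validated against its registry of planted truth.

* **Counts.** NB(μ·library/10⁶, φ) per sample; baselines log-uniform on
  [30, 5000] CPM so features clear detection and tests exercise the DE
  logic, not detection edges. Defaults: mRNA 4 replicates/stage, φ = 0.1;
  miRNA 1 pooled library/stage, φ = 0.02 (pooling four birds averages
  biological variance; the true variance of pooled libraries is unknowable,
  so φ is a free design parameter). Planted features are floored at 100 CPM
  (mRNA) / 500 CPM (miRNA — the validated regulators are abundant hepatic
  miRNAs, and unreplicated comparisons need counts for power).
* **Fold changes.** Planted effects anchor the **higher** of the two stages
  at the baseline and put the other at baseline/2^|lfc|, with geometric
  interpolation at intermediate stages — the switch genes go from barely
  detectable to high, not from typical to astronomically high. The default
  effect grid spans log2FC 1–9.45 (2-fold to ~700-fold, the observed range
  of the switch).
* **UTRs.** Background uniform over {A,C,G,U}, so the chance rate of a
  class-A seed is exactly 4⁻⁷ per position — the closed form used by the
  null-rate check. Planted class-A sites are exact full-length reverse
  complements; class-B sites are full complements with the nt-8 pairing
  broken and configurable G:U wobbles in nt 13–16. Class-B candidates are
  **verified through the aligner** before acceptance (preferring a G:U break
  at nt 8; mismatch breaks are insulated against register slippage by also
  de-pairing bases opposite nt 9–10, which rule B leaves free), because a
  naive single mismatch can be evaded by a slipped, bulged alignment.
* **Clean-truth scrubbing.** When sites are planted, UTR backgrounds that
  happen to contain a threshold-passing chance site for a *planted* miRNA
  are redrawn, so the registry is the complete ground truth for those
  miRNAs (chance class-B sites otherwise appear at ~0.3% per miRNA–UTR pair
  at 500 nt). Designs that plant nothing are never scrubbed, keeping null
  analytics exact.
* **Determinism.** All outputs are pure functions of (design, seed).

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level error and mapping bias, non-uniform
UTR composition (real UTRs are AU-rich, so real chance-site rates differ
from 4⁻⁷), repeat content, transcript isoform mixtures, correlated
expression across genes, and composition effects of pooled libraries.
Recovery results on clean synthetic data are an upper bound on real-data
performance.

## Bundled end-to-end design

Ten planted regulations (miRNA down 4–16-fold E18→D3; target up 4- to
~700-fold; one class-A site each) among 40 miRNAs (gga-let-7c plus random
22-mers), 400 genes, 80 scanned 500-nt UTRs; libraries 1.4×10⁶ (miRNA) and
10⁶ (mRNA) reads — scaled-down library sizes chosen so a full run completes
in seconds on one CPU while keeping counts in a realistic CPM regime. The
planted regulations are the only DE truth, so any extra edge is a genuine
false positive; non-regulated background UTRs still exercise the site gate
against chance matches. Problem sizes used by the test suite and acceptance
script: 10,000 features for null calibration, 2,000 for dispersion and DE
recovery, 1,000 random UTRs for the null seed rate, 5 seeds end-to-end.

## Numerical choices and degenerate inputs

Exact-test tie tolerance 10⁻¹⁰ relative; p floored at 10⁻³⁰⁰; all-zero
totals give p = 1. Dispersion bounds [10⁻⁶, 10], tolerance 10⁻⁶; Poisson
data estimate at the lower bound. Pseudo-counts are clipped at 0. UTRs
shorter than 7 nt scan to an empty result. Alignment ties are broken
deterministically (smaller UTR start, then fewer gaps; traceback prefers
pairs over gaps). Site/edge tables print floats via `repr` so round-trips
are lossless. DNA input (T) is silently normalized to RNA (U); coordinates
are 0-based half-open everywhere except miRNA position numbering, which is
1-based from the mature 5′ end and confined to seed-rule logic.

## Known limitations

The exact test reproduces the published *method* (conditional NB test with
common dispersion), not the internals of the commercial software used for
the original analysis; per-feature (tagwise) dispersion, TMM normalization
and GLM designs are out of scope. The energy model is a stack-sum
approximation without loop entropies or target-site accessibility. The
miRanda-style scoring constants approximate the named version's defaults;
they are pinned and recorded rather than bit-exact. Real UTR composition
and conservation filtering are not modeled. The headline counts of the
original study (823 DE mRNAs, 31 DE miRNAs, per-category target tallies)
depend on the deposited sequencing data and annotation databases and are
not reproducible at desk scale; the package instead validates each stage
against analytic forms, independent oracles and planted truth.
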