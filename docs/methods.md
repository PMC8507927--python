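# Methods

## Scope and data flow

`dropscreen` implements the computational arm of a pooled-shRNA
negative-selection screen and its two companion analyses. The pipeline is

    library design → (simulated) screen → barcode quantification →
    normalization → depletion fold changes → second-best gene ranking →
    cross-setting comparison

with independent modules for Chou–Talalay synergy arithmetic and
differential-expression post-processing. No stage depends on wet-lab data
formats beyond FASTQ, TSV/CSV and YAML; all joins are by identifier.

## Library model

A design is an ordered catalogue of (shRNA id, gene symbol, barcode,
reliable flag). Constraints enforced on every design: barcodes are unique,
fixed-length, over {A,C,G,T}; every *reliable* gene carries 5 or 6 hairpins.
Auxiliary targets (named `AUX0001`…) absorb hairpins beyond the reliable
allocation; they are counted and carried through fold-change tables but
never ranked.

Generated barcodes use a checksum code: the last base is the sum of the
preceding base indices mod 4, giving a guaranteed minimum pairwise Hamming
distance of 2. Consequence: a single sequencing substitution can never turn
one library barcode into another, so 1-mismatch assignment is unambiguous
for 1-error reads by construction (ambiguity handling remains testable with
hand-built adversarial barcode sets). This costs one base of entropy; the
generator therefore requires `4^(L−1) ≥ n` in addition to the basic
`4^L ≥ 2n` space check.

The 5-vs-6 split assigns the sixth hairpin to the first *k* genes of a
seeded random permutation, `k = n_reliable_shrnas − 5·n_genes`.

## Screen simulator

The generator emulates the statistical structure the downstream analysis
assumes, with three stochastic layers:

1. **Baseline representation** — symmetric Dirichlet with concentration
   `1/dispersion` (default dispersion 0.3, a mild skew; dispersion → 0
   approaches uniform representation). Drawn once per replicate and shared
   across that replicate's settings, mirroring a snap-frozen pre-selection
   control.
2. **Selection** — deterministic exponential depletion on relative
   abundances: `a_i ∝ a_i · exp(−s_i · days)`. Per-hairpin rates have two
   components:
   * *planted essentials*: a seeded fraction of reliable genes (default 5%)
     is labelled essential; a sub-fraction only acts under one named setting
     (condition-specific). For each essential gene, `ceil(0.8 · n_hairpins)`
     hairpins draw `s` from a zero-truncated Normal(0.5, 0.15) per day —
     over a 9-day selection a hairpin at the mean rate depletes ~90-fold,
     a strong but realistic dropout;
   * *background fitness*: every hairpin additionally draws a small rate
     from Normal(0, 0.03) per day, shared across replicates and settings.
     This models the construct-intrinsic off-target and mild fitness
     effects present in real screens; it is what makes replicate fold
     changes strongly rank-correlated (observed Spearman ≈ 0.93 at 500×
     coverage) while their counting noise stays independent. Setting
     `background_sd=0` recovers the bare planted-effects model.
3. **Sequencing** — barcodes drawn multinomially from the selected profile;
   reads are `5′ flank + barcode + 3′ flank` with i.i.d. per-base
   substitutions (no indels — appropriate for Illumina amplicon data) and
   constant quality. The emitter returns its exact pre-error per-barcode
   tally, which serves as ground truth for quantifier tests.

Cell-division stochasticity is not modelled explicitly; at the 200–1000×
coverage the protocol mandates, multinomial sampling at sequencing is the
dominant noise source. Transduction efficiency is sampled per replicate
(default uniform on [0.15, 0.35]) and is metadata only — it drives QC
exclusion, never counts. Settings are labels gating condition-specific
effects; time-varying media schedules within a setting are not modelled.

`simulate_screen_counts` is a count-level fast path for large parameter
studies: it draws the same multinomial counts and models read-level error
in aggregate by binomial thinning with keep probability
`(1−e)^L + L·e·(1−e)^(L−1)` (reads with ≥2 barcode errors are
unrecoverable; 0–1-error reads are assigned correctly thanks to the
distance-2 code). The FASTQ path and quantifier are exercised at full scale
separately.

## Quantification

The barcode occupies a fixed offset in every read (amplicon protocols fix
position), so quantification is substring extraction plus hash lookup —
O(reads). With `max_mismatch=1`, a failed exact lookup enumerates the 3·L
single-substitution neighbours; reads matching two barcodes at equal
distance are counted **ambiguous and discarded** (conservative and
order-independent, unlike fractional assignment). Reads shorter than
offset+length are unassigned, never truncated-matched. Invariant checked on
every file: assigned + ambiguous + unassigned = total.

Sample QC retains a selection sample iff its transduction efficiency lies in
[0.10, 0.40] (inclusive; the exclusion rule is stated for >40% and <10%).
Baseline samples are always retained.

## Normalization, fold changes, ranking

* **Pseudocount 0.5** added to every cell before reads-per-million scaling.
  Strong essentials are expected to deplete to zero counts; the pseudocount
  keeps fold changes finite (a 100-read hairpin going to 0 at equal depth
  gives FC = 100.5/0.5 = 201). The pseudocount is recorded in output
  metadata. At pseudocount 0 on positive counts the transform is plain RPM
  and fold changes are exactly depth-invariant.
* **Orientation**: depletion FC = baseline / follow-up, so larger = more
  depleted and "second largest fold change" picks the second-most-depleted
  hairpin. This matches the defining property that for each scoring hairpin
  another hairpin of the same gene shows an even larger baseline→follow-up
  change.
* **Second-best statistic**: per reliable gene, sort its hairpins' FCs and
  take the second largest (requires ≥2 measured hairpins; genes failing
  this raise a validation error listing them). Ties in gene scores are
  broken lexicographically and flagged — determinism across platforms.
* **Concordance**: Spearman of FCs is the headline replicate-agreement
  statistic (robust to the heavy right tail); Pearson of log₂ FC is
  reported alongside.
* **Set comparisons**: top fraction = `ceil(fraction × n_genes)` best ranks
  (top 1% of 4,974 genes = 50). Setting-specific genes =
  (∩ target-replicate top sets) − (∪ all other settings' top sets).

## Synergy module

Median-effect fits are ordinary least squares of `log₁₀(fa/fu)` on
`log₁₀(D)` — exact on noiseless model data, with the correlation coefficient
of the linearized fit reported as quality. fa values are clamped to
[0.005, 0.995] before the logit (divergence guard; recorded in metadata),
and zero-dose wells define the control signal only — log D is undefined at
zero. IC50 is reported as Dm from the same fit rather than a separate
four-parameter logistic, keeping one parametric family for IC50, Dx and CI.
A non-positive fitted slope is returned flagged rather than raised.

The CI uses the two-term mutually exclusive (Loewe-type) form — the default
of the standard software for this method. Identities tested: a drug
combined with itself at half-equivalent doses gives CI = 1 to 1e−9;
a single agent at its own equivalent dose gives CI = 1; CI is strictly
decreasing in the observed combination effect. The operation takes explicit
(d₁, d₂, fa) triples, covering both constant-ratio and non-constant-ratio
designs.

## DE post-processing

Strict inequalities at all three thresholds (p < 0.05, padj < 0.05,
|log₂FC| > 1); boundary values are excluded. Records with NA adjusted p
fail the filter silently — upstream independent filtering produces NAs for
low-count genes and there is no principled rescue at this stage. The GSEA
pre-ranking metric is `−log₁₀(p) × sign(log₂FC)` with p = 0 clamped to the
smallest positive double, `sign(0) = 0`, descending order, gene-symbol
tie-break. Negating every fold change negates every metric and exactly
reverses the order.

## Pipeline and reproducibility

Runs are plain directories with a JSON manifest (config hash, seed, SHA-256
per artifact). All randomness flows from the config seed through
`numpy.random.default_rng`; identical configs produce byte-identical
artifacts (FASTQ paths in sample sheets are stored relative to the sheet so
run directories are relocatable). The report verifies checksums before
summarizing; a missing or modified artifact aborts with the file named.
Logging is structured (stage, counts in/out) to one file per run, without
timestamps, so logs do not break determinism.

## Problem sizes used in the test and acceptance studies

Chosen as the smallest sizes at which the measured properties are stable:
quantifier ground-truth agreement at 1,000 barcodes × 10⁶ reads;
second-best oracle over 1,000 random 100-gene fixtures; recovery and
concordance at 2,000 genes × 5 hairpins, 500× coverage, duplicate
replicates, 5 simulations (count-level path); condition-specific recovery
with 20 planted essentials of which 3 setting-specific (the density at
which a 1% top set can contain all essentials, mirroring the three
setting-3-only genes the screen design anticipates); median-effect recovery
over 50 noisy curves (fa noise sd 0.02). The full-scale 27,500-hairpin
library is exercised for composition and round-trip only.

## What passing tests do and do not show

The simulator shares the analysis' structural assumptions (fixed barcode
position, substitution-only errors, exponential depletion, multinomial
sampling). Passing recovery tests therefore validates the *statistics and
bookkeeping* — not robustness to real-data pathologies the model excludes:
PCR amplification bias, indels, positional jitter, time-varying selection
pressure, clonal drift, or batch effects between sequencing runs. The QC
and normalization stages mitigate some of these in practice, but no claim
about them is tested here.

## Known limitations

* No probabilistic essentiality scores or p-values — the method ranks.
* Mismatch tolerance is capped at 1; higher error rates need alignment.
* The synergy module fits each drug independently; no joint surface model
  (Bliss, ZIP) is provided.
* The DE module post-processes an existing results table; it does not fit
  expression models.
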