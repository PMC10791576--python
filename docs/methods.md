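# Methods

## Intensity forward model

A polony is a clonal surface-bound cluster of concatemeric template copies;
its per-cycle fluorescence in four dye channels is the substrate of base
calling. The simulator models each polony as a population of strands that
advance along a common template. Per cycle a strand advances 0 positions
with probability `p_lag` (phasing), 2 with probability `p_lead`
(prephasing), and 1 otherwise, independently across cycles and strands. The
induced cycle × position distribution `P` is computed by a forward
recursion; `P[0]` is unit mass at position 0 and row *t* has support in
`[0, 2t]`. The trinomial step is the minimal model consistent with run-level
lag/lead probabilities; it is exactly invertible, which gives the base
caller a testable oracle. Real instruments may have per-cycle-varying
phasing; run-level scalars are used here.

Pure channel signal at cycle *t* is `brightness · decay^t ·
Σ_j P[t,j] · 1(template[j] = channel base)`. Observed signal applies a 4×4
spectral cross-talk matrix and additive Gaussian noise, clipped at zero.
Channel assignment is fixed A,C,G,T → 0..3. Per-polony brightness is
lognormal with mean 1 and a configurable coefficient of variation;
`signal_decay_per_cycle` is a single multiplicative factor (default 1) that
exists to stress normalization robustness rather than to model a specific
photophysical mechanism.

Defaults (`SimConfig`): 1,000 polonies × 150 cycles, `p_lag = 0.005`,
`p_lead = 0.002` (sub-percent per-cycle phasing, the regime in which a
well-tuned short-read instrument operates), brightness CV 0.15, additive
noise SD 0.02 on signals of order 1, a diagonally dominant cross-talk matrix
with ~5–8% bleed-through into neighbouring channels. The convenience
simulator draws templates exactly as long as the read, so the truncated
deconvolution below is the exact inverse of the forward model; longer
templates (prephased strands templating beyond the last cycle) are supported
through `generate_templates` and introduce a small final-cycle truncation
error.

## Base calling

Stage order: cross-talk inversion → phasing deconvolution → per-cycle
channel normalization → argmax call.

* **Cross-talk** is removed by solving `M·x = y` per polony per cycle.
  Negative components are clamped to zero after the solve (counted and
  logged), keeping the linear algebra exact. A singular matrix is an error
  naming the condition number; condition numbers above 1e3 warn.
* **Phasing** is removed by solving the cycles × cycles truncation of `P`
  per polony per channel. If the truncated system is ill-conditioned
  (condition number > 1e8) a ridge-regularized solve is used and the
  regularization strength logged. Correction is applied per channel.
* **Estimation** of `(p_lag, p_lead)` is a grid search (default 0–0.02 in
  steps of 5e-4) maximizing the mean clarity `(A+1)/(B+1)` of the corrected
  signal on a deterministic subsample of ≤100 polonies. `B` is taken as the
  second-highest *magnitude* so that over-deconvolution — which drives
  off-channel values negative — lowers the objective instead of being
  rewarded by clipping. Ties resolve to the smallest lag, then lead.
* **Normalization** maps, per channel per cycle, the 5th percentile of all
  values to 0 and the 95th percentile of on-state values (calls where the
  channel is the per-polony maximum) to 1. Percentiles are configurable;
  5/95 resists outlier polonies. Fewer than two distinct values in a
  channel/cycle is an error (a dead channel should fail loudly).
* **Calling** is argmax over channels; ties within 1e-8 resolve to the
  lowest channel index and are flagged.

On noiseless phased, cross-talked simulations the pipeline makes zero
miscalls (2,000 × 150 in the test suite), and the corrections reproduce the
pure one-hot signals to 1e-6 — these are the module's acceptance oracles.

## Quality model

Q = −10·log10(p) with p the probability the call is wrong, phred+33 encoded.
Four predictors per call: (1) maximum normalized intensity; (2) clarity
(A+1)/(B+1) computed on normalized intensities; (3) the run-level sum of
phasing and prephasing estimates; (4) cohort clarity — per cycle, the median
clarity of the 10% lowest-maximum-intensity polonies, shared by all calls of
the cycle. Predictors 1 and 2 use normalized values; predictor 4 is applied
at per-call granularity.

Training discretizes predictor space with equal-frequency bins (defaults
8 × 12 × 4 × 4 across predictors 1–4; duplicate quantile edges collapse, so
a constant predictor occupies one bin). Per-bin error rates use
`(errors+1)/(total+2)` smoothing, which keeps clean bins finite. Bins with
fewer than `min_bin_count` (default 200) observations are pooled with
adjacent bins along the clarity axis, and pooled rates are made monotone
non-increasing in clarity by weighted isotonic regression (PAVA) — clarity
is the strongest single predictor of correctness and the monotone constraint
removes sampling zig-zags without biasing well-populated bins. Q is rounded,
floored at 2 and capped at 45 (the chemistry's observed score range tops out
in the mid-40s). Assignment clamps out-of-range predictors to edge bins.

Truth labels come from the simulator (or any caller output paired with known
truth); no external recalibration tooling is involved. Calibration groups
calls by predicted Q and reports the mismatch-derived observed Q; zero-error
groups report the resolution bound −10·log10(1/(n+1)).

## Kinetics

Per-trace model: single exponential rise `baseline + amplitude(1−e^(−rate·t))`
or decay `baseline + amplitude·e^(−rate·t)`, direction auto-detected from the
trend. Fitting is unweighted nonlinear least squares with the rate
initialized by log-linearizing the early trace and 5 jittered starts
(×0.2…×5); the best-SSE converged start wins. Rate uncertainty is a seeded
residual-resampling bootstrap (default 200 resamples, percentile 95% CI,
widened to contain the point estimate). A flat trace returns rate 0 with a
wide CI rather than an error.

Rate-vs-concentration: `k_obs = k_pol·c/(K_d,app+c)`, optionally
inverse-variance weighted when per-rate standard errors are supplied;
parameters outside the sampled concentration range trigger a
weak-identifiability warning. The specificity constant `k_pol/K_d,app`
carries a first-order independent-error propagation, which the tests check
against a parametric bootstrap. Association rates regress per-trace
exponential rates through the origin against concentration
(`k_on = Σc·k / Σc²`). Dissociation: if the fitted decay over the observed
window is below the detection threshold — max(3 × residual SD, 1%) of the
starting signal — or its CI does not exclude the corresponding rate bound,
the result is "no measurable dissociation" with upper bound
`−ln(1−frac)/window`; the multivalent-substrate regime is `k_off = 0`,
the monovalent regime a fast decay (several-fold signal loss at the start of
imaging). Concentration units are carried as labels and never reinterpreted.

Simulators mirror the fit models exactly: quench-flow traces use
multiplicative Gaussian noise (errors scale with measured product),
real-time traces additive noise (detector-dominated); this conjugacy keeps
the noiseless-inversion tests exact.

## Error profiling

Homopolymer intervals come from a slopped BED (5 bases per side by default,
matching the naming convention of standard homopolymer stratification
files); the slop is trimmed arithmetically and, when a reference is
supplied, each trimmed interval is validated to be a single-base run.
Alignment records that are secondary, supplementary, unmapped or MAPQ 0 are
discarded. Reads are oriented 5′→3′ (for reverse-strand alignments the
genomic right side of the run is the *pre* segment) and split by the
reference projection of each aligned column into pre / overlapping / post
segments. Denominators count matched (CIGAR M/=/X) columns only: inserted
read bases, deletion columns, soft-clips, N-calls (read or reference) and
masked variant positions contribute to neither numerator nor denominator.
Reads with fewer than 5 aligned bases in either flank, or no overlap
columns, are discarded with a reason. The per-offset matrix indexes flank
columns by read-oriented offset, 0 being the first templated base after the
run's 3′ end and −1 the last base before it. Reads overlapping several runs
contribute once per run.

k-mer instances are windows of k consecutive reference positions fully
covered by matched, unmasked, non-N read bases with both read and reference
coordinates consecutive. Contexts are keyed in read orientation
(reverse-complemented for reverse-strand reads) by default; reference
orientation is available by flag — published analyses rarely state which
convention they use, so both are supported. Full counting is used at desk
scale; `sample_fraction` reproduces read-level subsampling with a seed.

The test suite validates all counts against an independent brute-force
per-base CIGAR walker that parses SAM text directly, and recovers injected
pre/post substitution rates within exact binomial intervals at 50,000 reads.

## Fixture generator

`generate_profiling_fixture` emulates the two study regimes: elevated
post-homopolymer substitution (post rate a multiple of the pre rate, the
behaviour of chemistries that lose phase over long runs) and the flat regime
(equal rates). It writes a random reference with exact-length homopolymer
runs (flanking bases forced to differ), a slopped BED, and coordinate-sorted
SAM v1.6 alignments tiled across the runs — primary MAPQ-60 records plus
deliberate secondary/supplementary/unmapped/MAPQ-0 decoys to exercise the
filters. Substitutions are drawn per base in read orientation at independent
pre/post rates; planted SNP positions carry a fixed alternate allele in
every read so masking can be verified exactly. What the fixture does *not*
model: indel errors, quality-correlated errors, coverage variation, mapping
ambiguity — so passing tests demonstrate correct counting and rate recovery,
not robustness to alignment artefacts.

## Problem sizes and numerical choices

Test and acceptance runs use 2,000 polonies × 150 cycles for the end-to-end
calling oracle, ~2.4M calls for calibration checks, 50,000 × 60-bp reads for
error-rate recovery, and 100 seeded replicates for kinetic parameter
recovery — sizes at which the statistical checks have comfortable power on a
single CPU. Optimizer tolerances are 1e-10 (traces); linear solves use LAPACK
via numpy with explicit condition-number guards as above. All randomness is
seeded; simulators are bit-reproducible given config + seed.

## Known limitations

* Phasing probabilities are run-level scalars; per-cycle drift is not
  modelled or estimated.
* The phasing deconvolution truncates the state matrix at the read length;
  with templates longer than the read, the final ~`2·p_lead·T` cycles carry
  small residual blur.
* The quality model is validated on self-consistent simulations; real-data
  calibration depends on alignment-based truth labels that the package
  accepts but does not generate (no aligner is bundled).
* No optical stage is simulated: the pipeline starts at extracted per-polony
  intensities and ends at FASTQ plus profiling tables.
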