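# Methods

This note documents the models, defaults and numerical choices behind
`oiswaves`, and what the synthetic study does and does not establish.

## The synthetic study

The generator emulates a MEK-inhibitor (MEKi) time course in senescent
MAPK-driven glioma cells: samples at 0 (control), 15, 60, 360 and 1440
minutes, with 3 biological replicates for RNA-seq and 4 for proteomics and
phosphoproteomics. All views index into one global sample table; views with
fewer replicates simply omit the extra columns while preserving ordering.

**Latent wave factors.** Each of `K_true = 4` factors corresponds to one
wave of MAPK pathway activity: direct substrate phosphorylation (15 min),
immediate-early genes (1 h), target genes (6 h), late remodelling (24 h). A
factor's trajectory is a sigmoidal pulse in log-time — switching on between
the preceding grid time and its wave's time point (log-midpoint centre,
sharpness 0.35 log-units) and off again before the next wave; the last wave
stays on. Trajectories are centred and symmetrically (Löwdin)
orthogonalised, so each factor peaks at its own wave, the factors are
exactly uncorrelated (matching the "largely uncorrelated" behaviour real
multi-omics factor models display on such designs), and the half-maximum
wave-assignment rule recovers the planted wave on the noiseless
trajectories.

**Loadings.** Each factor loads on a disjoint block of `n_signature = 30`
genes, represented across layers with a wave-specific pattern: the 15-min
wave on phospho (strong) and protein (weak) only, the 1-h wave mainly
transcriptional, the 6-h wave on all three layers, the 24-h wave on
protein/phospho only. Half of each block is *down* upon MEKi (i.e. up in
the senescent baseline — these genes constitute the true OIS_UP signature),
half the converse. The loading scale is `effect_size = 2.0`, tapered by 0.9
per factor rank so ranked factors differ in strength as they do in fitted
models.

**Noise model.** RNA counts are negative-binomial with dispersion 0.1 (a
typical bulk RNA-seq scale) around `exp(baseline + WZ + batch + ε)` with
log-normal jitter σ = 0.3; protein/phospho are Gaussian (σ = 0.5 / 0.6)
around `baseline + WZ + batch`. Batch offsets (two batches, σ ≈ 0.2–0.3)
are drawn per feature. Proteomic missingness is missing-not-at-random: the
dropout probability is a logistic function of latent abundance, calibrated
to the target rates (20% protein, 25% phospho). Setting a view's
`noise_sd` to 0 yields the deterministic noiseless limit (counts become the
rounded mean), which the tests exploit. Per-gene dispersions and noise
levels of real data are unknown; these defaults are free parameters of the
emulation, not estimates.

**Companion generators.** The knowledge generator gives every true
signature gene ≥ 3 concordant-direction senescence publications, plants one
PPI module per signature direction with internal density `p_in = 0.6`
against a `p_out = 0.05` background over a 300-gene universe, links
consecutive-wave effectors with > 3 literature references, and maps planted
kinases/TFs onto the phospho sites and 6-h genes. The survival generator
draws exponential event times under proportional hazards (baseline 0.02
events/month, true HR 0.25 for the signature-high half, exponential
censoring tuned to a 30% marginal rate) with a signature-score separation
of 3 sd between groups — a strong, clearly-split score axis of the kind the
emulated Kaplan–Meier analysis displays; at much smaller separations the
score threshold misassigns enough patients to dilute the scan below
Bonferroni significance. The drug generator produces paired
single-agent/MEKi-pre-treated 4PL curves (the MAPK-dependent senolytic's
IC50 shifts 3.62-fold under pre-treatment) and single-dose screen readouts
from class archetypes with replicate noise 0.05.

**What passing tests do not show.** The generator plants disjoint loading
blocks, exactly orthogonal trajectories and independent Gaussian/NB noise.
Real data have correlated factors, overlapping gene programmes, structured
(non-independent) noise and peptide-to-protein ambiguity, so recovery rates
measured here are upper bounds on real-data performance; the oracle and
calibration tests, by contrast, are data-independent statements about the
implementations themselves.

## Preprocessing

Size factors are DESeq-style median-of-ratios over features expressed in
every sample; counts are transformed as `log2(count/sf + 1)` — a
parameter-free, monotone stand-in for a dispersion-based variance
stabilising transform, adequate at this scale. Batch correction estimates
batch coefficients jointly with preserved condition terms by least squares
and subtracts only the batch part; confounded designs abort with the
aliased pair named. Proteomic views are median-centred per sample and
imputed in two stages: condition-specific normal draws where ≥ 50% of a
condition's replicates are observed, then a down-shifted tail
(mean − 1.8 sd, width 0.3 sd — common MNAR down-shift conventions) for the
rest; observed values are never altered. Differential statistics use
Welch's t per treated time point against the time-0 control (the upstream
analysis this emulates does not name its test); raw p-values are used for
filtering, with no multiplicity adjustment, mirroring the printed
criterion. Filters use strict inequalities, and the RNA layer additionally
requires p < 0.05 and protein-coding status; protein/phospho layers filter
on fold change only.

## Temporal factor model

The fit minimises

    sum_v ||Y_v − W_v Zᵀ||²_F + λ · sum_k ||w_k||² · sum_i (z_k(t_{i+1}) − z_k(t_i))²

over per-view weights and shared scores, samples sorted by time (the
penalty also ties same-time replicates together). The roughness of each
factor is weighted by its stacked loading norm because the bilinear
objective is otherwise degenerate under the W/Z scale split — an unweighted
penalty can be evaded by shrinking Z into W, which manifests as large-λ
fits failing to flatten. Both updates remain exact linear solves, so the
objective is non-increasing (asserted each iteration). λ defaults to 0.01
on z-scored data: large enough to break ties and share information across
replicates, small enough not to smear the weakest factor's switch time
(larger values visibly distorted late-wave trajectories during method
development). Convergence: relative objective change < 1e-6, at most 500
iterations (non-convergence returns a flagged model, not an exception).

Identifiability: the least-squares fit is rotation-invariant, so the
converged basis is rotated by **varimax** on the stacked loadings — the
deterministic counterpart of the sparsity/ARD priors that identify factors
in Bayesian multi-omics factor models, and exactly right when true loadings
concentrate on (near-)disjoint feature blocks. Scores are then scaled to
unit variance, factors ordered by total variance explained, and signs fixed
so the largest-|weight| entry per factor is positive. Initialisation is the
truncated SVD of the row-concatenated views (zero-filled for view-absent
samples); the fit is fully deterministic.

Variance decomposition reports per-view per-factor
`R²_vk = 1 − ||Y_v − w_vk z_kᵀ||² / ||Y_v||²` (clipped at 0; correlated
fitted factors can make the raw value marginally negative) and per-view
totals from the full reconstruction. Factor selection keeps factors whose
variance-explained z-score (across factors, within view) exceeds 0 in at
least one view; `select_model` scans K = 2..15 and keeps the largest K
whose factors all pass, mirroring how the emulated analysis settled on its
factor count. Feature selection thresholds weight z-scores within (view,
factor) at |z| > 1; z-scores are per view because that is the weight vector
the downstream filters operate on.

Wave assignment gives each factor the earliest time point at which its mean
score deviates from the time-0 baseline by at least half its maximum
deviation (ties: earliest). View exclusion uses the variance-explained
z-score (< 0 excludes the view from that factor's dissection) rather than a
fraction-of-best-view R² cutoff: with ~20 samples every view has a
per-factor R² noise floor of roughly 1/n_samples, so small ratio cutoffs
never fire even for views with no planted loading, while the z-score
criterion — the same machinery as factor selection — separates cleanly and
reproduces the expected behaviour (RNA excluded from the 15-min and 24-h
factors).

## Enrichment

ssGSEA ranks features per sample (descending; ties broken by feature name
for determinism) and sums the difference between the |value|^α-weighted
in-set ECDF and the count-based out-of-set ECDF, α = 0.75, no
normalisation — scores are in arbitrary units. Two-group GSEA ranks by
signal-to-noise, uses the weighted-KS enrichment score, a seeded gene-set
permutation null (sample permutation is underpowered at these group
sizes), NES = ES / mean(|same-sign null ES|), and signed-pool FDR q. KSEA
reports `z = (mean FC_substrates − mean FC_all)·√m / sd(FC_all)` with a
two-sided normal p, flagging kinases at p < 0.05 with ≥ 5 substrates. TFEA
is a one-sided hypergeometric test per TF with Benjamini–Hochberg
adjustment (the emulated platform does not disclose its correction);
direction is the majority sign of the overlapping query genes. Trajectory
clustering is whole-vector k-means (scikit-learn, seeded, 10 restarts).
The consistency filter keeps a signature when its end-vs-start change
agrees in sign across all measuring layers and exceeds 0.5 z-units in each
(the qualitative criterion it operationalises names no threshold).

## Knowledge network

The senescence filter keeps genes with ≥ 3 total supporting publications
and assigns the direction with more support; ties are flagged ambiguous and
excluded by default (a flag includes them under both directions). Edges
instead require **strictly more than three** references — the two
thresholds differ deliberately, following the wording of the procedures
they implement. Signature assembly intersects the wave-annotated effectors
(factor features with direction = weight sign × trajectory direction;
TFEA TFs; inferred kinases) with the filtered senescence table; effectors
down upon MEKi form OIS_UP. Connectivity statistics are computed on the
induced PPI subgraph over mapped genes (unmapped genes count toward
`n_listed` only); clustering coefficients are 0 for degree < 2. The null
draws B = 100 random same-size lists uniformly (no degree matching, per the
emulated procedure) from the filtered senescence universe; ranks share the
best position on ties and empirical p uses the add-one estimator, so p is
never 0.

## Survival and drug response

Kaplan–Meier and the two-group log-rank statistic (hypergeometric variance,
χ² with 1 df) are implemented directly in numpy — the cutoff scan evaluates
thousands of log-rank tests — and are cross-checked against lifelines in
the tests. Scan candidates are every distinct observed score value leaving
at least 10% of patients in each arm; the best raw p is multiplied by the
number of candidates (Bonferroni; the granularity of the platform this
emulates is unpublished, so these definitions are declared stand-ins). Cox
models delegate to statsmodels' partial-likelihood implementation with
Breslow tie handling and Wald intervals; categorical covariates are one-hot
encoded against the first level, constant predictors report HR 1, and
suspected separation flags the fit as non-converged.

4PL fits use least squares with multi-start over a log-spaced IC50 grid and
two hill-slope starts; curves with negative fitted slope are re-oriented so
`top` is always the low-dose asymptote. Fold changes are reported as
`IC50_b / IC50_a` with orientation recorded, and the mean fold across
plates is the arithmetic mean of per-plate ratios (the averaging convention
is stated because alternatives — ratio of means, geometric mean — differ).
The single-dose classifier uses δ = 0.2 around the control level: drugs
inert alone are "ineffective" regardless of the pre-treated readout, making
the rule a total partition of the (A, T) plane; the boundary between
"marginal" and "effective" is qualitative in the emulated screen, so δ is
exposed in the configuration.

## Pipeline, seeds and problem sizes

A nested-dict configuration (YAML-serialisable, unknown keys rejected)
carries one global seed fanned out to per-stage seeds through a SHA-256
hash, keeping every artefact independently reproducible; identical config +
seed reproduces every output byte for byte. The default study size is
2000/800/600 features (RNA/protein/phospho) with 30-gene signature blocks;
tests and the acceptance script run the full pipeline at this size or a
reduced 500/250/180 variant, and Monte-Carlo checks use 20–500 replicates
per quantity — sizes chosen so the whole suite completes in a few minutes
on one CPU while leaving the measured rates well away from their thresholds.

## Known limitations

The factor model is a deterministic penalised least-squares method, not a
posterior over factors: it reports no uncertainties and relies on varimax
rather than priors for identifiability. The VST stand-in ignores the
mean-dispersion trend. The weight z-score rule (|z| > 1) has limited
precision at 20 samples — filtered noise features routinely pass it, which
is precisely why the downstream senescence-evidence intersection is
load-bearing. Peptide-to-protein roll-up, GP kernel learning, degree-
matched nulls and time-varying covariates are out of scope.
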