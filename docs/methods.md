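# Methods

## The measurement model

A raw spectrometer acquisition of liver autofluorescence is modelled as

    raw(λ) = clean(λ) · R(λ) + D(λ) + ε(λ)

where `R` is the instrument's relative spectral response (unitless, > 0),
`D` the dark spectrum (counts) and `ε` zero-mean Gaussian noise. The clean
tissue emission is a non-negative mixture of fluorophore bands,

    clean(λ) = Σ_f  A_f(g) · m_f(s) · e_f(λ_exc) · b_f(λ),

with `A_f(g)` the mean amplitude of fluorophore `f` in dietary group `g`
(arbitrary intensity units), `m_f(s)` a per-subject lognormal multiplier,
`e_f(λ_exc)` the excitation efficiency at the source wavelength, and `b_f` a
unit-peak Gaussian band shape, optionally with a second Gaussian lobe (the
porphyrin emission at 620 nm carries a secondary lobe at 680 nm with mixture
weight 0.30).

Band shapes are Gaussian because only peak positions are physically
constrained; a one- or two-lobe Gaussian mixture is the simplest shape that
reproduces the qualitative spectra: a blue NAD(P)H/vitamin-A band that
dominates under 330/365 nm excitation, a flavin peak at 520 nm, lipopigment
emission at 540 nm, and the lipofuscin/porphyrin band at 620 nm that grows
with disease stage and dominates under 405/415 nm excitation where NAD(P)H
and vitamin A are not excited at all (their efficiencies are exactly 0
there, and the porphyrin efficiency rises monotonically with excitation
wavelength).

## Stage profiles and their defaults

The three dietary groups are the control (MCC) and the
methionine–choline-deficient diet fed for two (MCD2w) or eight (MCD8w)
weeks. Default per-group parameters:

| parameter | MCC | MCD2w | MCD8w | meaning |
|---|---|---|---|---|
| NAD(P)H / vitamin A amplitude | 100 / 40 | 100 / 40 | 100 / 40 | metabolic background, held flat |
| flavins | 30 | 48 | 65 | redox cofactors, grow with fat |
| lipopigments | 18 | 45 | 85 | lipid-oxidation products |
| lipofuscin | 14 | 45 | 110 | dominant 620-nm band |
| porphyrins | 10 | 32 | 75 | 620/680-nm bands |
| subject CV | 0.15 | 0.25 | 0.35 | between-mouse heterogeneity |
| relative noise scale | 0.020 | 0.025 | 0.030 | sd = scale · (floor + signal) |
| lipid mean ± sd (% area) | 0.16 ± 0.35 | 6.73 ± 5.78 | 10.99 ± 6.83 | morphometric moments |

The lipid moments are the study's morphometric values; the amplitudes are
not published anywhere, so they are a design choice made once: lipid-
associated bands increase strictly with stage (by factors ~2–3 per step,
comfortably above the subject CV) so that the three documented qualitative
trends emerge from the mixture rather than being painted on — intensity
above 550 nm grows with diet time, the emission envelope red-shifts as the
620-nm band overtakes the blue band, and the between-spectrum spread grows
with stage. The NAD(P)H and vitamin-A amplitudes are held constant across
stages (rather than decreasing) so that the per-wavelength standard
deviation is monotone in stage at every grid point; the red-shift still
emerges because the other bands grow around them.

Subject effects use two unit-mean lognormal multipliers per mouse, one
shared by the lipid-associated bands (lipopigments, lipofuscin, porphyrins)
and driven by a latent severity factor `z ~ N(0,1)`, and an independent one
for the remaining bands; `σ_ln = sqrt(ln(1+CV²))`. Measurement noise is
Gaussian with sd proportional to the local signal plus a signal-equivalent
floor (default 100 counts), matching error bars that grow with intensity.

Lipid content is drawn from a normal truncated at zero (negative area is
impossible) via a Gaussian copula on the severity factor: the Gaussian score
`ρ z + sqrt(1−ρ²) ε` is mapped through the truncated-normal quantile
function, so the marginal is exactly the stated truncated normal while the
rank correlation with the lipid-band amplitudes is positive by construction.
The copula correlation ρ defaults to 0.8; ρ = 0 decouples lipid from
fluorescence for null testing. Note the truncated distribution's mean
slightly exceeds the location parameter (e.g. ≈ 0.31 when the parameters are
0.16 ± 0.35); tests compare simulated draws against the truncated
distribution, not the raw moments.

The default study design is 9/6/7 subjects per group measured at five
excitation wavelengths with the published per-cell spectra counts (1870
total; the MCD2w group has only three subjects at 415 nm). Spectra are
assigned to a group's subjects round-robin. The wavelength grid is
420–810 nm at the spectrometer's 0.77-nm resolution. The point counts
printed for each measured interval are treated as descriptive; the package
derives counts from its own grid.

What the generator does **not** emulate: photon transport
(absorption/scattering, probe-pressure effects), wavelength-dependent
band-shape changes within a fluorophore, within-liver spatial correlation
beyond the subject effect, and day/instrument drift. Passing tests therefore
demonstrate that the analysis chain recovers structure of this generative
form at the study's sample sizes — not that real livers are this easy.

## Preprocessing

Order: dark subtraction → sensitivity correction → boxcar smoothing → range
restriction → normalization; every output spectrum's `processing_log`
records the applied steps in order. Decisions, with rationale:

- Negative post-dark intensities are clipped to 0 (counts are physical).
- The response is estimated as measured-lamp / reference-lamp and divided
  out; it is interpolated onto the spectrum grid and must be positive.
- The boxcar width is not documented for the original acquisition software;
  default 5 points, configurable, odd only. Edge windows truncate rather
  than shrink the grid.
- The normalization wavelength (600 nm by default, 450 nm available for
  plotting) is resolved to the nearest grid point, which then equals exactly
  1; the operation is idempotent.
- Retained emission ranges per excitation: 330 → 435.5–721.2 nm,
  365 → 435.5–722, 385 → 440.9–741.6, 405 → 490.9–795.8, 415 → 500.2–750.7
  (closed intervals).

## Spectral AUC

Trapezoidal integration over fixed per-excitation intervals (330/365 →
425–800 nm, 385 → 440–800, 405 → 490–800, 415 → 500–800). These intervals
exceed the measured ranges; the integral is taken over the intersection with
the grid and a warning is emitted — within one excitation the comparison is
unaffected because every spectrum shares the grid. The AUC is computed on
the sensitivity-corrected, range-restricted spectra **before** the 600-nm
normalization: the 600-nm reference intensity itself grows with stage, so
normalizing first would divide out precisely the effect the statistic
measures; the classifier, by contrast, consumes the normalized spectra,
where shape rather than brightness carries the signal (brightness depends on
irradiation geometry and source power).

Group comparison is one-way ANOVA with Tukey HSD (Tukey–Kramer for the
unequal group sizes; with two groups the adjusted p equals the pooled
t-test p). The lipid correlation uses the per-subject mean AUC (several
spectra per mouse) against that mouse's lipid %, Spearman with average ranks
and the t approximation on n−2 df. Degenerate inputs: zero within-group
variance with unequal means reports p = 0; constant inputs to the rank
correlation raise.

## Classification chain

PCA is an SVD of the mean-centered spectra matrix; six components are kept
by default with a warning if they explain < 90% of the variance. Automatic
scree-elbow selection is deliberately not implemented (ill-defined); the
component count is an explicit, documented choice. Loading signs are fixed
(largest-magnitude entry positive) for determinism. PCA is fit once on the
full data set and reused inside LOOCV folds — the cross-validation retrains
only the classifier; refitting PCA per fold is available via
`pca_fit`+`loocv` composition for sensitivity analysis but is not the
default path.

Box's M uses the standard χ² approximation with the usual small-sample
correction factor; p < α recommends QDA. On the synthetic spectra, as on the
real ones, homogeneity is rejected decisively, so the quadratic variant is
the production path (no linear-DA production path is provided).

QDA estimates class means and sample covariances (n−1 denominator);
priors default to empirical class frequencies because the groups are
unequal ("uniform" is available). Posteriors are the softmax of the log
discriminants, which equals Bayes' rule with Gaussian densities; exact
argmax ties break to the lexicographically first label and are logged. A
ridge of 1e−10·trace is added only on exact singularity, with a logged
warning. LOOCV refits the QDA per left-out observation; every group must
retain more observations than dimensions.

Confusion matrices are reported as paired in-sample / cross-validated
counts. The total error rate is reported under **both** circulating
definitions — the pooled share of misclassifications, and the unweighted
mean of the per-group error rates — because published summaries mix the two
(the embedded reference tables themselves match the pooled definition at
some excitations and the unweighted one at others); report renderers label
each.

The canonical plane solves the generalized eigenproblem `B a = λ W a`
(between/within scatter), keeps the two leading axes (three groups give
exactly two canonical variables), scales each axis to unit pooled
within-class variance, and rasterizes decision boundaries by classifying
every node of a 400 × 400 grid spanning the observed canonical scores plus a
10% margin with a QDA refit on the 2-D scores.

## ROC and Youden

Scores are the per-class posteriors with that class positive and the other
two pooled negative. Thresholds are the distinct observed scores plus a +∞
sentinel pinning (0,0); tied scores collapse into one step, making the
trapezoidal AUC equal the Mann–Whitney U fraction with ties counted half.
The Youden optimum maximizes sensitivity + specificity − 1; ties resolve to
the lowest (most sensitive) threshold, consistent with giving equal weight
to both error types. By default ROC scores come from the in-sample
classification model, matching how the reference report pairs its tables; a
flag switches to LOOCV posteriors for an honest out-of-sample evaluation.
Per-excitation reports carry the three one-vs-rest curves and their
arithmetic averages. No confidence intervals on AUC are provided.

## Determinism and problem sizes

All randomness flows from one `numpy` `default_rng(seed)`; identical seed
and configuration give byte-identical CSV output, and a run's manifest
records a SHA-256 checksum per artifact. Each excitation wavelength is
analyzed independently; spectra are never pooled across excitations into one
classifier. The test suite runs the full 1870-spectrum default study once
per session (a few seconds) and uses reduced designs (e.g. 12 spectra per
group per excitation) for pipeline plumbing tests; distributional generator
properties (monotone means and spreads) are asserted on a 300-spectra-per-
group ensemble at 405 nm, where subject-level lognormal spread is well
sampled. Box's M calibration uses 500 replicates at n=100 per group in
dimension 3, with the rejection rate required to sit within three binomial
standard errors of the nominal 5%.

## Known limitations

- The simulator's separability at the default amplitudes makes 365–415 nm
  classification nearly perfect; the real study's residual errors stem from
  tissue physics the generator does not model, so synthetic error rates
  should be read as qualitative, not quantitative, mirrors (the 330-nm
  condition, where band overlap is worst, does reproduce the "worst
  wavelength" behavior).
- One-vs-rest ROC on in-sample posteriors is optimistic by construction;
  use `roc_score_source="loocv"` for honest operating points.
- Box's M is known to be sensitive to non-normality; it is used here, as in
  the field, purely as a gate for the LDA/QDA choice.
- The canonical-plane renderer supports exactly three groups.
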