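# Methods

## Posture-space model

A motion-capture trial of M markers at sample rate f_s is treated as a
trajectory in 3M-dimensional posture space.  Subject-specific anthropometry
is removed before pooling: each subject's frames are centered on their own
mean posture, divided by stature (meters), and each marker's three
coordinates are multiplied by the relative mass of the segment the marker
represents.  Weighting is linear in the mass fraction w_i (the alternative
√w_i kinetic-energy normalization is not used).  Mass fractions follow the
standard anthropometric table (head+neck 0.081, trunk 0.497, thigh 0.100,
shank 0.0465, foot 0.0145, upper arm 0.028, forearm+hand 0.022 per side),
each segment's fraction split equally among its markers and renormalized
over the marker set actually analyzed, so weights always sum to 1.

Left-foot-front tandem trials are mirrored (y negated, L/R labels swapped)
into a common right-foot-front convention before analysis.  Unpaired,
non-bilaterally-symmetric markers (the `BACK` label in the canonical set)
are dropped.  Marker order after selection is alphabetical, which is what
makes pooled matrices column-compatible across subjects.

Because every subject is centered individually, the pooled matrix has
column means ~1e-16 and is **not** re-centered before the decomposition;
the PCA is computed by singular value decomposition of the pooled matrix,
with the population (1/N) variance convention and a deterministic sign
convention (the largest-magnitude coefficient of each eigenvector is made
positive).  rSTD percentages are computed over all nonzero components; the
number of components carried into the statistics (default 9) is recorded
with the results.

## Kinematics and control variables

Score series are lowpass filtered with a 5th-order Butterworth at 7 Hz,
applied forward-backward (zero phase).  Velocities and accelerations come
from applying an order-50 linear-phase FIR differentiator twice (pass
5 Hz, stop 7 Hz at 240 Hz), with the 25-sample group delay compensated so
derivatives are time-aligned.  The differentiator is a weighted
least-squares type III (antisymmetric, odd length) design: with these
narrow band edges an equiripple design leaves ~2% passband amplitude
ripple, whereas the least-squares design with a 1000:1 passband weight
achieves <0.1% passband error at the cost of stopband attenuation that the
preceding Butterworth already provides.  The first and last 0.5 s of each
trial are discarded to remove filter transients; the analysis window
length is always reported next to N_k, since N_k scales with duration.

A zero crossing is a sign change between consecutive non-zero samples,
located by linear interpolation; runs of exact zeros collapse to a single
crossing at the run center when flanked by opposite signs (this prevents
double-counting in noise-free synthetic signals).  σ_k is the sample
(n−1) standard deviation of inter-crossing intervals and requires at least
three crossings; otherwise it is NaN with a warning.

## Cross-validation of components

Leave-one-subject-out: each fold refits the pooled PCA without one subject
and the angle between the fold's PC_k and the full-data PC_k (matched by
eigenvalue rank, sign-invariant) is recorded.  A component is robust when
its worst-case angle over all folds is at most 15°.  Matching by rank
rather than by similarity is deliberate: eigenvalue degeneracy then
surfaces as large angles, which is exactly what the diagnostic should
flag.  The fold-vs-fold alternative reference was considered and rejected
because the full-data basis is the one actually interpreted.

## Group statistics

Each endpoint (rSTD_k, N_k, σ_k per component) enters a 2x2
between-subjects ANOVA (age group x gender) with Type III sums of squares
and sum-to-zero effect coding — the convention of mainstream GLM software
for unbalanced factorials such as the 17 F / 8 M per age group design,
where df2 = n − 4.  Partial η² = SS_effect/(SS_effect + SS_error);
observed power is computed from the noncentral F distribution with
noncentrality λ = F·df1 at α = 0.05.  Normality is checked per cell with
the Lilliefors-corrected Kolmogorov-Smirnov test (the appropriate form
when mean and SD are estimated) and Shapiro-Wilk; variance homogeneity
with Levene's test (center = mean).  When an interaction is significant,
the post-hoc family is the four simple-effects comparisons (age within
each gender, gender within each age group), tested on the pooled error
term and Sidak-adjusted with m = 4.  Percent changes are reported with
the younger (resp. male) marginal mean as the 100% reference.  Missing
endpoint values are excluded casewise per variable x component.  No
correction is applied across the variable x component families.

## Synthetic cohorts

The generator emulates multi-subject tandem-stance recordings as a mean
standing posture plus K orthonormal movement modes (random directions in
the weighted-normalized space of the selected markers) driven by
quasi-sinusoidal score series, inverted through the normalization chain
(un-weight, un-normalize by stature, add the template posture scaled to
the subject's height) and degraded with i.i.d. Gaussian measurement noise
in lab space and optional occlusion gap runs (geometric lengths, mean
0.25 s).  Score series are s(t) = A·sin(φ(t)) with the phase advancing π
per half-cycle whose duration is drawn from a mean-preserving log-normal
with mean 1/(2f) and relative SD equal to the *jitter* parameter — chosen
because it gives direct, independent control of the σ_k endpoint, with the
analytic expectation E[N] = 2·f·T for the acceleration crossings.

Defaults represent the study conditions: 240 Hz, 80 s trials, 37 markers,
5 modes with strictly decreasing amplitudes (0.0040…0.00052
normalized-posture units, ratios ≥ 1.5 so the eigenvalue order is
identifiable), dominant frequencies 1.2–2.8 Hz (signal power in the 1–3 Hz
band), baseline jitter 0.15, measurement noise SD 0.5 mm, heights uniform
on [1.55, 1.90] m.  Between-subject individuality is modeled as a 3% CV on
mode frequency and 10% on amplitude.  The default planted aging effect
gives the older group a 10% lower control frequency and 15% higher jitter
on mode 2, mirroring the direction and order of magnitude of reported
age differences in mediolateral sway control; all effects are configurable
per (group, mode) as multiplicative modifiers.

What the generator does *not* model: musculoskeletal dynamics or any
feedback controller (modes are geometric, not mechanical), soft-tissue
artifact, non-stationarity, marker relabeling errors, or amplitude-
dependent noise.  Passing recovery tests therefore demonstrates that the
pipeline is correct and sensitive under a low-rank oscillatory model, not
that real cohorts will show comparable effect sizes.

## Numerical choices and edge cases

- Gap filling: iterative low-rank imputation (linear-interpolation
  initialization; per-iteration column centering, rank-r SVD
  reconstruction of missing entries; default rank 10, tol 1e-8 m, 100
  iterations).  Observed samples are never altered; a marker with no
  observations at all is unrecoverable and raises.
- Eigen-rank cutoff: components with variance below 1e-14 x the leading
  eigenvalue are treated as numerically zero; requesting more components
  than the matrix supports retains the nonzero ones with a warning.
- Static (all-zero) input: PCA yields no components; rSTD is NaN with a
  warning rather than a division error.
- Scaled-down problem sizes in tests and the acceptance script (20 s
  trials, reduced marker counts for the Monte-Carlo statistics) were
  selected so recovery and power behavior match the full-size conditions
  while simulations stay cheap; the sizes used are always stated in the
  respective outputs.

## Benchmark identifiability

For a noise-free rank-K cohort the SVD recovers the planted signal
subspace to machine precision; the residual angle between an eigenvector
and "its" planted mode is a rotation *within* that subspace, determined
entirely by the sample covariance of the generated score series (the test
suite verifies this equivalence directly against the score-covariance
oracle).  Sample cross-correlation between two modes grows with spectral
overlap, so the eigenvector-recovery benchmark cohort uses jitter 0.05:
mode bandwidths (~f x jitter ≈ 0.1 Hz) then stay well below the 0.3 Hz
minimum frequency separation and the sampling rotation stays within the
1° recovery tolerance.  Statistics and power studies keep the realistic
0.15 baseline jitter, where eigenvector rotation of a degree or two is
immaterial because the crossing statistics depend on the dominant
frequency, not the exact basis orientation.

## Known limitations

- C3D files are not read directly; recordings must be converted to the
  package's CSV dialect.
- PCA is linear; a single real postural strategy spread across several
  components will dilute the per-component endpoints.
- N_k and σ_k remain filter-dependent (they count features of a doubly
  differentiated signal); the `filter_sensitivity_sweep` exists precisely
  to check that group conclusions survive reasonable filter choices.
- The post-hoc family definition (m = 4 simple effects) is one defensible
  convention; software packages differ here.
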