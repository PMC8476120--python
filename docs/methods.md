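# Methods

`collapse-kinetics` analyses single-molecule fluorescence kymographs of
GFP-tagged myosin-S1 heads binding to and releasing from regulated thin
filaments (actin + tropomyosin ± troponin) held as "tightropes" between
beads. Under sub-maximal calcium and low ATP the filament is metastably
active: heads bind in clusters ("active regions") that grow, shrink and —
the phenomenon of interest — sometimes vanish in a single frame at a far
higher probability than independent head release predicts ("catastrophic
collapse"). The package provides the full chain from image to kinetics, plus
a generative simulator so that every stage is testable without raw movies.

## The stochastic cluster model

Time is discrete (frame interval `t = 0.3 s`, 3.3 frames/s). A cluster of
`n` bound heads evolves each frame in a fixed event order:

1. **Concerted collapse** with probability `pc(n)`: all `n` heads release at
   once. `pc` is a free user-supplied table — no functional form is imposed,
   because the measured collapse curve is roughly flat in `n` and a
   mechanistic law would be an unsupported extrapolation. Collapse and
   stochastic detachment are mutually exclusive within one frame, matching
   the dichotomy of stepwise vs contemporaneous release.
2. **Independent detachment**: each head leaves with probability
   `Pd = 1 − exp(−k_T·[ATP]·t)`, set by ATP binding to the bound head
   (ADP release is far faster at these ATP levels and is neglected). At
   `k_T = 1.9 µM⁻¹s⁻¹`, `[ATP] = 0.1 µM`: rate `0.19 s⁻¹`, `Pd = 0.0554`
   per frame. A region whose occupancy hits zero closes.
3. **Attachment**: with probability `Pa` one head joins at the left or right
   cluster edge with equal probability (`Pa` is per region per frame; the
   paperless alternative — per exposed site — is not identifiable from the
   data this pipeline emulates). Attachment is blocked at the simulation cap
   `n_max_sim` (default 12).
4. **Nucleation**: a new one-head region appears at a uniform random
   position with per-frame probability `p_nuc`, rejected if within
   `min_region_separation_px` (default 12 px) of an existing region or
   within `edge_margin_px` (default 6 px) of the filament ends. Both
   constraints mirror the data: active regions are microns apart, and the
   bead-adjacent stretches of a tightrope are not analysable (a peak
   centred on the image border cannot be detected as a local maximum).

The exact one-frame law of this model (including the attach–detach
coupling: a head can only be *seen* joining if none of the `i` bound heads
left in the same frame) is re-derived independently in the test suite and
used as the simulator's oracle.

### Rendering

Each bound head contributes a pixel-integrated 1-D Gaussian (PSF σ 150 nm,
pixel 126.4 nm) with an integrated intensity drawn once at attachment from
`Normal(unit, cv·unit)` — a fixed fluorophore brightness, not per-frame
scintillation. A constant background and i.i.d. Gaussian read noise are
added and the image clipped at zero. Defaults: unit intensity 200 counts,
CV 10%, background 100, noise SD 6 (single-head peak amplitude ≈ 11× the
noise SD). Head spacing within a cluster is one actin pseudo-repeat
(38.5 nm), sub-pixel at this magnification, so rendering is insensitive to
it. Deliberately not modelled: photobleaching, Poisson shot noise, filament
curvature, 2-D movies, mechanics. Passing tests therefore demonstrate
correctness of the analysis chain under Gaussian noise and stable
brightness — not robustness to bleaching or strongly non-Gaussian cameras.

## Image analysis chain

**Background subtraction.** Classic grey-scale rolling ball (radius 50 px)
applied to the 2-D kymograph, negative residuals clipped to zero. The
sliding-paraboloid variant is not used. The ball rides under the noise
floor, leaving a small positive residual baseline; detection accounts for
it (below) and each local fit carries a constant baseline term.

**Peak fitting.** Per frame, candidates are local maxima above a threshold
(default: image median + 3× the robust noise SD, 1.4826×MAD) separated by
≥ 6 px. Candidates are grouped when closer than 8 px and each group is
fitted by nonlinear least squares to a sum of Gaussians plus a constant,
seeded from the candidates, with σ bounded to [0.5, 4] px around the PSF.
Model order is reduced greedily while the BIC improves (the number of
Gaussians is thus chosen autonomously and reproducibly); fitted peaks whose
amplitude falls below the detection level are dropped; non-converged groups
are returned flagged rather than silently discarded. The photometric
quantity carried forward is the fitted integral `A·σ·√(2π)` — clusters
broaden slightly as they spread, so the integral, not the amplitude, is
proportional to occupancy.

**Calibration.** Per kymograph (illumination varies between tightropes),
the peak integrals are histogrammed (Freedman–Diaconis, refined to ≥ 10
bins per component when the rule is too coarse for multimodal data) and
fitted by least squares to a sum of Gaussians with increasing means. The
class means regress linearly on the count index (free intercept; R² is
reported). Each class claims the band `mean ± 2·SD`; overlapping bands are
resolved at the mid-point between means (nearest-mean rule), which makes
assignment monotone in intensity by construction; intensities outside all
bands are UNASSIGNED and treated as missing, never as zero. Kymographs
without enough populated classes fall back to a dataset-pooled calibration.

**Tracking.** A greedy nearest-neighbour linker (ties: smaller distance,
then leftmost) with `max_link_distance` 4 px and `max_gap_frames` 1 —
adequate because regions are sparse and nearly stationary; a full LAP
solver would add nothing here. A track that disappears before the movie
ends contributes a terminal transition to count 0 at the first peak-free
frame (complete detachment is the phenomenon of interest); tracks reaching
the final frame are right-censored. Tracks with fewer than two observed
frames contribute no transitions.

## Transition matrices and kinetics

Frame pairs `(i → j)` are tallied per kymograph with both sizes observed
and ≤ `n_max = 6` (larger clusters are too rare to analyse and are
discarded). Two normalisations are kept throughout:

- **conditional** — probability of the move *given a change*; zero
  diagonal, observed rows sum to 1. This is the published-table layout.
- **per_frame** — counts divided by all observed pairs starting at `i`,
  including `i → i` dwells. This is the scale of the kinetic model
  (`Pd`, `Pa` are per-frame probabilities).

The distinction matters more than it looks. The conditional superdiagonal
is `Pa(1−Pd)^i / P(change | i)`, which is far from `Pa` when changes are
rare; a conditional-matrix superdiagonal mean can therefore only be read as
an attachment probability for data in which collapse dominates the
denominator. `estimate_pa(m)` implements the plain superdiagonal mean (the
estimator used for published conditional tables); `estimate_pa(m, pd=...)`
divides each per-frame superdiagonal entry by its survival factor
`(1−Pd)^i` and is the unbiased estimator used in all parameter-recovery
analyses here.

The **predicted matrix** takes `p[i][j] = Pa^(j−i)` above the diagonal and
`p[i][j] = C(i, i−j)·Pd^(i−j)` below it. The detachment block omits the
`(1−Pd)^j` survival factor of the heads that stay; it is implemented
verbatim as the default for fidelity, with `full_binomial=True` supplying
the corrected law. Both unnormalised (per-frame scale) and row-normalised
variants are emitted, since the published predicted table's normalisation
is ambiguous.

The **collapse curve** is the first column; per-cell SEMs are computed
across the kymographs whose rows carry observations. Collapse probabilities
invert to effective detachment rate constants via
`k = −ln(1 − p^(1/i)) / t`, the algebraic inverse of `p = (1−e^{−kt})^i`.

**Statistical comparisons.** Predicted first-column probabilities span
eight orders of magnitude (`Pd^i` down to ~3×10⁻⁸), so "within 3 standard
errors" is asserted literally only where expected counts are large; where
they are small the package uses an exact two-sided binomial test at
α = 10⁻³ (the same nominal level as 3σ) — empirical SEMs degenerate to zero
when every kymograph observes zero events, and the normal approximation is
meaningless at expected counts ≪ 1. Rows with fewer than 50 observed frame
pairs are reported but excluded from curve comparisons (sampling noise
dominates), mirroring the sample-size-based exclusion of clusters above
six. The collapse-excess flag considers sizes ≥ 2 only: `pc(1) = 0` by
construction, so the size-1 first column is ordinary single-head
detachment.

## Reversible-jump mixture analysis

An independent route from intensities to counts, used to cross-check the
histogram calibration for bias. Univariate normal mixture with unknown k:
`k ~ U{1..k_max}`, weights `Dirichlet(δ)`, means `Normal(ξ, κ⁻¹)` kept
strictly increasing (the identifiability constraint standing in for the
linear-intensity prior), precisions `Gamma(α, β)` with `β ~ Gamma(g, h)`.
Defaults `α = 2, g = 0.2, h = 10/R², ξ = mid-range, κ = 1/R², δ = 1`, R
the data range — a weakly informative hierarchy. Each sweep: Gibbs updates
(weights, means with ordering rejection, variances, allocations, β), then a
split/combine move and a birth/death move for empty components with the
standard dimension-matching acceptance ratios. Four chains and 50% burn-in
by default. Summaries condition on a chosen k; the convergence diagnostic
is a PSRF-style between/within ratio over conditional component means.
With the RJ moves disabled the sampler is a plain Gibbs sampler, validated
in the tests against a 2-D quadrature evaluation of the exact
single-component posterior (β integrated out analytically). A post-hoc
linearity check regresses the non-background class means on the count
index. Count thresholds are mid-points between successive means; a
reference nine-component posterior summary is bundled for threshold work
without re-running the sampler.

## Problem sizes and reproducibility

Default synthetic study conditions: 20 kymographs of 396 frames (2 min at
3.3 fps), 128 px filaments, nucleation 0.15/frame — ≈ 350 change
transitions per kymograph, ≈ 7,000 per dataset, matching the scale of the
published tables. Simulator-only analyses use longer runs (~10⁵ frame
pairs). RJMCMC validation uses n = 1000 points, 4 × 4000 sweeps. Every
stochastic stage takes an explicit seed; `generate_dataset` and
`run_chains` derive per-replicate seeds from a master seed, and a pipeline
run embeds a SHA-256 hash of its full configuration in the report, so any
run is reproducible from its YAML config alone.

## Known limitations

- Sub-resolution positions of individual heads within a cluster are not
  (and cannot be) recovered; occupancy is photometric.
- Heavily overlapping regions (closer than ~6 px) would be merged by
  detection; the linker does not model merge/split events.
- The per-kymograph mixture calibration needs each count class populated;
  rare high classes borrow statistical strength only through the pooled
  fallback.
- Single heads below the detection threshold are lost, as acknowledged for
  the original analysis; no correction is applied.
- The collapse channel `pc(n)` is descriptive, not mechanistic.
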