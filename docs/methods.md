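# Methods

## Scope

`hepacomet` models and analyzes the trapping-enhanced alkaline CometChip:
comets arrayed on a ~240 µm microwell lattice, scored as % tail DNA, with
repair-synthesis inhibition (HU/AraC) used to convert short-lived
nucleotide-excision-repair (NER) intermediates at bulky lesions into
comet-visible single-strand breaks (SSBs). The package covers the
mechanistic forward model, synthetic image generation with exact ground
truth, image quantification, gamma-ray SSB calibration, and screen
statistics. Wet-lab protocol steps (lysis, electrophoresis, dosimetry,
CYP biochemistry) are out of scope; metabolism is represented only by
per-enzyme activity scalars.

## Damage and trapping model

**Kinetics.** Each lesion class follows linear two-compartment kinetics
(lesion → incision → SSB → resolution):

    dB/dt = −k_inc·B,   dS/dt = k_inc·B − k_res_eff·S

with closed-form solution used throughout and cross-checked against
numerical ODE integration in the tests. Effective rates:

| parameter | default | units | meaning |
|---|---|---|---|
| `k_inc` | 3.0 | /h | NER incision rate; 0 for XPG/XPA-null. Sets the ~1 h trapping plateau (95% incised by 1 h). |
| `k_res` | 7.804 | /h | SSB resolution rate (solved, see below) |
| `f_inhib` | 0.01 | – | residual resolution under HU/AraC |
| `ber_k_inc` | 12.0 | /h | BER lesion → SSB conversion (fast) |
| `ber_k_res` | 0.5 | /h | intrinsic BER-gap resolution (slow → comet-visible without trapping) |
| `baseline_ssb` | 2000 | SSB/cell | burden corresponding to the basal 10% tail |
| `spont_trap_ssb` | 300 | SSB/cell | trapped spontaneous-repair intermediates (HU/AraC alone ⇒ +0.3 points, deliberately sub-significance) |
| `n₀` | 60 000 | SSB/cell | e-folding scale of the tail transform |
| `x₀` | 5000 | crosslinks/cell | e-folding of crosslink migration suppression |

The XPG-E791A separation-of-function mutant incises normally but cannot
complete repair: `k_res_eff = 0` irrespective of inhibitors, so it
phenocopies chemical trapping. Directly deposited SSBs (gamma: 1000
SSB/Gy; treated as total comet-visible breaks, alkali-labile sites not
distinguished) decay at the same resolution rate; gamma calibrations are
scored at repair time zero (irradiation on ice).

**Tail transform.** `%T(s) = 75 − 65·exp(−s/n₀)` on the induced
(above-baseline) burden; crosslinks multiply the whole migrating signal
by `exp(−X/x₀)`, so heavy crosslinking pushes Δ%T below zero — which the
one-directional caller can never score positive.

**Calibration of the free constants.** The model has three genuinely free
constants (`k_res`, `n₀`, the UV-C lesion yield) and three landmark
anchors: untreated = 10%, UV 5 J/m² at 1 h = 20%, the same dose under
HU/AraC = 74.5% (the 73–78% steady-state band; its midpoint is
unreachable because the transform saturates at 75). Requiring one `n₀`
to satisfy both UV endpoints fixes the trapped/untrapped SSB ratio at
1 h to ln(130)/ln(65/55) ≈ 29.1; `k_res` is solved for that ratio by
bisection at import time. `f_inhib = 0.01` (99% inhibition) is chosen
because it holds the trapped plateau inside 73.9–74.5% from 0.5 h to
4 h; at 95% inhibition the plateau decays below the band within 2 h.
`n₀ = 60 000` sets the gamma ladder (0–9 Gy = 0–9000 SSBs) in the
quasi-linear regime of the transform, so the origin-forced standard-curve
slope stays within ~6% of the transform linearized at background. The
implied UV yield is ~6.5×10⁴ lesions per J/m². The trapped/control ratio
is 74.5/20 = 3.7, the model's reading of "approximately four-fold"
(saturation caps it at 3.75).

**Metabolism and inhibitors.** Cell models carry CYP activity scalars
(HepaRG ≡ 1; HepG2: CYP3A4 0.01, CYP1A2 0.1; TK6: 0) and residual
factors for ketoconazole (CYP3A4 ×0.01 in HepaRG, ×0.1 in HepG2) and
α-naphthoflavone (CYP1-family ×0.02). An agent's lesion load is
`yield × dose × scalar` — linear in dose, with the activating enzyme's
scalar zeroable by the matching inhibitor. HepG2's CYP2E1 scalar (0.1)
is not constrained by any anchor and is a plausible placeholder.

**Effect sizes of the screened chemicals.** The nine screen compounds'
lesion yields are free parameters set once so that the reference verdict
pattern emerges under the default design (see the header of
`src/hepacomet/data/agents.yaml`, where this circularity is declared).
They are not potency estimates. Viability is a per-agent Hill curve
`v(d) = 1/(1+(d/d50)^h)`; HU/AraC multiplies in a 0.85 survival factor
(the co-treatment is chosen to keep ≥80% survival). The hydroquinone and
top-dose chloramphenicol presets fall below 50% viability, and
p-chloroaniline reaches ≈50% at 5 mM, so the optional 50% viability
threshold excludes exactly those doses.

## Synthetic image generator

Each comet is a discrete-sum-normalized isotropic Gaussian head
(σ = well_diameter/4 = 11.25 µm) receiving fraction `1−f` of the photon
budget, plus a half-Gaussian tail along the electrophoresis axis
(transverse σ = 0.8·head σ) receiving fraction `f`, where `f` is the true
tail fraction — so ground truth is exact by construction and photon
conservation holds to border clipping. The tail length scale
`L(f) = 12 + 48·f` µm is chosen so a fully migrated comet (head + 4L)
stays within one 240 µm pitch: lattice neighbors never overlap, which is
what makes the inverse problem well-posed at this pitch. Defaults:
16-bit rasters, 1.6 µm/px (4× objective regime; the true scale is not
constrained, and all geometry-dependent code is parameterized by it),
constant background offset 20 counts, per-pixel Poisson counting noise,
single tail direction (+columns).

Condition simulation mirrors the default study design: n = 3 replicate
wells, a 48-site grid per field at 90% Bernoulli occupancy (~130 clean
comets per condition, headroom over the 100-comet QC gate), per-comet
tail fractions Beta-distributed (concentration κ = 60) around the
model's condition mean with a Normal(0, 1 point) per-well jitter, photon
budgets lognormal (CV 0.1) around 2×10⁵.

**What the generator does not emulate:** illumination and focus
gradients, stage-tile stitching, overlapping or free-form (non-arrayed)
comets, nucleus-to-nucleus DNA-content variation beyond the budget
spread, halo/cloud morphologies, and apoptotic "hedgehog" comets.
Passing tests therefore demonstrate correctness of the measurement chain
under the stated image model, not performance on arbitrary real
micrographs.

## Quantification

**Grid registration.** Lattice rotation is estimated by maximizing the
sharpness (variance) of the two axis projections over a coarse-to-fine
angle grid with parabolic refinement; pitch from the first prominent
autocorrelation peak of each (derotated) projection, sub-pixel refined
and averaged across axes; phase from the circular mean of projection
peak positions modulo the pitch. Blank or aperiodic fields raise
`NoGridFound`. Recovered pitch is accurate to ≪1% and rotation to
±0.05° on default fields.

**Windows.** One window per lattice node: one pitch transverse, 0.35
pitches behind to 0.75 pitches ahead of the node along the tail axis.
The forward end is deliberately short of the downstream neighbor's head
wing (4σ ≈ 0.2 pitch), which would otherwise masquerade as tail signal;
at `L(f) = 12+48f` µm it still captures >99% of any tail. Windows
clipped by the raster border are flagged `edge`.

**Segmentation.** Background is the median of the transverse margin rows
(a local robust percentile), subtracted *without* clipping at zero so
residual noise stays mean-zero (clipping rectifies noise into a several-
point % tail bias). The window collapses to a 1-D profile along the tail
axis. The head center is the profile peak: coarse boxcar-smoothed argmax
(width 7 px) in the search region around the expected node, then the
*smallest* index within τ of the raw maximum in a ±7 px neighborhood —
the anti-tail tie-break, with τ = 2.5 column-noise sigmas estimated from
the margins (τ = 0 on noiseless data). The tolerance can be generous
because the one-sided tail makes the profile jump at the head center:
walking left past it is blocked by a gap far larger than the plateau
fluctuations to its right. The head/tail split is the reflection rule —
head = peak column + twice the leading mass (the anti-tail half mirrored
about the center), tail = total − head — so head + tail = total exactly.
Tail moment = (tail fraction) × intensity-weighted centroid distance of
the tail excess, in px and µm.

Known bias: the center column's tail contribution is counted into the
head, giving a small monotone deficit of −0.7 (f = 0.1) to −2.1 (f = 0.9)
points on noiseless renders; per-well medians under default noise track
the model truth within ~2.5 points at the trapped landmark. Flags:
`empty_well`/`low_signal` use floors relative to the per-field robust
comet intensity (10% and 40% of the 75th-percentile window total),
`saturated` marks rasters touching the 16-bit ceiling, `edge` as above.
Flagged records are excluded from all summaries; conditions with <100
clean comets fail QC and are excluded from statistics.

## Calibration

`SSB = slope × Δ%T` with Δ%T the background-corrected condition mean and
the slope fitted by least squares *through the origin* (background
correction already removes the intercept; the unforced variant is a
flag). Doses within 2 points of the 75% saturation ceiling carry no
slope information and are excluded (and reported). Fewer than three
usable nonzero doses → `InsufficientDoses`; nonpositive slope →
`DegenerateCurve`. Negative SSB estimates are reported raw with a
`no_change` flag, never clamped. Replicates are pooled to condition
means before fitting; per-replicate fitting is possible by calling the
fit per well.

## Statistics

Wells are the unit of replication (comet-level testing would
pseudoreplicate); the well statistic is the median % tail DNA, robust to
segmentation outliers (mean available by option). Dose series: one-way
ANOVA plus Dunnett many-to-one comparisons (multivariate-t, via scipy),
one-sided for increases in the caller; a seeded max-t permutation
implementation is kept as an independent cross-check and agrees to
Monte-Carlo accuracy. Two-factor designs: two-way ANOVA (OLS, type-II)
with Bonferroni-adjusted pairwise contrasts at each level of the second
factor using the pooled residual variance. Matched arms: two-tailed
paired t, with degenerate inputs resolved explicitly (identical vectors
→ p = 1; constant nonzero differences → p → 0 with a warning).

A compound is called "+" iff ≥1 dose shows a Dunnett-significant
increase over vehicle (α = 0.05); the optional 50% viability threshold
removes cytotoxic doses before the verdict. Only increases count, so
crosslinker-suppressed migration cannot produce a positive. In each arm
the vehicle shares the arm's inhibitor state, so the small HU/AraC-alone
increment cancels in the comparisons.

**Replicated consensus.** A full screen evaluates 18 independent
significance families (9 compounds × 2 arms) at familywise α = 0.05, so
a single simulated screen reproduces the expected verdict pattern only
with probability ≈0.6 — one null family flipping positive is likely
somewhere. The pattern-level API therefore repeats the simulated
experiment five times with independent seeds and reports the modal
verdict per compound and arm, the in-silico analogue of repeating an
experiment before tabulating it; the consensus pattern is then stable
across seeds (error ≲3% per family). Single-screen results remain
available and are what `run_experiment` writes.

## Reproducibility and numerical choices

Every stochastic stage takes an explicit seed; replicate seeds are
spawned via `SeedSequence`. Identical config + seed gives bit-identical
rasters and byte-identical CSV outputs. Config files are YAML; outputs
carry a SHA-256 config hash. Problem sizes used by the shipped tests and
the acceptance script — 48-site fields, 3 wells/condition, 2500-replicate
null simulations, five-replicate screen consensus — were chosen as the
smallest designs that leave comfortable statistical margins for each
check. Ties in profile peaks break toward the anti-tail side; pixel
coordinates are 0-based, row-major, pixel-center physical positions;
doses are carried in native units (J/m², Gy, µM, mM) and never silently
converted.

## Known limitations

- The model is a phenomenological reduction: linear kinetics, a single
  effective resolution pool, scalar CYP activities; no cell cycle,
  apoptosis, transcriptional induction (beyond the ANF-blockable CYP1A2
  scalar), or saturating metabolism.
- Chemical lesion yields are pattern-calibrated free parameters (above).
- The segmentation's head/tail boundary is this package's reflection
  rule; no equivalence with any historical comet analyzer is claimed.
- The generator's image model is idealized (no overlap, known PSF); the
  quantifier's accuracy statements are with respect to that model.
- Significant dose *ranges* in simulated screens can extend below the
  calibrated minimum significant dose (linear dose response plus
  sampling), so range edges are less stable than verdicts.
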