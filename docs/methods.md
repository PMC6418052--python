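# Methods

`volespace` re-implements, as a tested pipeline, the analysis chain of a
field study linking consistent individual differences in behavior
("personality") to space use in free-ranging bank voles: a repeated
dark–light / open-field assay scored into boldness and exploration, an
automated radio-telemetry array localizing tagged voles, kernel home
ranges and intraspecific overlap, microhabitat rasters, and a battery of
mixed models connecting the two sides. Because such field data are rarely
archived, the package ships a synthetic-data generator that emulates the
whole study with known ground truth; every stage is validated by
recovering what the generator put in.

## Synthetic study

**Site.** A 5 × 11 live-trapping grid with 10-m spacing (55 traps,
~0.4 ha) surrounded by a rectangular array of eight omnidirectional
antennas (four corners + four side midpoints, 10-m margin). Vegetation is
a two-regime mosaic measured at every trap: a grass/herb matrix and
shrub patches (by default three, radii 8–16 m). Maximum vegetation
heights are drawn per regime from gamma distributions moment-matched to
grass 94.6 ± 76.4 cm and shrub 151.9 ± 105.6 cm; a gamma keeps heights
non-negative while preserving the stated mean, which a normal truncated
at zero would inflate by ~15 cm. Ground cover is high in grass (~78%)
and low under shrubs (~38%), giving the negative height–cover association
of the field mosaic.

**Voles.** Each vole carries two independent standard-normal latent
traits, boldness and exploration. Space-use consequences are slopes on
the log scale (`EffectConfig`): by default boldness raises the movement
scale (+0.35 per SD on log range scale, base 12 m) and the target
distance to conspecifics (+0.6 per SD on log nearest-neighbour distance,
base 20 m), and lowers shrub preference (−1.0 per SD around a baseline
preference of +1.4). Home centers are settled sequentially, boldest
first: each vole picks, from 64 uniform candidates, the point that best
matches its spacing target and habitat preference. These defaults were
calibrated once so that the battery's effect strengths match the
magnitudes the field study reported (marginal R² of roughly 0.2–0.45 for
the boldness rows) and were then frozen. The spacing mechanism — not a
direct overlap effect — is what produces lower intraspecific overlap for
bolder voles; conspecific trapping-point counts inherit a weaker, less
reliable version of the same direction because counts also scale with
range area.

**Movement.** A discrete-time Ornstein–Uhlenbeck process around the home
center, parameterized by its stationary SD (`range_scale_m`) and a
home-range crossing time of 60 min; sampled at the tracking cadence
(20 min) for 4 days → 288 fixes, starting at stationarity. In this
parameterization the "infinite attraction" limit corresponds to
`range_scale → 0` (all fixes at the home center); the stationary SD is
held fixed rather than the diffusion. Note the field description of the
cadence ("every 20 min, i.e. ~96/day") is internally inconsistent
(20 min → 72/day); we follow the stated 20-min cadence.

**Signals.** Log-distance path loss, `S = S0 − 10·γ·log10(d)` (S0 = 100 dB
at 1 m, γ = 2, distance floored at 1 m), with i.i.d. Gaussian repeat noise
over the 7 repeats per antenna. The default repeat-noise SD (4 dB) was
calibrated once against the full localization chain so the median fix
error is ~10 m, the accuracy reported for the original array.

**Captures.** Per night (8 nights, p = 0.55) a vole is captured at most
once, at a trap drawn with Gaussian weight (SD 7 m) around a stationary
position draw; defaults give ~4.4 captures/individual, matching the
field effort of 4.33 ± 3.56.

**Behavioral assay.** Each variable in a block (boldness block: head and
body emergence latencies; exploration block: middle latency, sections,
crossings, activity) is
`sqrt(ICC)·T_i + sqrt(1−ICC)·(b·e_ir + sqrt(1−b²)·u_vir)`,
so every block variable's between-individual variance fraction equals
the requested ICC (defaults: boldness 0.453, exploration 0.217, the
component repeatabilities of the field study), while `b²` (0.50 / 0.56)
sets within-round block correlations. The shares were calibrated once so
the scored assay reproduces the field structure: two retained components
near 78% cumulative variance. Monotone mappings put variables on assay
scales (latencies censored at [1, 300] s; sections clipped to 0–16;
30 Bernoulli activity scans). Trap-emergence latency (ICC 0.02) and
jumps (ICC 0.05) are generated as weakly repeatable and are expected to
be discarded by the screen. The discretized scales (counts, binomial
scans, censoring) attenuate observed correlations slightly below the
latent ones, which is intended — real assay scores carry the same
coarseness.

## Analysis chain

**Localization.** Median of 7 repeats per antenna → side sums over the
four sides (3 antennas per side, corners shared) on background-subtracted,
floor-clamped medians → opposing-side proportions `E/(E+W)`, `N/(N+S)` →
per-axis isotonic (monotone piecewise-linear) calibration fitted on
known-location test-transmitter scans (default 3 × 3 grid; the background
defaults to just below the weakest calibration median). Proportions
depend weakly on the transverse coordinate, so even noiseless held-out
points retain a residual bias of ~1–3 m; this is an irreducible property
of the side-proportion reconstruction, not of the noise. Outlier rule:
a fix farther than 50 m from **both** temporal neighbors (its single
neighbor at track ends) is flagged in one pass over the original track —
robust to a lone bad fix while keeping genuine long steps.

**Repeatability.** R = V_ind / (V_ind + V_res) from a random-intercept
model estimated by REML. The restricted likelihood is profiled to the
single variance ratio and maximized by bounded scalar search — exact,
fast (needed for the parametric bootstrap and for simulation batteries),
and verified in tests against both the balanced-design ANOVA closed form
and `statsmodels.MixedLM` on unbalanced data. The p-value is a
likelihood-ratio test of V_ind = 0 against the boundary-corrected
`0.5·χ²₀ + 0.5·χ²₁` null; SE/CI come from a parametric bootstrap
(default 1000 refits). The REML estimate is truncated at 0, so under a
true ICC of 0 its mean sits slightly above 0 — the null tests therefore
assert "small and non-significant", not exactly zero.

**PCA.** Eigendecomposition of the correlation matrix; components with
eigenvalue > 1 retained; oblique rotation by gradient-projection direct
quartimin (oblimin, γ = 0), implemented in-package; regression-method
scores. Sign and label conventions are anchored: the component loading
most on crossings/sections/activity is "exploration" (positive = more
active), the one loading on inverted emergence latencies is "boldness"
(positive = faster emergence). Latencies are inverted by negation
(direction flip, spacing preserved); `300 − latency` is available.

**Individual scores.** Conditional modes (BLUPs) of a mixed model per
component with within-individual-centered test day as fixed effect and
individual as random intercept (REML, `statsmodels.MixedLM`). Centering
makes scores invariant to shifting all test days.

**Home ranges.** Gaussian product-kernel UD on a 1-m grid with the
reference bandwidth `h = sigma_pooled · n^(−1/6)`, grid padded 3
bandwidths beyond the fix bounding box. Isopleths (95% home range, 50%
core area) accumulate cells by decreasing density until the level is
reached, then polygonize at cell edges, so the enclosed mass is exact up
to one cell and area bookkeeping is exact (no sub-cell contouring).
Overlap is the area fraction of the focal polygon covered by the union
of conspecific polygons at the same level. Point-in-polygon is
boundary-inclusive, and an individual's own mean trapping point is
excluded from its conspecific count.

**Habitat.** IDW interpolation (power 2, all samples, no search radius),
exact at sample points and bounded by the sample range; half-open cell
convention for extraction; range means average the per-fix extracted
values over the fixes inside each polygon (not over raster cells).

**Linkage battery.** One model per response × score (never both scores
at once, matching the small-n design): transformed response ~ score +
sex + (1 | site), Gaussian LMM via ML for the LRT and its df = 1 p-value.
Transforms: log for areas/distances/heights, logit for overlap fractions
and cover/100, log1p for counts; the family is recorded per row. Counts
use a log1p Gaussian LMM rather than a Poisson GLMM because no installed
mixed-model implementation provides a true likelihood for a
random-intercept Poisson fit, which the LRT contract requires; the
variational approximations that exist report an ELBO instead. With fewer
than 3 sites, or on a singular fit, the model falls back to a fixed site
effect (flagged per row). R²: marginal = fixed-effects variance over
total, conditional = (fixed + site) over total. A Benjamini–Hochberg
column is emitted for transparency but not used for decisions, matching
the original analysis.

## Study-scale defaults

Five sites × 13 voles tested (65; the field study tested 62) with 3
assay rounds each; 7 voles tracked on each of the 3 densest sites (21
tracked: the field count) for 4 days at 20-min cadence. One
`run_world` takes ~2 s; replicate-world batteries in the tests use 50
worlds.

## What passing tests do and do not show

The generator produces stationary, isotropic, unimodal ranges; real vole
tracks are autocorrelated beyond OU, anisotropic along habitat edges,
and non-stationary (females shift ranges around parturition). Signal
propagation ignores vegetation attenuation and multipath, which in the
field would make errors position-dependent. Recovering generating values
here validates the estimators' correctness, not their robustness to
those field realities. Known limitations:

- The LRT for the score term is slightly anti-conservative at n = 21
  (type-I ≈ 0.08 at nominal 0.05 in simulation); at the behavioral
  sample size (n = 62) it is well calibrated (≈ 0.04).
- The "core areas sit in taller vegetation than home ranges" tendency is
  directionally reproduced but with a thin margin (≈ 60% of replicate
  worlds show a majority), because default shrub-patch radii are
  comparable to core-area radii.
- The sign of the boldness effect on conspecific trapping-point counts
  is less reliable than on overlap fractions (counts confound isolation
  with range area).
- Determinism: identical seed + config gives identical output; results
  will differ across major numpy/scipy versions only through their RNG
  and optimizer internals.
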