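# Methods

This note documents the models implemented by `fuse-kinetics`, the
assumptions behind them, the defaults of the synthetic-data generators, and
the numerical choices that are not obvious from the API.

## Arrhenius analysis of fusion kinetics

Bulk vesicle-fusion kinetics are read out by a FRET lipid-mixing assay: NBD
fluorescence dequenches as membrane merger dilutes the NBD/rhodamine pair.
The analysis treats the fusion energy landscape as a single effective
barrier, so the initial speed of fusion follows

    nu(T) = nu0 * exp(-E_A / kB T),

with `E_A` the apparent activation energy and `nu0` the nucleation
frequency — the attempt rate at which interacting membranes adopt
fusion-competent configurations. Because the model averages over molecular
detail, both parameters are effective quantities tied to the assay's
temperature range; `nu0`'s own temperature dependence is ignored across
27–47 °C, where the exponential dominates.

**Units.** `E_A` is reported in units of kB·T at the reference temperature
310.15 K (37 °C, the assay's central temperature), so the fitted law is
`nu(T) = nu0 * exp(-E_A * T_ref / T)` with `nu0` in min⁻¹. One fusion cycle
means 100% of the vesicle population having fused once; speeds are in
cycles/min.

**Pipeline.** Each trace is normalized by its detergent-solubilization
reference, `(F - F0) / (F_triton - F0)`. The initial speed is the
ordinary-least-squares slope over the initial window — the leading samples
acquired before the signal reaches 10% of the plateau (configurable). On
noisy traces the window end is located on a lightly smoothed copy of the
signal (centered moving average over n/20 samples) so that one noisy
excursion cannot truncate the window; the slope itself is always fitted on
raw samples. The baseline F0 defaults to the first sample in
`normalize_trace` (so t=0 maps exactly to 0) but the batch pipeline
(`speeds_from_traces`) averages the leading 1% of samples instead: under
multiplicative noise a single-sample baseline injects a ~2% scale error
into every speed through the normalization denominator.

The Arrhenius fit regresses ln(nu) on 1/T (log-linear), which is
numerically stable over the narrow 20 K range; a nonlinear refinement on
the speeds themselves is available behind `method="nonlinear"` and agrees
to well under 1% on clean data. Independent experiments (one full
temperature series per replicate) are fitted separately; `E_A` is
summarized as mean ± SEM across those fits, while `nu0` is taken from the
single fit to replicate-averaged speeds — the prefactor is exponentially
sensitive to fit noise, so averaging the speeds first is the stabler
estimate, and the two quantities are deliberately treated asymmetrically.

**Dequenching-to-cycles calibration.** The conversion from normalized NBD
dequenching to fusion-cycle fraction depends on dye loading and the
quenching curve, which are assay properties. Generator and analyzer share a
single pluggable `Calibration` object (forward map, inverse, and gain at
zero signal); the default is the identity on the early-time regime, which
closes the parameter-recovery loop without committing to a particular
photophysical model.

**Window-bias trade-off.** The OLS slope of a saturating trace
`F = 1 - exp(-nu t)` over a window ending at signal fraction w carries a
relative bias of about w/2 (≈5% at the default 10% window). Because the
window is defined by signal level, the bias factor is the same at every
temperature and cancels exactly in `E_A`; it shifts log10(nu0) by only
~0.02. Noiseless validation therefore uses a narrow window (1e-4), where
the recovery of both parameters is exact to 1e-4 relative error; the 10%
default is kept for noisy data, where a narrow window would be
noise-dominated.

## Curvature-energy leaflet partitioning

A conical lipid (small head relative to chain cross-section, spontaneous
curvature c0 < 0, e.g. DOPE at c0 ≈ -0.4 nm⁻¹) pays different bending
energies on the concave inner and convex outer monolayers of a small
vesicle (radius R). For a binary mixture whose host lipid is cylindrical,
ignoring the leaflet area difference:

    e_i = 2 kappa a (c0 + 1/R)^2,   e_o = 2 kappa a (c0 - 1/R)^2
    delta_e = e_o - e_i = -8 kappa a c0 / R
    r = exp(-delta_e)                      (outer/inner number ratio)
    f_o = 2 f r / (1 + r),  f_i = 2 f / (1 + r)

with kappa the bending modulus (kBT), a the area per lipid (nm²), f the
input molar fraction. `r` is independent of `f`. The per-lipid prefactor is
implemented verbatim as `2 kappa a` — the convention of the model this
package implements — although a bare Helfrich expansion per lipid would
give `kappa a / 2`; the difference is a constant factor absorbable into
kappa and does not change the structure of the partition. The sign
convention (inner leaflet sees +1/R, outer -1/R) is likewise implemented
as stated, without re-derivation.

With kappa = 20 kBT, a = 0.65 nm², c0 = -0.4 nm⁻¹, R = 40 nm:
delta_e = 1.04 kBT, r = 0.3535, and (f_i, f_o) = (0.37, 0.13) at f = 0.25,
(0.74, 0.26) at f = 0.5 (2 d.p., half-even rounding — the convention used
for all two-decimal table comparisons).

**Labeling inverse.** A two-step experiment labels externally accessible
amine head groups first, then the total pool after solubilization; each dye
read is normalized by a co-read NBD intensity tracking total lipid. The
external fraction is the ratio of ratios
`(I_ext/I_NBD1) / (I_tot/I_NBD2)`, and with equal lipid counts per leaflet
the occupancies follow as `f_o = 2 f fe`, `f_i = 2 f (1 - fe)` with implied
ratio `r_hat = f_o/f_i`. Intensities are validated (positive; external not
exceeding total beyond tolerance) and the forward generator and inverse are
exact mirrors at zero noise.

## Hydrophobic packing defects

A packing defect is a membrane surface patch where the first atoms seen
perpendicular from the water phase belong to acyl chains rather than polar
heads. The detector rasterizes one leaflet of a flat bilayer onto a square
grid (1 Å cells by default, the conventional resolution for this analysis):

* an atom covers a cell when the cell center lies inside the atom's van der
  Waals disk in x/y, with periodic wrapping in both directions;
* covering atoms are ranked by the top of their vdW sphere along the
  viewing direction (z + radius for the upper leaflet, mirrored for the
  lower);
* the topmost atom classifies the cell: polar head → `polar`; hydrophobic
  with its top at least 1 Å below the leaflet-mean central glycerol carbon
  → `deep_defect`; hydrophobic but shallower → `shallow_defect`; no
  coverage → `uncovered` (water gap);
* exact height ties between polar and hydrophobic atoms go to polar, which
  conservatively underestimates defects;
* `all` is the union of deep and shallow.

Contiguous defect cells form components (4-connectivity by default,
8 behind a flag), stitched across the periodic box edges by union-find over
the edge-adjacent labels. The headline statistic is the surface fraction
occupied by defect cells; the default denominator is the full box area
("fraction of membrane area"), with `covered_only` available to exclude
water gaps. Component areas are reported, but no exponential fit of the
defect-size distribution is performed — the surface fraction is the metric
of interest here.

Only flat bilayers are supported. Leaflets are assigned per lipid by the
sign of the reference-atom height (the classifier's central glycerol
carbon, falling back to the residue mean) relative to the midplane (mean z
of all atoms). Atom classification (polar/hydrophobic per residue and atom
name, glycerol reference, vdW radii) is configuration, loadable from YAML;
element-based radii (C 1.7, H 1.2, N 1.55, O 1.52, P 1.8, S 1.8 Å) are the
fallback when an atom name has no explicit radius.

**Correctness strategy.** The optimized rasterizer (per-atom stamping into
polar/hydrophobic height buffers) is validated bit-for-bit against a dense
brute-force oracle that enumerates every cell against every atom and every
periodic image, on randomized snapshots up to 50×50 cells and 200 atoms;
component labeling is validated against an explicit torus flood fill. Both
paths compute coverage and heights with identical floating-point
expressions, so bit-identity is well-defined.

## Synthetic data: what it emulates, what it does not

`synthetic` generates every input the pipeline consumes.

**Dequenching traces** follow `F(t) = F0 + A·g(1 - exp(-nu t))` with the
identity calibration g by default, baseline F0 = 100 a.u., amplitude
A = 900 a.u. scaled by the labeled fraction of the population (default
0.5), and per-point multiplicative lognormal noise of configurable CV
(mean-one parameterization). Default design mirrors the assay: 5
temperatures from 300.15 to 320.15 K in 5 K steps, 5 replicates, CV 10%.
Sampling spans the time to reach 0.5 fusion cycles (~40% of plateau) at
2400 samples per trace, so the default 10% window holds ≈500 points; the
duration therefore adapts to the speed at each temperature, as an
experimenter would choose acquisition times. Traces are seeded per
(temperature, replicate) through spawned child streams, bit-reproducible.
Not emulated: FRET photophysics beyond the calibration map, vesicle size
dispersion, baseline drift, or well-to-well cross-talk — so parameter
recovery here demonstrates estimator correctness, not robustness to every
plate-reader artifact.

**Toy bilayers** are flat rectangular bead lattices: polar head beads
(spacing 1 Å, radius 0.9 Å) at z = 20 Å with axis-aligned rectangular
holes, over a continuous hydrophobic tail layer at z = 17 Å. The radius is
chosen just below the spacing so each lattice bead covers exactly the grid
cell it sits on at 1 Å resolution: constructed hole areas then translate
into exact defect-cell counts, and the ground-truth defect fraction is the
shapely-computed union of the hole rectangles over the box area.
Overlapping holes are unioned, not an error. Tail tops sit 2.1 Å below the
head reference, so constructed holes classify as deep defects. These toys
validate geometry and counting; they do not emulate thermal roughness,
atomic packing or real lipid chemistry, so agreement on them says nothing
quantitative about defect fractions of simulated all-atom bilayers.

**Labeling quadruples** are built from the ground-truth external fraction
with a fixed label-yield coefficient and a fixed dilution factor between
the two reads (removed by NBD normalization), plus optional multiplicative
lognormal noise per intensity. With four independently noisy intensities
the single-experiment estimator SD is ≈2·CV; validation therefore averages
16 replicate experiments, the standard experimental remedy.

**Collision contact times** use Stokes–Einstein diffusion
`D = kB T/(6 pi eta r)` and `t = d²/(c·m·D)`, where the convention picks
the mean-squared-displacement dimensionality factor c (2 for 1-D, 6 for
3-D) and whether relative diffusion of both vesicles is used (m = 2) or a
single vesicle's D (m = 1). The conventional 60 ns–6 µs window for 2–20 nm
gaps at 40 nm radius is reproduced by the relative 3-D convention with
eta = 1.0e-3 Pa·s at one-significant-figure precision; no single convention
can land strictly inside that window at both gap endpoints because the time
scales exactly as d² and the window ratio equals (20/2)². The convention
and viscosity are therefore explicit parameters.

## Problem sizes and determinism

All validation runs at desk scale: temperature series are 25 traces of 2400
points; stochastic recovery checks use 200 seeded pipeline runs; oracle
equivalence uses 50 randomized snapshots up to 50×50 cells and 200 atoms.
Every stochastic component takes an explicit integer seed and uses spawned
`numpy` child streams, so all results in the test suite and the acceptance
script are bit-reproducible. File writes are atomic (temporary sibling +
rename), and every pipeline report embeds the seed and a hash of its
configuration.

## Known limitations

* The dequenching→cycles conversion is an identity by default; assays with
  strong dye-dilution nonlinearity need a custom `Calibration`.
* `E_A` is a single effective barrier; multi-barrier kinetics,
  temperature-dependent prefactors and vesicle-size corrections are out of
  scope.
* The leaflet model is binary (one conical + one cylindrical lipid), with
  equal lipid counts per leaflet and no area-difference elasticity or
  flip-flop kinetics.
* The defect detector handles flat membranes only, and reads PDB/GRO
  coordinates — trajectory formats needing topology reconstruction
  (XTC/TRR/DCD) are not supported in the core.
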