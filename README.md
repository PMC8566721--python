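# fuse-kinetics

Analysis tools for bulk vesicle-fusion experiments and flat-bilayer
simulations: how lipid shape and malleability control membrane fusion
kinetics.

The package is aimed at membrane biophysicists running FRET lipid-mixing
assays and/or bilayer simulations, and implements three layers:

1. **Fusion kinetics** (`fuse_kinetics.kinetics`). NBD dequenching traces
   are normalized by their detergent-solubilization reference, the initial
   slope gives the initial speed of fusion in fusion cycles per minute, and
   the temperature dependence of those speeds is fitted with an Arrhenius
   law

   `nu(T) = nu0 · exp(−E_A / k_B T)`

   yielding the apparent activation energy `E_A` (in k_BT at 310.15 K) and
   the nucleation frequency `nu0` (min⁻¹), with replicate-level
   uncertainties.

2. **Leaflet partitioning** (`fuse_kinetics.leaflets`). A conical lipid
   with spontaneous curvature `c0` on a vesicle of radius `R` pays
   per-lipid bending energies `e_i = 2κa(c0 + 1/R)²` and
   `e_o = 2κa(c0 − 1/R)²` on the inner/outer leaflets, so it partitions
   with Boltzmann ratio `r = exp(−Δe)`, `Δe = −8κa·c0/R`, giving leaflet
   occupancies `f_o = 2fr/(1+r)` and `f_i = 2f/(1+r)`. The inverse problem
   — per-leaflet occupancies from two-step external/total labeling
   intensities — is included.

3. **Packing defects** (`fuse_kinetics.defects`). Flat-bilayer snapshots
   (PDB/GRO) are rasterized per leaflet on a 1 Å grid; each cell is
   classified by its topmost covering atom (polar / shallow defect / deep
   defect / uncovered, "deep" meaning ≥1 Å below the central glycerol
   carbon), contiguous defect cells are merged across periodic boundaries,
   and the surface fraction occupied by defects is reported per category.

A synthetic-data module (`fuse_kinetics.synthetic`) generates every input
with known ground truth — seeded dequenching traces whose initial slopes
follow the Arrhenius law, toy bead bilayers with holes of exactly known
area, and labeling intensity quadruples — so the full pipeline is testable
without instrument or simulation data.

## Worked example

The packaged demo simulates a synaptic-vesicle/plasma-membrane-like fusion
series (E_A = 22.6 k_BT, nu0 = 10⁶ min⁻¹, five temperatures from 27 to
47 °C, five replicates, 10% multiplicative noise), fits it back, evaluates
the leaflet model at κ = 20 k_BT, a = 0.65 nm², c0 = −0.4 nm⁻¹, R = 40 nm,
and quantifies defects on a toy bilayer:

```sh
$ fuse-kinetics demo --seed 1 --out report.json
kinetics: E_A = 22.29 kBT, nu0 = 6.87e+05 min^-1
leaflet f=0.25: f_i=0.37, f_o=0.13, r=0.35
leaflet f=0.5: f_i=0.74, f_o=0.26, r=0.35
defects: all-category fraction = 0.0381
report written to report.json
```

The fitted activation energy (22.29 k_BT) recovers the generating value
within the replicate-level uncertainty; the leaflet table shows the conical
lipid enriched on the inner leaflet (f_i = 0.37 vs f_o = 0.13 at a 25%
input fraction, outer/inner ratio 0.35); and the toy bilayer's defect
fraction (0.0381) reflects the constructed hole area plus one-cell
discretization at the hole edges.

The same stages are available individually:

```sh
$ fuse-kinetics leaflet --kappa 20 --area 0.65 --c0 -0.4 --radius 40 \
      --fraction 0.25 --fraction 0.5
f=0.25: delta_e=1.04 kBT, r=0.3535, f_i=0.3694, f_o=0.1306
f=0.5: delta_e=1.04 kBT, r=0.3535, f_i=0.7389, f_o=0.2611

$ fuse-kinetics simulate --e-a 27.6 --nu0 1e8 --seed 4 --out traces.tsv
$ fuse-kinetics fit --traces traces.tsv --out fit.json
$ fuse-kinetics defects --coords bilayer.pdb --classifier classifier.yaml \
      --category all --out defects.json
```

Library use mirrors the CLI:

```python
import fuse_kinetics as fk

params = fk.KineticParams(E_A=27.6, nu0=1e8, seed=0)
traces = fk.simulate_temperature_series(params)
fit = fk.fit_arrhenius(fk.speeds_from_traces(traces))
print(fit.E_A, fit.nu0)
```

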