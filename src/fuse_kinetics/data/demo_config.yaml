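# Packaged end-to-end demonstration: synaptic-vesicle/plasma-membrane-like
# kinetics, the conical-lipid leaflet partition table, a toy defect map and
# one labeling round trip.
kinetics:
  E_A: 22.6          # kBT at 310.15 K
  nu0: 1.0e+6        # min^-1
  noise_cv: 0.1
  n_replicates: 5
leaflet:
  kappa: 20.0        # kBT
  area: 0.65         # nm^2
  c0: -0.4           # nm^-1
  radius: 40.0       # nm
  fractions: [0.25, 0.5]
defects:
  box_x: 40.0        # A
  box_y: 40.0
  hole_rects:
    - [8.0, 8.0, 13.0, 13.0]
    - [25.0, 20.0, 31.0, 26.0]
  cell_size: 1.0
labeling:
  f: 0.25
  frac_external: 0.26
  noise_cv: 0.0
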