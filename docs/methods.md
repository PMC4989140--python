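# Methods

## Model

A large artery (porcine abdominal aorta scale) is modeled as a 2-D planar
section through the vessel axis, unit depth for all volumetric quantities:
a blood strip of height 12 mm (the lumen diameter) bounded above and below
by 1.5 mm wall strips, 250 mm long, embedded in a muscle rectangle of
700 mm (axial) × 200 mm (transverse). All outer boundaries are electrically
insulating and thermally adiabatic — the tissue block sits at core body
temperature, exchanging no net heat with its surroundings.

Material constants (SI):

| | blood | wall | muscle | electrode (304 steel) |
|---|---|---|---|---|
| σ (S/m) | 0.7 | 0.25 | 0.25 | 2.22·10⁶ |
| ρ (kg/m³) | 1000 | 1102 | 1090 | 7900 |
| k (W/m·K) | 0.52 | 0.46 | 0.49 | 14 |
| c_p (J/kg·K) | 3640 | 3306 | 3421 | 477 |

Blood in the lumen carries a perfusion rate w_b = 58.34 s⁻¹ (1.575 L/min
through a 6 mm inner diameter over a 50 mm heated length), scaled by the
run's perfusion factor (1.0 / 0.1 / 0.01) to emulate progressive
constriction. Metabolic heat 33 800 W/m³ belongs to living tissue
(wall + muscle, not blood — exposed as a switch).

### Electrical problem

Pulse plateaus (10 ms) are ~10⁶ charge-relaxation times (ε/σ ≈ µs), so the
resistive electro-quasistatic model ∇·(σ∇φ) = 0 is exact for the plateau;
permittivities are carried in the database but unused. Electrodes are
Dirichlet regions (fixed potential over their footprint) — justified by
steel being ~10⁷× more conductive than tissue. The electrode–electrolyte
interface impedance is neglected.

### Electrode configurations

Endovascular electrodes are catheter-mounted 1 × 1 mm bands. A band on a
3 mm catheter intersects the axial section plane twice, so each electrode
is rasterized as a **symmetric pair of 1 × 1 mm squares centered at
±1.5 mm** from the centerline, both at the band's potential
(`catheter_diameter = 0` collapses the pair to a single centerline
square). This representation was selected because it reproduces the
reported wall-field values of all nine studied (scheme, electrode-count)
combinations simultaneously to within ±19% (mostly single digits), whereas
centerline squares systematically underestimate the bipolar scheme by up
to 29%, with the deficit growing with electrode count.

- **Scheme 1** (endovascular bipolar): n bands with alternating polarity
  (+V, 0, +V, 0 …); an odd count puts the active band in the middle.
- **Scheme 2**: all bands active; two 3 mm circular return electrodes
  1.5 mm outside the wall, one above and one below the vessel at the
  group's axial midpoint (their exact axial position is not prescribed;
  the symmetric choice is ours).
- **Scheme 3**: all bands active; a 150 × 15 mm grounded plate 40 cm above
  the outer wall, ending on the (extended) upper domain boundary.

Electrode groups are centered on the vessel's axial midpoint with equal
spacing d (center-to-center).

### Discretization

Cell-centered finite volumes on a tensor-product rectilinear grid:
transverse spacing 0.25 mm and axial spacing 0.5 mm in a uniform window
(±80 mm axially, ±13 mm transversely) containing vessel, electrodes and
analysis regions, with geometric coarsening (ratio 1.35, cap 20 mm)
outside. Material interfaces coincide with cell faces in the fine window.
Face conductances are harmonic means of the adjacent cell conductivities
(exact series-resistor composition); Dirichlet cells are eliminated
symmetrically and the SPD system solved by sparse LU, with a 1e-10
relative-residual check and a discrete maximum-principle check.

The electric field is reconstructed per cell from **face current
densities**, E = J/σ with J the average of the cell's face fluxes. Unlike
differencing φ, this preserves the physical jump of the normal field at
the blood/wall conductivity step (E ratio = inverse σ ratio) instead of
smearing it across the 6-cell wall; it renders the slab verification
fixtures exact to machine precision.

Verification: parallel-plate and two-layer slabs against closed forms;
dense LAPACK inversion of the full system as an independent oracle on toy
grids (≤ 1e-8 agreement); charge conservation between electrode groups
(< 1%); mesh halving changes the wall-averaged field by < 2% (0.25 →
0.125 mm gives +1.1%).

### Analysis regions and metrics

All metrics are area-weighted over cells whose centers fall in the region.

- **Wall ROI**: the upper wall strip (1.5 mm) over a 50 mm axial window
  centered on the electrode group. Mean field, and homogeneity =
  100·STD/mean (area-weighted population STD; whether the reported values used
  area or node weighting is unstated).
- **Tissue ROI**: the same 50 mm window of upper muscle, from the outer
  wall surface **to the edge of the geometry** — 92.5 mm in the standard
  box (nominally "100 mm"), and up to the remote plate in the extended
  scheme-3 box. Electrode cells inside the window (scheme-2 disks) are
  excluded from the average.
- **LV** = wall mean / tissue mean.

The upper side is used throughout; scheme 1 is symmetric, schemes 2–3
follow the same upper-wall convention.

### Distance sweeps

Default grid 1–50 mm in 1 mm steps (extended beyond the nominal 1–20 mm
study range to cover all reported optima, some of which lie at 35–45 mm).
One independent solve per distance; infeasible distances are skipped with
a logged warning. Optima are grid argmax/argmin with ties to the smaller
distance. `summary_table` reports, per (scheme, count), the
field-optimal distance with its three metrics plus the argmin-STD and
argmax-LV distances, so criteria mismatches stay visible.

### Thermal problem

Pennes bioheat with the perfusion sink w_b c_b ρ_b (T_a − T) only in lumen
cells (blood properties: c_b = 3640, ρ_b = 1000), T_a = 310.15 K, Joule
source σ|E|² gated by the pulse train (duty = pulse_duration × rate). The
conduction solve is reused for every pulse: one-way electro-thermal
coupling with temperature-independent σ.

Time stepping is backward Euler (unconditionally stable): 1 ms steps
during the 10 ms pulse, up to 10 ms steps between pulses; the two system
matrices are factorized once per session. Halving both steps changes the
reported rise by < 0.1%. On an adiabatic test box the scheme conserves
energy to round-off (enthalpy gain = integrated source power).

Sessions report the temperature **perturbation around the metabolic
baseline**: the equation is linear, so starting from a uniform 310.15 K
with the metabolic source off yields exactly the Joule-driven rise above
whatever steady baseline metabolism maintains. (A literal equilibration of
this reduced geometry is not meaningful: with perfusion confined to the
lumen and all boundaries adiabatic, metabolic heat alone has no bounded
steady state resembling tissue.) `include_metabolic=True` restores the
full equation, which the point-tissue fixtures exercise against the
closed-form Pennes step response.

`max_wall_rise` is the session maximum of the **wall probe** at the
group's axial center, mid-wall — the natural single-trace location for
the wall's temperature dynamics (≈1.1 K in the worst case: 50 Hz, 1%
perfusion, 40 s). The hottest wall cell anywhere (directly above an
electrode band) reaches ≈1.9 K and is exposed separately as
`max_anywhere_rise`.

The transient runs on a cropped window (electrode group + 15 mm margin,
vessel ± 15 mm transversely): the 40 s thermal diffusion length in tissue
is √(αt) ≈ 2 mm, and the cropped result matches the full-grid result to
eight decimals on the worst-case scenario. `crop_margin=None` restores
full-grid stepping.

## Verification fixtures

All fixtures are generated programmatically (no data files): plate
capacitor slabs (uniform field V/gap; steel plates place the effective
Dirichlet surface on the plate's inner face, so the gap is the inner-face
separation), two-layer slabs (field ratio = inverse conductivity ratio),
and single-cell Pennes step responses (exponential saturation with
τ = ρc_p/(w_b c_b ρ_b), linear ramp without perfusion). A canned list of
the nine electrostatic study combinations and nine thermal scenarios is
provided by `reference_configs()`.

## Known limitations

- Planar 2-D representation: no true cylindrical geometry, so absolute
  field/temperature levels carry the section-plane approximation; the
  catheter-band pair is that plane's image of a ring electrode.
- The target geometry is under-specified in places (muscle box
  orientation, scheme-2 return positions, scheme-3 ground placement);
  choices documented above were fixed globally, not per result.
- No electroporation-induced conductivity change, no electrode
  polarization impedance, no temperature-dependent properties, no
  thermal-damage integral, and no flow convection beyond the Pennes sink.
- Reported values are reproduced within roughly ±20% (fields)
  and ±10% (LV, STD); exact agreement is not expected given the geometric
  ambiguities and the different discretizations.
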