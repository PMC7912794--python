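# Methods

`nanosede` models the rejection of a charged micropollutant — sulfadiazine
(SDZ), an amphoteric sulfonamide antibiotic that is predominantly
mono-anionic at pH 7 (pKa 2.00/6.50) — by polyamide nanofiltration
membranes, using the SEDE framework: **S**teric, **E**lectric (Donnan) and
**D**i**E**lectric (Born) exclusion coupled to extended Nernst–Planck (ENP)
transport through a bundle of straight cylindrical nanopores.

## Model

**Geometry and state.** The active layer is a bundle of cylindrical pores of
radius `rp` and lumped effective thickness `Δx_eff = Δw/Ak` (active-layer
thickness over porosity; tortuosity is implicit). Under the uniform-potential
approximation, concentrations `c_i(x)` and potential `ψ(x)` are radially
averaged functions of the normalized axial coordinate `x ∈ [0, 1]`.

**Interfacial partitioning.** At both pore mouths,

```
c_pore,i / c_bulk,i = φ_i · exp(−z_i F ΔψD / RT) · exp(−ΔW_i)
```

with the Ferry steric factor `φ_i = (1 − λ_i)²`, `λ_i = r_i/rp`; the Donnan
potential `ΔψD` is the unique root that lets the partitioned ions neutralize
the local fixed charge (bracketed scalar search, |Δψ| ≤ 1 V, residual
tolerance ~1e-15); and the Born solvation penalty

```
ΔW_i = (z_i e)² / (8π ε0 kB T r_cav,i) · (1/εp − 1/εb)
```

for moving an ion from bulk water (εb = 78.4 at 25 °C) into the
lower-dielectric pore fluid (εp, per-membrane). Cavity radii default to
Stokes radii; both are configurable per species.

**Intrapore transport.** The radially averaged ENP equations, on the
normalized axis,

```
dc_i/dx = A_i (Kc_i c_i − c_p,i) + z_i c_i Ē(x),   A_i = Jv Δx_eff / (Kd_i D_i)
```

are closed by local electroneutrality `Σ z_i c_i(x) + CLoc(x) = 0`, which
eliminates the Poisson equation and yields the scaled axial field

```
Ē(x) = −[ Σ_i z_i A_i (Kc_i c_i − c_p,i) + dCLoc/dx ] / Σ_i z_i² c_i
```

(`Ē = −(F/RT) dψ/dx` per unit normalized length; physical field
`E = Ē·RT/(F·Δx_eff)`). Hindrance factors `Kd` (diffusion) and `Kc`
(convection) use the Bungay–Brenner centerline series, valid over the whole
λ range; the coefficients are hard-coded and exposed for independent
verification. Rejection is reported as `R_i = 1 − c_permeate,i / c_feed,i`.

**Oversized solutes.** SDZ (rs = 0.40 nm) is larger than the mean pore of the
tight membranes (rp = 0.34–0.35 nm), where the Ferry/hindrance picture is
formally invalid. Real membranes still transmit such solutes (pore-size
dispersity, pore swelling), so λ is capped at a configurable `λ_max` with a
warning. The default cap is 0.98: it must exceed the largest *physical*
sub-unity λ in the bundled set (SDZ in NF270, λ = 0.952), otherwise the cap
itself would erase a genuine steric difference between membranes; 0.98 keeps
a margin to the λ→1 singularity of the hindrance series.

## Numerical solution of the boundary-value problem

The steady state couples the unknown permeate composition to the ODEs (the
permeate appears in the convective term) and to the exit partitioning. The
solver shoots **backwards** (permeate → feed): in the forward direction the
transported mode grows like `exp(Pe)` and destroys shooting/fixed-point
schemes already at moderate Péclet number, whereas backwards it decays, so
the method stays well-conditioned at the Pe ~ 1e4 reached by oversized
solutes. The outer iteration is a quasi-Newton (`scipy` hybrd) root on the
log permeate concentrations with two matching conditions: feed-side Donnan
partitioning at x = 0 and permeate electroneutrality. Several scaled-feed
initial guesses are tried in sequence; non-convergence is flagged on the
returned solution, never silent. Integration uses LSODA (Radau fallback for
a dense-output corner case) with rtol 1e-10 and per-species atol
`1e-14·scale`; profiles are reported on a 401-point grid with the exact
dense interpolant retained for diagnostics. A rejection-only mode skips the
dense pass and is used inside fitting loops.

Verified limits: with z = 0, `CLoc ≡ 0`, `εp = εb` the solver reproduces the
closed-form hindered-transport rejection law to better than 1e-6 over
Pe ∈ [0.01, 50]; interfacial partitioning reproduces the quadratic
ideal-Donnan closed form to 1e-8; electroneutrality drift is ≤ 1e-8
(relative) at every grid point; and the species flux recomputed from the
differentiated profiles is constant to ≤ 1e-6 when normalized by the local
transport-term scale `max(Kc_i c_i, c_p,i)`. That normalization matters: for
a 99.99 %-rejected species the net flux is the near-cancellation of
convective and electromigration terms several orders larger, and a residual
relative to the raw flux would measure floating-point differentiation noise.
At very low fluxes an additional caveat applies: a sharp internal depletion
junction (width ~1e-7 in x) forms where the fixed charge crosses zero, and
the finite-difference verification itself loses accuracy there (~1e-4) even
though the integrator resolves the junction.

## Membrane characterization

**Pore radius.** For a neutral tracer the infinite-Péclet (limiting)
rejection depends only on λ: `R∞ = 1 − φ·Kc`, strictly increasing on
[0, 0.95]. Each tracer curve (dioxane, erythritol, xylose; rs = 0.234,
0.263, 0.290 nm) yields `R∞` either by a two-parameter fit of the full
rejection-vs-flux law (default) or by a highest-flux plateau average;
`R∞` inverts to λ by bracketed root search, `rp = rs/λ`, and per-tracer
radii are averaged arithmetically. Round-tripping the tabulated per-tracer λ
values reproduces the mean radii 0.34, 0.42, 0.35, 0.44 nm for NF90, NF270,
VNF2-8040 and TMN20H-400 at two decimals.

**Pore dielectric constant.** The printed correlation for εp(rp) in the
source material is typographically corrupted and no reading of it reproduces
the tabulated values, so εp is table-driven per membrane (33.4, 35.7, 33.7,
36.4) with a pluggable `εp(rp)` hook for users who have their own
correlation.

**Fixed-charge profiles.** Polyamide layers formed by interfacial
polymerization carry deprotonated carboxyls on the outer (feed) face and
protonated amines on the inner face, making the pore **bipolar**: negative
entrance plateau, positive exit plateau. The profile family is a
boundary-clamped logistic step `CLoc(x)` with parameters (c_entrance,
c_exit, x0, w) — smooth, monotone, analytic derivative, exact plateau values
at x = 0, 1. Zeta potentials map to surface charge by Gouy–Chapman
(`sign σ = sign ζ`) and to volumetric charge by `CLoc = 2σ/(F rp)`; the
strong-base zeta sets the entrance plateau, the strong-acid zeta the exit
plateau, and x0 can be refit so the axial average matches a measured mean
charge.

## Bundled fixtures and their calibration

Only orderings and averages of the four membranes' charge state are
available: entrance magnitudes ordered NF270 > TMN20H-400 > NF90 >
VNF2-8040, exit magnitudes NF90 > TMN20H-400 > VNF2-8040 > NF270, NF90 and
TMN20H-400 sharing nearly the same entrance density, and mean fixed charges
of −25.8 (NF90) and −33.0 mmol/L (VNF2-8040 and TMN20H-400). The bundled
plateaus (mol/m³): NF90 (−58, +50), NF270 (−62, +24), VNF2-8040 (−45, +25),
TMN20H-400 (−60, +40), with w = 0.08 and x0 fitted per membrane to the mean
charge. NF270's mean is not reported; −30.0 mmol/L (between its neighbours)
is used. NF270's plateau ratio is kept below e so that the field minimum
(which sits at the zero-crossing of CLoc, offset from x0 by w·ln(|c_ent|/c_exit))
stays within one transition width of the maximum-slope point.

The feed is SDZ⁻ at 4.0e-3 mol/m³ (1 mg/L ÷ 250.28 g/mol) with Na⁺ as
counterion and a 1.0 mol/m³ NaCl background representing the ionic strength
left by pH adjustment; composition is configurable. `Δx_eff` defaults to
1e-2 m (e.g. Δw ≈ 200 nm at Ak ≈ 2e-5). This value is a calibration, not a
measurement: it places the reference flux window (Jv = 0.6–6 ×10⁻⁴ m/s) in
the regime where the *convective* term of the axial field dominates the
charge-gradient term, which is the regime in which the field intensity
scales nearly linearly with flux (an order of magnitude over a flux decade).
At much smaller `Δx_eff` the charge-gradient term dominates instead: the
field pit is deeper and nearly flux-independent, and there the
pit-vs-steepness property (sharper transition ⇒ deeper pit) is expressed.
The test suite probes each property in the regime where its mechanism
operates, and this split is deliberate.

**A structural note on the field sign.** With a positive exit plateau whose
magnitude exceeds the permeate salt level, the electroneutral ENP closure
*forces* the axial field positive in the anion-dominated exit region: in the
exit plateau the quasi-steady balance gives `Ē ≈ A_Cl (Kc − c_p/CLoc(1)) > 0`
whenever the exit counterion level `≈ CLoc(1)` exceeds the permeate
concentration. With mean charges of tens of mmol/L (anchored by the reported
averages) and a trace feed, this is unavoidable at any flux; a globally
negative field would require either a vanishing positive exit region or a
background electrolyte far above trace level. The model therefore predicts
E < 0 over the cation-dominated front and transition of the pore (where the
screening "pit" forms) and a smaller positive field in the exit plateau.

## Synthetic data

Generators are pure functions of a `SyntheticSpec` (seed + ground truth):
tracer rejection curves from the neutral hindered-transport law on 8
log-spaced fluxes spanning Pe ≈ 0.1–20 (so the limiting plateau is
identifiable); sigmoidal zeta–pH curves pinned to zero exactly at the true
isoelectric point; and SDZ rejection-vs-pressure datasets from the forward
SEDE model. Noise is multiplicative lognormal on the transmission (1−R)
(default σ = 0.02), which keeps noisy rejections below 1 by construction and
mimics relative concentration-assay error; tracer curves are additionally
clipped at R = 0.999 as an assay resolution limit. The generators emulate
ideal steady-state filtration: no concentration polarization, fouling,
membrane compaction, pore-size dispersity or pH drift, so recovery tests
demonstrate identifiability under the model's own assumptions, not
robustness to real-world artefacts.

Recovery performance under the defaults: pore radius to ±0.02 nm from
1%-noise tracer campaigns; fixed-charge amplitude to a few percent (±15%
tolerance) from 2%-noise rejection curves, fitted by least squares on
log-transmission — rejections near 1 carry their information in the
transmission, not the rejection digits.

## Tunable parameters (defaults)

| parameter | default | units | meaning |
|---|---|---|---|
| `mu` | 0.89e-3 | Pa·s | water viscosity at 25 °C |
| `eps_b` | 78.4 | — | bulk dielectric constant at 25 °C |
| `r_cav` | = r_stokes | m | Born cavity radius, per species |
| `lambda_max` | 0.98 | — | cap on rs/rp for oversized solutes |
| `dx_eff` | 1e-2 | m | effective thickness Δw/Ak (fixtures) |
| `w` | 0.08 | — | charge-transition width |
| `x0` | 0.65 (or fit) | — | charge-transition midpoint |
| background NaCl | 1.0 | mol/m³ | feed ionic strength |
| `rtol` | 1e-10 | — | ODE relative tolerance |
| noise σ | 0.02 | — | lognormal sigma on (1−R) |

## Known limitations

- Concentration polarization, fouling, transient operation and pore-size
  distributions are out of scope; the λ cap is a crude stand-in for
  dispersity when the solute exceeds the mean pore.
- The Gouy–Chapman conversion ignores charge regulation, so zeta-derived
  charges overestimate the true surface charge.
- Rejections of oversized solutes sit very close to 1 at any realistic flux
  (the hindered diffusivity collapses, so the pore Péclet number is always
  large); comparisons between membranes are then best read in transmission
  (1−R).
- Speciation is reported, but transport treats SDZ as a single z = −1
  species (the dominant form at pH 7); multi-form transport is not modelled.
- The Born term uses a single cavity radius per ion; image-charge dielectric
  exclusion is not included.
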