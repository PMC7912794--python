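# nanosede

Steric–electric–dielectric exclusion (SEDE) transport modelling of
nanofiltration membranes, built for studying the removal of charged
antibiotics — sulfadiazine (SDZ) in particular — by commercial polyamide
membranes (NF90, NF270, VNF2-8040, TMN20H-400). It is aimed at membrane
scientists and environmental engineers who want a tested, scriptable
implementation of the full chain from membrane characterization data to
predicted rejection curves and intrapore field/concentration profiles.

## What it computes

The active layer is treated as a bundle of cylindrical nanopores (radius
`rp`, effective thickness `Δx_eff = Δw/Ak`) carrying a **bipolar** axial
fixed-charge distribution `CLoc(x)`: carboxylate-negative at the feed
entrance, amine-positive at the permeate exit. Solutes partition at both
pore mouths by

- steric exclusion `φ = (1−λ)²`, `λ = rs/rp` (Ferry),
- Donnan exclusion `exp(−zFΔψD/RT)` with `ΔψD` set by electroneutrality,
- dielectric (Born) exclusion `exp(−ΔW)`,
  `ΔW = (ze)²/(8πε0 kB T r_cav)·(1/εp − 1/εb)`,

and move through the pore by the radially averaged extended Nernst–Planck
equation with Bungay–Brenner hindrance factors `Kd`, `Kc`, closed by local
electroneutrality `Σ z_i c_i(x) + CLoc(x) = 0`. The rejection of species
*i* is `R_i = 1 − c_permeate,i/c_feed,i`. The boundary-value problem is
solved by backward (permeate→feed) shooting with a quasi-Newton outer
iteration on the permeate composition, which remains stable at arbitrarily
high Péclet number. See `docs/methods.md` for the full model account.

The package also covers the surrounding workflow:

- **Pore-size characterization** from neutral-tracer rejection curves via
  the limiting-rejection law `R∞ = 1 − φKc` (`PoreSizeEstimator`);
- **Charge-profile calibration** from acid/base zeta potentials
  (Gouy–Chapman → `CLoc = 2σ/(F rp)`), with the transition midpoint fitted
  to a measured mean charge;
- **Synthetic data generation** with known ground truth for recovery tests;
- a **CLI** (`nanosede`) and sklearn-style estimators (`fit`/`predict`)
  that compose with scikit-learn tooling.

## Worked example

```python
import numpy as np
from nanosede import fixtures
from nanosede.model import SEDETransportModel
from nanosede.transport import OperatingPoint, solve_transport

feed = fixtures.default_feed()          # SDZ- 4 umol/L + Na+ + 1 mM NaCl, pH 7
nf90 = fixtures.membrane("NF90")        # rp=0.34 nm, eps_p=33.4, bipolar charge

# rejection vs transmembrane pressure
model = SEDETransportModel(membrane=nf90, feed=feed, driver="pressure")
for dp_mpa, r in zip([0.4, 1.2, 2.0], model.predict(np.array([0.4, 1.2, 2.0]) * 1e6)):
    print(f"dP = {dp_mpa:.1f} MPa  ->  SDZ rejection = {r:.6f}")

# intrapore state at a reference flux
sol = solve_transport(nf90, OperatingPoint(feed=feed, Jv=6e-4))
print(f"field minimum {sol.E.min():.3g} V/m at x = {sol.x_grid[sol.E.argmin()]:.3f}")
```

prints

```
dP = 0.4 MPa  ->  SDZ rejection = 1.000000
dP = 1.2 MPa  ->  SDZ rejection = 1.000000
dP = 2.0 MPa  ->  SDZ rejection = 1.000000
field minimum -1.29e+05 V/m at x = 0.718
```

SDZ (Stokes radius 0.40 nm) is sterically oversized for NF90's 0.34 nm
pores and additionally Donnan- and Born-excluded, so its predicted
rejection saturates within a few parts in 10⁸ of 1 — membrane comparisons
are better read in transmission, e.g. `1 - model.predict(...)`, where NF90
transmits ~3×10⁻⁸ of the feed versus ~2×10⁻⁶ for TMN20H-400, reproducing
the observed ordering R(NF90) > R(VNF2-8040) > R(NF270) > R(TMN20H-400).
The field minimum ("pit") at x ≈ 0.72 marks the charge-transition zone
where the negative electric field screens the pore against the anion.

From the shell:

```bash
nanosede hindrance-table --n 50 --out hindrance.csv
nanosede simulate-data --preset nf90-sdz --seed 1 --out data/
nanosede characterize-pore --input data/tracers.csv --out table_pore.csv
nanosede predict-rejection --membrane NF90 --pressures 0.4:2.0:9 --out curve.csv
nanosede profiles --membrane NF90 --jv 6e-4 --out profiles.csv
```

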