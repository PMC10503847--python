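# vesselwall

Passive biomechanics and extracellular-matrix microstructure of large elastic
arteries, as measured by biaxial extension–inflation myography and multiphoton
z-stack imaging.

The package is written for vascular-mechanics labs that run pressure-myograph
protocols on vessel segments (e.g. rodent common carotid arteries) and image
the same vessels with second-harmonic generation (collagen) and two-photon
fluorescence (elastin). It turns the raw instrument outputs — pressure /
outer-diameter / axial-force sweeps, traced ring circumferences, and
depth-ordered TIFF stacks — into the standard derived quantities: biaxial
Cauchy stresses, the in vivo axial stretch, the circumferential tangent
modulus at mean arterial pressure (MAP), collagen fiber straightness
distributions, depth-resolved fiber orientation maps, the
circumferential-to-axial orientation ratio, and the adventitia–media
interface depth. A synthetic-data module generates all three input kinds with
known ground truth, so every step of the pipeline is testable end to end.

## The model

The vessel is treated as an incompressible thin-walled cylinder held at axial
stretch λz and inflated with transmural pressure P. With deformed outer
diameter d_o and unloaded diameters D_i, D_o (from traced ring
circumferences, D = C/π), conservation of wall volume gives the deformed
inner diameter

    d_i = sqrt( d_o² − (D_o² − D_i²)/λz ),

and equilibrium of the pressurised tube gives the mean biaxial Cauchy
stresses

    σ_θ = P·r_i / h,
    σ_z = (f + P·π·r_i²) / (π·h·(2·r_i + h)),

with r_i = d_i/2 the deformed inner radius, h the deformed wall thickness and
f the measured axial force. The in vivo axial stretch is the λz at which f is
invariant under pressurisation (found by interpolating the per-sweep slopes
of f vs P to zero), and the circumferential tangent modulus is the local
slope dσ_θ/dλ_θ at the load point nearest MAP.

On the imaging side, fiber straightness is P_s = chord length / arc length of
each traced fiber centerline (P_s = 1: straight). Orientation distributions
come from angular binning of the 2-D FFT power spectrum, on (−90°, 90°] with
0° the axial and ±90° the circumferential direction; Q_C/Q_A is the spectral
mass beyond ±45° divided by the mass within, and the adventitia–media
interface is the first depth at which the stack turns persistently
circumferential-dominant (Q_C/Q_A > 1).

## Worked example

Simulate a rat-carotid-like vessel with the built-in constitutive model,
locate its force-invariant stretch, and analyse three sweeps at that stretch
± 5% — the standard protocol:

```python
import math
import numpy as np
from vesselwall.data_io import RingGeometry
from vesselwall.mechanics import estimate_in_vivo_stretch, process_sweep
from vesselwall.synth import VesselModel, find_force_invariant_stretch, simulate_sweep

model = VesselModel()                      # rat-carotid-like synthetic vessel
lam_star = find_force_invariant_stretch(model)
sweeps = [simulate_sweep(model, lam_star * f)[0] for f in (0.95, 1.0, 1.05)]
iv = estimate_in_vivo_stretch(sweeps)
ring = RingGeometry(math.pi * model.D_i, math.pi * model.D_o)
res = process_sweep(sweeps[1], ring, reference_pressure=100.0)
k = int(np.argmin(np.abs(sweeps[1].pressures - 100.0)))
print(f"in vivo axial stretch     λ_iv = {iv.lambda_iv:.3f}")
print(f"circumferential stress    σθ(MAP) = {res.sigma_theta[k]:.1f} kPa")
print(f"axial stress              σz(MAP) = {res.sigma_z[k]:.1f} kPa")
print(f"tangent modulus           E_θ(MAP) = {res.tangent_modulus_theta:.2f} MPa")
```

prints

```
in vivo axial stretch     λ_iv = 1.674
circumferential stress    σθ(MAP) = 157.1 kPa
axial stress              σz(MAP) = 134.3 kPa
tangent modulus           E_θ(MAP) = 1.12 MPa
```

λ_iv is the stretch at which the artery neither pulls nor pushes axially as
pressure rises — the vessel's operating length in situ. The stresses are the
mean wall stresses at 100 mmHg, and the tangent modulus is the local
circumferential stiffness there; all three are the quantities compared across
experimental groups in hypertension studies.

The same analyses are available from the shell:

```bash
vesselwall simulate sweep --seed 1 --out sweeps.csv --truth-out truth.json
vesselwall mechanics --sweeps sweeps.csv --ring ring.csv --map 100 \
    --out-csv states.csv --out-json summary.json
vesselwall simulate stack --n-frames 40 --interface-frame 20 --out stack.tif
vesselwall fibers --stack stack.tif --out-prefix fib
vesselwall orientation --stack stack.tif --out-prefix ori
vesselwall run-all --config manifest.yaml --out results/
```

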