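# boldwalk

Monte Carlo simulation of MR-signal formation for BOLD fMRI and diffusion
experiments.  Spins random-walk through a voxel-mesh phantom whose substrates
(e.g. intravascular and extravascular space) carry their own T1, T2,
diffusivity and membrane permeability; each spin accumulates precession phase
from susceptibility-induced off-resonance while a hard-pulse sequence (GRE,
SE, bSSFP, GRASE, STE, or a custom RF/gradient timeline) acts on its
magnetization.  Echo signals are recorded per tissue compartment and combined
into rest-vs-active BOLD contrasts.  The intended users are fMRI physicists
studying how sequence choice, vessel size, blood volume, oxygenation and
vessel-wall permeability shape the measurable signal.

## Model

A spin *s* diffusing with substrate diffusivity *D* takes Gaussian steps with
per-axis standard deviation sqrt(2 D dt) and accumulates phase

    dPhi_s(t) = gamma * dBz(r_s, t) * dt,

so the echo-time signal is the coherent sum over Ns walkers,

    S(TE) = sum_s exp(i Phi_s) exp(-TE / T2_s).

Vessels are modeled as randomly placed infinite cylinders of radius R; the
field offset of one cylinder at perpendicular distance r, azimuth phi (from
the projection of B0 onto the plane orthogonal to the axis) and axis angle
theta to B0 is

    dBz = 2 pi B0 (1-Y) dchi (R/r)^2 cos(2 phi) sin^2(theta)    (r >= R)
    dBz = 2 pi B0 (1-Y) dchi (cos^2(theta) - 1/3)               (r <  R)

with Y the blood oxygenation fraction and dchi the susceptibility difference
between fully deoxygenated blood and tissue (0.11 ppm, cgs convention).
Field maps are stored at B0 = 1 T and scaled analytically to the working
field strength and oxygenation state.  Crossings between substrates i and j
are accepted with probability P_ij (P_ij = 0 is an impermeable wall; a
rejected step is redrawn).  One phantom serves every vessel size through
virtual field-of-view scaling: reinterpreting a phantom of FoV L at scale c
as a box of size cL simply divides the random-walk step by c and reuses the
stored field map.  See `docs/methods.md` for assumptions, conventions and
numerical choices.

## Worked example

Extravascular BOLD signal change of a 4% blood-volume cylinder phantom at
9.4 T (oxygenation 78% at rest, 85% active; T2 IV/EV per state as in the
simulated protocol):

```python
import numpy as np
from boldwalk import (SubstrateSet, StatePair, build_gre, build_se,
                      make_cylinder_phantom, run_rest_active,
                      percent_signal_change)

phantom = make_cylinder_phantom(
    fov=[300.0] * 3, grid=[128] * 3, radius=8.0, target_bvf=0.04,
    orientation="perpendicular", seed=7,
)
print(f"phantom: {phantom.attrs['n_cylinders']} cylinders, "
      f"BVF = {phantom.attrs['bvf_achieved']:.4f}")

impermeable = np.eye(2)
states = StatePair(
    substrates_rest=SubstrateSet(t1=[2200, 2500], t2=[41, 13], d=[1, 1],
                                 perm=impermeable),
    substrates_active=SubstrateSet(t1=[2200, 2500], t2=[41, 20], d=[1, 1],
                                   perm=impermeable),
    y_rest=0.78, y_active=0.85,
)
for tl in (build_gre(20.0, 0.05), build_se(30.0, 0.05)):
    pair = run_rest_active(phantom, tl, states, n_spins=5000, b0=9.4, seed=1)
    s = {k: abs(r.compartment_signal(0)[-1]) for k, r in pair.items()}
    change = percent_signal_change(s["rest"], s["active"])
    print(f"{tl.name.upper():5s} TE={tl.echo_times[-1]:.0f} ms: "
          f"extravascular signal change = {100 * change:.2f} %")
```

Output:

```
phantom: 18 cylinders, BVF = 0.0401
GRE   TE=20 ms: extravascular signal change = 9.60 %
SE    TE=30 ms: extravascular signal change = 3.73 %
```

The gradient echo is the more sensitive but less vessel-size-specific
readout: activation (higher Y) weakens the perturbation field around vessels,
so less irreversible dephasing survives to the echo and the extravascular
signal rises; the 180-degree refocusing of the spin echo removes the static
part of that dephasing, leaving the smaller diffusion-mediated share.

## Command line

```bash
boldwalk phantom --fov 600 --grid 240 --radius 8 --bvf 0.04 --seed 1 --out cyl.h5
boldwalk run protocol.ini             # one HDF5 result per phantom per config
boldwalk sweep protocol.ini --radii 1,2,4,8,16,30 --out sweep.csv
```

Configurations are INI files (sections GENERAL / SCAN / TISSUE / FILES /
SIMULATION; schema documented in `boldwalk/config.py`).  Phantoms are HDF5
files with datasets `/substrate` (integer labels) and `/db0` (Tesla at 1 T)
plus a `fov` attribute, so externally generated microstructures can be
supplied in the same format.

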