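# springboard

Kinematics and energetics of latch-mediated spring-actuated (LaMSA) jumps
from compliant cantilever platforms.

Grasshoppers and other LaMSA jumpers launch by releasing a pre-loaded
elastic element, far too quickly for neural feedback to compensate when the
substrate gives way underfoot. Experiments that quantify this film animals
jumping from "diving boards" of varying stiffness with a high-speed camera,
digitize two landmarks per jump (a body point and the tarsus–platform
contact point), and ask how substrate stiffness and mass reshape take-off
velocity, elevation, energy and power. `springboard` implements that entire
measurement and analysis chain for people doing such experiments — and, for
developing and validating it without videos, a coupled jumper–platform
simulator that fabricates realistic tracked jumps with known ground truth.

## The model at the core

A jump is summarised by the stiffness of the hypothetical linear spring
that would reproduce it. With body mass *m*g, take-off velocity *v* (the
chord of the body landmark over the 10 ms after last contact, divided by
10 ms) and leg-extension stroke *x*, conservation of energy gives

    ½ k_g x² = ½ m_g v²   ⇒   k_g = m_g v² / x²

The stroke follows from leg geometry by the law of cosines, treating femur
and tibia (lengths *L*f ≈ *L*t) as an isosceles two-bar linkage opened to
the femur–tibia angle α at take-off:

    x = sqrt(L_f² + L_t² − 2 L_f L_t cos α)

Platform stiffness *k*p is measured per marked line from load–deflection
calibration (*k* = *m g*/δ). Each experimental jump is normalized to the
mean of that animal's rigid-surface control jumps (ratios; elevation as a
difference, being a polar quantity), split into regimes by comparing *k*p
with the across-animal mean *k*g, and analysed with one-sample tests and
linear mixed-effects models (platform stiffness as covariate, platform type
as fixed factor in the stiff regime, per-animal random intercepts).

The simulator integrates a point-mass jumper driven by the leg spring
against a lumped spring–mass–damper platform tip along the thrust axis,
with unilateral contact: take-off occurs when the contact force falls to
zero. It reproduces the qualitative regime structure of such experiments —
speed lost on compliant boards, preserved on stiff ones, and recovery of
energy from a light, stiff board that recoils before take-off.

## Worked example

```python
from springboard import energetics as en, kinematics as kin
from springboard.tracking_io import Morphometrics
from springboard.simulate import SimConfig, simulate

morph = Morphometrics("gh01", body_mass=1.13e-3,
                      tibia_length=15.6e-3, takeoff_angle_deg=113.0)
x = kin.acceleration_distance(morph)
k_g = en.grasshopper_stiffness(morph.body_mass, 1.44, x)
ke = en.kinetic_energy(morph.body_mass, 1.44)
print(f"stroke x        = {x*1e3:.2f} mm")
print(f"k_g             = {k_g:.3f} N/m")
print(f"kinetic energy  = {ke*1e3:.3f} mJ")
print(f"KE density      = {en.kinetic_energy_density(ke, morph.muscle_mass):.2f} J/kg")

res = simulate(SimConfig(k_p=24.0, m_p_eff=2.5e-4))   # light, stiff board
print(f"take-off at     = {res.takeoff_time*1e3:.1f} ms")
print(f"max sag at      = {res.t_max_platform_displacement*1e3:.1f} ms "
      f"({res.max_platform_displacement*1e3:.1f} mm)")
print(f"recoil before take-off: {res.recoil_before_takeoff}")
print(f"take-off speed  = {res.takeoff_speed:.3f} m/s "
      f"({res.takeoff_speed/res.config.rigid_takeoff_speed:.1%} of rigid)")
```

prints

```
stroke x        = 26.02 mm
k_g             = 3.462 N/m
kinetic energy  = 1.172 mJ
KE density      = 24.80 J/kg
take-off at     = 38.1 ms
max sag at      = 30.2 ms (3.1 mm)
recoil before take-off: True
take-off speed  = 1.394 m/s (97.4% of rigid)
```

A 1.13 g jumper leaving at 1.44 m s⁻¹ over a 26 mm stroke behaves like a
3.46 N m⁻¹ spring carrying 1.17 mJ. On a 24 N m⁻¹ board with a 0.25 g
effective tip mass the board bottoms out 3.1 mm down at 30 ms and springs
back up while the feet are still planted, handing most of the borrowed
energy back: take-off speed is 97% of the rigid-surface value.

The full pipeline (calibration → kinematics → energetics → normalization →
statistics) runs from the shell over a YAML config; the shipped demo
generates a synthetic dataset of 5 animals × 15 jumps and analyses it:

```sh
springboard all -c examples/demo.yaml
```

Outputs land in `out/demo/`: `stiffness_profiles.csv`, `jump_table.csv`
(one row per jump, all variables in SI units), `normalized.csv`,
`one_sample_tests.csv`, `regime_models.csv` and a `manifest.json` recording
the seed and config hash. Reruns with the same seed are byte-identical.

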