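# HuRoSim

Lumped-parameter simulation and design optimization of the **physical
human–robot interaction interface (PHRII)** — the layered contact region
(skin, subcutaneous tissue, device padding, attachment straps) through which
a wearable robot exchanges forces with the body.

Wearable exoskeletons are usually attached by tightening straps and
softening padding, which trades anchoring against comfort blindly. HuRoSim
makes that trade-off computable for a hand exoskeleton attached to the
dorsum: it predicts the relative displacement, pressure distribution and
lift-off behaviour of the attachment under moment loading about the MCP
(knuckle) joint, and derives the padding stiffness profile that minimises
peak contact pressure — the standard proxy for discomfort via the
pain-pressure threshold.

## The model

**Lumped network.** The device is a planar network of point masses linked by
inelastic distance constraints (rigid plates are ternary triples of such
constraints) and compliant tension-only strap links. Each contact point is a
*PHRII unit*: a soft-tissue element and a padding element stacked in series,
with independent normal (compression) and tangential (skin stretch / padding
shear) directions. Material laws are smoothed piecewise-linear, e.g. the
tensile skin law of 0.1 MPa up to strain 0.4 followed by 18.8 MPa. Elastic
elements combine in series exactly (compliances add segment-wise in the
force domain); viscous elements combine as R₁R₂/(R₁+R₂). Contact is
unilateral: the normal force is clamped at zero, so rapid withdrawal or
moment loading produces lift-off rather than adhesion. The bones are rigid
reference grounds; the proximal phalanx ground moves with the MCP angle.

**Constrained dynamics.** With diagonal inertia M, applied forces Q and the
twice-differentiated constraints A q̈ = b, accelerations follow the
Udwadia–Kalaba closed form

    q̈ = M⁻¹Q + M^(−1/2) (A M^(−1/2))⁺ (b − A M⁻¹Q),

where ⁺ is the Moore–Penrose pseudo-inverse (redundant constraints are
harmless). Baumgarte stabilization bounds position-level drift. Explicit
adaptive Runge–Kutta and implicit multistep (BDF) solvers are both
available; the `auto` policy switches to the implicit method when the
estimated stiffness ratio max(k/m) is large.

**Interface design theory.** Resolving the external load into a normal force
F_L and moment M_L at the plate centre plus a strap bias force F_b, the
pressure distribution minimising the peak consists of two uniform regions
with

    x = M_L / (F_L + F_b),   P_peak = (F_L + F_b) / (L − 2x),
    F_b* = max(0, 4 M_L / L − F_L),

and a 15-point discrete plate-on-unilateral-springs model reproduces the
optimum and the trade-off between peak pressure and relative displacement
as the stiffness profile gradient (k_mid − k_edge)/(L/2) varies.

**Indentation analysis.** Dorsum stiffness is fitted as the loading-segment
slope of force–deflection records and corrected for instrument compliance
by the series-spring inversion k_dorsum = k_m·k_i/(k_i − k_m) with
k_i = 2.67 N/mm; the padding that realises a target effective stiffness is
k_pHRI = k_eff·k_dorsum/(k_dorsum − k_eff). A seeded synthetic generator
emulates the 15-location × 5-repetition measurement protocol.

## Worked example

```python
from hurosim.hand import (build_hand_system, LoadProtocol,
                          run_isometric_moment_study, detect_liftoff_pattern)
from hurosim.design import PlateLoadCase, analytic_peak, optimal_bias_force
from hurosim.indentation import (generate_synthetic_indentation,
                                 analyze_records, summarize_map)

system = build_hand_system()
study = run_isometric_moment_study(system, LoadProtocol(),
                                   [0.0, 0.25, 0.5], [2.0])
print(study[["moment_Nm", "angle_deg", "peak_pressure_kPa"]])
print(detect_liftoff_pattern(study.iloc[-1]))

case = PlateLoadCase(F_L=10.0, M_L=0.5, F_b=30.0, L=0.05)
print(analytic_peak(case), optimal_bias_force(10.0, 0.5, 0.05))

records, _ = generate_synthetic_indentation(seed=1)
print(summarize_map(analyze_records(records))["overall_mean"])
```

prints (abridged):

```
 moment_Nm  angle_deg  peak_pressure_kPa
      0.00       0.00               8.31
      0.25     -10.79              56.42
      0.50     -19.12             116.19
{'which_end_lifted': 'near_mcp', 'gap': 0.0074}
1600.0 30.0
1.0772
```

Under a 0.5 N·m extension moment at 2 N strap pretension the phalanx
attachment rotates 19° and its near-MCP edge lifts 7.4 mm off the skin —
the lift-off pattern the physical hardware exhibits. The example load case
(10 N force, 0.5 N·m moment on a 50 mm plate with 30 N bias) has its
optimal high-pressure region centred 12.5 mm from the plate centre with a
peak line pressure of 1600 N/m, attained exactly at the analytic optimal
bias force of 30 N. The synthetic indentation pipeline recovers a mean
dorsum stiffness of 1.077 N/mm against a generator configured around the
in-vivo regional means (1.13 N/mm over bone, 1.01 N/mm between bones).

## Command line

```bash
hurosim simulate     --config run.yaml    --out results/
hurosim design-sweep --config design.yaml --out results/
hurosim synth        --config synth.yaml  --out data/ --seed 42
hurosim indent-fit   --config fit.yaml    --out results/
hurosim validate     run.yaml
```

Each run writes CSV tables plus a `manifest.json` (config hash, version,
seed, wall time); identical config and seed reproduce identical output.

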