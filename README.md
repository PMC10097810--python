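# spinesim

Forward-dynamic neuro-musculoskeletal simulation of the thoracolumbar
spine, for biomechanists who want to study **internal load sharing** — how
the intervertebral discs, the ligaments and the trunk muscles divide the
load at each spinal level — during upright stance and a forward
flexion-to-extension movement, without prescribing any kinematics.

The model is a fully articulated chain T1–S1: 20 rigid bodies, 17
intervertebral joints with all six degrees of freedom (102 DOF in total),
the pelvis spatially fixed. Each joint carries an intervertebral-disc
bushing — a diagonal 6×6 stiffness with region presets, small uniform
damping and a constant intradiscal-pressure offset along the local
longitudinal axis, with the rotational displacement taken as the rotation
vector of the relative joint rotation and the elastic torque mapped back
energy-conservingly. 192 tension-only ligament threads (ALL, PLL, LF, SSL,
ITV and the capsular ligament, bilateral at every level T1/2…L4/5) follow
a two-point characteristic curve (toe to point A, linear through point B)
scaled to rest lengths that realise literature prestrains in the neutral
pose. Trunk muscles are four-element Hill-type muscle–tendon units
(CE, PEE, SEE, SDE) with Hatze-style activation dynamics and parameters
derived from PCSA and fibre-length ratio (F_max = σ·PCSA with
σ = 23 N/cm²; l_CE,opt = m_ratio·l_MTU; l_SEE,0 = l_MTU − l_CE,opt).

Movement is generated purely by muscle stimulation under a hybrid
equilibrium-point controller,

    u = ½ (u_open + κ (l_CE − λ) / l_CE,opt),   u ∈ [0, 1],  κ = 2,

with open-loop co-contraction levels u_open = 0.02/0.04
(abdominals/back), and an event-based schedule of target postures Λ_k in
2° increments of the lumbar angle change Δφ_lum: descend to
Δφ_lum,peak = −20°, hold 2 s, return upright.

The package includes a parametric generator for a plausible generic
50th-percentile geometry (so everything runs at desk scale with no
external data), a landmark-based individualisation pipeline in the style
of CT-derived subject-specific modelling, and the post-processing used to
report results: spinal angles, per-joint load-sharing decomposition at
Δφ_lum = −20°, and mean (k_mean) and local (k_local) functional-spinal-
unit stiffness.

## Worked example

```python
import spinesim as ss
from spinesim.dynamics import SpineSimulation, DynamicsConfig

model = ss.build_generic_model()          # 20 bodies, 17 joints, 102 DOF,
                                          # 192 ligament threads, 72 MTUs
sim = SpineSimulation(model, ss.ControllerConfig(),
                      DynamicsConfig(method="split-rk4", fixed_dt=5e-4,
                                     settle_rate_rot=2e-3,
                                     settle_rate_trans=2e-4,
                                     settle_max_time=15.0, output_rate=25))

state, phi_ref = sim.settle()             # gravitational settling
run = sim.run_flexion(state)              # descend - hold 2 s - ascend

print(f"phi_lum_ref = {phi_ref:.2f} deg")
print(f"peak dphi_lum = {run.dphi_lum.min():.2f} deg, "
      f"final = {run.dphi_lum[-1]:.2f} deg")
for rec in ss.load_sharing(run, "L4/5", -20.0, "F_z"):
    print(f"  {rec.structure:<9s} {rec.percentage:5.1f} %")
print(f"k_mean(L4/5) = {ss.fsu_stiffness_mean(run, 'L4/5'):.2f} Nm/deg")
print(f"k_local(L4/5, equ) = {ss.fsu_stiffness_local(sim, state, 'L4/5'):.2f} Nm/deg")
```

Output of this run (several minutes on one core):

```
phi_lum_ref = 24.01 deg
peak dphi_lum = -20.58 deg, final = -1.20 deg
  IVD        64.4 %
  ligament    5.4 %
  muscle     30.3 %
k_mean(L4/5) = 8.51 Nm/deg
k_local(L4/5, equ) = 5.53 Nm/deg
```

Reading the numbers: the column settled into a slightly deeper lordosis
(24.0° from the 22.5° build pose), the movement reached the commanded
−20° lumbar flexion and returned to within ~1° of the equilibrated angle.
At L4/5 the disc carries about two thirds of the axial load at peak
flexion, with the muscles carrying most of the rest; the net
torque–angle slope over the descent (k_mean) and the tonic stiffness of
the upright posture (k_local) are in the physiological few-Nm-per-degree
range. The percentages and stiffness magnitudes are properties of the
synthetic desk-scale geometry — see `docs/methods.md` for what they do
and do not show.

A command-line interface wraps the same pipeline:

```
spinesim build-generic --height 1.78 --mass 81.5 -o model.json
spinesim settle model.json -o equ.chk
spinesim flex model.json --from equ.chk --peak -20 -o run.h5
spinesim analyze run.h5 --joint L4/5
spinesim synth-landmarks --lordosis 22.5 --kyphosis 22.3 -o lm.csv
spinesim individualise --landmarks lm.csv -o subject.json
spinesim cocontraction-sweep model.json
```

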