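# petkin

Quantification and group analysis of dynamic brain PET with a reversibly
binding radioligand, built around a fully synthetic, seed-reproducible data
generator.

## The problem

Estimating how densely a target enzyme or receptor is expressed across the
brain from a dynamic PET scan means turning a 4-D image (38 frames over
60 min) into a per-voxel or per-region *nondisplaceable binding potential*
(BPnd). The reference-tissue Logan method does this without arterial blood:
the terminal slope of a graphical plot against a reference region
(cerebellum, no specific binding) gives the distribution volume ratio
DVR = BPnd + 1. The method needs validation against the arterial route
(Logan Vt from a metabolite-corrected input function), an estimate of the
reference-region efflux constant k2′, and careful statistics downstream:
sex comparisons, trait regressions on regional BPnd, and voxel-wise
association mapping with family-wise-error control.

Real subject-level scans of this kind are not publicly deposited, so this
package pairs every analysis stage with a synthetic generator whose ground
truth is known exactly — kinetics are simulated from the two-tissue
compartment model in closed form — making each estimator testable against
its truth and each statistical procedure testable for calibration.
See [docs/methods.md](docs/methods.md) for models, defaults and rationale.

## Worked example

Simulate a target region with true BPnd = 1.5 and a cerebellar reference on
the study's 38-frame schedule, then quantify with reference Logan:

```python
from petkin import core, kinetics, synthetic as syn

sched = core.make_study_schedule()          # 6x10s, 6x30s, 11x60s, 15x180s
aif = syn.AifParams()                       # parent-tracer input model
tac = syn.simulate_2tcm(syn.tcm_for_bpnd(1.5), aif, sched)
ref = syn.simulate_2tcm(syn.tcm_for_bpnd(0.0), aif, sched)

res = kinetics.logan_reference_bpnd(tac, ref, k2_prime=0.25)
print(f"BPnd = {res.bpnd:.4f}  DVR = {res.dvr:.4f}")
```

prints

```
BPnd = 1.4973  DVR = 2.4973
```

i.e. the noiseless estimator recovers the truth to 0.2 %. With realistic
frame noise:

```python
noisy = syn.add_tac_noise(tac, sched, noise_fraction=0.02, seed=1)
print(f"BPnd = {kinetics.logan_reference_bpnd(noisy, ref, k2_prime=0.25).bpnd:.4f}")
# BPnd = 1.4989
```

The default metabolite model predicts that 50.45 % of plasma activity is
unchanged tracer at 60 min (`100 * syn.HillParams()(60.0)`).

The full pipeline (cohort simulation → input-function fitting → parametric
images → regional statistics → association mapping) runs from one command:

```
petkin run --out-dir petkin_run --seed 0
```

## Layout

```
src/petkin/        library: core I/O, synthetic generator, input-function
                   fitting, Logan kinetics, regional stats, mapping, pipeline
analysis/          numbered driver scripts reproducing the study
scripts/           acceptance.py (standalone target recomputation)
tests/             pytest suite (acceptance criteria in test_acceptance.py)
docs/methods.md    models, defaults, generator scope, limitations
results/           tables/JSON written by the analysis scripts
```
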