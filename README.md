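# mrflesion

Joint processing of magnetic resonance fingerprinting EPI (MRF-EPI) brain
data: conventional dictionary reconstruction of quantitative T1 and T2* maps,
and a multi-output regression U-net that maps the 35 magnitude baseline
frames directly to T1, T2*, NAWM-, GM- and white-matter-lesion probability
maps. The intended users are quantitative-MRI and medical-image-analysis
researchers studying multiple sclerosis (MS) lesion mapping.

## The problem

MS lesions show elevated T1 and T2* relaxation times. MRF-EPI acquires a
train of EPI frames with varying flip angle α (34–86°), TE (16–76.5 ms) and
TR (3530–6370 ms), so each voxel traces a magnitude signal evolution — a
*fingerprint* — jointly sensitive to T1, T2* and the transmit-field scale
B1+. Conventional reconstruction matches every voxel against a precomputed
dictionary of simulated fingerprints

- T1 grid: 300–3500 ms, geometric, 5% steps,
- T2* grid: 10–2500 ms, geometric, 5% steps,
- B1+ scale: 0.6–1.4 in steps of 0.1,

assigning each voxel the parameters of the atom with maximal normalized
inner product. Before matching, the stack is denoised with Marchenko–Pastur
PCA (MPPCA): per sliding window, eigenvalues of the Casorati-matrix
covariance that are consistent with the Marchenko–Pastur law are identified
as noise and suppressed.

The package then trains a 2-D U-net (encoder depth 3, skip connections,
linear output) that replaces the whole conventional chain: input is the raw
35-frame stack, output the five maps above, including a continuous lesion
*probability* map that is binarized at a 33% threshold for evaluation.
Eight network variants (loss ∈ {MSE, MAE, LCL, DICE} × outputs ∈ {5, 1},
plus a 2-input reference network) reproduce the study design, including the
known failure mode where some losses collapse to an all-zero lesion channel.

Because no patient data are deposited, a seeded digital brain phantom
(concentric-ellipsoid geometry, soft tissue-probability maps, focal WM
lesions with 10–60% elevated T1/T2*, smooth polynomial B1+ field, Rician
noise) supplies ground truth for training and evaluation.

## Worked example

```python
import numpy as np
from mrflesion import (PhantomConfig, generate_phantom, default_schedule,
                       simulate_baseline_stack, add_rician_noise,
                       build_dictionary, default_grid, reconstruct_maps,
                       mppca_denoise, dice, binarize)

phantom = generate_phantom(PhantomConfig(shape=(64, 64, 6),
                                         lesion_radius_vox=(2.5, 5.0)), seed=7)
schedule = default_schedule()
stack = add_rician_noise(simulate_baseline_stack(phantom, schedule),
                         snr=40, seed=1)
denoised = mppca_denoise(stack).denoised
dictionary = build_dictionary(schedule, default_grid())
maps = reconstruct_maps(denoised, dictionary, phantom.brain_mask)
brain = phantom.brain_mask
err = np.mean(np.abs(maps.t1_ms[brain] - phantom.t1_map[brain])
              / phantom.t1_map[brain])
print(f"atoms: {dictionary.n_atoms}")
print(f"mean T1 relative error: {100 * err:.1f}%")
```

prints

```
atoms: 53820
mean T1 relative error: 1.6%
```

i.e. the dictionary holds 52 × 115 × 9 atoms and pattern matching on the
denoised noisy stack recovers T1 with a few percent mean error (the grid
step alone bounds the noiseless error at half a 5% step). The same
`QuantitativeMaps` object carries `t2s_ms`, `b1_scale`, `m0` and a
per-voxel match `correlation`.

Training and evaluating a network variant end-to-end (phantoms → noise →
denoise → dictionary targets → training → prediction → dice/detection-rate
reports) is orchestrated by `mrflesion.pipeline.run_experiment`, or from the
shell:

```bash
mrflesion run-all --config experiment.yaml
```

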