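# spikecl

Multi-channel extracellular **spike sorting** built around three
hardware-friendly primitives: **NEO** spike detection, **PDAC** feature
extraction and **competitive-learning (CL)** online clustering.  The
package is aimed at researchers evaluating low-complexity sorting
pipelines of the kind used in implantable neural recording front ends: it
provides the full detect → extract → train → classify → score chain, the
standard baselines (PCA and GHA features; K-means, fuzzy C-means and a
simplified OSORT), a synthetic spike-train generator with exact ground
truth, and a classification-success-rate (CSR) evaluator, so every stage
can be verified without external recordings.

## The algorithms

**Detection.**  The nonlinear energy operator

```
psi(j) = S(j)^2 - S(j-1) S(j+1)
```

emphasizes sharp, high-amplitude transients.  The smoothed NEO output is
compared against a threshold `gamma = c * sigma_hat^2`, with `sigma_hat =
median(|S|)/0.6745` a spike-robust noise estimate (default `c = 8`).
After a hit, peak alignment finds the spike extremum and cuts an
`m = 64`-sample window.  For `M` channels sharing one computation core at
clock rate `rc` and sampling rate `rs`, the channel capacity is
`Mmax = floor(rc/rs)`.

**Features (PDAC).**  With `imin`/`imax` the arg-extrema of a spike
`x = [x_1 ... x_m]`, the two areas above the minimum,

```
a1 = sum_{i<=imin} (x_i - x_imin),   a2 = sum_{i>imin} (x_i - x_imin),
```

give the 2-D feature vector `f_i = a_i / (imin - imax)`.  One pass over
the samples suffices for both the extrema and the areas.

**Clustering (CL).**  Per channel, K centers compete for each feature
vector; the nearest (squared Euclidean) winner moves by

```
C_k <- C_k + eta (X - C_k),        eta = 2^-5,
```

all other centers stay.  A power-of-two `eta` reduces the multiply to an
arithmetic shift; `shift_mode` reproduces that integer datapath exactly.
Training is a single pass (`O(2KT)` distance terms for 2-D features and
`T` presentations), and an adaptive variant grows K online from 2
whenever an input lands farther than a threshold from every center.

**Scoring.**  CSR = correctly classified spikes / total spikes, under the
optimal one-to-one mapping of predicted clusters to true units (Hungarian
assignment on the confusion matrix).

## Worked example

```python
import numpy as np
import spikecl as scl

templates = scl.make_templates(2, m=64, seed=0)
spec = scl.SimulationSpec(k_units=2, duration_s=10.0, snr_db=8.0, seed=3)
rec, truth = scl.generate_recording(spec, templates)

spikes = scl.process_multichannel(rec)
print(len(truth), len(spikes))            # 86 92

pairs, _, _ = scl.match_detections(
    [s.peak_index for s in spikes],
    truth.events["sample_index"].to_numpy(), tolerance_samples=32)
wf = np.vstack([spikes[i].waveform for i, _ in pairs])
true = truth.events["label"].to_numpy()[[j for _, j in pairs]]

feats = scl.pdac_feature_matrix(wf)
cb = scl.init_codebook({0: feats}, k=2, seed=0)
scl.cl_train({0: feats}, cb, scl.TrainingConfig(k=2))
report = scl.csr(scl.cl_classify_batch(cb, 0, feats), true)
print(f"CSR = {report.csr:.4f}")          # CSR = 0.9651
```

All 86 inserted spikes are recovered (the 6 extra detections are isolated
noise crossings, excluded from CSR), and CL assigns 96.5% of the true
spikes to the correct unit — the expected operating point for 2-D PDAC
features at 8 dB.

The same pipeline is available from the shell:

```
spikecl simulate --duration 10 --snr 8 --seed 3 --out rec.bin
spikecl detect   --in rec.bin --out spikes.h5
spikecl extract  --spikes spikes.h5 --method pdac --out features.csv
spikecl train    --features features.csv --k 2 --out codebook.json
spikecl classify --features features.csv --codebook codebook.json --out labels.csv
spikecl run      --seed 3 --out run_dir/     # full pipeline + manifest
```

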