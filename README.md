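# arrayemg

Continuous finger-angle decoding from a high-density surface EMG array
wrapped around the forearm.

Finger muscles are small, deep, and anatomically variable, so conventional
single-electrode EMG depends heavily on where an operator sticks the
sensor — and for amputees the right spot may be unknowable. An electrode
*array* (here 96 channels in flexor/extensor panels) records every muscle
on many channels at once and moves the placement problem into software:
independent component analysis (ICA) unmixes the channel signals into
muscle sources, spatial topology maps and anatomical masks vet the
candidates, and the best-correlated source per finger and direction drives
a decoder.

Two decoders are provided. The **musculoskeletal equilibrium-point model
(MSM)** treats each finger as one joint pulled by an antagonist
flexor/extensor pair; with contraction levels u₁, u₂ the joint settles at
the torque-balancing angle

    θ_eq = Σₙ aₙKₙLₙ / Σₙ aₙ²Kₙ,   Kₙ = k0ₙ + k1ₙuₙ,  Lₙ = l0ₙ + l1ₙuₙ,

with moment arms a₁ > 0 > a₂ and positive stiffness/length constants
fitted by constrained nonlinear least squares. The **linear regression
model (LRM)** is ordinary least squares θ = β₀ + β₁u₁ + β₂u₂. Ground-truth
angles come from the instructed protocol trigger composed with normalized
finger displacement, θ_f = T_dir · NRMSD_f (T_dir = 2.094 rad in flexion,
−0.523 rad in extension, 0 at rest). Decoders are scored by Pearson
correlation (CC) and RMSE against that ground truth.

Because suitable public array-EMG recordings with synchronized finger
kinematics are scarce, the package ships a first-class synthetic
generator (`arrayemg.simulate`) that reproduces the full experiment
structure — per-finger train runs, mixed-finger test runs, spatially
overlapping muscle sources, mains interference, sensor noise, motion
artifacts — with exact known ground truth, so every pipeline stage is
testable end to end. See `docs/methods.md` for the models, assumptions and
design choices in detail.

## Worked example

Simulate two subjects (scaled-down: one train experiment per finger, two
mixed test experiments, 10 dB SNR), run the train→test protocol for the
equilibrium decoder on both ICA components and raw masked channels, and
compare:

```python
from arrayemg.pipeline import run_pipeline
from arrayemg.evaluate import ic_emg_ttest

cfg = {
    "seed": 42,
    "simulate": {"n_subjects": 2, "fs_raw": 1024.0, "motions_per_train_exp": 2,
                 "train_exps_per_finger": 1, "test_exps": 2, "cycles_per_test_exp": 5,
                 "snr_db": 10.0},
    "protocol": {"which": "A", "methods": ["MSM-ICA", "MSM-EMG"],
                 "ica_components": 16, "msm_restarts": 4},
}
table = run_pipeline(cfg)
print(table.report())
print(ic_emg_ttest(table, model="MSM", protocol="A"))
```

prints

```
Protocol A (RMSE in degrees)
method    value            Thumb     Index    Middle      Ring     Pinky
MSM-ICA   CC mean          0.964     0.945     0.940     0.931     0.964
MSM-ICA   CC std           0.009     0.008     0.007     0.006     0.001
MSM-ICA   RMSE mean        6.075     7.406     7.866     8.676     5.934
MSM-ICA   RMSE std         0.597     0.203     0.660     0.479     0.116
MSM-EMG   CC mean          0.966     0.798     0.809     0.835     0.942
MSM-EMG   CC std           0.024     0.014     0.020     0.061     0.031
MSM-EMG   RMSE mean        6.478    16.617    15.821    14.590     8.657
MSM-EMG   RMSE std         2.599     0.536     1.378     3.524     2.514

{'t': 3.723030494803603, 'df': 9, 'p': 0.004748328494341657, 'undefined': False}
```

Reading this: each column is one finger, rows are mean ± std across the
two simulated subjects. CC near 1 means the decoded trajectory tracks the
ground-truth angle; RMSE is in degrees against a ±120° flexion range. The
ICA route matches or beats the raw-channel route on every finger — most
visibly on the middle fingers, whose spatially overlapping sources
cross-contaminate raw channels — and the paired t-test on (subject,
finger) CC pairs confirms the direction (t = 3.72, df = 9, p ≈ 0.005).

The same pipeline is scriptable from the shell:

```bash
arrayemg simulate --seed 1 --subjects 1 --out data/          # write a dataset
arrayemg preprocess --input data/subject00/train00_Thumb.csv --out proc.csv
arrayemg ica --input proc.csv --components 16 --outdir ica/  # unmixing + sources
arrayemg run --config cfg.yaml --out results/                # full pipeline
```

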