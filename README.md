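# paatlas — dual-wavelength photoacoustic atlas method

`paatlas` estimates, pixel by pixel, the volume fraction of an exogenous
contrast agent (methylene blue, MB) mixed with an endogenous chromophore
(hemoglobin, Hb) from raw photoacoustic channel data acquired at two laser
wavelengths (710 and 870 nm).  It is aimed at researchers in photoacoustic
imaging who need to monitor local contrast-agent concentration — for
example during catheter-based interventions where MB is injected into blood
and accumulations must be kept below toxic levels.

## Method

Raw RF frames are beamformed twice: delay-and-sum (DAS, one-way delays) for
amplitude, and M-weighted short-lag spatial coherence (SLSC, cumulative lag
M = 20, triangular lag weights) for segmentation.  Coherence masks
(absolute threshold 0.7, or −3 dB) from all frames and both wavelengths are
OR-merged per trial.  Masked pixels are converted to features: IQ
demodulation (2.75 MHz, 85% bandwidth), sliding 1.8-mm axial kernel power
spectra, concatenation of the 710- and 870-nm spectra, row-wise
normalization with 60-dB log compression, and PCA (p = 1) fitted on pooled
pure-class training rows.

The estimator regresses a test feature x against N random pairs drawn from
the atlas of projected pure-class samples (PCA_MB, PCA_Hb):

    C'_i = 1/2 + (‖x − Hb_i‖₁ − ‖x − MB_i‖₁) / (2 ‖Hb_i − MB_i‖₁),  0 ≤ C' ≤ 1

A histogram filter (most populated of 10 bins) reduces each C' distribution
to a scalar, and a 0.64 mm × 0.70 mm × 30-frame median filter reduces the
per-frame tensor to the final concentration map.  Performance is summarized
by the R² of the 1:1 fit of estimated versus true fractions, Spearman's ρ
(|ρ| ≥ 0.8 = strong monotonic trend) and the mean absolute error (MAE, %).

A synthetic phantom simulator (15-mm mixture chamber 20 mm from a
128-element linear array, fiber-tip fluence, per-shot laser-energy jitter
3.13 ± 0.4 mJ) generates the full 11-concentration study so that every
stage is testable without experimental data; see `docs/methods.md` for the
forward model and its limits.

## Worked example

```python
from paatlas import RunConfig
from paatlas.cli_pipeline import run_pipeline, scaled_study_config

report = run_pipeline(scaled_study_config(seed=1), "out/")
print(report["spearman_rho"], report["r_squared"], report["mae_overall_percent"])
```

This simulates 11 MB fractions × 2 trials, trains the atlas on one pure-MB
and one pure-Hb trial, estimates concentration maps for the remaining 20
trials, and prints

```
1.0 0.9596337671921308 5.372785660296789
```

i.e. the per-concentration mean estimates are perfectly rank-ordered
(ρ = 1.0), track the 1:1 line with R² = 0.96, and deviate from the true
fractions by 5.4% concentration on average; `out/report.json` additionally
lists per-label MAEs (2.6% for pure Hb, 1.6% for pure MB in this run).
Maps, an evaluation report and a manifest sufficient to reproduce the run
bit-exactly are written to `out/`.

The same stages are available from the shell:

```bash
paatlas simulate --out data/ --seed 42
paatlas atlas --mb data/set_c100_t0.h5 --hb data/set_c000_t0.h5 --out atlas.h5
paatlas estimate --atlas atlas.h5 --in data/set_c060_t1.h5 --out map.h5 --seed 7
paatlas evaluate --maps maps/ --out report.json
```

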