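# gazentropy

Analysis pipeline relating **visual attention dispersion**, measured as the
Shannon entropy of a gaze heatmap, to **response time** in screen-based
information-search tasks. It is aimed at human-factors and eye-tracking
researchers who want a global, AOI-free workload metric for visually dense
interfaces (control-room displays, dashboards) where stable areas of
interest cannot be drawn.

## The metric

For each trial, raw 100 Hz gaze is segmented into fixations with the
dispersion-threshold (I-DT) algorithm (minimum duration 100 ms, dispersion
threshold 1° of visual angle converted to pixels from the viewing
geometry). Each fixation *f* with centroid (x_f, y_f) contributes an
isotropic Gaussian kernel over the W×H pixel grid,

```
f_XY(x, y)   = 1/(2πσ²) · exp(−((x−x_f)² + (y−y_f)²) / 2σ²)          σ = 30 px
f̃_XY(x, y)  = Σ_f  d_f · f_XY(x, y),   d_f = duration_f / Σ durations
```

and the renormalised mixture is scored with the Shannon entropy

```
HE = − Σ_xy  f̃_XY(x, y) · log₂ f̃_XY(x, y)        [bits]
```

On a 1280×1024 grid HE ranges from 0 (all attention in one pixel) to
log₂(1280·1024) ≈ 20.32 bits (uniform scatter); a single σ = 30 px fixation
yields ≈ 13.9 bits. HE is then related to response time with Pearson
correlation and simple OLS regression, overall and stratified by task
difficulty, alongside a one-way ANOVA on Likert difficulty ratings and
Welch tests for gender differences.

Because raw study data of this kind are rarely shareable, the package
includes a first-class synthetic generator (`gazentropy.synth`) that
produces gaze streams, trial tables and ratings with a known ground truth —
including fixation patterns calibrated to hit prescribed entropy targets —
so every stage of the pipeline is testable end to end.

## Worked example

```sh
python analysis/01_simulate.py           # 240-trial synthetic dataset
python analysis/02_full_chain_entropy.py # gaze -> I-DT -> KDE -> entropy check
python analysis/03_analyze.py            # correlation / regression / ANOVA
python analysis/04_recovery.py           # 100-replicate parameter recovery
```

`03_analyze.py` prints, for the seed-0 dataset:

```
overall (n=240):  RT =  -57.80 + 3.852 x HE   r = 0.577  R2 = 0.333  p = 1.1e-22
type 1  (n=80):   RT =  -66.59 + 4.500 x HE   r = 0.613  R2 = 0.376  p = 1.5e-09
type 2  (n=80):   RT =  -27.26 + 1.879 x HE   r = 0.490  R2 = 0.240  p = 4e-06
type 3  (n=80):   RT =  -30.14 + 2.100 x HE   r = 0.453  R2 = 0.205  p = 2.4e-05
difficulty ratings ANOVA: F = 32.4, p = 1.9e-09
```

i.e. more dispersed attention (higher HE) predicts longer response times in
every difficulty stratum, with a single replicate's fits scattered around
the generating models. `04_recovery.py` averages over 100 replicates and
recovers the generating parameters closely (overall slope 4.282 vs the
configured 4.28, R² 0.362 vs 0.354; see `results/recovery.csv`).
`02_full_chain_entropy.py` shows the spatial chain is calibrated: 80
Type-1 trials rescored from raw gaze average 16.39 bits against targets
drawn from 16.46 ± 0.92, with a mean per-trial error of 0.03 bits.

The same operations are available as subcommands of the `gazentropy` CLI
(`simulate`, `detect`, `entropy`, `analyze`, `run`).

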