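# qtshape

Semi-automated QT-interval analysis for long-term (Holter-style) ECG.

The pipeline standardizes heartbeats into fixed 1600 ms windows, clusters
them by shape (K-shape with the shape-based distance), picks one template
beat per cluster, takes operator-registered QRS-onset / T-end fiducials on
each template, and transfers those fiducials to every beat through a
dynamic-time-warping alignment whose warping-path length is capped at the
series length plus 10. QT is measured per beat and corrected with Bazett's
formula; agreement with a reference (ICC(2,1) with 95 % CI, Bland–Altman,
Pearson r, morphology-stratified bias tables) is built in. A synthetic ECG
generator with analytic ground-truth fiducials makes every stage testable
without downloading data.

## Layout

| module | role |
| --- | --- |
| `qtshape.io_formats` / `qtshape.wfdb_io` | WFDB (.hea/.dat formats 16 & 212, MIT annotations) and the CSV contracts for fiducials and measurements |
| `qtshape.preprocess` | zero-phase low-pass (50/60 Hz, 3/40 dB), beat extraction, RR-based exclusion, z-normalization |
| `qtshape.shape_metrics` | cross-correlation sequences and the shape-based distance |
| `qtshape.kshape` | K-shape clustering (restarts, inertia model selection, small-cluster filtering) |
| `qtshape.warping` | DTW and length-limited DTW with explicit warping paths |
| `qtshape.template_qt` | template selection, 90th-percentile outlier screen, fiducial transfer, QT/QTcB |
| `qtshape.evaluation` | ICC(2,1)+CI, Bland–Altman, morphology tables |
| `qtshape.synth_ecg` | Gaussian-wave beat model, RR jitter, time warps, noise, ground truth |
| `qtshape.pipeline` / `qtshape.cli` | orchestration and the staged command line |

## CLI

Stages write plain-file artifacts into `--outdir` and can be re-run
individually; the manual fiducial-registration step happens between
`templates` and `measure` by editing `fiducials.csv`.

```bash
qtshape --outdir out --seed 1 simulate --n-beats 900
qtshape --outdir out preprocess
qtshape --outdir out --seed 1 cluster --k 12 --n-init 100 --max-iter 100
qtshape --outdir out templates
# either register from a hand-edited CSV ...
qtshape --outdir out register --fiducials my_fiducials.csv
# ... or, for simulated data, derive registration from generator truth:
qtshape --outdir out register --from-truth
qtshape --outdir out measure
qtshape --outdir out evaluate
```

For users who download PhysioNet QT Database records locally:

```bash
qtshape --outdir out replicate-qtdb \
    --records-dir qtdb/ --include include.csv --ann-ext q1c
```

where `include.csv` has columns `record_id[,morphology]`.

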