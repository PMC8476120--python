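# collapse-kinetics

Single-molecule analysis of myosin-S1 binding to and releasing from
regulated thin filaments (actin + tropomyosin ± troponin), from fluorescence
kymographs to kinetic rate constants.

Under sub-maximal calcium and low ATP, GFP-tagged myosin-S1 heads bind thin
filament "tightropes" in metastable clusters (active regions). The number of
heads in a region changes frame to frame: heads join one at a time, leave
one at a time by ATP binding — or the whole cluster disappears in a single
frame, far more often than independent release predicts. This package
implements the complete analysis chain used to quantify that *catastrophic
collapse*, together with a ground-truthed synthetic data generator so that
every stage is testable without raw movies:

1. **simulate** — stochastic cluster dynamics (attachment probability `Pa`,
   per-head detachment `Pd = 1 − e^(−k_T·[ATP]·t)`, optional concerted
   collapse channel `pc(n)`, nucleation) rendered as noisy kymographs;
2. **kymo** — TIFF/CSV I/O and rolling-ball background subtraction
   (radius 50 px);
3. **peaks** — per-frame fits of each line profile to a sum of Gaussians
   with BIC-guided model order;
4. **calibrate** — intensity-histogram mixture fit, means-vs-count line, and
   `mean ± 2·SD` bands mapping intensity to integer head counts;
5. **tracking** — greedy nearest-neighbour threading of peaks into
   active-region tracks with gap bridging;
6. **transitions** — cluster-size transition matrices (conditional and
   per-frame), the model-predicted matrix
   (`Pa^(j−i)` above the diagonal, `C(i, i−j)·Pd^(i−j)` below), empirical
   `Pa` estimation, collapse-probability curves, and inversion of collapse
   probabilities to detachment rate constants
   `k = −ln(1 − p^(1/i)) / t`;
7. **rjmcmc** — a reversible-jump MCMC sampler for normal mixtures with an
   unknown number of components, the independent route from intensities to
   head counts (mid-point cutoffs between class means).

See `docs/methods.md` for the model, estimators, numerical choices and
limitations.

## Worked example

Simulate five 2-minute kymographs at the standard assay conditions
(`Pa = 0.15`, `[ATP] = 0.1 µM`, frame 0.3 s, pixel 126.4 nm), run the full
image pipeline, and recover the kinetics:

```python
import collapse_kinetics as ck

report = ck.run_pipeline(ck.RunConfig(n_kymographs=5, seed=7))
print(f"transitions analysed:        {report['n_transitions']}")
print(f"per-frame Pd (from kinetics): {report['pd_per_frame']:.4f}")
print(f"recovered Pa:                 {report['pa_per_frame']:.3f}")
p10 = report['collapse_curve_per_frame'][0]['p']
rate = ck.invert_collapse_to_rate(p10, 1, 0.3)
print(f"measured p(1->0) = {p10:.4f} -> detachment rate {rate:.3f} /s")
```

which prints

```
transitions analysed:        1690
per-frame Pd (from kinetics): 0.0554
recovered Pa:                 0.151
measured p(1->0) = 0.0580 -> detachment rate 0.199 /s
```

The detachment probability expected from ATP binding alone is
`1 − e^(−1.9·0.1·0.3) = 0.0554` per frame (a 0.19 s⁻¹ rate constant); the
measured single-head first-column entry reproduces it, and the recovered
attachment probability matches the configured 0.15. Adding a concerted
collapse channel (`SimulationParams(pc={n: 0.2 for n in range(2, 13)})`)
makes the measured first column exceed the binomial prediction `Pd^i` by
orders of magnitude at every cluster size ≥ 2 — the signature of
cooperative detachment — while the binding side of the matrix is unchanged.

The same stages are available as a CLI:

```bash
collapse-kinetics simulate --n 2 --seed 1 --outdir demo/
collapse-kinetics preprocess --in demo/000.tif --radius 50 --out demo/000_bg.tif
collapse-kinetics peaks --in demo/000_bg.tif --out demo/000_peaks.csv
collapse-kinetics calibrate --peaks demo/000_peaks.csv --components 6 --out demo/cal.json
collapse-kinetics track --peaks demo/000_peaks.csv --calibration demo/cal.json --out demo/tracks.csv
collapse-kinetics transitions --tracks demo/tracks.csv --nmax 6 --kt 1.9 --atp 0.1 --frame 0.3 --outdir demo/
collapse-kinetics run --config config.yaml --outdir run/
```

Every pipeline run writes all intermediates (background-subtracted TIFF,
peak CSV, calibration JSON, track CSV, matrix/collapse/rate CSVs) plus a
JSON report embedding a hash of the full configuration, so runs are
reproducible from the config alone.

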