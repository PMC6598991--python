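# zincquant

Quantitative analysis of intracellular Zn²⁺ imaging experiments, for
cell biologists working with genetically encoded FRET sensors (e.g.
NES-ZapCV2) or intensity dyes (e.g. FluoZin-3 AM) in cultured neurons or
other cells.

Labile cytosolic Zn²⁺ sits in the picomolar range, far below any sensor's
dissociation constant, so raw fluorescence is meaningless without an
in-situ calibration. The package implements the full quantification chain:

* **Calibrated saturation.** After a chelator (TPA) drives the sensor to
  its minimum signal *F*<sub>min</sub> and an ionophore (pyrithione) with
  excess ZnCl₂ drives it to its maximum *F*<sub>max</sub>, any signal *X*
  maps to a fractional saturation

  FS = (X − F<sub>min</sub>) / (F<sub>max</sub> − F<sub>min</sub>)

* **Hill inversion.** FS converts to a free-Zn²⁺ concentration through the
  Hill isotherm with dissociation constant *K*<sub>d</sub> and Hill
  coefficient *n*:

  [Zn²⁺] = K<sub>d</sub> / (1/FS − 1)<sup>1/n</sup>

* **Titration fitting** — pooled nonlinear least squares of
  R(c) = f<sub>min</sub> + (f<sub>max</sub> − f<sub>min</sub>)·cⁿ/(K<sub>d</sub>ⁿ + cⁿ)
  across replicate in-vitro titrations, with curvature-based standard errors.
* **Trace pipeline** — background subtraction, FRET/donor ratio,
  endpoint extraction from the calibration phases, resting/peak
  quantification and per-cell QC flags, with across-cell mean ± SEM
  summaries.
* **Exact nonparametric tests** — Wilcoxon signed-rank and Mann–Whitney U
  with exact combinatorial null distributions (n ≤ 50, tie-free), the
  regime where small imaging experiments live and normal approximations
  misstate p-values by orders of magnitude.
* **Colocalization** — integer-shift channel registration by
  cross-correlation, adaptive local-mean thresholding, and Pearson 2D
  correlation scoring of two-channel fields.
* **Synthetic data** — seeded generators for titrations, calibration
  traces, stimulation experiments (transient vs. sustained responders) and
  two-channel puncta images, each returning its ground truth, so every
  stage of the analysis can be validated by recovery.

## Worked example

Simulate a depolarization experiment (32 cells, true resting 110 pM rising
to 220 pM during a 10 s stimulation) and quantify it:

```sh
zincquant simulate --kind stimulation --seed 7 --n-cells 32 \
    --resting-pm 110 --peak-pm 220 --out sim/
zincquant quantify --traces sim/traces.csv --phases sim/phases.json \
    --sensor fluozin3 --out quant/
```

which prints

```
32 cells quantified (0 excluded); mean resting [Zn2+] = 112.7 pM
```

`quant/cells.csv` holds the per-cell resting/peak fractional saturations
and concentrations with QC flags, and `quant/summary.json` the mean ± SEM
across cells — here a recovered resting mean of 112.7 pM against the 110 pM
generating truth, with the peak mean near 220 pM. A paired comparison of
resting vs. peak saturation:

```sh
zincquant test --kind signed-rank --from-statistic 0 --n 32
```

```json
{"kind": "signed-rank", "statistic": 0.0, "p_two_sided": 4.656612873077393e-10, ...}
```

i.e. when all 32 cells respond in the same direction the exact two-sided
p-value is 2/2³² ≈ 4.7 × 10⁻¹⁰.

The same operations are available as a library:

```python
from zincquant import load_sensor, quantify_cell, summarize_experiment, stimulation_protocol
from zincquant.synthetic import SimulationConfig, simulate_stimulation_experiment

cfg = SimulationConfig(n_cells=32, noise_sd=0.02, seed=7)
phases = stimulation_protocol()
traces, truth = simulate_stimulation_experiment(cfg, 110.0, 220.0, phases=phases)
sensor = load_sensor("fluozin3")
cells = [quantify_cell(t, phases, sensor) for t in traces]
print(summarize_experiment(cells).mean)
```

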