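# prolspec

Hyperspectral chemometrics for high-throughput phenotyping of **free
proline (FP)** — the osmolyte that accumulates in rice leaves under cadmium
stress — from 500–950 nm reflectance hypercubes.

The package is aimed at plant-phenotyping and chemometrics researchers who
want a tested, reusable implementation of the standard imaging-spectroscopy
workflow for leaf biochemistry:

1. **Radiometric calibration** — two-point correction
   R = (I − I_dark) / (I_white − I_dark) of raw ENVI cubes against white
   and dark reference frames.
2. **Leaf extraction** — NIR-threshold segmentation, masked mean spectra,
   4-leaf averaging into a samples × bands table.
3. **Calibration models** — PLS (NIPALS, latent variables chosen at minimum
   leave-one-out RMSECV), LS-SVM (RBF kernel; the dual reduces to one linear
   system in (gam, sig2)), and ELM (random sigmoid hidden layer,
   least-squares output weights, node count by LOO RMSECV).
4. **Wavelength selection** — CARS (Monte-Carlo PLS with an exponentially
   decreasing retention schedule r_i = a·e^(−k·i), r₁ = 1, r_N = 2/p, and
   |b|-weighted adaptive resampling), a binary GA with PLS-RMSECV fitness,
   and Bw (peaks/valleys of the PLS regression vector).
5. **Pixel-wise mapping** — the fitted model applied to every in-leaf pixel,
   rendered as pseudo-colour FP distribution maps with a shared scale.

Models are scored the way the chemometrics literature reports them:
Rc/RMSECV from leave-one-out cross-validation on the calibration set and
Rp/RMSEP on a rank-based 3:1 held-out prediction set (samples sorted by FP;
the third of every four goes to prediction).

Because no public rice/FP hyperspectral dataset exists, `prolspec` includes
a first-class **synthetic study generator** (`prolspec.synth`): 5 Cd
concentrations (0–100 µM) × 4 stress durations (5–20 d) × 5 samples per
group, each sample the average of 4 leaves, with leaf-shaped hypercubes
whose spectra carry a known FP-linked absorber at six recorded informative
bands. Every downstream stage is tested against this planted ground truth;
see `docs/methods.md` for the forward model and its limits.

## Worked example

```python
import numpy as np
from prolspec import (StudyDesign, simulate_spectra_table, rank_split,
                      cars_select, elm_fit, evaluate)

table = simulate_spectra_table(StudyDesign(seed=0))     # 100 samples x 350 bands
cal, pred = rank_split(table.y)                         # rank-based 3:1 split

sel = cars_select(table.X[cal], table.y[cal], table.grid, seed=0)
print(f"CARS kept {sel.n_selected} of {table.p} bands")

model, cv = elm_fit(table.X[np.ix_(cal, sel.indices)], table.y[cal], seed=0)
rep = evaluate(model,
               table.X[np.ix_(cal, sel.indices)], table.y[cal],
               table.X[np.ix_(pred, sel.indices)], table.y[pred])
print(f"ELM ({model.n_nodes} hidden nodes): "
      f"Rc={rep.Rc:.4f} RMSECV={rep.RMSECV:.4f} mg/g  "
      f"Rp={rep.Rp:.4f} RMSEP={rep.RMSEP:.4f} mg/g")
```

prints

```
CARS kept 157 of 350 bands
ELM (23 hidden nodes): Rc=0.9853 RMSECV=0.0062 mg/g  Rp=0.9650 RMSEP=0.0096 mg/g
```

i.e. on the default synthetic study the CARS-selected ELM predicts held-out
FP with correlation 0.965 and an error of ~0.01 mg/g against an FP range of
roughly 0.07–0.22 mg/g — and improves on the full-spectrum ELM (Rp 0.904),
the qualitative signature of successful wavelength selection.

The full 12-cell comparison ({full, GA, CARS, Bw} × {PLS, LS-SVM, ELM})
plus the day × concentration FP map panel comes from one call:

```sh
prolspec run-all --outdir myrun --seed 0     # ~3 min on one core
```

which writes `report.txt`, per-selector band lists and traces, and
`fp_map_panel.png`.

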