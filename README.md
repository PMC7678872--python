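# alphaflash

Simulation and analysis of **single-cell TIRF imaging of glucagon release**
from pancreatic alpha cells.

Alpha cells secrete glucagon when blood glucose falls. In a TIRF recording of
a single alpha cell expressing a glucagon–pHluorin biosensor, each granule
fusion appears as a sudden, localized flash of fluorescence: the pH-sensitive
fluorophore is dark at acidic granule pH and lights up the moment the granule
lumen contacts the neutral extracellular buffer. Counting these flashes per
unit membrane area and time turns a microscope movie into a single-cell
secretion assay — sensitive enough to resolve whether an *isolated* alpha
cell, with no paracrine input, steps up its release when glucose drops below
the hypoglycaemic threshold, and whether that regulation survives
glucokinase knockdown.

`alphaflash` implements the full analysis chain, plus a ground-truth
simulator so every stage is testable without any microscope:

1. **Simulator** (`alphaflash.simulate`) — homogeneous Poisson fusion events
   whose rate follows a glucose dose–response model (with pharmacological
   modifiers: glucokinase activator, glycolysis inhibitors, mannoheptulose,
   arginine, and a glucokinase-knockdown genotype), rendered into 16-bit
   camera movies (Gaussian PSF flash, exponential decay, shot + read noise,
   slow bleaching). Defaults: 0.277 µm pixels, 90 ms frames.
2. **Event caller** (`alphaflash.detect`) — a grid of 10 × 10 pixel squares
   over the cell footprint; per-square mean-intensity traces; peaks above a
   rolling-median baseline by `k_sigma` × robust (MAD) noise sd; and
   spillover rejection: a peak that coincides (same frame) with a strictly
   larger peak in one of the eight neighboring squares is discarded as
   optical bleed. Counts are normalized to **events / 100 µm² / min**:

   `rate = n_events / (area_µm² / 100) / duration_min`

3. **Protocol analysis** (`alphaflash.analysis`) — condition windows, fold
   change between stimulatory (1–3 mM) and inhibitory (≥ 4 mM) glucose, and
   the threshold of stimulation: repeated-measures ANOVA across glucose
   levels followed by Scheffé comparisons against the 11 mM reference, with
   the threshold reported as a bracketing interval between adjacent tested
   concentrations.
4. **Statistics** (`alphaflash.stats`) — pooled/Welch two-sample t,
   one-way, repeated-measures and balanced two-way ANOVA, and the Scheffé
   post-hoc test, implemented from their sums-of-squares formulas:
   a pair (i, j) differs when

   `(m_i − m_j)² / (MS_within (1/n_i + 1/n_j)) > (k − 1) F_crit(α; k−1, df_within)`

## Worked example

Run one simulated cell through the descending glucose ramp
(11, 5, 4, 3, 2, 1, 0 mM for 3 min each) and call its release events:

```python
import alphaflash as af

config = af.RunConfig(n_cells=8)          # 8 cells, default ramp protocol
result = af.run_experiment(config, seed=0)

print(result.rates.groupby("glucose_mM")["rate"].mean().round(2))
print("fold change:", round(result.fold.ratio, 2))
t = result.threshold
print("regulated:", t.regulated)
print("stimulatory:", t.stimulatory_set, "threshold:", t.threshold_interval_mM)
print("F = %.2f, df = %s, p = %.2e" % (t.anova.statistic, t.anova.df, t.anova.p_value))
```

Output (seed 0):

```
glucose_mM
0.0     0.84
1.0     1.50
2.0     1.84
3.0     1.77
4.0     0.86
5.0     0.81
11.0    0.98
fold change: 1.93
regulated: True
stimulatory: (3.0, 2.0) threshold: (3.0, 4.0)
F = 11.43, df = (6.0, 42.0), p = 1.52e-07
```

Mean detected rates (events / 100 µm² / min, averaged over the 8 cells)
double at hypoglycaemic glucose (1–3 mM) relative to ≥ 4 mM, fall back at
0 mM (glucose-free buffer suppresses release), and the Scheffé comparisons
against 11 mM bracket the stimulation threshold between 3 and 4 mM. Which of
1, 2, 3 mM reach significance in a given run fluctuates with the Poisson
counts; across seeds the modal stimulatory set is {3, 2, 1} mM. With
`af.DoseResponseModel(genotype="gk_knockdown")` the same analysis returns
`regulated: False` — the flat knockdown secretion profile shows no
significant differences between glucose levels.

The same pipeline is scriptable from the shell:

```bash
alphaflash init-config --preset wildtype-ramp --out sim.yaml
alphaflash simulate --config sim.yaml --seed 1 --out-prefix run/ramp
alphaflash detect --movie run/ramp_cell00_movie.tif --mask run/ramp_mask.tif --out events00.csv
alphaflash run-experiment --config sim.yaml --seed 1 --out-dir run/full
alphaflash benchmark --seed 0 --n-movies 20
```

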