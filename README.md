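# platescreen

Analysis of single-well phenotypic plate screens: per-well SSMD* scoring,
threshold-based hit classification with two-replicate concordance, and
control-based quality control — plus a synthetic screen generator with
planted ground truth so the whole pipeline is testable without wet-lab data.

## The problem

High-throughput screens with one organism (e.g. one zebrafish embryo
carrying an *hsp70*-DsRed neuronal-stress reporter) per well measure each
compound **once** per replicate. With no within-plate replication there is
no per-compound variance, so conventional assay statistics (Z-score, S/N,
S/B, Z′) either ignore the plate's variability or cannot be formed at all.
The replicate-free strictly standardised median difference (SSMD*, the
"B value") scores each well against its own plate's test-compound
population, assuming most compounds are inert:

```
score_i = (X_i − median(reference)) / (√2 · 1.4826 · MAD(reference))
```

where the reference is the plate's ok test wells. Wells below −0.5 call
inhibitors (below −1.0 strong inhibitors), above +1.0 activators; dead
wells are toxic and rescreened at lower doses. A compound is a final hit
only when both screen replicates agree. Per plate, the known controls turn
the cutoff into a diagnostic test: sensitivity = 100·TP/(TP+FN) over
positive controls, specificity = 100·TN/(TN+FP) over negative controls.

Intended users: screening groups analysing plate-reader exports (tidy CSV
plate maps and well readings) and methodologists studying robust single-well
hit calling.

## Worked example

Simulate a 4-plate, two-replicate screen (192 compounds; 6 planted
inhibitors of which 2 strong, 3 activators, 12 toxic), score it, call hits
and run QC:

```python
import numpy as np
from platescreen import (AnalysisConfig, SimulationConfig, simulate_screen,
                         score_screen, screen_hit_calls, hit_summary,
                         screen_qc_summary, make_planted_truth)

truth = make_planted_truth(192, n_inhibitors=6, n_strong_inhibitors=2,
                           n_activators=3, n_toxic=12,
                           rng=np.random.default_rng(0))
config = AnalysisConfig()
dataset, truth = simulate_screen(SimulationConfig(plates=4, seed=0), truth=truth)
scores = score_screen(dataset, config)
calls = screen_hit_calls(scores, config)
print(hit_summary(calls, len(calls)).to_string(index=False))
print(screen_qc_summary(scores, thresholds=[-0.5, -1.0]).summary.round(1)
      .to_string(index=False))
```

prints

```
threshold_class  n_hits  n_screened  percent
     below_-0.5       9         192 4.687500
     below_-1.0       2         192 1.041667
     above_+1.0       2         192 1.041667
   caused_death      16         192 8.333333

 replicate  threshold  n_plates  sensitivity_mean  sensitivity_sd  specificity_mean  specificity_sd
         1       -0.5         4             100.0             0.0              77.9            11.7
         1       -1.0         4             100.0             0.0              91.2             6.9
         2       -0.5         4             100.0             0.0              83.1            11.6
         2       -1.0         4             100.0             0.0              93.6             8.1
```

Reading this: both strong planted inhibitors replicate below −1.0; the
below-−0.5 row picks up the planted inhibitors plus a few concordant
borderline compounds (single-well scoring at −0.5 is a permissive cutoff —
see `docs/methods.md`); all 12 planted-toxic compounds plus background
deaths appear in the caused-death row. The 50 %-effect positive controls
are detected on every plate (sensitivity 100 %), and tightening the cutoff
from −0.5 to −1.0 raises specificity at the cost of sensitivity, the
expected trade-off.

The same pipeline runs from the shell:

```
platescreen simulate --seed 3 --out-dir run/sim
platescreen score --plate-map run/sim/plate_map.csv --readings run/sim/readings.csv --out-dir run/scores
platescreen hits  --scores run/scores/scores.csv --out-dir run/hits
platescreen qc    --scores run/scores/scores.csv --out-dir run/qc
```

Each command writes CSV/JSON outputs and a run manifest (inputs, config
snapshot, seed, version, record counts) sufficient to re-run identically.

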