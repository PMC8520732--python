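# aggrephagy

Quantification of **aggrephagy** — the selective autophagic clearance of
protein aggregates — from live-cell, dual-excitation **mKeima** ratiometric
imaging, with a ground-truth synthetic microscopy simulator for end-to-end
validation.

## The assay and the statistic

mKeima is a pH-sensitive fluorescent protein: its excitation spectrum
shifts from ~445 nm at neutral (cytosolic) pH to ~561 nm at acidic
(lysosomal) pH while emission stays in a single red band. Tagging
inducible aggregates (PIM, particles induced by multimerization) with
mKeima makes delivery to the lysosome measurable per particle as the
ratio

```
r = I(ex445) / (I(ex445) + I(ex561))
```

on background-subtracted integrated intensities: `r` near 1 means a
neutral aggregate, `r` near 0 an acidified one. A particle is scored
*cleared* when `r < 0.35`, and the cleared fraction of a condition is the
unweighted mean over replicate experiments. Because mKeima needs only the
red emission channel, a GFP-tagged autophagy factor (DFCP1, STX17 or
RAB7) can be imaged simultaneously, which turns recruitment timing into a
measurable quantity: marker-presence episodes, the DFCP1-release →
acidification interval (normalized DFCP1 drops and stays below 0.7 of its
maximum; ratio drops and stays below 0.8), STX17 dwell time, acidification
progress at STX17 release, trace ensembles aligned on STX17 disappearance
or on the ratio half-drop frame, and aggregate mobility before / during /
after the marker episode. A FACS-style module gates two-channel per-cell
populations and reports region-of-interest percentages.

No real imaging data ship with the package. Instead, `aggrephagy.sim`
generates dual-excitation time-lapse stacks with scripted ground truth
(positions, pH / ratio series, marker windows, motion regimes) and
matching FACS populations, so every pipeline stage is validated by
parameter recovery against the script that generated its input.

## Layout

- `src/aggrephagy/` — the library: `sim` (simulator), `detection`
  (band-pass/SNR punctum detection, z-projection, intensity measurement),
  `ratiometry` (ratios, histograms, clearance), `tracking` (LAP linking,
  traces, displacements), `events` (episode scoring, timing, alignment,
  mobility), `facs` (gating), `benchmarks` (cohort-scale recovery
  experiments), `cli`.
- `analysis/` — numbered narrative drivers (`01_simulate_fields.py` …
  `05_facs.py`) that run the pipeline and write tables under `results/`.
- `tests/` — pytest suite including end-to-end recovery tests.
- `scripts/acceptance.py` — recomputes all headline quantities from scratch.

## Worked example

```
$ python analysis/02_clearance.py
early        n= 300  cleared (ratio<0.35):  15.7%
late         n= 300  cleared (ratio<0.35):  41.3%
bafilomycin  n= 300  cleared (ratio<0.35):   0.0%
```

Three simulated 300-particle fields: shortly after aggregate induction few
aggregates have reached the lysosome (15.7% cleared), hours later many
have (41.3%), and blocking lysosomal acidification with a V-ATPase
inhibitor abolishes the shift (0.0%). The detected fractions match the
scripted acidified probabilities (0.16 / 0.43 / 0) to within sampling
noise of the 300-particle draw.

```
$ python analysis/03_marker_timing.py
STX17: 20 events, mean dwell 7.00 min, mean progress at release 0.26
DFCP1: 20/20 valid events, intervals 5.0-14.0 min (mean 9.8)
```

On movies scripted with a 21-frame (7 min at 20 s/frame) STX17 episode
released at 30% of the total acidification change, the pipeline recovers
the dwell exactly and the progress statistic to within the one-frame
discretization of the script; DFCP1-release → acidification intervals
scripted uniformly over 5–15 min come back within one frame each.

The same pattern holds for mobility (`04_mobility.py`: confined before and
during the episode, ~2.5× larger median displacements after; tether-release
frame recovered with median error 0) and FACS gating (`05_facs.py`:
scripted shifted fractions of 1% / 20% / 0% read back as 0.95% / 20.27% /
0.01%).

The command line exposes the same stages for files on disk:

```
aggrephagy simulate --scenario control_8h --n-aggregates 20 --seed 1 --out field/
aggrephagy detect --in field/stack.tif --particle-size 4 --snr 8 --out det.csv
aggrephagy ratio --in det.csv --threshold 0.35 --out ratios.csv
aggrephagy track --stack field/stack.tif --out traces.csv
aggrephagy events --traces traces.csv --marker stx17 --out events/
aggrephagy simulate-facs --n-cells 20000 --frac-shifted 0.2 --seed 1 --out facs.csv
```

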