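# clonetrack

Analysis pipeline for **multicolor clonal lineage tracing** in the developing
retina, built around StarTrack-style combinatorial labeling: progenitors take
up a random subset of 12 integrable constructs (6 fluorescent proteins — YFP,
mKO, mCerulean, mCherry, mT-Sapphire, EGFP — each targeted to the nucleus or
the cytoplasm), and every cell they generate inherits that fluorophore
combination as a heritable **color code**. Cells within an embryo that share a
nonempty code are sibling cells: a **clone**.

The package is aimed at researchers doing clonal analysis of progenitor
potency from multichannel microscopy: it turns per-cell intensity tables (or
synthetic section images) into called codes, assembled clones, clone
classifications and cohort statistics.

## What it computes

Given per-cell measurements `I(channel, compartment)` with per-channel
background statistics `(μ_bg, σ_bg)`:

1. **Presence calling** — channel *c* is positive in a compartment iff
   `I > μ_bg + k·σ_bg` (default `k = 3`); a nuclear call additionally requires
   the nucleus/cytoplasm ratio `I_nuc / I_cyt ≥ 2` unless the cytoplasm is
   negative, guarding against cytoplasmic bleed-through. The 12 booleans form
   the cell's code, serialized as `N:003050/C:000006`-style strings.
2. **Clone assembly** — partition of labeled cells by `(embryo, code)`.
   The identifiability assumption is quantified by the nonuniform birthday
   problem: a nonempty code occurs with probability
   `q(c) = p^|c|(1−p)^(12−|c|) / (1−(1−p)^12)` under per-construct uptake
   probability `p`, and the pairwise collision risk is `Σ_c q(c)²`
   (exact for n ≤ 3 progenitors, Monte-Carlo beyond).
3. **Classification** — cell types from laminar position and morphology
   (cone photoreceptor, horizontal, amacrine, radial glia, RGC, undefined);
   clones by layer distribution (trilaminar, GCL+INL, INL+ONL, GCL+ONL, and
   the three layer-restricted classes) and by inferred progenitor potency
   (≥3 differentiated types → multipotent, 2 → bipotent, a single type with
   no undefined members → committed, otherwise undetermined).
4. **Cohort statistics** — per-layer labeled-cell percentages, clone-class
   proportions and size mean ± SEM, potency shares, fraction of clones
   containing RGCs, the per-embryo cells~clones Pearson correlation, a
   locally-weighted polynomial regression (tricube weights, degree 2,
   span 0.75) of clone-size counts with pointwise standard errors, and
   Gaussian-KDE clone-size densities per potency class.

Because raw data for such studies are typically not deposited, the package
ships a first-class synthetic cohort generator (`clonetrack.simulate`) whose
defaults emulate a five-embryo study: ~203 clones, ~2050 labeled cells,
columnar clones across 50 µm sections, and the published layer and
clone-class mixtures, with full ground truth for validation.

## Worked example

```python
from clonetrack import PipelineConfig, run_pipeline

result = run_pipeline(PipelineConfig(seed=1))
s = result.summary.to_dict()
print(s["n_cells_assigned"], "cells in", s["n_clones"], "clones")
print(s["layer_percentages"]["pooled"])
print(s["potency"])
```

prints

```
1930 cells in 207 clones
{'ONL': 10.26, 'INL': 80.73, 'GCL': 9.02}
{'undetermined_pct': 67.63, 'determined_pct': 32.37, 'committed_pct': 10.14,
 'bi_multipotent_of_determined_pct': 68.66}
```

i.e. this seed's cohort assigned 1930 labeled cells to 207 clones; ~81% of
labeled cells sit in the inner nuclear layer, ~10% are cones in the outer
nuclear layer and ~9% are ganglion cells; two-thirds of progenitors remain
undetermined (their clones contain morphologically unresolved cells), and
among determined progenitors about 69% are bi-/multipotent.

The same run from a shell:

```bash
clonetrack run-all --seed 1 --out out/
clonetrack report out/cells.csv --out out2/   # re-analyse a persisted table
clonetrack validate out/cells.csv
```

Each run writes `cells.csv`, `clones.csv`, `report.json`, ground-truth
sidecars and a log, all embedding the seed and a config hash; identical
configurations are byte-identical.

## Layout

```
src/clonetrack/
  barcode.py    color-code type, serialization, code-space utilities
  simulate.py   synthetic cohorts with ground truth (SimConfig, archetypes)
  imaging.py    section rendering + segmentation (optional image front-end)
  calling.py    presence calling and unlabeled-cell filtering
  assembly.py   clone assembly, dispersion, collision probability
  classify.py   cell typing and clone layer/potency classes
  report.py     cohort statistics, LOESS fit, size densities
  plotting.py   optional figures
  pipeline.py   stage orchestration; tables.py: CSV format + validation
  cli.py        `clonetrack` command
```

See `docs/methods.md` for the underlying model, parameter choices and known
limitations.
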