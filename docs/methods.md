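# Methods

## The labeling model

Combinatorial lineage tracing labels a progenitor with a random subset of 12
integrable constructs: six fluorescent proteins, each in a nucleus- or
cytoplasm-targeted form. Uptake is modeled as 12 independent Bernoulli events
with per-construct probability `p_uptake`; no copy-number or dosage dimension
is modeled (presence/absence only). A progenitor with an all-absent draw is
retained but invisible to tracing. All progeny of a progenitor inherit its
code exactly — integration is assumed stable, and non-integrated plasmid is
assumed fully diluted by analysis time, so it simply never appears.

The canonical code is the 12-bit (channel × compartment) presence matrix,
serialized as `N:d1..d6/C:d1..d6` with digit *i* marking channel *i*. A
6-number projection (presence in either compartment) is available for display
only; it is not the clone key, because clones sharing fluorophores can differ
by compartment.

## Presence calling and its observability limit

A compartment measurement is positive when it exceeds the channel background
by `k` standard deviations (`k = 3` by default; the threshold rule and the
nuclear ratio are deliberate artifact choices — the original analyses of this
kind were pseudo-automated with manual curation, which is not reproducible).
A nuclear call additionally requires `I_nuc / I_cyt ≥ nuclear_ratio_min`
(default 2.0) unless the cytoplasm is itself negative; nuclear candidates
vetoed by the ratio are flagged "ambiguous" rather than silently dropped.

The ratio gate has a structural consequence: a channel genuinely present in
*both* compartments measures a ratio near 1 and is therefore called
cytoplasm-only. Clonal identity is thus observable only up to the map
`true code → noise-free called code` (implemented as
`calling.expected_called_code`). The synthetic generator enforces
within-embryo uniqueness of the *observable* code, so distinct progenitors
remain distinguishable after calling; with noise-free intensities the
assembled partition then equals the ground-truth partition exactly (adjusted
Rand index 1.0), and called codes equal true codes for every cell whose code
has no dual-compartment channel.

## Collision risk

Two progenitors drawing the same code merge silently — the method's known
failure mode. Under Bernoulli uptake the nonempty codes are nonuniform:
`q(c) = p^|c|(1−p)^(12−|c|) / (1−(1−p)^12)`. Because codes of equal
complexity are equiprobable, power sums over the 4095-code space collapse to
12 binomial terms, giving closed forms for up to three progenitors
(`P₂ = S₂`, `P₃ = 3S₂ − 2S₃` with `S_j = Σ_c q(c)^j`); larger cohorts use a
conditioned Monte-Carlo estimator reported with its standard error. The
pairwise form is verified against full enumeration of the code space.

## The synthetic cohort

The generator emulates a five-embryo study analysed at a stage where cones,
horizontal cells, amacrine cells, radial glia and retinal ganglion cells
(RGCs) are morphologically recognisable, rods are absent and bipolar cells
have not yet differentiated; unresolvable inner-nuclear-layer cells are
"undefined". Defaults are the emulated study's conditions:

* **Cohort structure** — per-embryo targeted-progenitor counts
  `(18, 28, 41, 55, 63)` (≈205 progenitors; counts vary across embryos so
  that clone number tracks sample size, as reported), `p_uptake = 0.25`
  (typical code complexity ~3, matching the 2–3-construct example codes),
  3.4% of analysed cells rendered unassignable (background-only labeling),
  mirroring the 73-of-2123 excluded cells whose exclusion cause is not
  stated in the source study.
* **Clone archetypes** — clones are drawn from a joint table of
  (layer-class, potency-class, composition template) archetypes whose
  weights are the published per-class clone counts of a 203-clone cohort
  (31 trilaminar / 30 GCL+INL / 32 INL+ONL / 4 GCL+ONL / 86 INL / 9 ONL /
  11 GCL; 131 undetermined, 28+24 bi-/multipotent, 20 committed). Each
  archetype guarantees one cell per required type (which realises its layer
  and potency class) and fills the rest i.i.d. from per-archetype type
  probabilities calibrated so the expected per-layer cell totals reproduce
  the published table (e.g. ~2 cones and ~2 RGCs in a 25-cell trilaminar
  clone; pooled expectation INL 78.8% / ONL 11.3% / GCL 9.9%).
* **Clone size** — minimum feasible size (the number of required types)
  plus a negative-binomial excess (shape 2) with mean set so the expected
  clone size equals the class mean (25.1 trilaminar, 2.9 cone-only, 2.6
  RGC-only, ...). The shifted form was chosen over a zero-truncated law
  because it honours both the structural minimum and the target mean
  exactly.
* **Geometry** — micrometre coordinates; 50 µm sections as half-open
  intervals `[50k, 50(k+1))`; each clone is a radial column anchored at a
  uniform tangential position with Normal(0, 20 µm) per-cell jitter, so
  clones near a boundary span adjacent sections; radial soma depth is drawn
  within disjoint per-layer depth bands (GCL 0.02–0.18, INL 0.30–0.80, ONL
  0.86–0.98 of retinal thickness; gaps stand for the plexiform layers).
* **Intensities** — each of the 12 measurements is Gaussian background
  (10 ± 2) plus, when the construct is present, Gaussian signal (100 ± 15),
  clipped at 0; constructs light only their own compartment.

What the generator does **not** emulate: spectral bleed-through between
fluorophores, per-embryo brightness variation, touching/overlapping cells,
central-retina gradients, lineage structure within clones, or any intensity
dosage information. Passing tests therefore demonstrate the pipeline's
correctness under the stated statistical model, not robustness to real
microscopy artifacts.

## Cell typing and clone classification

Typing is a deterministic cascade on laminar position and morphology: ONL →
cone; GCL with a large soma → RGC (small GCL somas — candidate displaced
amacrines — stay undefined); INL spanning the retina → radial glia; INL soma
within the inner quarter of the layer with processes toward the inner
plexiform layer → amacrine; within the outer quarter toward the outer
plexiform layer → horizontal; anything else undefined. The 0.25/0.75 depth
cutoffs operationalise the qualitative "inner/outer boundary" and are
config-exposed.

Potency counts distinct differentiated types among {cone, horizontal,
amacrine, RGC}; radial glia is excluded by default (flag available) since
potency in such studies is defined over those four types. Committed requires
a single type *and* no undefined members; any clone whose identity could be
hidden by undefined cells is undetermined.

## Curve analyses

`size_count_fit` smooths the (size, count) scatter of clone sizes with a
locally-weighted polynomial regression written from first principles: at each
grid point the span fraction (default 0.75) of nearest data points is tricube
weighted and a degree-2 polynomial is solved by weighted least squares via
the closed-form linear-smoother row; windows with fewer points than
parameters are widened with a warning. Pointwise standard errors are
`σ̂ · ‖r(x₀)‖₂` with the residual scale estimated globally using
`n − tr(L)` effective degrees of freedom; the 95% band is ±1.96 SE. The
reported mean-SE-up-to-size profile quantifies over which size range the fit
is best supported. The implementation is tested for exact equality with an
independent brute-force weighted polynomial solve, and reproduces constant
and linear inputs exactly.

`size_density_by_potency` uses a Gaussian KDE with Silverman bandwidth per
potency class (bi- and multipotent pooled, as such densities are usually
displayed); classes with fewer than two distinct sizes are omitted with a
warning, and the default grid extends five bandwidths past the extremes so
each curve integrates to 1 within 10⁻³.

SEM throughout is the sample standard deviation (n−1 denominator) over √n;
a single-clone class reports SEM 0 by convention. Displayed rounding follows
the conventions of the emulated study: percentages to 2 decimals, means and
SEMs to 1. The fraction of clones containing RGCs is reported together with
its complement, since either direction may be the quantity of interest.

## Imaging front-end

Synthetic sections render each cell as a blurred disk (soma radius 7 px)
with a concentric nucleus (3 px): nuclear constructs deposit signal in the
nucleus disk, cytoplasmic ones in the annulus; the stack is blurred with an
isotropic Gaussian PSF (σ = 1 px) and Gaussian background is added.
Segmentation thresholds each channel at background + k·SD (robust
median/MAD background estimate; Otsu fallback when the background variance
is zero), takes the union across channels, labels connected components and
fills holes (a cell with no nuclear construct thresholds as an annulus). The
nucleus mask is the component's erosion core, eroded adaptively down to the
expected nucleus scale; the cytoplasm is measured in a fixed-width ring
offset two pixels from the core — deliberately independent of the component
extent, because a nuclear-only cell's dark cytoplasm must still be measured
to read negative. Touching-cell separation (watershed) is intentionally out
of scope; densities are kept low. At high SNR and low density the
render → segment → call round trip recovers ≥99% of codes.

## Numerical and degenerate-input conventions

* Presence calling uses strict inequality, so an intensity exactly at the
  threshold is negative.
* `collision_probability` rejects `p = 0` (no labeled clones exist) and
  returns 1 for `p = 1, n ≥ 2` (only the all-present code remains).
* Empty clones are rejected by both classifiers; empty cell tables are
  rejected by the reporting layer.
* LOESS windows at duplicate-x degeneracies fall back to uniform weights;
  the effective-df denominator is floored at 1.
* All randomness flows through `numpy.random.Generator` seeded from the
  run seed via `SeedSequence` spawning (one stream per embryo), so cohorts
  are reproducible and byte-identical across runs.

## Problem sizes

Default analyses run on cohorts of ~2000 cells / ~200 clones across five
embryos; property tests use 300–4000-draw simulations, the collision
Monte-Carlo uses 40k–60k cohort draws, and imaging round trips use 49-cell
sections at 440×440 px — all chosen to give stable statistics at
interactive runtimes.

## Known limitations

* Clone identity is purely code-based; spatially separate same-code groups
  are one clone (an optional tangential-gap split is available but off by
  default, as spatial splitting is an undocumented extension of the method).
* The nuclear-ratio gate trades dual-compartment sensitivity for
  bleed-through robustness (see "observability limit" above).
* The collision model assumes exchangeable progenitors and independent
  uptake; real electroporation may correlate construct uptake, which would
  raise collision risk above the reported values.
* Morphological typing is only as good as its features; the generator's
  zero-noise features make typing exact, which upper-bounds real accuracy.
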