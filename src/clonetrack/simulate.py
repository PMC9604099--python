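"""Synthetic multicolor lineage-tracing cohorts with known ground truth.

No raw data are deposited for this kind of clonal study, so the pipeline is
exercised on simulated cohorts that reproduce the structure the analysis
assumes: a handful of electroporated embryos, each with a few dozen targeted
retinal progenitors that independently take up any subset of 12 integrable
constructs (6 fluorophores x nucleus/cytoplasm) and pass the resulting color
code to their progeny; progeny arranged in radial columns with limited
tangential dispersion across 50 um sections; cell types (and hence nuclear
layers) drawn from clone "archetypes" that jointly fix the clone's
layer-distribution class, its progenitor potency class and its expected size.

The default archetype table is calibrated so that the expected cohort matches
the study conditions: ~203 clones and ~2050 labeled cells over 5 embryos,
layer shares near INL 78.8% / ONL 11.3% / GCL 9.9%, the seven
layer-distribution classes at 15.3/14.8/15.8/2.0/42.4/4.4/5.4%, and mean
clone sizes of 25.1 (trilaminar), 2.9 (cone-only) and 2.6 (RGC-only) cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .barcode import CHANNEL_NAMES, N_CONSTRUCTS, ColorCode, serialize_code
from .classify import CELL_TYPES, LAYER_CLASSES, POTENCY_CLASSES, TYPE_TO_LAYER

__all__ = [
    "IntensityNoise",
    "CloneArchetype",
    "SimConfig",
    "EmbryoDataset",
    "GroundTruth",
    "ConfigError",
    "default_archetypes",
    "simulate_uptake",
    "simulate_clone",
    "place_clone",
    "render_intensities",
    "simulate_cohort",
    "CELL_TABLE_COLUMNS",
    "LAYER_DEPTH_BANDS",
]

#: Radial depth bands (fraction of retinal thickness, 0 = basal/inner,
#: 1 = apical/outer) occupied by somas of each nuclear layer.  Disjoint by
#: construction; the gaps stand for the plexiform layers.
LAYER_DEPTH_BANDS = {
    "GCL": (0.02, 0.18),
    "INL": (0.30, 0.80),
    "ONL": (0.86, 0.98),
}


class ConfigError(ValueError):
    """Invalid simulation configuration; ``.fields`` names the offenders."""

    def __init__(self, problems: dict[str, str]):
        self.fields = problems
        msg = "; ".join(f"{k}: {v}" for k, v in sorted(problems.items()))
        super().__init__(f"invalid simulation config -- {msg}")


@dataclass(frozen=True)
class IntensityNoise:
    """Gaussian intensity model for one channel/compartment measurement.

    A present construct reads ``background + signal`` (both Gaussian draws),
    an absent one reads pure background; negative draws are clipped to 0.
    """

    background_mean: float = 10.0
    background_sd: float = 2.0
    signal_mean: float = 100.0
    signal_sd: float = 15.0


@dataclass(frozen=True)
class CloneArchetype:
    """One clone-generating program: who is in the clone and how big it is.

    ``required_types`` get one guaranteed cell each (they realise the
    archetype's layer class and potency class); the remaining cells are drawn
    i.i.d. from ``filler_probs``.  Clone size is ``len(required_types)`` plus
    a negative-binomial excess with mean ``mean_size - len(required_types)``
    and shape ``dispersion``, so the expected size is exactly ``mean_size``.
    """

    name: str
    layer_class: str
    potency_class: str
    required_types: tuple[str, ...]
    filler_probs: dict[str, float]
    weight: float
    mean_size: float
    dispersion: float = 2.0

    @property
    def min_size(self) -> int:
        return len(self.required_types)


def default_archetypes() -> tuple[CloneArchetype, ...]:
    """Archetype table reproducing the study's clone-class and size structure.

    Weights are the per-class clone counts of a 203-clone cohort; filler
    probabilities are set so each archetype's expected per-layer cell counts
    reproduce the printed per-class cell totals (e.g. 779 cells in 31
    trilaminar clones with ~2 cones and ~2 RGCs each).
    """
    a = CloneArchetype
    return (
        a("tri_multipotent", "trilaminar", "multipotent",
          ("cone_photoreceptor", "RGC", "horizontal"),
          {"cone_photoreceptor": 0.045, "RGC": 0.045, "horizontal": 0.05,
           "amacrine": 0.09, "radial_glia": 0.05, "undefined": 0.72},
          weight=24, mean_size=25.1),
        a("tri_bipotent", "trilaminar", "bipotent",
          ("cone_photoreceptor", "RGC", "undefined"),
          {"cone_photoreceptor": 0.045, "RGC": 0.045, "undefined": 0.91},
          weight=7, mean_size=25.1),
        a("gcl_inl_multipotent", "GCL+INL", "multipotent",
          ("RGC", "amacrine", "horizontal"),
          {"RGC": 0.364, "amacrine": 0.2, "horizontal": 0.1, "undefined": 0.336},
          weight=2, mean_size=9.67),
        a("gcl_inl_bipotent", "GCL+INL", "bipotent",
          ("RGC", "amacrine"),
          {"RGC": 0.317, "amacrine": 0.3, "undefined": 0.383},
          weight=4, mean_size=9.67),
        a("gcl_inl_undetermined", "GCL+INL", "undetermined",
          ("RGC", "undefined"),
          {"RGC": 0.317, "undefined": 0.683},
          weight=24, mean_size=9.67),
        a("inl_onl_multipotent", "INL+ONL", "multipotent",
          ("cone_photoreceptor", "horizontal", "amacrine"),
          {"cone_photoreceptor": 0.489, "horizontal": 0.15, "amacrine": 0.15,
           "undefined": 0.211},
          weight=2, mean_size=9.59),
        a("inl_onl_bipotent", "INL+ONL", "bipotent",
          ("cone_photoreceptor", "horizontal"),
          {"cone_photoreceptor": 0.424, "horizontal": 0.2, "undefined": 0.376},
          weight=4, mean_size=9.59),
        a("inl_onl_undetermined", "INL+ONL", "undetermined",
          ("cone_photoreceptor", "undefined"),
          {"cone_photoreceptor": 0.424, "undefined": 0.576},
          weight=26, mean_size=9.59),
        a("gcl_onl_bipotent", "GCL+ONL", "bipotent",
          ("cone_photoreceptor", "RGC"),
          {"cone_photoreceptor": 0.556, "RGC": 0.444},
          weight=4, mean_size=4.25),
        a("inl_bipotent", "INL_only", "bipotent",
          ("horizontal", "amacrine"),
          {"horizontal": 0.3, "amacrine": 0.3, "undefined": 0.4},
          weight=5, mean_size=7.0),
        a("inl_undetermined", "INL_only", "undetermined",
          ("undefined",),
          {"undefined": 0.8, "amacrine": 0.1, "radial_glia": 0.1},
          weight=81, mean_size=7.0),
        a("onl_committed", "ONL_only", "committed",
          ("cone_photoreceptor",),
          {"cone_photoreceptor": 1.0},
          weight=9, mean_size=2.89),
        a("gcl_committed", "GCL_only", "committed",
          ("RGC",),
          {"RGC": 1.0},
          weight=11, mean_size=2.64),
    )


@dataclass(frozen=True)
class SimConfig:
    """Full parameterisation of a synthetic cohort.

    Defaults are the study conditions: five embryos, per-embryo progenitor
    counts that vary (so clone number tracks sample size), independent
    construct uptake at ``p_uptake`` per construct, the default archetype
    table, 50 um sections and modest tangential jitter around each clone's
    column.  ``excluded_fraction`` adds analysed-but-unassignable cells
    (background-only labeling) at the study's 73-of-2123 rate.
    """

    n_embryos: int = 5
    n_targeted_progenitors_per_embryo: int | Sequence[int] = (18, 28, 41, 55, 63)
    p_uptake: float = 0.25
    archetypes: tuple[CloneArchetype, ...] = field(default_factory=default_archetypes)
    layer_mixture: dict[str, float] = field(
        default_factory=lambda: {"ONL": 0.1132, "INL": 0.7883, "GCL": 0.0985}
    )
    excluded_fraction: float = 73.0 / 2123.0
    section_thickness_um: float = 50.0
    column_sigma_tangential_um: float = 20.0
    n_sections_per_embryo: int = 30
    morphology_jitter_sd: float = 0.0
    intensity_noise: IntensityNoise = field(default_factory=IntensityNoise)
    ensure_unique_codes: bool = True
    seed: int = 0

    # -- derived mixtures ---------------------------------------------------

    def _weights(self) -> np.ndarray:
        w = np.array([a.weight for a in self.archetypes], dtype=float)
        return w / w.sum()

    def potency_mixture(self) -> dict[str, float]:
        """Marginal potency-class probabilities implied by the archetypes."""
        out = {c: 0.0 for c in POTENCY_CLASSES}
        for a, w in zip(self.archetypes, self._weights()):
            out[a.potency_class] += w
        return out

    def layer_class_mixture(self) -> dict[str, float]:
        """Marginal layer-class probabilities implied by the archetypes."""
        out = {c: 0.0 for c in LAYER_CLASSES}
        for a, w in zip(self.archetypes, self._weights()):
            out[a.layer_class] += w
        return out

    def expected_type_mixture(self) -> dict[str, float]:
        """Expected per-cell type probabilities over the whole cohort."""
        counts = {t: 0.0 for t in CELL_TYPES}
        for a, w in zip(self.archetypes, self._weights()):
            excess = a.mean_size - a.min_size
            for t in a.required_types:
                counts[t] += w
            for t, p in a.filler_probs.items():
                counts[t] += w * excess * p
        total = sum(counts.values())
        return {t: c / total for t, c in counts.items()}

    def expected_layer_mixture(self) -> dict[str, float]:
        """Expected per-cell layer probabilities over the whole cohort."""
        out = {"ONL": 0.0, "INL": 0.0, "GCL": 0.0}
        for t, p in self.expected_type_mixture().items():
            out[TYPE_TO_LAYER[t]] += p
        return out

    def progenitor_counts(self) -> list[int]:
        n = self.n_targeted_progenitors_per_embryo
        if isinstance(n, int):
            return [n] * self.n_embryos
        counts = list(n)
        if len(counts) != self.n_embryos:
            raise ConfigError(
                {"n_targeted_progenitors_per_embryo":
                 f"need {self.n_embryos} per-embryo counts, got {len(counts)}"}
            )
        return counts

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        """Raise :class:`ConfigError` listing every offending field."""
        bad: dict[str, str] = {}
        if self.n_embryos < 1:
            bad["n_embryos"] = "must be >= 1"
        if not 0.0 <= self.p_uptake <= 1.0:
            bad["p_uptake"] = "probability must lie in [0, 1]"
        if not 0.0 <= self.excluded_fraction < 1.0:
            bad["excluded_fraction"] = "must lie in [0, 1)"
        if self.section_thickness_um <= 0:
            bad["section_thickness_um"] = "must be positive"
        if self.column_sigma_tangential_um < 0:
            bad["column_sigma_tangential_um"] = "must be >= 0"
        if self.n_sections_per_embryo < 1:
            bad["n_sections_per_embryo"] = "must be >= 1"
        if self.morphology_jitter_sd < 0:
            bad["morphology_jitter_sd"] = "must be >= 0"
        noise = self.intensity_noise
        if noise.background_sd < 0 or noise.signal_sd < 0:
            bad["intensity_noise"] = "standard deviations must be >= 0"
        if abs(sum(self.layer_mixture.values()) - 1.0) > 1e-9:
            bad["layer_mixture"] = "proportions must sum to 1"
        if set(self.layer_mixture) != {"ONL", "INL", "GCL"}:
            bad["layer_mixture"] = "must give ONL, INL and GCL shares"
        if not self.archetypes:
            bad["archetypes"] = "need at least one archetype"
        for a in self.archetypes:
            label = f"archetypes[{a.name}]"
            if a.weight <= 0:
                bad[label] = "weight must be positive"
            if a.mean_size < a.min_size:
                bad[label] = (
                    f"mean_size {a.mean_size} below minimum feasible size "
                    f"{a.min_size}")
            if a.min_size < 1:
                bad[label] = "needs at least one required type"
            if abs(sum(a.filler_probs.values()) - 1.0) > 1e-9:
                bad[label] = "filler probabilities must sum to 1"
            if a.layer_class not in LAYER_CLASSES:
                bad[label] = f"unknown layer class {a.layer_class!r}"
            if a.potency_class not in POTENCY_CLASSES:
                bad[label] = f"unknown potency class {a.potency_class!r}"
            for t in (*a.required_types, *a.filler_probs):
                if t not in CELL_TYPES:
                    bad[label] = f"unknown cell type {t!r}"
        try:
            self.progenitor_counts()
        except ConfigError as e:
            bad.update(e.fields)
        if bad:
            raise ConfigError(bad)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class EmbryoDataset:
    """All cells of one simulated embryo plus acquisition metadata."""

    embryo_id: str
    cells: pd.DataFrame
    n_targeted_progenitors: int
    section_thickness_um: float

    @property
    def n_cells(self) -> int:
        return len(self.cells)


@dataclass
class GroundTruth:
    """Per-cell and per-progenitor truth emitted alongside a cohort.

    ``cells`` maps cell_id -> (embryo_id, clone_id, cell_type, code, layer,
    excluded); ``progenitors`` maps clone_id -> (embryo_id, code, labeled,
    archetype, potency_class, layer_class, clone_size).
    """

    cells: pd.DataFrame
    progenitors: pd.DataFrame


# ---------------------------------------------------------------------------
# elementary generators


def simulate_uptake(
    n_progenitors: int, p_uptake: float, rng: np.random.Generator
) -> list[ColorCode]:
    """Independent Bernoulli uptake of each of the 12 constructs.

    Progenitors whose draw is all-absent keep their empty code (they are
    retained but effectively invisible to the tracing).
    """
    if not 0.0 <= p_uptake <= 1.0:
        raise ValueError("p_uptake must lie in [0, 1]")
    bits = rng.random((n_progenitors, N_CONSTRUCTS)) < p_uptake
    return [ColorCode.from_bits(row) for row in bits]


def _draw_size(archetype: CloneArchetype, rng: np.random.Generator) -> int:
    excess_mean = archetype.mean_size - archetype.min_size
    if excess_mean <= 0:
        return archetype.min_size
    theta = archetype.dispersion
    excess = rng.negative_binomial(theta, theta / (theta + excess_mean))
    return archetype.min_size + int(excess)


def simulate_clone(
    archetype: CloneArchetype | str,
    rng: np.random.Generator,
    archetypes: Sequence[CloneArchetype] | None = None,
    size: int | None = None,
) -> list[str]:
    """Draw the cell-type composition of one clone.

    ``archetype`` may be a :class:`CloneArchetype` or a potency-class name,
    in which case an archetype of that class is drawn from ``archetypes``
    (default table) with probability proportional to its weight.  Returns the
    member cell types; one cell per required type is guaranteed, the rest are
    filler draws, so the clone always realises its layer and potency class.
    """
    if isinstance(archetype, str):
        pool = [a for a in (archetypes or default_archetypes())
                if a.potency_class == archetype]
        if not pool:
            raise ValueError(f"unknown potency class {archetype!r}")
        w = np.array([a.weight for a in pool], dtype=float)
        archetype = pool[rng.choice(len(pool), p=w / w.sum())]
    n = _draw_size(archetype, rng) if size is None else int(size)
    if n < archetype.min_size:
        raise ValueError(
            f"size {n} below minimum {archetype.min_size} for {archetype.name}")
    types = list(archetype.required_types)
    n_fill = n - len(types)
    if n_fill:
        filler_types = list(archetype.filler_probs)
        p = np.array([archetype.filler_probs[t] for t in filler_types])
        counts = rng.multinomial(n_fill, p / p.sum())
        for t, c in zip(filler_types, counts):
            types.extend([t] * int(c))
    rng.shuffle(types)
    return types


_MORPHOLOGY = {
    # type: (depth range within layer, soma, apical, basal, orientation)
    "cone_photoreceptor": ((0.0, 1.0), "small", 0.05, 0.05, "none"),
    "horizontal": ((0.80, 1.0), "small", 0.10, 0.02, "toward_OPL"),
    "amacrine": ((0.0, 0.20), "small", 0.02, 0.10, "toward_IPL"),
    "radial_glia": ((0.20, 0.80), "small", 1.0, 1.0, "spanning"),
    "RGC": ((0.0, 1.0), "large", 0.02, 0.30, "toward_IPL"),
    "undefined": ((0.30, 0.70), "small", 0.0, 0.0, "none"),
}


def _morphology_row(cell_type: str, rng: np.random.Generator,
                    jitter_sd: float) -> dict:
    (lo, hi), soma, apical, basal, orient = _MORPHOLOGY[cell_type]
    depth = rng.uniform(lo, hi)
    if jitter_sd > 0:
        depth = float(np.clip(depth + rng.normal(0.0, jitter_sd), 0.0, 1.0))
    return {
        "layer": TYPE_TO_LAYER[cell_type],
        "soma_relative_depth": depth,
        "soma_size": soma,
        "apical_process_extent": apical,
        "basal_process_extent": basal,
        "process_orientation": orient,
    }


def place_clone(
    cells: list[dict],
    section_thickness_um: float,
    column_sigma_tangential_um: float,
    rng: np.random.Generator,
    tangential_extent_um: float | None = None,
    anchor_um: float | None = None,
) -> list[dict]:
    """Position a clone's cells as a radial column with tangential jitter.

    The clone is anchored at one tangential coordinate; each cell scatters
    around it with Normal(0, sigma) offsets, so clones near a section
    boundary span adjacent 50 um sections.  Radial position comes from the
    cell's layer depth band.  Sections are half-open ``[k*t, (k+1)*t)``.
    """
    if tangential_extent_um is None:
        tangential_extent_um = 30 * section_thickness_um
    if anchor_um is None:
        anchor_um = rng.uniform(0.0, tangential_extent_um)
    eps = 1e-9
    out = []
    for cell in cells:
        t = anchor_um + rng.normal(0.0, column_sigma_tangential_um)
        t = float(np.clip(t, 0.0, tangential_extent_um - eps))
        lo, hi = LAYER_DEPTH_BANDS[cell["layer"]]
        depth = lo + cell["soma_relative_depth"] * (hi - lo)
        placed = dict(cell)
        placed["tangential_um"] = t
        placed["radial_depth_frac"] = depth
        placed["section_index"] = int(math.floor(t / section_thickness_um))
        out.append(placed)
    return out


def render_intensities(
    code: ColorCode,
    noise: IntensityNoise,
    rng: np.random.Generator,
) -> dict[str, float]:
    """Per-channel, per-compartment mean intensities for one cell.

    A construct present in the code adds a Gaussian signal to its own
    compartment's measurement only; every measurement also carries Gaussian
    background.  Values are clipped at 0.  Background statistics are reported
    alongside, as an imaging pipeline would estimate them per channel.
    """
    out: dict[str, float] = {}
    for i, name in enumerate(CHANNEL_NAMES):
        for comp_label, present in (("nuc", code.nucleus[i]),
                                    ("cyt", code.cytoplasm[i])):
            value = rng.normal(noise.background_mean, noise.background_sd)
            if present:
                value += rng.normal(noise.signal_mean, noise.signal_sd)
            out[f"{name}_{comp_label}"] = float(max(value, 0.0))
        out[f"bg_mean_{name}"] = noise.background_mean
        out[f"bg_sd_{name}"] = noise.background_sd
    return out


# ---------------------------------------------------------------------------
# cohort assembly

_MORPH_COLUMNS = [
    "layer", "soma_size", "soma_relative_depth",
    "apical_process_extent", "basal_process_extent", "process_orientation",
]

CELL_TABLE_COLUMNS = (
    ["cell_id", "embryo_id", "section_index", "tangential_um",
     "radial_depth_frac"]
    + _MORPH_COLUMNS
    + [f"{n}_{c}" for n in CHANNEL_NAMES for c in ("nuc", "cyt")]
    + [f"bg_mean_{n}" for n in CHANNEL_NAMES]
    + [f"bg_sd_{n}" for n in CHANNEL_NAMES]
    + ["code", "cell_type"]
)


def _unique_codes(
    n: int, p_uptake: float, rng: np.random.Generator,
    noise: IntensityNoise,
) -> list[ColorCode]:
    """Uptake draws unique within an embryo among nonempty codes.

    Uniqueness is enforced on the *observable* code — the image of the true
    code under noise-free presence calling — because clones are only
    distinguishable up to that map (a channel present in both compartments
    is called cytoplasm-only by the nuclear-ratio rule).
    """
    from .calling import expected_called_code

    def observable(c: ColorCode) -> ColorCode:
        return expected_called_code(c, noise.background_mean,
                                    noise.signal_mean,
                                    background_sd=noise.background_sd)

    codes = simulate_uptake(n, p_uptake, rng)
    seen: set[ColorCode] = set()
    for idx, code in enumerate(codes):
        tries = 0
        while not code.is_empty and observable(code) in seen:
            code = simulate_uptake(1, p_uptake, rng)[0]
            tries += 1
            if tries > 10_000:
                raise RuntimeError(
                    "cannot draw distinct codes: code space exhausted for "
                    f"{n} progenitors at p_uptake={p_uptake}")
        codes[idx] = code
        if not code.is_empty:
            seen.add(observable(code))
    return codes


def simulate_cohort(config: SimConfig) -> tuple[list[EmbryoDataset], GroundTruth]:
    """Generate a full cohort of embryos plus its ground truth.

    Deterministic given ``config.seed``.  Cell tables carry spatial
    coordinates, morphology features and rendered intensities; the ``code``
    and ``cell_type`` columns are left empty for the analysis pipeline to
    fill.  Ground truth records the true clone partition, codes and types,
    including the unassignable "excluded" cells mixed into each embryo.
    """
    config.validate()
    seed_seq = np.random.SeedSequence(config.seed)
    embryo_seeds = seed_seq.spawn(config.n_embryos)
    weights = config._weights()

    embryos: list[EmbryoDataset] = []
    truth_cells: list[dict] = []
    truth_progenitors: list[dict] = []

    for e_idx, (n_prog, child_seq) in enumerate(
            zip(config.progenitor_counts(), embryo_seeds)):
        rng = np.random.default_rng(child_seq)
        embryo_id = f"E{e_idx + 1}"
        extent = config.n_sections_per_embryo * config.section_thickness_um

        if config.ensure_unique_codes:
            codes = _unique_codes(n_prog, config.p_uptake, rng,
                                  config.intensity_noise)
        else:
            codes = simulate_uptake(n_prog, config.p_uptake, rng)

        rows: list[dict] = []
        cell_counter = 0
        for p_idx, code in enumerate(codes):
            clone_id = f"{embryo_id}_p{p_idx + 1:03d}"
            labeled = not code.is_empty
            archetype = config.archetypes[rng.choice(len(weights), p=weights)]
            record = {
                "clone_id": clone_id,
                "embryo_id": embryo_id,
                "code": serialize_code(code),
                "labeled": labeled,
                "archetype": archetype.name,
                "potency_class": archetype.potency_class,
                "layer_class": archetype.layer_class,
                "clone_size": 0,
            }
            if not labeled:
                # unlabeled progenitor: progeny carry no trace, emit nothing
                truth_progenitors.append(record)
                continue
            types = simulate_clone(archetype, rng)
            cells = [_morphology_row(t, rng, config.morphology_jitter_sd)
                     for t in types]
            placed = place_clone(
                cells, config.section_thickness_um,
                config.column_sigma_tangential_um, rng,
                tangential_extent_um=extent)
            record["clone_size"] = len(placed)
            truth_progenitors.append(record)
            for cell_type, cell in zip(types, placed):
                cell_counter += 1
                cell_id = f"{embryo_id}_c{cell_counter:05d}"
                row = {"cell_id": cell_id, "embryo_id": embryo_id, **cell}
                row.update(render_intensities(code, config.intensity_noise, rng))
                row["code"] = ""
                row["cell_type"] = ""
                rows.append(row)
                truth_cells.append({
                    "cell_id": cell_id, "embryo_id": embryo_id,
                    "clone_id": clone_id, "cell_type": cell_type,
                    "layer": cell["layer"], "code": serialize_code(code),
                    "excluded": False,
                })

        # analysed-but-unassignable cells: labeling too faint/ambiguous to
        # carry a code; rendered as pure background so calling excludes them
        n_assigned = cell_counter
        f = config.excluded_fraction
        n_excluded = int(round(n_assigned * f / (1.0 - f))) if f > 0 else 0
        layer_names = list(config.layer_mixture)
        layer_p = np.array([config.layer_mixture[l] for l in layer_names])
        empty = ColorCode.empty()
        for _ in range(n_excluded):
            cell_counter += 1
            layer = layer_names[rng.choice(len(layer_names), p=layer_p)]
            proxy_type = {"ONL": "cone_photoreceptor", "INL": "undefined",
                          "GCL": "RGC"}[layer]
            cell = _morphology_row(proxy_type, rng, config.morphology_jitter_sd)
            placed = place_clone(
                [cell], config.section_thickness_um,
                config.column_sigma_tangential_um, rng,
                tangential_extent_um=extent)[0]
            cell_id = f"{embryo_id}_c{cell_counter:05d}"
            row = {"cell_id": cell_id, "embryo_id": embryo_id, **placed}
            row.update(render_intensities(empty, config.intensity_noise, rng))
            row["code"] = ""
            row["cell_type"] = ""
            rows.append(row)
            truth_cells.append({
                "cell_id": cell_id, "embryo_id": embryo_id,
                "clone_id": None, "cell_type": proxy_type,
                "layer": placed["layer"], "code": serialize_code(empty),
                "excluded": True,
            })

        cells_df = pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)
        embryos.append(EmbryoDataset(
            embryo_id=embryo_id, cells=cells_df,
            n_targeted_progenitors=n_prog,
            section_thickness_um=config.section_thickness_um))

    truth = GroundTruth(
        cells=pd.DataFrame(
            truth_cells,
            columns=["cell_id", "embryo_id", "clone_id", "cell_type",
                     "layer", "code", "excluded"]),
        progenitors=pd.DataFrame(
            truth_progenitors,
            columns=["clone_id", "embryo_id", "code", "labeled", "archetype",
                     "potency_class", "layer_class", "clone_size"]),
    )
    return embryos, truth


def cohort_frame(embryos: list[EmbryoDataset]) -> pd.DataFrame:
    """Concatenate per-embryo cell tables into one cohort table."""
    return pd.concat([e.cells for e in embryos], ignore_index=True)
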