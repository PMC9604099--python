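"""Morphology-based cell typing and clone classification.

At the analysed stage of chick retinogenesis the recognisable cell types are
cone photoreceptors (ONL), horizontal and amacrine interneurons and radial
glia (INL), and retinal ganglion cells (GCL); rods and bipolar cells have not
yet differentiated.  Cells in the INL whose morphology does not resolve a type
are recorded as ``undefined`` (immature or migrating cells).

Clones are classified two ways:

* by the set of nuclear layers their members occupy (seven classes:
  trilaminar, three bilaminar combinations, three layer-restricted classes);
* by the inferred potency of their progenitor, from the number of distinct
  differentiated types among the members (multipotent >= 3, bipotent == 2,
  committed == single type with no undefined members, otherwise
  undetermined).
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "CELL_TYPES",
    "DIFFERENTIATED_TYPES",
    "LAYERS",
    "LAYER_CLASSES",
    "POTENCY_CLASSES",
    "TYPE_TO_LAYER",
    "MorphologyFeatures",
    "classify_cell_type",
    "classify_clone_layers",
    "classify_clone_potency",
    "has_rgc",
]

LAYERS = ("ONL", "INL", "GCL")

CELL_TYPES = (
    "cone_photoreceptor",
    "horizontal",
    "amacrine",
    "radial_glia",
    "RGC",
    "undefined",
)

#: The four types counted when inferring progenitor potency.
DIFFERENTIATED_TYPES = frozenset(
    {"cone_photoreceptor", "horizontal", "amacrine", "RGC"}
)

#: Deterministic laminar home of each type at this stage.
TYPE_TO_LAYER = {
    "cone_photoreceptor": "ONL",
    "horizontal": "INL",
    "amacrine": "INL",
    "radial_glia": "INL",
    "undefined": "INL",
    "RGC": "GCL",
}

LAYER_CLASSES = (
    "trilaminar",
    "GCL+INL",
    "INL+ONL",
    "GCL+ONL",
    "INL_only",
    "ONL_only",
    "GCL_only",
)

POTENCY_CLASSES = ("multipotent", "bipotent", "committed", "undetermined")

_LAYERSET_TO_CLASS = {
    frozenset({"ONL", "INL", "GCL"}): "trilaminar",
    frozenset({"GCL", "INL"}): "GCL+INL",
    frozenset({"INL", "ONL"}): "INL+ONL",
    frozenset({"GCL", "ONL"}): "GCL+ONL",
    frozenset({"INL"}): "INL_only",
    frozenset({"ONL"}): "ONL_only",
    frozenset({"GCL"}): "GCL_only",
}


@dataclass(frozen=True)
class MorphologyFeatures:
    """Per-cell morphology descriptors used by the typing cascade.

    Parameters
    ----------
    layer
        Nuclear layer of the soma: ``"ONL"``, ``"INL"`` or ``"GCL"``.
    soma_relative_depth
        Soma position within its layer, 0 (inner/basal boundary) to
        1 (outer/apical boundary).
    soma_size
        ``"small"`` or ``"large"`` — large somas in the GCL mark ganglion
        cells as opposed to displaced amacrines.
    apical_process_extent, basal_process_extent
        Process reach as a fraction of retinal thickness.
    process_orientation
        ``"toward_IPL"``, ``"toward_OPL"``, ``"spanning"`` or ``"none"``.
    """

    layer: str
    soma_relative_depth: float = 0.5
    soma_size: str = "small"
    apical_process_extent: float = 0.0
    basal_process_extent: float = 0.0
    process_orientation: str = "none"

    def __post_init__(self) -> None:
        if self.layer not in LAYERS:
            raise ValueError(f"unknown layer {self.layer!r}")
        for name in ("soma_relative_depth", "apical_process_extent",
                     "basal_process_extent"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")


def classify_cell_type(
    f: MorphologyFeatures,
    inner_depth_max: float = 0.25,
    outer_depth_min: float = 0.75,
) -> str:
    """Assign a cell type from laminar position and morphology.

    Rule cascade: any ONL soma is a cone photoreceptor (no rods at this
    stage); a large GCL soma is an RGC; an INL cell spanning the retina is
    radial glia; an INL soma at the inner boundary with processes toward the
    IPL is amacrine; at the outer boundary with processes toward the OPL,
    horizontal; anything else (including small-soma GCL cells, candidate
    displaced amacrines) is left ``undefined``.

    ``inner_depth_max`` / ``outer_depth_min`` place the qualitative
    "inner/outer boundary of the INL" on the 0-1 within-layer depth axis.
    """
    if f.layer == "ONL":
        return "cone_photoreceptor"
    if f.layer == "GCL":
        return "RGC" if f.soma_size == "large" else "undefined"
    # INL
    if f.process_orientation == "spanning":
        return "radial_glia"
    if f.soma_relative_depth <= inner_depth_max and f.process_orientation == "toward_IPL":
        return "amacrine"
    if f.soma_relative_depth >= outer_depth_min and f.process_orientation == "toward_OPL":
        return "horizontal"
    return "undefined"


def classify_clone_layers(member_layers) -> str:
    """Layer-distribution class of a clone from its members' layers."""
    layers = frozenset(member_layers)
    if not layers:
        raise ValueError("cannot classify an empty clone")
    unknown = layers - set(LAYERS)
    if unknown:
        raise ValueError(f"unknown layers in clone: {sorted(unknown)}")
    return _LAYERSET_TO_CLASS[layers]


def classify_clone_potency(
    member_types,
    glia_counts_as_differentiated: bool = False,
) -> str:
    """Infer progenitor potency from the member cell types of one clone.

    Let D be the number of distinct differentiated types present among
    {cone photoreceptor, horizontal, amacrine, RGC} (radial glia is included
    only if ``glia_counts_as_differentiated``).  D >= 3 -> multipotent;
    D == 2 -> bipotent; D == 1 with no undefined members -> committed (a
    uniform clone); otherwise the progenitor's potency is undetermined.
    """
    types = list(member_types)
    if not types:
        raise ValueError("cannot classify an empty clone")
    unknown = set(types) - set(CELL_TYPES)
    if unknown:
        raise ValueError(f"unknown cell types in clone: {sorted(unknown)}")
    differentiated = set(DIFFERENTIATED_TYPES)
    if glia_counts_as_differentiated:
        differentiated.add("radial_glia")
    d = len(set(types) & differentiated)
    if d >= 3:
        return "multipotent"
    if d == 2:
        return "bipotent"
    has_undefined = "undefined" in types
    if d == 1 and not has_undefined:
        return "committed"
    return "undetermined"


def has_rgc(member_types) -> bool:
    """True iff any member of the clone is a retinal ganglion cell."""
    return any(t == "RGC" for t in member_types)
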