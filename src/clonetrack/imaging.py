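"""Synthetic section rendering and segmentation front-end.

Renders positioned labeled cells into six-channel section images (one
channel per fluorophore) and segments such images back into per-cell,
per-compartment mean intensities, closing the loop image -> measurement ->
code.  Somas are Gaussian-blurred disks with a concentric nucleus disk:
nucleus-targeted constructs deposit signal only in the nucleus disk,
cytoplasm-targeted ones only in the surrounding annulus.

Touching-cell separation is out of scope; synthetic densities are kept low
enough for connected components to isolate cells.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage
from skimage import draw, filters, measure, morphology

from .barcode import CHANNEL_NAMES, ColorCode, parse_code

__all__ = [
    "SectionImage",
    "RenderResult",
    "render_section",
    "segment_section",
    "write_section_tiff",
    "read_section_tiff",
]


@dataclass
class SectionImage:
    """Six-channel image of one section.  ``data`` has shape (6, H, W)."""

    data: np.ndarray
    pixel_size_um: float = 1.0
    section_index: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != len(CHANNEL_NAMES):
            raise ValueError(
                f"expected ({len(CHANNEL_NAMES)}, H, W) data, got "
                f"{self.data.shape}")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")


@dataclass
class RenderResult:
    image: SectionImage
    skipped_cell_ids: list[str] = field(default_factory=list)


def render_section(
    cells: pd.DataFrame,
    image_shape: tuple[int, int] = (256, 256),
    psf_sigma_px: float = 1.0,
    soma_radius_px: float = 7.0,
    nucleus_radius_px: float = 3.0,
    background_mean: float = 10.0,
    background_sd: float = 2.0,
    signal_mean: float = 400.0,
    signal_sd: float = 20.0,
    pixel_size_um: float = 1.0,
    section_index: int = 0,
    rng: np.random.Generator | int | None = None,
) -> RenderResult:
    """Render positioned cells into a six-channel section image.

    ``cells`` needs columns ``cell_id``, ``x_px``, ``y_px`` and ``code``
    (canonical code string or :class:`~clonetrack.barcode.ColorCode`).
    Each present construct deposits a per-cell Gaussian signal amplitude in
    its own compartment's region; the stack is then blurred with an
    isotropic Gaussian PSF and Gaussian background noise is added.  Cells
    whose soma does not fit inside the frame are skipped and listed.
    """
    if rng is None or isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    h, w = image_shape
    stack = np.zeros((len(CHANNEL_NAMES), h, w), dtype=float)
    skipped: list[str] = []
    margin = soma_radius_px
    for _, row in cells.iterrows():
        x, y = float(row["x_px"]), float(row["y_px"])
        if not (margin <= x < w - margin and margin <= y < h - margin):
            skipped.append(str(row["cell_id"]))
            continue
        code = row["code"]
        if not isinstance(code, ColorCode):
            code = parse_code(str(code))
        soma_rr, soma_cc = draw.disk((y, x), soma_radius_px, shape=(h, w))
        nuc_rr, nuc_cc = draw.disk((y, x), nucleus_radius_px, shape=(h, w))
        nuc_mask = np.zeros((h, w), dtype=bool)
        nuc_mask[nuc_rr, nuc_cc] = True
        for i in range(len(CHANNEL_NAMES)):
            if code.nucleus[i]:
                amp = max(rng.normal(signal_mean, signal_sd), 0.0)
                stack[i, nuc_rr, nuc_cc] += amp
            if code.cytoplasm[i]:
                amp = max(rng.normal(signal_mean, signal_sd), 0.0)
                annulus = np.zeros((h, w), dtype=bool)
                annulus[soma_rr, soma_cc] = True
                annulus &= ~nuc_mask
                stack[i][annulus] += amp
    if skipped:
        warnings.warn(
            f"{len(skipped)} cell(s) outside the frame were skipped",
            stacklevel=2)
    for i in range(len(CHANNEL_NAMES)):
        if psf_sigma_px > 0:
            stack[i] = ndimage.gaussian_filter(stack[i], psf_sigma_px)
        stack[i] += rng.normal(background_mean, background_sd, size=(h, w))
    np.clip(stack, 0.0, None, out=stack)
    return RenderResult(
        image=SectionImage(stack, pixel_size_um=pixel_size_um,
                           section_index=section_index),
        skipped_cell_ids=skipped)


def _robust_background(channel: np.ndarray) -> tuple[float, float]:
    """Background mean/SD from median and MAD (cells are sparse outliers)."""
    med = float(np.median(channel))
    mad = float(np.median(np.abs(channel - med)))
    return med, 1.4826 * mad


def segment_section(
    image: SectionImage,
    threshold_rule: str = "background_sd",
    k: float = 3.0,
    min_area_px: int = 20,
    nucleus_radius_px: float = 3.0,
    cytoplasm_guard_px: int = 2,
) -> pd.DataFrame:
    """Detect cells and measure per-compartment channel intensities.

    Foreground is the union over channels of per-channel threshold masks:
    with ``threshold_rule="background_sd"`` a channel's threshold is its
    (robustly estimated) background mean + ``k`` background SDs; with
    ``"otsu"`` it is Otsu's threshold.  Connected components of area at
    least ``min_area_px`` are cells.  Each component's nucleus mask is its
    morphological erosion core, eroded down to roughly
    ``nucleus_radius_px`` (the erosion radius adapts to the component's
    equivalent radius, relaxed if it would empty the mask); the cytoplasm
    mask is the component shrunk away from its dim blurred rim, minus a
    ``cytoplasm_guard_px`` dilation of the nucleus core so point-spread
    leakage from the nucleus does not contaminate the cytoplasm reading.

    Returns one row per detection: centroid, area, the 12 compartment mean
    intensities and the per-channel background estimates — directly
    consumable by the presence-calling stage.
    """
    data = image.data
    n_ch, h, w = data.shape
    bg_stats = [_robust_background(data[i]) for i in range(n_ch)]

    fg = np.zeros((h, w), dtype=bool)
    for i in range(n_ch):
        bg_mean, bg_sd = bg_stats[i]
        if threshold_rule == "background_sd" and bg_sd == 0:
            warnings.warn(
                f"channel {CHANNEL_NAMES[i]} has zero background variance; "
                "falling back to Otsu", stacklevel=2)
            rule = "otsu"
        else:
            rule = threshold_rule
        if rule == "background_sd":
            thr = bg_mean + k * bg_sd
        elif rule == "otsu":
            if data[i].min() == data[i].max():
                continue  # constant channel contributes no foreground
            thr = filters.threshold_otsu(data[i])
        else:
            raise ValueError(f"unknown threshold rule {threshold_rule!r}")
        fg |= data[i] > thr

    labels = measure.label(fg, connectivity=2)

    rows = []
    for region in measure.regionprops(labels):
        if region.area < min_area_px:
            continue
        # fill holes: a cell with no nuclear construct thresholds as an
        # annulus, but its nucleus still belongs to the cell
        comp = ndimage.binary_fill_holes(labels == region.label)
        r_eq = math.sqrt(region.area / math.pi)
        r_er = max(int(round(r_eq - nucleus_radius_px)), 1)
        nucleus = comp
        while r_er > 0:
            candidate = morphology.erosion(comp, morphology.disk(r_er))
            if candidate.any():
                nucleus = candidate
                break
            r_er -= 1
        else:
            nucleus = comp  # tiny component: no separable core
        # cytoplasm ring: a fixed-width annulus around the nucleus core,
        # offset by the PSF guard distance.  Deliberately independent of the
        # component extent: a cell with no cytoplasmic construct thresholds
        # as just its nucleus, yet its (dark) cytoplasm must still be
        # measured to read as negative.
        guard = max(cytoplasm_guard_px, 1)
        inner_excl = morphology.dilation(nucleus, morphology.disk(guard))
        cytoplasm = morphology.dilation(nucleus,
                                        morphology.disk(guard + 2)) & ~inner_excl
        if not cytoplasm.any():
            cytoplasm = comp & ~nucleus
        if not cytoplasm.any():
            cytoplasm = comp
        cy, cx = region.centroid
        row = {
            "detection_id": int(region.label),
            "cell_id": f"det{region.label:04d}",
            "x_px": float(cx), "y_px": float(cy),
            "area_px": int(region.area),
        }
        for i, name in enumerate(CHANNEL_NAMES):
            row[f"{name}_nuc"] = float(data[i][nucleus].mean())
            row[f"{name}_cyt"] = float(data[i][cytoplasm].mean())
            row[f"bg_mean_{name}"] = bg_stats[i][0]
            row[f"bg_sd_{name}"] = bg_stats[i][1]
        rows.append(row)
    columns = (["detection_id", "cell_id", "x_px", "y_px", "area_px"]
               + [f"{n}_{c}" for n in CHANNEL_NAMES for c in ("nuc", "cyt")]
               + [f"bg_mean_{n}" for n in CHANNEL_NAMES]
               + [f"bg_sd_{n}" for n in CHANNEL_NAMES])
    return pd.DataFrame(rows, columns=columns)


def write_section_tiff(image: SectionImage, path) -> None:
    """Write a section as a multipage TIFF, one page per channel.

    Pages follow the fixed channel order; each page's description records
    its channel name.
    """
    with tifffile.TiffWriter(path) as tif:
        for i, name in enumerate(CHANNEL_NAMES):
            tif.write(image.data[i].astype(np.float32), description=name,
                      contiguous=False)


def read_section_tiff(path, pixel_size_um: float = 1.0,
                      section_index: int = 0) -> SectionImage:
    """Read a multipage TIFF written by :func:`write_section_tiff`."""
    with tifffile.TiffFile(path) as tif:
        pages = [p.asarray() for p in tif.pages]
    if len(pages) != len(CHANNEL_NAMES):
        raise ValueError(
            f"expected {len(CHANNEL_NAMES)} pages, found {len(pages)}")
    return SectionImage(np.stack(pages), pixel_size_um=pixel_size_um,
                        section_index=section_index)
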