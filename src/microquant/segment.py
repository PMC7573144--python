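"""Automated nucleus / cell-body segmentation of 4-channel fields.

The pipeline mirrors a marker-based watershed scheme for confocal images of
transfected cells:

1. nuclei — median-smooth the DAPI channel (10 x 7x7), threshold above 20,
   label 8-connected components, discard components below 5,000 px, fill
   holes, then split fused nuclei by a watershed seeded at the regional
   extrema of the Euclidean distance transform;
2. bodies — median-smooth the ZsGreen1 channel, threshold above 0 (only
   true background is 0 in this channel), discard components below
   3,000 px, fill holes, then partition bodies by a watershed seeded with
   the nucleus labels, so each body inherits its nucleus label;
3. exclusion — drop cells that are dim (body mean ZsGreen1 below 6),
   apoptotic (a bright blob smaller than the nucleus concentrating the
   body's intensity), on the image border, or without a matched
   nucleus/body pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage as ndi

from .imageops import (
    STRUCTURE_8,
    area_filter,
    connected_components,
    edt_minima_markers,
    fill_holes,
    iterative_median_filter,
    marker_watershed,
    threshold_above,
)
from .synthetic import MultiChannelImage

FLAG_NAMES = ("dim", "apoptotic", "edge", "unmatched")


@dataclass
class FmisConfig:
    """Constants of the segmentation pipeline.

    The preprocessing and filtering constants (median window/iterations,
    DAPI and ZsGreen1 thresholds, minimum areas, the dim-cell cutoff) are
    the published ones; the two apoptosis parameters make the qualitative
    bright-blob criterion operational and are exposed for tuning.
    """

    median_window: int = 7
    median_iterations: int = 10
    dapi_threshold: int = 20
    zs_threshold: int = 0  # "above 0", i.e. value >= 1
    nucleus_min_area: int = 5000
    body_min_area: int = 3000
    body_mean_intensity_min: float = 6.0
    apoptosis_bright_k: float = 2.0
    apoptosis_intensity_fraction: float = 0.5

    def __post_init__(self) -> None:
        for t in (self.dapi_threshold, self.zs_threshold, self.body_mean_intensity_min):
            if not 0 <= t <= 255:
                raise ValueError(f"threshold {t} outside [0, 255]")
        if self.nucleus_min_area < 0 or self.body_min_area < 0:
            raise ValueError("minimum areas must be >= 0")


@dataclass
class CellFlags:
    label: int
    dim: bool = False
    apoptotic: bool = False
    edge: bool = False
    unmatched: bool = False

    @property
    def retained(self) -> bool:
        return not (self.dim or self.apoptotic or self.edge or self.unmatched)


@dataclass
class SegmentationResult:
    """Matched nucleus/body label masks plus per-cell exclusion flags.

    ``nucleus_mask`` and ``body_mask`` share a label set; a retained label
    appears in both, with the nucleus a subset of its body.
    """

    nucleus_mask: np.ndarray
    body_mask: np.ndarray
    cells: list[CellFlags] = field(default_factory=list)

    @property
    def retained_labels(self) -> list[int]:
        return [c.label for c in self.cells if c.retained]

    def flags(self, label: int) -> CellFlags:
        return next(c for c in self.cells if c.label == label)

    def exclusion_counts(self) -> dict[str, int]:
        counts = {name: sum(getattr(c, name) for c in self.cells) for name in FLAG_NAMES}
        counts["retained"] = len(self.retained_labels)
        return counts


def segment_nuclei(dapi: np.ndarray, cfg: FmisConfig | None = None) -> np.ndarray:
    """Nucleus label mask from the DAPI channel (watershed-split)."""
    cfg = cfg or FmisConfig()
    smooth = iterative_median_filter(dapi, cfg.median_window, cfg.median_iterations)
    mask = threshold_above(smooth, cfg.dapi_threshold)
    labels = connected_components(mask)
    labels = area_filter(labels, cfg.nucleus_min_area)
    labels = fill_holes(labels)
    fg = labels > 0
    if not fg.any():
        return labels
    markers = edt_minima_markers(fg)
    split = marker_watershed(fg, markers)
    # watershed-split pieces must still clear the area filter
    return area_filter(split, cfg.nucleus_min_area)


def segment_bodies(
    zsgreen: np.ndarray, nuclei: np.ndarray, cfg: FmisConfig | None = None
) -> np.ndarray:
    """Body label mask from the ZsGreen1 channel, seeded by nucleus labels.

    Bodies inherit the label of the nucleus they contain; body foreground
    with no nucleus marker stays background (flagged unmatched downstream).
    """
    cfg = cfg or FmisConfig()
    smooth = iterative_median_filter(zsgreen, cfg.median_window, cfg.median_iterations)
    mask = threshold_above(smooth, cfg.zs_threshold)
    labels = connected_components(mask)
    labels = area_filter(labels, cfg.body_min_area)
    labels = fill_holes(labels)
    fg = labels > 0
    if not fg.any() or nuclei.max() == 0:
        return np.zeros_like(nuclei)
    markers = np.where(fg, nuclei, 0)
    if markers.max() == 0:
        return np.zeros_like(nuclei)
    return marker_watershed(fg, markers)


def detect_apoptotic(
    intensity: np.ndarray, body: np.ndarray, nucleus_area: int, cfg: FmisConfig | None = None
) -> bool:
    """Bright-blob apoptosis criterion on a single cell body.

    Bright pixels are those at or above body mean + k*SD of the body-channel
    intensity.  The cell is flagged when the largest 8-connected bright
    region is smaller than the nucleus yet carries at least the configured
    fraction of the body's total intensity.  A zero-variance body has no
    bright pixels and is never flagged.
    """
    cfg = cfg or FmisConfig()
    body = np.asarray(body).astype(bool)
    vals = intensity[body].astype(np.float64)
    if vals.size == 0:
        raise ValueError("empty cell body")
    sd = vals.std()
    if sd == 0:
        return False
    bright = body & (intensity >= vals.mean() + cfg.apoptosis_bright_k * sd)
    if not bright.any():
        return False
    blobs, n = ndi.label(bright, structure=STRUCTURE_8)
    areas = ndi.sum_labels(np.ones_like(blobs), blobs, index=range(1, n + 1))
    biggest = int(np.argmax(areas)) + 1
    blob = blobs == biggest
    if blob.sum() >= nucleus_area:
        return False
    total = intensity[body].astype(np.int64).sum()
    if total == 0:
        return False
    return bool(
        intensity[blob].astype(np.int64).sum() >= cfg.apoptosis_intensity_fraction * total
    )


def exclude_cells(
    image: MultiChannelImage,
    nuclei: np.ndarray,
    bodies: np.ndarray,
    cfg: FmisConfig | None = None,
) -> SegmentationResult:
    """Match nuclei to bodies and apply the exclusion rules.

    Nucleus pixels are clipped to their body so nucleus ⊆ body always holds
    (guaranteeing a non-negative cytoplasm).  Flags: ``dim`` if the body
    mean ZsGreen1 is strictly below the configured cutoff; ``apoptotic``
    per :func:`detect_apoptotic` on ZsGreen1; ``edge`` if any body pixel
    lies in the first/last row or column; ``unmatched`` if the label lacks
    a nucleus or a body.
    """
    cfg = cfg or FmisConfig()
    zs = image.channel("zsgreen")
    nucleus_mask = np.where(bodies == nuclei, nuclei, 0).astype(np.int32)
    body_mask = np.asarray(bodies).astype(np.int32)

    labels = sorted(set(np.unique(nuclei)) | set(np.unique(bodies)))
    cells: list[CellFlags] = []
    border = np.zeros(body_mask.shape, dtype=bool)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    for label in labels:
        if label == 0:
            continue
        flags = CellFlags(label=int(label))
        body = body_mask == label
        nuc = nucleus_mask == label
        if not body.any() or not nuc.any():
            flags.unmatched = True
            cells.append(flags)
            continue
        if float(zs[body].mean()) < cfg.body_mean_intensity_min:
            flags.dim = True
        if bool((body & border).any()):
            flags.edge = True
        if detect_apoptotic(zs, body, int(nuc.sum()), cfg):
            flags.apoptotic = True
        cells.append(flags)

    # flagged cells keep their pixels so callers can inspect what was removed;
    # everything downstream is keyed on retained_labels only
    return SegmentationResult(nucleus_mask=nucleus_mask, body_mask=body_mask, cells=cells)


def segment_field(image: MultiChannelImage, cfg: FmisConfig | None = None) -> SegmentationResult:
    """Full pipeline: nuclei, bodies, matching and exclusion for one field."""
    cfg = cfg or FmisConfig()
    nuclei = segment_nuclei(image.channel("dapi"), cfg)
    bodies = segment_bodies(image.channel("zsgreen"), nuclei, cfg)
    return exclude_cells(image, nuclei, bodies, cfg)


def config_to_dict(cfg: FmisConfig) -> dict:
    return asdict(cfg)
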