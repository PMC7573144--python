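"""Synthetic multi-channel confocal fields with full ground truth.

Emulates fields of transfected microglial cells imaged in four channels:
DAPI (nuclei), ZsGreen1 (cell bodies of transfected cells), AF568
(a generic immunostained marker) and AF647 (the nucleocytoplasmic protein
whose translocation is staged).  Each generated cell carries a programmed
translocation stage realised as per-compartment AF647 levels, plus optional
phenotype flags (dim, apoptotic, edge-clipped) and optional touching
partners, so segmentation, exclusion, quantification and staging can all be
scored against exact ground truth.

Intensity model
---------------
Cells are rotated ellipses (nucleus concentric inside the body).  Inside a
compartment a channel takes its programmed mean level; outside cells it
takes the channel's diffuse background level.  Additive Gaussian noise is
applied, then values are clipped to [0, 255] and rounded to 8-bit integers.
Pixels whose noiseless value is exactly 0 stay 0, modelling the zero
detector offset that makes a threshold of 1 meaningful in the ZsGreen1
channel.  No-primary-antibody control fields are identical except that the
AF647 channel contains only the diffuse background process.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Iterator

import numpy as np

CHANNELS = ("dapi", "zsgreen", "af568", "af647")
STAGES = ("none", "mild", "moderate", "severe")
CATEGORIES = ("clean", "dim", "apoptotic", "edge")


@dataclass
class MultiChannelImage:
    """A 4-channel 8-bit field; ``data`` has shape (4, H, W)."""

    data: np.ndarray
    channels: tuple[str, ...] = CHANNELS

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[1:]


@dataclass
class SceneParams:
    """Generator configuration; the defaults define the benchmark conditions.

    Intensity levels are 8-bit means.  The per-stage AF647 levels keep a
    margin of several intensity units to the control-field background so
    that staging survives the default pixel noise.
    """

    field_size: tuple[int, int] = (512, 512)
    n_cells: int = 4
    nucleus_radius_range: tuple[float, float] = (41.0, 45.0)
    body_radius_range: tuple[float, float] = (72.0, 80.0)
    stage_mix: dict[str, float] = field(
        default_factory=lambda: {"none": 0.25, "mild": 0.25, "moderate": 0.25, "severe": 0.25}
    )
    nuclear_level: dict[str, float] = field(
        default_factory=lambda: {"none": 60.0, "mild": 60.0, "moderate": 30.0, "severe": 0.0}
    )
    cytoplasmic_level: dict[str, float] = field(
        default_factory=lambda: {"none": 0.0, "mild": 20.0, "moderate": 60.0, "severe": 60.0}
    )
    background_level: dict[str, float] = field(
        default_factory=lambda: {"dapi": 5.0, "zsgreen": 0.0, "af568": 0.0, "af647": 2.0}
    )
    dapi_level: float = 180.0
    zsgreen_level: float = 50.0
    dim_level: float = 3.0
    apoptotic_base_level: float = 15.0
    apoptotic_blob_level: float = 220.0
    marker_level: float = 40.0
    fraction_marker_positive: float = 0.94
    noise_sd: float = 5.0
    fraction_touching: float = 0.0
    fraction_apoptotic: float = 0.1
    fraction_dim: float = 0.1
    fraction_edge: float = 0.1
    aspect_jitter: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if abs(sum(self.stage_mix.values()) - 1.0) > 1e-9:
            raise ValueError(f"stage_mix must sum to 1, got {sum(self.stage_mix.values())}")
        if set(self.stage_mix) - set(STAGES):
            raise ValueError(f"unknown stages in stage_mix: {set(self.stage_mix) - set(STAGES)}")
        for d in (self.nuclear_level, self.cytoplasmic_level, self.background_level):
            for v in d.values():
                if not 0 <= v <= 255:
                    raise ValueError(f"intensity mean {v} outside [0, 255]")
        if min(self.nucleus_radius_range) <= 0 or min(self.body_radius_range) <= 0:
            raise ValueError("radii must be positive")
        if max(self.nucleus_radius_range) * (1 + self.aspect_jitter) >= min(
            self.body_radius_range
        ) / (1 + self.aspect_jitter):
            raise ValueError("nucleus radius range must lie strictly inside body radius range")
        if self.n_cells < 0:
            raise ValueError("n_cells must be >= 0")
        fr = self.fraction_apoptotic + self.fraction_dim + self.fraction_edge
        if not 0 <= fr <= 1:
            raise ValueError("flag fractions must be in [0, 1] and sum to <= 1")


@dataclass
class CellTruth:
    label: int
    center: tuple[float, float]
    stage: str
    category: str  # clean | dim | apoptotic | edge
    marker_positive: bool
    touching_partner: int | None = None


@dataclass
class SyntheticTruth:
    """Ground truth for one scene: label masks plus per-cell annotations."""

    nucleus_mask: np.ndarray
    body_mask: np.ndarray
    cells: list[CellTruth]
    params: SceneParams

    def cell(self, label: int) -> CellTruth:
        return next(c for c in self.cells if c.label == label)

    def clean_labels(self) -> list[int]:
        return [c.label for c in self.cells if c.category == "clean"]


def _ellipse_mask(shape, cy, cx, a, b, theta) -> np.ndarray:
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    y = yy - cy
    x = xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = x * ct + y * st
    v = -x * st + y * ct
    return (u / a) ** 2 + (v / b) ** 2 <= 1.0


def _place_centers(params: SceneParams, rng: np.random.Generator):
    """Sample cell centres: edge cells hug a border, touching pairs overlap,
    everything else keeps full separation.  Raises if the field is too small."""
    h, w = params.field_size
    r_max = max(params.body_radius_range)
    margin = r_max * (1 + params.aspect_jitter) + 4
    sep = 2 * r_max * (1 + params.aspect_jitter) + 8
    if params.n_cells and (h <= 2 * margin or w <= 2 * margin):
        raise ValueError(f"field {params.field_size} too small for bodies of radius {r_max}")

    n = params.n_cells
    n_pairs = int(round(params.fraction_touching * n / 2))
    categories: list[str] = []
    p_flags = [params.fraction_apoptotic, params.fraction_dim, params.fraction_edge]
    for i in range(n):
        in_pair = i < 2 * n_pairs
        u = rng.random()
        if not in_pair and u < p_flags[0]:
            categories.append("apoptotic")
        elif not in_pair and u < p_flags[0] + p_flags[1]:
            categories.append("dim")
        elif not in_pair and u < sum(p_flags):
            categories.append("edge")
        else:
            categories.append("clean")

    last_err = None
    for _attempt in range(20):
        try:
            centers, partners = _try_place(params, rng, categories, n_pairs, margin, sep)
            return centers, categories, partners
        except _PlacementFailure as err:
            last_err = err
    raise ValueError(str(last_err))


class _PlacementFailure(Exception):
    pass


def _try_place(params, rng, categories, n_pairs, margin, sep):
    h, w = params.field_size
    r_max = max(params.body_radius_range)
    n = params.n_cells
    centers: list[tuple[float, float]] = []
    partners: list[int | None] = [None] * n
    max_tries = 2000
    for i in range(n):
        if i < 2 * n_pairs and i % 2 == 1:
            # second member of a touching pair: closer than the two body radii
            cy0, cx0 = centers[i - 1]
            for _ in range(max_tries):
                ang = rng.uniform(0, 2 * np.pi)
                d = 0.85 * 2 * r_max
                cy, cx = cy0 + d * np.sin(ang), cx0 + d * np.cos(ang)
                if margin < cy < h - margin and margin < cx < w - margin and all(
                    (cy - y) ** 2 + (cx - x) ** 2 >= sep**2 for y, x in centers[: i - 1]
                ):
                    break
            else:
                raise _PlacementFailure("could not place touching partner; field too crowded")
            partners[i] = i - 1
            partners[i - 1] = i
        elif categories[i] == "edge":
            for _ in range(max_tries):
                side = rng.integers(4)
                off = 0.8 * r_max
                t = rng.uniform(margin, (w if side < 2 else h) - margin)
                cy, cx = [(off, t), (h - off, t), (t, off), (t, w - off)][side]
                if all((cy - y) ** 2 + (cx - x) ** 2 >= sep**2 for y, x in centers):
                    break
            else:
                raise _PlacementFailure("could not place edge cell; field too crowded")
        else:
            for _ in range(max_tries):
                cy = rng.uniform(margin, h - margin)
                cx = rng.uniform(margin, w - margin)
                if all((cy - y) ** 2 + (cx - x) ** 2 >= sep**2 for y, x in centers):
                    break
            else:
                raise _PlacementFailure(f"could not place {params.n_cells} cells; field too small")
        centers.append((cy, cx))
    return centers, partners


def _sample_stage(rng: np.random.Generator, mix: dict[str, float]) -> str:
    stages = [s for s in STAGES if mix.get(s, 0) > 0]
    probs = np.array([mix[s] for s in stages])
    return stages[rng.choice(len(stages), p=probs / probs.sum())]


def _finalize(clean: np.ndarray, rng: np.random.Generator, noise_sd: float) -> np.ndarray:
    """Noise + 8-bit quantisation; true-zero pixels stay zero."""
    noise = rng.normal(0.0, noise_sd, size=clean.shape) if noise_sd > 0 else 0.0
    noisy = np.where(clean > 0, clean + noise, clean)
    return np.clip(np.rint(noisy), 0, 255).astype(np.uint8)


def _build(params: SceneParams, rng: np.random.Generator, af647_background_only: bool):
    h, w = params.field_size
    nucleus_mask = np.zeros((h, w), dtype=np.int32)
    body_mask = np.zeros((h, w), dtype=np.int32)
    # clean (noiseless) per-channel fields
    clean = {
        name: np.full((h, w), params.background_level[name], dtype=np.float64)
        for name in CHANNELS
    }

    centers, categories, partners = _place_centers(params, rng)
    cells: list[CellTruth] = []
    claims: list[tuple[int, np.ndarray, np.ndarray]] = []  # label, body, norm dist
    geoms = []
    for i, (cy, cx) in enumerate(centers):
        label = i + 1
        r_nuc = rng.uniform(*params.nucleus_radius_range)
        r_body = rng.uniform(*params.body_radius_range)
        s = rng.uniform(1.0, 1.0 + params.aspect_jitter)
        theta = rng.uniform(0, np.pi)
        stage = _sample_stage(rng, params.stage_mix)
        marker_pos = bool(rng.random() < params.fraction_marker_positive)
        body = _ellipse_mask((h, w), cy, cx, r_body * s, r_body / s, theta)
        nuc = _ellipse_mask((h, w), cy, cx, r_nuc * s, r_nuc / s, theta)
        yy, xx = np.ogrid[:h, :w]
        ndist = np.sqrt((yy - cy) ** 2 + (xx - cx) ** 2) / r_body
        claims.append((label, body, ndist))
        geoms.append((cy, cx, r_nuc, s, theta, nuc))
        cells.append(
            CellTruth(label, (cy, cx), stage, categories[i], marker_pos,
                      None if partners[i] is None else partners[i] + 1)
        )

    # resolve body overlaps (touching pairs) by normalised radial distance
    if claims:
        dist_stack = np.stack([np.broadcast_to(nd, (h, w)) for _, _, nd in claims])
        mask_stack = np.stack([b for _, b, _ in claims])
        dist_stack = np.where(mask_stack, dist_stack, np.inf)
        winner = np.argmin(dist_stack, axis=0)
        any_body = mask_stack.any(axis=0)
        for k, (label, _, _) in enumerate(claims):
            own = any_body & (winner == k)
            body_mask[own] = label
    for k, (label, body, _) in enumerate(claims):
        nuc = geoms[k][5] & (body_mask == label)
        nucleus_mask[nuc] = label

    # paint channels per cell
    for cell, geom in zip(cells, geoms):
        body = body_mask == cell.label
        nuc = nucleus_mask == cell.label
        cyt = body & ~nuc
        clean["dapi"][nuc] = params.dapi_level
        if cell.category == "dim":
            clean["zsgreen"][body] = params.dim_level
        elif cell.category == "apoptotic":
            clean["zsgreen"][body] = params.apoptotic_base_level
            cy, cx, r_nuc, s, theta, _ = geom
            nuc_area = int(nuc.sum())
            r_blob = np.sqrt(0.5 * nuc_area / np.pi)
            blob = _ellipse_mask((h, w), cy, cx, r_blob, r_blob, 0.0) & body
            clean["zsgreen"][blob] = params.apoptotic_blob_level
        else:
            clean["zsgreen"][body] = params.zsgreen_level
        if cell.marker_positive:
            clean["af568"][body] = params.marker_level
        else:
            clean["af568"][body] = 0.0
        if not af647_background_only:
            clean["af647"][nuc] = params.nuclear_level[cell.stage]
            clean["af647"][cyt] = params.cytoplasmic_level[cell.stage]

    data = np.stack([_finalize(clean[name], rng, params.noise_sd) for name in CHANNELS])
    image = MultiChannelImage(data)
    truth = SyntheticTruth(nucleus_mask, body_mask, cells, params)
    return image, truth


def generate_scene(params: SceneParams) -> tuple[MultiChannelImage, SyntheticTruth]:
    """Generate one immunostained field plus its ground truth.

    Identical ``params`` (including seed) give bit-identical output.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    return _build(params, rng, af647_background_only=False)


def generate_background_field(params: SceneParams) -> MultiChannelImage:
    """Generate a no-primary-antibody control field.

    Cells carry their normal DAPI/ZsGreen1/AF568 signal, but AF647 contains
    only the diffuse background process: with ``noise_sd=0`` the AF647
    channel is constant at its background level everywhere.  With the same
    seed the geometry matches :func:`generate_scene` exactly.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    image, _ = _build(params, rng, af647_background_only=True)
    return image


def scene_batch(
    n_scenes: int, base_seed: int, **overrides
) -> Iterator[tuple[MultiChannelImage, SyntheticTruth]]:
    """Yield ``n_scenes`` independent scenes seeded ``base_seed + i``."""
    for i in range(n_scenes):
        params = replace(SceneParams(**overrides), seed=int(base_seed) + i)
        yield generate_scene(params)


def params_to_dict(params: SceneParams) -> dict:
    return asdict(params)
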