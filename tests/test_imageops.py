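"""Brute-force-oracle tests for the low-level image operators."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage as ndi
from skimage.morphology import disk

from microquant.imageops import (
    area_filter,
    connected_components,
    edt_minima_markers,
    fill_holes,
    iterative_median_filter,
    marker_watershed,
    threshold_above,
    white_tophat,
)

N_RANDOM_INSTANCES = 25  # per oracle test; 4 oracle tests x 25 >= 100 instances


# ---------------------------------------------------------------------------
# oracles


def median_oracle(img: np.ndarray, window: int) -> np.ndarray:
    """Per-pixel sort-and-middle median with symmetric (reflect) borders."""
    r = window // 2
    padded = np.pad(img, r, mode="symmetric")
    out = np.empty_like(img)
    for i in range(img.shape[0]):
        for j in range(img.shape[1]):
            out[i, j] = np.median(padded[i : i + window, j : j + window])
    return out


def flood_fill_components(mask: np.ndarray) -> list[frozenset]:
    """8-connected components as coordinate sets, via explicit BFS."""
    mask = mask.astype(bool)
    seen = np.zeros_like(mask)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        comp, queue = set(), [start]
        seen[start] = True
        while queue:
            y, x = queue.pop()
            comp.add((y, x))
            for dy in (-1, 0, 1):
                for dx in (-1, 0, 1):
                    ny, nx = y + dy, x + dx
                    if (
                        0 <= ny < mask.shape[0]
                        and 0 <= nx < mask.shape[1]
                        and mask[ny, nx]
                        and not seen[ny, nx]
                    ):
                        seen[ny, nx] = True
                        queue.append((ny, nx))
        comps.append(frozenset(comp))
    return comps


def border_flood_background(fg: np.ndarray) -> np.ndarray:
    """Background pixels reachable from the border (8-conn), via BFS."""
    bg = ~fg.astype(bool)
    reach = np.zeros_like(bg)
    h, w = bg.shape
    queue = [
        (y, x)
        for y in range(h)
        for x in range(w)
        if (y in (0, h - 1) or x in (0, w - 1)) and bg[y, x]
    ]
    for q in queue:
        reach[q] = True
    while queue:
        y, x = queue.pop()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w and bg[ny, nx] and not reach[ny, nx]:
                    reach[ny, nx] = True
                    queue.append((ny, nx))
    return reach


def opening_oracle(img: np.ndarray, footprint: np.ndarray) -> np.ndarray:
    """Grey erosion-then-dilation by explicit min/max over the footprint."""
    r = footprint.shape[0] // 2
    offs = [(dy - r, dx - r) for dy, dx in zip(*np.nonzero(footprint))]

    def erode(a):
        p = np.pad(a, r, mode="symmetric").astype(np.int64)
        return np.min(
            [p[r + dy : r + dy + a.shape[0], r + dx : r + dx + a.shape[1]] for dy, dx in offs],
            axis=0,
        )

    def dilate(a):
        p = np.pad(a, r, mode="symmetric").astype(np.int64)
        return np.max(
            [p[r - dy : r - dy + a.shape[0], r - dx : r - dx + a.shape[1]] for dy, dx in offs],
            axis=0,
        )

    return dilate(erode(img))


# ---------------------------------------------------------------------------
# median filter


def test_median_constant_image_unchanged():
    img = np.full((20, 20), 37, dtype=np.uint8)
    assert np.array_equal(iterative_median_filter(img, 7, 10), img)


def test_median_removes_isolated_bright_pixel():
    img = np.full((15, 15), 10, dtype=np.uint8)
    img[7, 7] = 250
    out = iterative_median_filter(img, 7, 1)
    assert out[7, 7] == 10


def test_median_zero_iterations_is_identity():
    img = np.arange(64, dtype=np.uint8).reshape(8, 8)
    assert np.array_equal(iterative_median_filter(img, 3, 0), img)


def test_median_rejects_even_window():
    with pytest.raises(ValueError):
        iterative_median_filter(np.zeros((4, 4)), window=4)


def test_median_matches_bruteforce_oracle(rng):
    for _ in range(N_RANDOM_INSTANCES):
        img = rng.integers(0, 256, size=(9, 9)).astype(np.uint8)
        assert np.array_equal(iterative_median_filter(img, 3, 1), median_oracle(img, 3))


# ---------------------------------------------------------------------------
# thresholding


@pytest.mark.parametrize(
    "value,t,expected",
    [(0, 20, False), (20, 20, False), (21, 20, True), (255, 20, True)],
)
def test_threshold_is_strictly_above(value, t, expected):
    assert threshold_above(np.array([[value]]), t)[0, 0] == expected


# ---------------------------------------------------------------------------
# connected components


def test_components_empty_mask():
    assert connected_components(np.zeros((8, 8), bool)).max() == 0


def test_components_two_squares():
    mask = np.zeros((12, 12), bool)
    mask[1:4, 1:4] = True
    mask[7:11, 7:11] = True
    labels = connected_components(mask)
    assert labels.max() == 2
    assert sorted(np.bincount(labels.ravel())[1:]) == [9, 16]


def test_components_match_flood_fill_oracle(rng):
    for _ in range(N_RANDOM_INSTANCES):
        mask = rng.random((16, 16)) < 0.4
        labels = connected_components(mask)
        got = {
            frozenset(zip(*np.nonzero(labels == k))) for k in range(1, labels.max() + 1)
        }
        assert got == set(flood_fill_components(mask))


# ---------------------------------------------------------------------------
# area filter


def test_area_filter_boundary_is_strict():
    just_under = np.zeros((80, 80), dtype=np.int32)
    just_under[:62, :80] = 1  # 4,960 px < 5,000 -> removed
    assert area_filter(just_under, 5000).max() == 0
    exactly = np.ones((50, 100), dtype=np.int32)  # exactly 5,000 px -> kept
    assert np.array_equal(area_filter(exactly, 5000), exactly)


def test_area_filter_zero_min_area_is_identity(rng):
    labels = connected_components(rng.random((20, 20)) < 0.3)
    assert np.array_equal(area_filter(labels, 0), labels)


def test_area_filter_survivors_keep_identity():
    labels = np.zeros((10, 30), dtype=np.int32)
    labels[2:8, 2:8] = 3
    labels[2:4, 20:22] = 7
    out = area_filter(labels, 10)
    assert set(np.unique(out)) == {0, 3}


def test_area_filter_idempotent(rng):
    for _ in range(10):
        labels = connected_components(rng.random((24, 24)) < 0.35)
        once = area_filter(labels, 4)
        assert np.array_equal(area_filter(once, 4), once)


# ---------------------------------------------------------------------------
# hole filling


def test_fill_holes_annulus_becomes_disk():
    yy, xx = np.ogrid[:21, :21]
    r2 = (yy - 10) ** 2 + (xx - 10) ** 2
    annulus = ((r2 <= 81) & (r2 >= 16)).astype(np.int32)
    filled = fill_holes(annulus)
    assert np.array_equal(filled > 0, r2 <= 81)


def test_fill_holes_solid_disk_unchanged():
    yy, xx = np.ogrid[:15, :15]
    disk_mask = ((yy - 7) ** 2 + (xx - 7) ** 2 <= 25).astype(np.int32)
    assert np.array_equal(fill_holes(disk_mask), disk_mask)


def test_fill_holes_matches_border_flood_oracle(rng):
    for _ in range(N_RANDOM_INSTANCES):
        mask = ndi.binary_dilation(rng.random((20, 20)) < 0.2, np.ones((3, 3)))
        labels = connected_components(mask)
        filled = fill_holes(labels)
        outside = border_flood_background(mask)
        assert np.array_equal(filled > 0, ~outside)


def test_fill_holes_idempotent(rng):
    for _ in range(10):
        labels = connected_components(ndi.binary_dilation(rng.random((20, 20)) < 0.2))
        once = fill_holes(labels)
        assert np.array_equal(fill_holes(once), once)


def test_hole_between_two_components_goes_to_longer_boundary():
    # a 1-px hole enclosed by label 1 on three sides and label 2 on one
    labels = np.zeros((5, 5), dtype=np.int32)
    labels[1:4, 1:4] = 1
    labels[2, 2] = 0  # hole
    labels[3, 1:4] = 2
    out = fill_holes(labels)
    assert out[2, 2] == 1


# ---------------------------------------------------------------------------
# EDT markers + watershed


def _disk_mask(shape, cy, cx, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def test_single_disk_yields_single_central_marker():
    mask = _disk_mask((41, 41), 20, 20, 15)
    markers = edt_minima_markers(mask)
    assert markers.max() == 1
    cy, cx = ndi.center_of_mass(markers > 0)
    assert abs(cy - 20) < 2 and abs(cx - 20) < 2


def test_dumbbell_yields_two_markers_and_watershed_splits_evenly():
    mask = _disk_mask((41, 81), 20, 22, 15) | _disk_mask((41, 81), 20, 58, 15)
    markers = edt_minima_markers(mask)
    assert markers.max() == 2
    labels = marker_watershed(mask, markers)
    assert set(np.unique(labels)) == {0, 1, 2}
    sizes = np.bincount(labels.ravel())[1:]
    # symmetric lobes: equal sizes up to the ridge-pixel column
    assert abs(int(sizes[0]) - int(sizes[1])) <= mask.shape[0]
    assert (labels > 0).sum() == mask.sum()


def test_empty_mask_yields_no_markers():
    assert edt_minima_markers(np.zeros((10, 10), bool)).max() == 0


def test_watershed_single_marker_takes_whole_blob():
    mask = _disk_mask((31, 31), 15, 15, 10)
    markers = np.zeros((31, 31), dtype=np.int32)
    markers[15, 15] = 5
    labels = marker_watershed(mask, markers)
    assert np.array_equal(labels > 0, mask)
    assert set(np.unique(labels)) == {0, 5}


def test_watershed_zero_markers_warns_and_returns_background():
    mask = _disk_mask((21, 21), 10, 10, 6)
    with pytest.warns(UserWarning):
        labels = marker_watershed(mask, np.zeros_like(mask, dtype=np.int32))
    assert labels.max() == 0


def test_watershed_matches_nearest_marker_oracle():
    # two symmetric fused disks with two point markers: each pixel should be
    # claimed by the closer marker (ties at the ridge may go either way)
    mask = _disk_mask((41, 81), 20, 22, 15) | _disk_mask((41, 81), 20, 58, 15)
    markers = np.zeros(mask.shape, dtype=np.int32)
    markers[20, 22] = 1
    markers[20, 58] = 2
    labels = marker_watershed(mask, markers)
    yy, xx = np.nonzero(mask)
    d1 = (yy - 20) ** 2 + (xx - 22) ** 2
    d2 = (yy - 20) ** 2 + (xx - 58) ** 2
    strict = d1 != d2
    expected = np.where(d1 < d2, 1, 2)
    agree = (labels[yy, xx] == expected)[strict].mean()
    assert agree == 1.0


# ---------------------------------------------------------------------------
# white top-hat


def test_tophat_constant_image_is_zero():
    img = np.full((20, 20), 99, dtype=np.uint8)
    assert white_tophat(img, 5).max() == 0


def test_tophat_keeps_small_bright_spot():
    img = np.full((31, 31), 10, dtype=np.uint8)
    img[14:17, 14:17] = 200
    out = white_tophat(img, 6)
    assert out[15, 15] == 190
    assert out[0, 0] == 0


def test_tophat_matches_opening_oracle(rng):
    footprint = disk(2)
    for _ in range(N_RANDOM_INSTANCES):
        img = rng.integers(0, 256, size=(12, 12)).astype(np.uint8)
        expected = img.astype(np.int64) - opening_oracle(img, footprint)
        assert np.array_equal(white_tophat(img, 2), expected)
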