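"""Projection and cell/nucleus segmentation.

Reproduces the segmentation workflow of dual-colour smiFISH analysis: a
focus-based 2D projection of the stack, Otsu + distance-transform
watershed for nuclei in the DAPI channel, and a nucleus-seeded watershed
in the smiFISH channel for cells. Externally supplied (manual) outlines
enter through :func:`load_geometry`.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label
from skimage.segmentation import watershed

from .datatypes import CellGeometry, VolumetricImage, warn


def focus_projection(
    stack: VolumetricImage | np.ndarray, window: int = 15
) -> tuple[np.ndarray, np.ndarray]:
    """Project a z-stack to 2D by per-pixel local focus.

    The focus metric is local intensity variance in a ``window``-pixel
    square. Candidate z-planes are restricted to +/-1 of the globally
    best-focused plane (the plane with the highest mean local variance);
    within the candidates each output pixel takes the stack value at the z
    maximizing the local metric, ties broken toward the lowest z.

    Returns ``(projection, z_map)``.
    """
    data = stack.data if isinstance(stack, VolumetricImage) else np.asarray(stack)
    if data.ndim != 3:
        raise ValueError("expected a (z, y, x) stack")
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    nz = data.shape[0]
    if nz == 1:
        warn("single-plane stack: focus projection returns it unchanged")
        return data[0].copy(), np.zeros(data.shape[1:], dtype=int)

    img = data.astype(float)
    size = (1, window, window)
    mean = ndi.uniform_filter(img, size=size, mode="reflect")
    sq_mean = ndi.uniform_filter(img**2, size=size, mode="reflect")
    local_var = np.maximum(sq_mean - mean**2, 0.0)

    global_focus = local_var.mean(axis=(1, 2))
    z_best = int(np.argmax(global_focus))
    lo, hi = max(z_best - 1, 0), min(z_best + 1, nz - 1)

    cand = local_var[lo : hi + 1]
    z_rel = np.argmax(cand, axis=0)  # argmax takes the first (lowest z) on ties
    z_map = z_rel + lo
    yy, xx = np.indices(z_map.shape)
    projection = data[z_map, yy, xx]
    return projection, z_map


def segment_nuclei(dapi2d: np.ndarray, min_area: int = 50) -> np.ndarray:
    """Otsu threshold + distance-transform watershed nucleus segmentation.

    Touching nuclei are split by a watershed on the negated distance
    transform seeded at distance maxima; objects below ``min_area`` pixels
    are removed and labels renumbered 1..K.
    """
    img = np.asarray(dapi2d, dtype=float)
    if img.ndim != 2:
        raise ValueError("expected a 2D image")
    if np.ptp(img) == 0:
        raise ValueError("no foreground: DAPI image is constant")
    fg = img > threshold_otsu(img)
    if not fg.any():
        raise ValueError("no foreground after Otsu thresholding")

    dist = ndi.distance_transform_edt(fg)
    # seeds: maxima of the smoothed distance map, one per nucleus centre
    smooth = gaussian(dist, sigma=2, preserve_range=True)
    footprint = np.ones((9, 9), dtype=bool)
    peaks = (smooth == ndi.maximum_filter(smooth, footprint=footprint)) & fg & (dist > 1)
    seeds = cc_label(peaks)
    labels = watershed(-dist, markers=seeds, mask=fg)

    return _filter_small_and_relabel(labels, min_area)


def _filter_small_and_relabel(labels: np.ndarray, min_area: int) -> np.ndarray:
    out = np.zeros_like(labels, dtype=np.int32)
    next_id = 1
    for lab in np.unique(labels):
        if lab == 0:
            continue
        m = labels == lab
        if m.sum() >= min_area:
            out[m] = next_id
            next_id += 1
    return out


def segment_cells(fish2d: np.ndarray, nuclei: np.ndarray, smooth_sigma: float = 1.5) -> np.ndarray:
    """Nucleus-seeded watershed cell segmentation in the smiFISH channel.

    The FISH image is smoothed, an Otsu threshold defines the cell
    foreground, and a watershed on the inverted smoothed intensity, seeded
    by the nucleus labels, partitions the foreground into cells. Each cell
    inherits its seed nucleus label; nuclei are forced inside their cells.
    A nucleus falling outside the foreground yields a cell equal to the
    nucleus mask, with a warning.
    """
    img = np.asarray(fish2d, dtype=float)
    nuclei = np.asarray(nuclei)
    if img.shape != nuclei.shape:
        raise ValueError("image and nucleus mask differ in shape")
    if nuclei.max() == 0:
        raise ValueError("at least one nucleus seed label is required")

    # suppress diffraction-limited spots before thresholding so Otsu splits
    # background vs cell body rather than cell body vs spots
    body = ndi.median_filter(img, size=7)
    smooth = gaussian(body, sigma=smooth_sigma, preserve_range=True)
    fg = smooth > threshold_otsu(smooth)
    cells = watershed(-smooth, markers=nuclei, mask=fg | (nuclei > 0))
    cells = np.where(nuclei > 0, nuclei, cells)  # nuclei always inside cells

    for lab in np.unique(nuclei):
        if lab == 0:
            continue
        nuc = nuclei == lab
        if not fg[nuc].any():
            warn(f"nucleus {lab} lies outside the cell foreground; cell set to nucleus")
            cells[nuc] = lab
    return cells.astype(np.int32)


def load_geometry(cell_mask: np.ndarray, nucleus_mask: np.ndarray) -> CellGeometry:
    """Build a CellGeometry from externally supplied label masks.

    Nucleus labels are matched to cell labels by maximal pixel overlap and
    the output is relabelled so that nucleus i pairs with cell i. Nuclei
    with no overlapping cell are rejected and listed in the diagnostics;
    nucleus pixels outside their matched cell are trimmed. Idempotent on
    its own output.
    """
    cells = np.asarray(cell_mask).astype(np.int64)
    nucs = np.asarray(nucleus_mask).astype(np.int64)
    if cells.shape != nucs.shape:
        raise ValueError("cell and nucleus masks differ in shape")

    diagnostics: list[str] = []
    out_cells = np.zeros_like(cells, dtype=np.int32)
    out_nucs = np.zeros_like(cells, dtype=np.int32)

    # match each nucleus to the cell it overlaps most
    claim: dict[int, int] = {}  # cell label -> nucleus label
    for nlab in sorted(set(np.unique(nucs)) - {0}):
        overlap = cells[nucs == nlab]
        overlap = overlap[overlap > 0]
        if overlap.size == 0:
            diagnostics.append(f"nucleus {nlab}: no overlapping cell, rejected")
            continue
        vals, counts = np.unique(overlap, return_counts=True)
        best = int(vals[np.argmax(counts)])
        if best in claim:
            diagnostics.append(
                f"nucleus {nlab}: cell {best} already claimed by nucleus {claim[best]}, rejected"
            )
            continue
        claim[best] = int(nlab)

    next_id = 1
    for clab in sorted(set(np.unique(cells)) - {0}):
        cmask = cells == clab
        if clab not in claim:
            diagnostics.append(f"cell {clab}: no matched nucleus, kept without nucleus")
            out_cells[cmask] = next_id
            next_id += 1
            continue
        nmask = (nucs == claim[clab]) & cmask
        trimmed = int(((nucs == claim[clab]) & ~cmask).sum())
        if trimmed:
            diagnostics.append(
                f"nucleus {claim[clab]}: {trimmed} px outside cell {clab} trimmed"
            )
        out_cells[cmask] = next_id
        out_nucs[nmask] = next_id
        if not (cmask & ~nmask).any():
            diagnostics.append(f"cell {next_id}: empty cytoplasm, non-analysable")
        next_id += 1

    return CellGeometry(cell_labels=out_cells, nucleus_labels=out_nucs, diagnostics=diagnostics)
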