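"""Image analysis: droplet segmentation, tracking, cell counting, traces.

Converts time-lapse multi-channel image stacks of a 2-D droplet
observation chamber into per-droplet intensity traces. Droplets are
segmented as near-circular connected components, tracked frame-to-frame
by greedy nearest-centroid matching, and every failure mode (lost track,
chamber/tile edge, stitch boundary) is flagged rather than silently
dropped; flagged droplets never enter downstream statistics.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from skimage.measure import label, regionprops

from .config import (
    AcquisitionSpec,
    CHANNEL_A647,
    CHANNEL_CELL_STAIN,
)

TRACK_OK = "ok"
TRACK_FAILED = "tracking_failed"
TRACK_EDGE = "edge"
TRACK_STITCH = "stitch_suspect"


@dataclass
class DropletRegion:
    """One segmented droplet in one frame. Coordinates are 0-based
    (row, col); ``coords`` are the member pixel indices."""

    frame_index: int
    centroid: tuple[float, float]
    radius_px: float
    coords: np.ndarray  # (n, 2) pixel indices
    edge_flag: bool = False
    mean_intensity: float = 0.0


def segment_droplets(
    image: np.ndarray,
    r_min: float = 5.0,
    r_max: float = 30.0,
    intensity_floor: float = 1.0,
    min_circularity: float = 0.6,
    frame_index: int = 0,
) -> list[DropletRegion]:
    """Segment near-circular droplets from a single-channel frame.

    Thresholds at ``intensity_floor``, labels connected components, and
    keeps regions whose equivalent radius lies in [r_min, r_max] and
    whose circularity 4*pi*A/P^2 exceeds ``min_circularity``. Regions
    touching the image border are flagged ``edge``. An empty image gives
    an empty list.
    """
    img = np.asarray(image)
    mask = img >= intensity_floor
    if not mask.any():
        return []
    lab = label(mask)
    out = []
    H, W = img.shape
    for rp in regionprops(lab, intensity_image=img):
        radius = math.sqrt(rp.area / math.pi)
        if not r_min <= radius <= r_max:
            continue
        if rp.perimeter > 0:
            circ = 4 * math.pi * rp.area / rp.perimeter**2
            if circ < min_circularity:
                continue
        minr, minc, maxr, maxc = rp.bbox
        edge = minr <= 0 or minc <= 0 or maxr >= H or maxc >= W
        out.append(
            DropletRegion(
                frame_index=frame_index,
                centroid=tuple(rp.centroid),
                radius_px=radius,
                coords=rp.coords,
                edge_flag=edge,
                mean_intensity=float(rp.intensity_mean),
            )
        )
    return out


def track_droplets(
    regions_per_frame: list[list[DropletRegion]],
    max_disp_factor: float = 0.5,
) -> pd.DataFrame:
    """Greedy nearest-centroid tracking across frames.

    A frame-to-frame match is valid when the displacement is at most
    ``max_disp_factor`` times the droplet radius and unambiguous (no two
    tracks claim the same region). Droplets unmatched in any frame are
    flagged ``tracking_failed``; droplets touching the border in any
    frame are flagged ``edge``. Returns a long table (droplet_id, frame,
    region_index, track_quality).
    """
    if len(regions_per_frame) < 2:
        raise ValueError("tracking needs >= 2 frames")
    n0 = len(regions_per_frame[0])
    ids = [f"d{i:06d}" for i in range(n0)]
    assign: list[list[int | None]] = [[i for i in range(n0)]]
    quality = {did: TRACK_OK for did in ids}
    pos = np.array([r.centroid for r in regions_per_frame[0]]).reshape(n0, 2)

    for f in range(1, len(regions_per_frame)):
        regs = regions_per_frame[f]
        col = [None] * n0
        if regs:
            cents = np.array([r.centroid for r in regs])
            tree = cKDTree(cents)
            dist, idx = tree.query(pos)
            claimed: dict[int, int] = {}
            for i in range(n0):
                max_disp = max_disp_factor * regions_per_frame[0][i].radius_px
                if not np.isfinite(dist[i]) or dist[i] > max_disp:
                    quality[ids[i]] = TRACK_FAILED
                    continue
                j = int(idx[i])
                if j in claimed:  # ambiguous: two tracks want one region
                    quality[ids[i]] = TRACK_FAILED
                    quality[ids[claimed[j]]] = TRACK_FAILED
                    continue
                claimed[j] = i
                col[i] = j
            for i in range(n0):
                if col[i] is not None and quality[ids[i]] == TRACK_OK:
                    pos[i] = regions_per_frame[f][col[i]].centroid
        else:
            for did in ids:
                quality[did] = TRACK_FAILED
        assign.append(col)

    for i, did in enumerate(ids):
        if any(a[i] is None for a in assign):
            if quality[did] == TRACK_OK:
                quality[did] = TRACK_FAILED
        frames_regions = [
            regions_per_frame[f][assign[f][i]]
            for f in range(len(assign))
            if assign[f][i] is not None
        ]
        if quality[did] == TRACK_OK and any(r.edge_flag for r in frames_regions):
            quality[did] = TRACK_EDGE

    rows = []
    for f, col in enumerate(assign):
        for i, j in enumerate(col):
            rows.append(
                {
                    "droplet_id": ids[i],
                    "frame": f,
                    "region_index": -1 if j is None else j,
                    "track_quality": quality[ids[i]],
                }
            )
    return pd.DataFrame(rows)


def count_cells(
    coords: np.ndarray,
    cell_stain_frames: np.ndarray,
    threshold: float = 90.0,
) -> int:
    """Number of distinct above-threshold cell blobs inside a droplet.

    Blobs are counted as intensity peaks (local maxima), so two adjacent
    cells whose stain blobs touch still count as two. The count is
    maximized over frames (cells may bleach), which keeps multi-cell
    exclusion conservative.
    """
    from skimage.feature import peak_local_max

    if coords.size == 0:
        raise ValueError("empty droplet mask")
    rr, cc = coords[:, 0], coords[:, 1]
    r0, r1 = rr.min(), rr.max() + 1
    c0, c1 = cc.min(), cc.max() + 1
    local = np.zeros((r1 - r0, c1 - c0), dtype=bool)
    local[rr - r0, cc - c0] = True
    best = 0
    for frame in cell_stain_frames:
        patch = frame[r0:r1, c0:c1].astype(float)
        blobs = label((patch >= threshold) & local)
        if blobs.max() == 0:
            continue
        peaks = peak_local_max(
            patch, labels=blobs, min_distance=2, threshold_abs=threshold,
            exclude_border=False,
        )
        best = max(best, len(peaks))
    return best


def _beadline_mean(
    patch_vals: np.ndarray,
    coords: np.ndarray,
    droplet_mean: float,
    quantile: float = 0.02,
) -> tuple[float, bool]:
    """Mean intensity of the nanoparticle beadline inside one droplet.

    The beadline is taken as the compact cluster of pixels well above the
    droplet mean; when no such cluster exists (no relocation yet) the
    mean of the top ``quantile`` intensity fraction is used and flagged.
    """
    bright = patch_vals > 1.3 * droplet_mean
    if bright.sum() >= 6:
        return float(patch_vals[bright].mean()), False
    k = max(int(len(patch_vals) * quantile), 1)
    top = np.partition(patch_vals, -k)[-k:]
    return float(top.mean()), True


def extract_traces(
    tracks: pd.DataFrame,
    regions_per_frame: list[list[DropletRegion]],
    images: dict[str, np.ndarray],
    acq: AcquisitionSpec,
    cell_threshold: float = 90.0,
) -> pd.DataFrame:
    """Per-droplet, per-frame, per-channel intensity traces.

    For every tracked droplet and channel: ``droplet_mean`` is the mean
    over the droplet mask, ``beadline_mean`` the mean over the beadline
    cluster in the A647 channel (top-quantile fallback flagged
    ``beadline_fallback``), and ``cell_mean`` the mean over detected cell
    pixels. Missing frames flag the droplet instead of dropping it.
    """
    times = acq.times_s
    stain = images.get(CHANNEL_CELL_STAIN)
    rows = []
    for did, grp in tracks.groupby("droplet_id", sort=False):
        grp = grp.sort_values("frame")
        quality = grp["track_quality"].iloc[0]
        ref = grp[grp["region_index"] >= 0]
        if ref.empty:
            continue
        region0 = regions_per_frame[int(ref["frame"].iloc[0])][int(ref["region_index"].iloc[0])]
        coords = region0.coords
        rr, cc = coords[:, 0], coords[:, 1]

        n_cells = 0
        if stain is not None:
            n_cells = count_cells(coords, stain, threshold=cell_threshold)
        cell_px = None
        if stain is not None and n_cells > 0:
            sel = stain[:, rr, cc].max(axis=0) >= cell_threshold
            cell_px = sel

        for _, rec in grp.iterrows():
            f = int(rec["frame"])
            if rec["region_index"] < 0:
                continue  # missing frame; droplet already flagged
            for ch, stack in images.items():
                vals = stack[f, rr, cc].astype(float)
                dmean = float(vals.mean())
                flags = []
                if ch == CHANNEL_A647:
                    bmean, fallback = _beadline_mean(vals, coords, dmean)
                    if fallback:
                        flags.append("beadline_fallback")
                else:
                    bmean = dmean
                if cell_px is not None:
                    cmean = float(vals[cell_px].mean())
                else:
                    cmean = 0.0
                rows.append(
                    {
                        "droplet_id": did,
                        "frame": f,
                        "time_s": times[f],
                        "channel": ch,
                        "droplet_mean": dmean,
                        "beadline_mean": bmean,
                        "cell_mean": cmean,
                        "n_cells": n_cells,
                        "track_quality": quality,
                        "flags": ";".join(flags),
                    }
                )
    return pd.DataFrame(rows)


def flag_stitch_suspects(
    traces: pd.DataFrame,
    centroids: pd.DataFrame,
    layout: dict,
    margin: float | None = None,
) -> pd.DataFrame:
    """Mark droplets near internal tile boundaries as ``stitch_suspect``.

    Inaccurate stitching of the tiled acquisition is a known source of
    spurious signal loss, so droplets within ``margin`` pixels (default:
    droplet radius + 1) of a tile line are excluded downstream.
    """
    margin = margin if margin is not None else float(centroids["radius_px"].iloc[0]) + 1
    suspects = set()
    for _, rec in centroids.iterrows():
        if any(abs(rec["row"] - L) <= margin for L in layout.get("row_lines", [])) or any(
            abs(rec["col"] - L) <= margin for L in layout.get("col_lines", [])
        ):
            suspects.add(rec["droplet_id"])
    out = traces.copy()
    sel = out["droplet_id"].isin(suspects) & (out["track_quality"] == TRACK_OK)
    out.loc[sel, "track_quality"] = TRACK_STITCH
    return out


def read_image_series(indir: str | Path) -> tuple[dict[str, np.ndarray], dict]:
    """Read per-channel TIFF stacks plus the stitch-layout JSON written
    by the synthetic renderer (or equivalently organized real data)."""
    import tifffile

    indir = Path(indir)
    with open(indir / "layout.json") as fh:
        layout = json.load(fh)
    images = {}
    for ch in layout["channels"]:
        frames = [
            tifffile.imread(indir / f"ch_{ch}_t{t:02d}.tif")
            for t in range(layout["n_frames"])
        ]
        images[ch] = np.stack(frames)
    return images, layout
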