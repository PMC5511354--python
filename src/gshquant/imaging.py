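"""Two-channel ratiometric image quantification.

Confocal frames are acquired as paired 405-nm- and 488-nm-excitation
intensity images.  The pipeline subtracts a per-channel scalar
background, segments cells on the channel-sum image, forms the per-pixel
ratio ch405/ch488 inside cells (with a denominator floor to keep dim
pixels from blowing up the ratio), reduces each cell to its median ratio,
and converts that to a GSH concentration through a fitted calibration.
Time-lapse stacks additionally link cells across frames by
nearest-centroid matching and report a population mean ± s.e.m. trace.

The per-cell statistic is the median ratio (robust to saturated and
floor-adjacent pixels), and the concentration is computed from that
median — not averaged over per-pixel concentrations — because the
calibration inversion is nonlinear.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import tifffile
from skimage import filters, measure

from .calibration import CalibrationModel, concentration_from_ratio

__all__ = [
    "TwoChannelImage",
    "RatioMap",
    "subtract_background",
    "segment_cells",
    "pixel_ratio_map",
    "per_cell_summary",
    "track_cells",
    "quantify_timelapse",
    "read_two_channel_tiff",
    "write_two_channel_tiff",
]


@dataclass
class TwoChannelImage:
    """Paired 405/488 excitation intensity planes of identical shape."""

    ch405: np.ndarray
    ch488: np.ndarray
    pixel_size_um: float = 1.0
    background: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ch405 = np.asarray(self.ch405, float)
        self.ch488 = np.asarray(self.ch488, float)
        if self.ch405.shape != self.ch488.shape:
            raise ValueError("channel shapes differ")
        if not (np.all(np.isfinite(self.ch405)) and np.all(np.isfinite(self.ch488))):
            raise ValueError("intensities must be finite")


@dataclass
class RatioMap:
    """Per-pixel 405/488 ratio, NaN outside the mask."""

    ratio: np.ndarray
    mask: np.ndarray
    denominator_floor: float

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.ratio[self.mask])):
            raise ValueError("ratio must be finite inside the mask")


def read_two_channel_tiff(path, channel_order=(0, 1), pixel_size_um: float = 1.0):
    """Read a 2-page TIFF; page order (405, 488) by default, overridable."""
    pages = tifffile.imread(path)
    if pages.ndim == 2 or pages.shape[0] < 2:
        raise ValueError("expected a multi-page TIFF with 2 pages per frame")
    i405, i488 = channel_order
    return TwoChannelImage(pages[i405], pages[i488], pixel_size_um=pixel_size_um)


def write_two_channel_tiff(img: TwoChannelImage, path) -> None:
    tifffile.imwrite(path, np.stack([img.ch405, img.ch488]).astype(np.float32))


def subtract_background(
    img: TwoChannelImage,
    method: str = "mode",
    percentile: float = 5.0,
    dark_region: tuple[slice, slice] | None = None,
) -> TwoChannelImage:
    """Remove a per-channel scalar background; negatives clip to zero.

    ``method="mode"`` (default) takes the median of the pixels below each
    channel's Otsu threshold — an unbiased estimate of the background
    level when cells cover a minority of the field, where a low
    percentile would systematically undershoot shot-noise-limited
    backgrounds.  ``method="percentile"`` uses a low percentile of each
    channel; ``method="dark-region"`` averages over a caller-supplied
    region of (presumed) cell-free pixels.  The estimated backgrounds and
    their standard deviations are recorded on the returned image.
    """
    if method == "mode":
        est = {}
        for name, ch in (("405", img.ch405), ("488", img.ch488)):
            if np.ptp(ch) == 0:
                dark = ch.ravel()
            else:
                dark = ch[ch <= filters.threshold_otsu(ch)]
                if dark.size == 0:
                    dark = ch.ravel()
            est[name] = (float(np.median(dark)), float(np.std(dark)))
        bg405, sd405 = est["405"]
        bg488, sd488 = est["488"]
    elif method == "percentile":
        bg405 = float(np.percentile(img.ch405, percentile))
        bg488 = float(np.percentile(img.ch488, percentile))
        low405 = img.ch405[img.ch405 <= np.percentile(img.ch405, 2 * percentile)]
        low488 = img.ch488[img.ch488 <= np.percentile(img.ch488, 2 * percentile)]
        sd405, sd488 = float(np.std(low405)), float(np.std(low488))
    elif method == "dark-region":
        if dark_region is None:
            raise ValueError("dark-region method requires a region")
        ys, xs = dark_region
        h, w = img.ch405.shape
        if (ys.stop or h) > h or (xs.stop or w) > w:
            raise ValueError("dark region outside image")
        bg405 = float(np.mean(img.ch405[ys, xs]))
        bg488 = float(np.mean(img.ch488[ys, xs]))
        sd405 = float(np.std(img.ch405[ys, xs]))
        sd488 = float(np.std(img.ch488[ys, xs]))
    else:
        raise ValueError(f"unknown background method {method!r}")
    out = TwoChannelImage(
        np.clip(img.ch405 - bg405, 0.0, None),
        np.clip(img.ch488 - bg488, 0.0, None),
        pixel_size_um=img.pixel_size_um,
    )
    out.background = {"bg405": bg405, "bg488": bg488, "sd405": sd405, "sd488": sd488}
    return out


def segment_cells(img: TwoChannelImage, min_area_px: int = 50) -> np.ndarray:
    """Label map from Otsu thresholding of the channel-sum image.

    Connected components use 8-connectivity; components smaller than
    ``min_area_px`` are dropped.  An all-background image yields an empty
    (all-zero) label map, which is a valid result, not an error.
    """
    if min_area_px < 1:
        raise ValueError("min_area_px must be >= 1")
    total = img.ch405 + img.ch488
    if np.ptp(total) == 0:
        return np.zeros(total.shape, dtype=int)
    thresh = filters.threshold_otsu(total)
    fg = total > thresh
    labels = measure.label(fg, connectivity=2)
    areas = np.bincount(labels.ravel())
    small = np.flatnonzero(areas < min_area_px)
    labels[np.isin(labels, small[small > 0])] = 0
    # renumber 1..N after dropping small components
    return measure.label(labels > 0, connectivity=2)


def pixel_ratio_map(
    img: TwoChannelImage,
    labels: np.ndarray,
    denominator_floor: float | None = None,
) -> RatioMap:
    """Per-pixel ch405/ch488 within labelled cells.

    Pixels whose 488 signal does not exceed the floor become NaN.  The
    default floor is three times the recorded background standard
    deviation (zero if no background was recorded), suppressing ratio
    blow-up in dim pixels.
    """
    if denominator_floor is None:
        denominator_floor = 3.0 * img.background.get("sd488", 0.0)
    if denominator_floor < 0:
        raise ValueError("denominator floor must be >= 0")
    valid = (labels > 0) & (img.ch488 > denominator_floor)
    ratio = np.full(img.ch488.shape, np.nan)
    ratio[valid] = img.ch405[valid] / img.ch488[valid]
    return RatioMap(ratio=ratio, mask=valid, denominator_floor=denominator_floor)


def per_cell_summary(
    rmap: RatioMap, labels: np.ndarray, cm: CalibrationModel
) -> pd.DataFrame:
    """Median ratio and calibrated concentration per labelled cell.

    Cells with no valid pixels are flagged ``"empty"``; out-of-range
    median ratios carry the calibration's below-range/saturated flags.
    """
    rows = []
    for lab in np.unique(labels[labels > 0]):
        vals = rmap.ratio[(labels == lab) & rmap.mask]
        if vals.size == 0:
            rows.append(
                {"cell_id": int(lab), "n_pixels": 0, "median_ratio": np.nan,
                 "gsh_mM": np.nan, "flag": "empty"}
            )
            continue
        med = float(np.median(vals))
        c, flag = concentration_from_ratio(med, cm)
        rows.append(
            {"cell_id": int(lab), "n_pixels": int(vals.size),
             "median_ratio": med, "gsh_mM": c, "flag": flag}
        )
    return pd.DataFrame(rows, columns=["cell_id", "n_pixels", "median_ratio", "gsh_mM", "flag"])


def _centroids(labels: np.ndarray) -> dict[int, np.ndarray]:
    return {
        p.label: np.asarray(p.centroid) for p in measure.regionprops(labels)
    }


def track_cells(
    label_maps: list[np.ndarray], max_displacement: float | None = None
) -> list[dict[int, int]]:
    """Link labels across frames by greedy nearest-centroid matching.

    Returns one ``{label: track_id}`` dict per frame.  Unmatched labels
    start new tracks; a cell that disappears ends its track (the id is
    never reassigned).  The default displacement bound is 20% of the mean
    equivalent cell diameter per frame.
    """
    if len(label_maps) < 2:
        raise ValueError("tracking needs at least 2 frames")
    if max_displacement is None:
        areas = [p.area for lm in label_maps for p in measure.regionprops(lm)]
        mean_diam = 2.0 * np.sqrt(np.mean(areas) / np.pi) if areas else 0.0
        max_displacement = max(0.2 * mean_diam, 1.0)

    assignments: list[dict[int, int]] = []
    next_track = 1
    prev: dict[int, np.ndarray] = {}
    prev_tracks: dict[int, int] = {}
    for lm in label_maps:
        cents = _centroids(lm)
        frame_map: dict[int, int] = {}
        used_prev: set[int] = set()
        # greedy: closest pairs first
        pairs = sorted(
            (
                (np.linalg.norm(c - pc), lab, plab)
                for lab, c in cents.items()
                for plab, pc in prev.items()
            ),
            key=lambda x: x[0],
        )
        for dist, lab, plab in pairs:
            if dist > max_displacement:
                break
            if lab in frame_map or plab in used_prev:
                continue
            frame_map[lab] = prev_tracks[plab]
            used_prev.add(plab)
        for lab in cents:
            if lab not in frame_map:
                frame_map[lab] = next_track
                next_track += 1
        assignments.append(frame_map)
        prev = cents
        prev_tracks = frame_map
    return assignments


def quantify_timelapse(
    stack: list[TwoChannelImage],
    times,
    cm: CalibrationModel,
    min_area_px: int = 50,
    background_method: str = "mode",
):
    """Full pipeline over a time-lapse stack.

    Each frame is background-subtracted, segmented, converted to a ratio
    map and summarised per cell; cells are then tracked across frames.
    Returns ``(cell_traces, population)`` DataFrames: one row per
    (track, frame), and the per-frame mean ± s.e.m. of per-cell
    concentrations over cells with in-range ratios.
    """
    times = np.asarray(times, float)
    if len(stack) != times.size:
        raise ValueError("one time point per frame required")
    shapes = {img.ch405.shape for img in stack}
    if len(shapes) > 1:
        raise ValueError("inconsistent frame shapes")

    frames = []
    label_maps = []
    for img in stack:
        sub = subtract_background(img, method=background_method)
        labels = segment_cells(sub, min_area_px=min_area_px)
        rmap = pixel_ratio_map(sub, labels)
        frames.append(per_cell_summary(rmap, labels, cm))
        label_maps.append(labels)

    if len(stack) >= 2:
        tracks = track_cells(label_maps)
    else:
        tracks = [{int(lab): int(lab) for lab in np.unique(label_maps[0]) if lab > 0}]

    rows = []
    for fi, (summary, frame_map) in enumerate(zip(frames, tracks)):
        for _, r in summary.iterrows():
            rows.append(
                {"frame": fi, "time_s": times[fi],
                 "cell_id": frame_map.get(int(r.cell_id), -1),
                 "median_ratio": r.median_ratio, "gsh_mM": r.gsh_mM,
                 "flag": r.flag}
            )
    cell_traces = pd.DataFrame(
        rows, columns=["frame", "time_s", "cell_id", "median_ratio", "gsh_mM", "flag"]
    )

    pop_rows = []
    for fi in range(len(stack)):
        sel = cell_traces[(cell_traces.frame == fi) & (cell_traces.flag == "ok")]
        c = sel.gsh_mM.to_numpy()
        n = c.size
        pop_rows.append(
            {"frame": fi, "time_s": times[fi],
             "mean_mM": float(np.mean(c)) if n else np.nan,
             "sem_mM": float(np.std(c, ddof=1) / np.sqrt(n)) if n > 1 else np.nan,
             "n_cells": n}
        )
    population = pd.DataFrame(pop_rows)
    return cell_traces, population
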