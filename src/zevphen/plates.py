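"""Colony-grid quantification and size normalization.

Quantification follows the standard pinned-plate recipe: detect the
periodic colony lattice from axis projections of foreground intensity,
then count pixels above a locally estimated background (adaptive
threshold) inside each grid cell.  Normalization removes plate,
positional, and competition effects in that order, and flags perimeter
colonies, which are excluded from downstream statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .config import LAYOUTS, QuantConfig

__all__ = [
    "GridModel",
    "GridDetectionError",
    "detect_grid",
    "measure_colonies",
    "normalize_sizes",
    "quantify_plate",
    "SIZES_COLUMNS",
]

SIZES_COLUMNS = [
    "plate_id",
    "medium",
    "dose_nM",
    "time_h",
    "row",
    "col",
    "strain_id",
    "raw_size",
    "normalized_size",
    "edge_flag",
    "excluded_flag",
]


class GridDetectionError(RuntimeError):
    """No periodic colony lattice could be located on the image."""


@dataclass
class GridModel:
    """Detected colony lattice: center coordinates and cell half-width."""

    row_centers: np.ndarray  # y coordinates, strictly increasing
    col_centers: np.ndarray  # x coordinates, strictly increasing
    half_width: float        # cell half-width in pixels

    @property
    def n_rows(self) -> int:
        return len(self.row_centers)

    @property
    def n_cols(self) -> int:
        return len(self.col_centers)

    @property
    def pitch(self) -> float:
        return float(
            np.mean([np.diff(self.row_centers).mean(), np.diff(self.col_centers).mean()])
        )

    def validate(self, image_shape: tuple[int, int]) -> None:
        for centers, bound in ((self.row_centers, image_shape[0]), (self.col_centers, image_shape[1])):
            if np.any(np.diff(centers) <= 0):
                raise ValueError("grid centers must be strictly increasing")
            if centers[0] < 0 or centers[-1] >= bound:
                raise ValueError("grid centers outside image bounds")


def _foreground_mask(image: np.ndarray) -> np.ndarray:
    med = float(np.median(image))
    mad = float(np.median(np.abs(image.astype(float) - med))) * 1.4826
    return image.astype(float) > med + 3.0 * max(mad, 1e-9)


def _axis_centers(profile: np.ndarray, n_expected: int) -> np.ndarray:
    """Locate the n_expected periodic peaks of a 1-D foreground profile."""
    pitch0 = len(profile) / (n_expected + 1)
    smooth = ndimage.gaussian_filter1d(profile.astype(float), sigma=max(pitch0 / 12, 1.0))
    if smooth.max() <= 0:
        raise GridDetectionError("no foreground signal on axis projection")
    peaks, _ = signal.find_peaks(
        smooth, distance=max(int(0.6 * pitch0), 1), prominence=0.05 * smooth.max()
    )
    if len(peaks) < max(2, int(0.5 * n_expected)):
        raise GridDetectionError(
            f"found only {len(peaks)} candidate grid lines, expected {n_expected}"
        )
    diffs = np.diff(peaks)
    pitch = float(np.median(diffs))
    good = diffs[(diffs > 0.5 * pitch) & (diffs < 1.5 * pitch)]
    if len(good):
        pitch = float(np.median(good))
    # fit positions to a lattice: p ~ offset + pitch * k
    k = np.round((peaks - peaks[0]) / pitch).astype(int)
    A = np.vstack([np.ones_like(k, dtype=float), k.astype(float)]).T
    coef, *_ = np.linalg.lstsq(A, peaks.astype(float), rcond=None)
    offset, pitch = float(coef[0]), float(coef[1])
    span = int(k.max()) + 1
    if span > n_expected:
        raise GridDetectionError(
            f"{span} lattice lines span the image but {n_expected} were expected"
        )
    # anchor the lattice window holding all observed lines; missing edge
    # lines are extrapolated from the fit
    start_shift = 0 if span == n_expected else -int(
        round((offset - (len(profile) - (n_expected - 1) * pitch) / 2) / pitch)
    )
    centers = offset + pitch * (np.arange(n_expected) - max(min(start_shift, n_expected - span), 0))
    # refine each center by local centroid of the raw profile
    refined = []
    for c in centers:
        lo = int(max(c - 0.35 * pitch, 0))
        hi = int(min(c + 0.35 * pitch + 1, len(profile)))
        w = profile[lo:hi].astype(float)
        refined.append((np.arange(lo, hi) * w).sum() / w.sum() if w.sum() > 0 else c)
    return np.asarray(refined)


def detect_grid(image: np.ndarray, n_rows: int, n_cols: int) -> GridModel:
    """Detect the colony lattice by projecting foreground onto both axes.

    Robust to missing colonies as long as each grid row/column retains some
    occupied positions.  Raises :class:`GridDetectionError` on blank or
    aperiodic images.
    """
    image = np.asarray(image)
    if image.ndim != 2:
        raise ValueError("image must be 2-D grayscale")
    fg = _foreground_mask(image)
    if fg.mean() < 0.002:
        raise GridDetectionError("image has no detectable foreground (blank plate?)")
    col_centers = _axis_centers(fg.sum(axis=0), n_cols)
    row_centers = _axis_centers(fg.sum(axis=1), n_rows)
    pitch = float(np.mean([np.diff(row_centers).mean(), np.diff(col_centers).mean()]))
    grid = GridModel(row_centers, col_centers, half_width=pitch / 2)
    grid.validate(image.shape)
    return grid


def measure_colonies(
    image: np.ndarray, grid: GridModel, config: QuantConfig | None = None
) -> pd.DataFrame:
    """Count pixels above a local adaptive threshold in every grid cell.

    The background is estimated per cell from a window spanning
    ``config.window_pitches`` grid pitches; the threshold is the window
    median plus ``mad_k`` robust standard deviations.  Empty cells yield 0.
    """
    config = config or QuantConfig()
    image = np.asarray(image, dtype=float)
    grid.validate(image.shape)
    pitch = grid.pitch
    hw = int(round(grid.half_width))
    win = int(round(config.window_pitches * pitch))
    rows = []
    for i, cy in enumerate(np.round(grid.row_centers).astype(int)):
        for j, cx in enumerate(np.round(grid.col_centers).astype(int)):
            if not (0 <= cy < image.shape[0] and 0 <= cx < image.shape[1]):
                raise ValueError(f"grid cell ({i},{j}) outside image")
            w = image[
                max(cy - win, 0) : cy + win + 1, max(cx - win, 0) : cx + win + 1
            ]
            med = np.median(w)
            mad = np.median(np.abs(w - med)) * 1.4826
            thr = med + config.mad_k * max(mad, 1e-9)
            cell = image[
                max(cy - hw, 0) : cy + hw + 1, max(cx - hw, 0) : cx + hw + 1
            ]
            rows.append((i, j, int((cell > thr).sum())))
    return pd.DataFrame(rows, columns=["row", "col", "raw_size"])


def quantify_plate(
    image: np.ndarray,
    layout: int,
    plate_meta: dict,
    position_map: pd.DataFrame | None = None,
    config: QuantConfig | None = None,
) -> pd.DataFrame:
    """Detect the grid, measure colonies, and attach plate metadata.

    ``position_map`` (row, col, strain_id) labels positions; unmapped
    positions get strain_id ''.
    """
    n_rows, n_cols = LAYOUTS[layout]
    grid = detect_grid(image, n_rows, n_cols)
    sizes = measure_colonies(image, grid, config)
    if position_map is not None:
        sizes = sizes.merge(position_map[["row", "col", "strain_id"]], on=["row", "col"], how="left")
        sizes["strain_id"] = sizes["strain_id"].fillna("")
    else:
        sizes["strain_id"] = ""
    for key in ("plate_id", "medium", "dose_nM", "time_h"):
        sizes[key] = plate_meta.get(key, "" if key in ("plate_id", "medium") else np.nan)
    return sizes


def _plate_normalize(
    g: pd.DataFrame, n_rows: int, n_cols: int, config: QuantConfig
) -> pd.DataFrame:
    grid = np.full((n_rows, n_cols), np.nan)
    grid[g["row"], g["col"]] = g["raw_size"].to_numpy(dtype=float)
    interior = np.zeros((n_rows, n_cols), dtype=bool)
    interior[1:-1, 1:-1] = True

    measurable = np.nanmean((grid[interior] > 0).astype(float))
    low_quality = bool(measurable < config.min_measurable)
    if low_quality:
        warnings.warn(
            f"plate {g['plate_id'].iloc[0]!r}: only {measurable:.0%} of interior "
            "colonies measurable; marked low-quality",
            stacklevel=3,
        )

    # (1) plate effect: interior median to 1
    plate_med = np.nanmedian(grid[interior])
    s = grid / plate_med if plate_med > 0 else grid.copy()

    # (2) positional effect: smooth spatial surface, then row/col medians
    filled = np.where(np.isnan(s), np.nanmedian(s), s)
    surface = ndimage.median_filter(filled, size=config.spatial_window, mode="nearest")
    surface = np.where(surface > 0, surface, 1.0)
    s = s / surface
    with warnings.catch_warnings():
        # perimeter rows/cols have no interior cells; their medians fall back to 1
        warnings.simplefilter("ignore", RuntimeWarning)
        row_med = np.nanmedian(np.where(interior, s, np.nan), axis=1, keepdims=True)
        col_med = np.nanmedian(np.where(interior, s, np.nan), axis=0, keepdims=True)
    s = s / np.where(row_med > 0, row_med, 1.0) / np.where(col_med > 0, col_med, 1.0)

    # (3) competition effect: cap colonies inflated by empty/dead neighbors
    empty = np.nan_to_num(s, nan=0.0) < config.empty_fraction
    n_empty = ndimage.uniform_filter(empty.astype(float), size=3, mode="constant") * 9
    n_empty = np.round(n_empty - empty.astype(float)).astype(int)  # 8-neighborhood
    with warnings.catch_warnings():
        # neighborhoods that are entirely empty yield NaN medians, handled below
        warnings.simplefilter("ignore", RuntimeWarning)
        nb_med = ndimage.generic_filter(
            np.where(empty, np.nan, s), np.nanmedian, size=config.spatial_window, mode="nearest"
        )
    cap_mask = (n_empty >= config.competition_min_empty) & ~empty & (s > nb_med)
    s = np.where(cap_mask & np.isfinite(nb_med), nb_med, s)

    # final rescale so the interior median is exactly 1
    final_med = np.nanmedian(s[interior])
    if final_med > 0:
        s = s / final_med

    out = g.copy()
    out["normalized_size"] = s[g["row"], g["col"]]
    edge = (g["row"].isin([0, n_rows - 1]) | g["col"].isin([0, n_cols - 1])).to_numpy()
    out["edge_flag"] = edge
    out["excluded_flag"] = edge | ~np.isfinite(out["normalized_size"].to_numpy())
    out.loc[out["excluded_flag"], "normalized_size"] = np.nan
    out["plate_low_quality"] = low_quality
    return out


def normalize_sizes(
    sizes: pd.DataFrame, layout: int, config: QuantConfig | None = None
) -> pd.DataFrame:
    """Normalize raw colony sizes for plate, positional, and competition effects.

    Each plate is processed independently: divide by the plate interior
    median, divide out a smoothed spatial surface plus row/column medians,
    cap colonies inflated by dead neighborhoods, then flag and exclude the
    perimeter.  Interior median of normalized sizes is exactly 1 per plate,
    and the result is invariant to a global rescaling of raw sizes.
    """
    config = config or QuantConfig()
    if sizes.empty:
        raise ValueError("empty size table")
    if (sizes["raw_size"] < 0).any():
        raise ValueError("raw_size must be nonnegative")
    n_rows, n_cols = LAYOUTS[layout]
    parts = [
        _plate_normalize(g, n_rows, n_cols, config)
        for _, g in sizes.groupby("plate_id", sort=True)
    ]
    return pd.concat(parts, ignore_index=True)
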