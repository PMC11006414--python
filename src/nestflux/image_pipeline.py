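"""Timelapse change-detection pipeline for building activity.

Turns a top-view timelapse of a building arena plus a trajectory table
into spatial probability maps of pellet collection P(C), pellet
deposition P(D) and animal occupancy P(O), their conditionals P(C|O) and
P(D|O), and radial activity profiles.

The change-detection chain: subsample the recording to one frame per
search-collection-deposition cycle (80 s), convert to greyscale, subtract
the animal-free reference frame, suppress the moving animals with a
rolling median over 10 consecutive frames, then integrate activity in
windows of 10 frames (800 s).  Collected pellets leave persistent dark
traces, deposited pellets persistent bright traces; each polarity is
thresholded and segmented with connected components, keeping components
between 10 and 400 px (half the smallest pellet up to a cluster of
resting animals).  Component masses are finally binned onto a grid whose
cell is one average pellet (0.75 mm).

Because pellets are almost always displaced only once, the change image
of the last window already contains every past event, so it serves as
the cumulative activity map.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

MEDIAN_WINDOW = 10
BLOCK_SIZE = 10
CELL_MM = 0.75
_LUMA = np.array([0.2126, 0.7152, 0.0722])


@dataclass
class TimelapseSequence:
    """In-memory timelapse: frames (n, H, W[, 3]), timestamps in s,
    pixel pitch in mm/px and the animal-free reference frame."""

    frames: np.ndarray
    timestamps: np.ndarray
    pixel_pitch: float
    reference: np.ndarray

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim not in (3, 4):
            raise ValueError("frames must be (n, H, W) or (n, H, W, 3)")
        if len(self.frames) != len(self.timestamps):
            raise ValueError("one timestamp per frame required")
        if len(self.timestamps) > 1 and not (np.diff(self.timestamps) > 0).all():
            raise ValueError("timestamps must be strictly increasing")
        if self.reference.shape != self.frames.shape[1:]:
            raise ValueError("reference frame shape mismatch")
        if self.pixel_pitch <= 0:
            raise ValueError("pixel pitch must be positive")

    @property
    def cadence(self) -> float:
        if len(self.timestamps) < 2:
            raise ValueError("cadence undefined for a single frame")
        return float(np.median(np.diff(self.timestamps)))

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:3]


@dataclass
class ChangeWindows:
    """Per-window change images.

    ``mean`` is the activity value integrated over each 800 s window (the
    quantity accumulated into heatmaps); ``low``/``high`` are the
    per-window pixelwise min/max across the window's ten median-filtered
    frames, used to require that a candidate trace is *static* within the
    window — a pellet trace holds its contrast for the whole window while
    residual animal transients do not.
    """

    mean: np.ndarray
    low: np.ndarray
    high: np.ndarray

    def __len__(self) -> int:
        return len(self.mean)


@dataclass
class ActivityHeatmap:
    """Per-window and cumulative activity grids at 0.75 mm cell size."""

    windows: np.ndarray        # (n_windows, H_c, W_c)
    cumulative: np.ndarray     # last-window estimate of cumulative activity
    window_length: float       # s
    cell_mm: float = CELL_MM


@dataclass
class OccupancyMap:
    windows: np.ndarray
    cumulative: np.ndarray     # sum over windows (positions are transient)
    window_length: float
    cell_mm: float = CELL_MM
    n_dropped: int = 0


@dataclass
class ConditionalMap:
    values: np.ndarray
    valid: np.ndarray


@dataclass
class Event:
    """One connected component in a window change image."""

    window: int
    centroid_px: tuple[float, float]   # (row, col)
    area_px: int
    mass: float


# ---------------------------------------------------------------------------
# Frame handling
# ---------------------------------------------------------------------------

def load_frames(paths: list, timestamps, pixel_pitch: float,
                reference_path=None) -> TimelapseSequence:
    """Read numbered TIFF/PNG frames into a sequence."""
    import imageio.v3 as iio

    frames = np.stack([iio.imread(str(p)) for p in paths])
    ref = iio.imread(str(reference_path)) if reference_path is not None else frames[0]
    return TimelapseSequence(frames, np.asarray(timestamps, float), pixel_pitch, ref)


def to_greyscale(img: np.ndarray) -> np.ndarray:
    if img.ndim == 3:
        return img.astype(float) @ _LUMA
    return img.astype(float)


def extract_frames(seq: TimelapseSequence, interval: float = 80.0) -> TimelapseSequence:
    """Subsample the recording to one frame every ``interval`` seconds.

    The interval must be a whole multiple of the native cadence.
    """
    cadence = seq.cadence
    ratio = interval / cadence
    if interval < cadence - 1e-9:
        raise ValueError(f"interval {interval}s below native cadence {cadence}s")
    if abs(ratio - round(ratio)) > 1e-9:
        raise ValueError(
            f"interval {interval}s is not a multiple of the cadence {cadence}s")
    step = int(round(ratio))
    return TimelapseSequence(seq.frames[::step], seq.timestamps[::step],
                             seq.pixel_pitch, seq.reference)


def n_windows(n_frames: int) -> int:
    """Analysis windows available from n subsampled frames (valid-mode
    rolling median of 10 followed by non-overlapping blocks of 10)."""
    return max((n_frames - MEDIAN_WINDOW + 1) // BLOCK_SIZE, 0)


def detect_changes(seq: TimelapseSequence) -> ChangeWindows:
    """Background-subtracted, animal-suppressed window change images.

    Greyscale conversion, subtraction of the animal-free reference, a
    trailing rolling median over 10 consecutive frames (valid mode), then
    integration over non-overlapping blocks of 10 median images (800 s
    windows at the 80 s working cadence).  Collected pellets appear as
    persistent negative (dark) values, deposits as positive (bright)
    values.  Fewer than 10 frames produce zero windows.
    """
    grey = np.stack([to_greyscale(f) for f in seq.frames])
    ref = to_greyscale(seq.reference)
    diff = grey - ref[None]
    n = len(diff)
    nw = n_windows(n)
    if nw == 0:
        z = np.zeros((0,) + diff.shape[1:])
        return ChangeWindows(z, z.copy(), z.copy())
    # trailing rolling median over MEDIAN_WINDOW frames, valid mode
    n_med = n - MEDIAN_WINDOW + 1
    med = np.empty((n_med,) + diff.shape[1:])
    for i in range(n_med):
        med[i] = np.median(diff[i:i + MEDIAN_WINDOW], axis=0)
    # non-overlapping blocks of BLOCK_SIZE median images
    mean = np.empty((nw,) + diff.shape[1:])
    low = np.empty_like(mean)
    high = np.empty_like(mean)
    for w in range(nw):
        block = med[w * BLOCK_SIZE:(w + 1) * BLOCK_SIZE]
        mean[w] = block.mean(axis=0)
        low[w] = block.min(axis=0)
        high[w] = block.max(axis=0)
    return ChangeWindows(mean, low, high)


def robust_threshold(change: np.ndarray, mask: np.ndarray | None = None,
                     k: float = 3.0) -> float:
    """k * MAD of the change-image values (over ``mask`` if given)."""
    vals = change[mask] if mask is not None else change.ravel()
    mad = np.median(np.abs(vals - np.median(vals)))
    return float(k * mad)


def extract_events(changes: ChangeWindows | np.ndarray, polarity: str,
                   threshold: float | None = None,
                   mask: np.ndarray | None = None,
                   area_min: int = 10, area_max: int = 400,
                   k: float = 3.0, static_only: bool = True) -> list[list[Event]]:
    """Segment per-window change images into candidate pellet events.

    ``polarity`` is "collection" (dark traces) or "deposition" (bright
    traces).  Components with area in the closed interval
    [area_min, area_max] px are retained.  When ``threshold`` is None it
    defaults to ``k`` times the MAD of the (signed) change values.

    With ``static_only`` (default) a pixel only counts if its trace holds
    at least half the threshold in *every* median frame of the window:
    pellet traces are static once laid down, so this removes the residual
    transients of animals that lingered long enough to leak through the
    rolling median.  Pass a plain array (or ``static_only=False``) to
    segment on the window means alone.
    """
    if isinstance(changes, ChangeWindows):
        means = changes.mean
        # the window-wise extreme on the trace side of zero
        floors = changes.low if polarity == "deposition" else -changes.high
    else:
        means = np.asarray(changes)
        floors = None
    if polarity == "collection":
        signal = -means
    elif polarity == "deposition":
        signal = means.copy()
    else:
        raise ValueError("polarity must be 'collection' or 'deposition'")
    out: list[list[Event]] = []
    for w, img in enumerate(signal):
        thr = threshold if threshold is not None else robust_threshold(img, mask, k)
        binary = img > thr
        if floors is not None and static_only:
            binary &= floors[w] > thr / 2
        if mask is not None:
            binary &= mask
        lbl, n = ndimage.label(binary)
        events = []
        if n:
            areas = ndimage.sum_labels(binary, lbl, index=np.arange(1, n + 1))
            keep = np.flatnonzero((areas >= area_min) & (areas <= area_max)) + 1
            if keep.size:
                cents = ndimage.center_of_mass(binary, lbl, keep)
                masses = ndimage.sum_labels(img, lbl, keep)
                for lab, cen, mass in zip(keep, cents, masses):
                    events.append(Event(w, (float(cen[0]), float(cen[1])),
                                        int(areas[lab - 1]), float(mass)))
        out.append(events)
    return out


def _bin_factor(pixel_pitch: float, cell_mm: float = CELL_MM) -> int:
    ratio = cell_mm / pixel_pitch
    if abs(ratio - round(ratio)) > 1e-6 or round(ratio) < 1:
        raise ValueError(
            f"cell size {cell_mm} mm must be a whole multiple of the pixel "
            f"pitch {pixel_pitch} mm/px")
    return int(round(ratio))


def accumulate(events: list[list[Event]], frame_shape: tuple[int, int],
               pixel_pitch: float, window_length: float = 800.0,
               mode: str = "mass", cell_mm: float = CELL_MM) -> ActivityHeatmap:
    """Bin events onto the analysis grid (one cell = one pellet, 0.75 mm).

    ``mode="mass"`` spreads each component's pixel area over the cells it
    covers (approximated by its area placed at the centroid cell
    neighbourhood); ``mode="count"`` adds one count at the centroid cell.
    The cumulative map is the last window (persistent traces accumulate
    in the change images themselves).
    """
    factor = _bin_factor(pixel_pitch, cell_mm)
    hc = frame_shape[0] // factor
    wc = frame_shape[1] // factor
    nw = len(events)
    grids = np.zeros((nw, hc, wc))
    for w, evs in enumerate(events):
        for ev in evs:
            i = min(int(ev.centroid_px[0] // factor), hc - 1)
            j = min(int(ev.centroid_px[1] // factor), wc - 1)
            grids[w, i, j] += 1.0 if mode == "count" else float(ev.area_px)
    cumulative = grids[-1] if nw else np.zeros((hc, wc))
    return ActivityHeatmap(grids, cumulative, window_length, cell_mm)


def occupancy_map(trajectories: pd.DataFrame, frame_shape: tuple[int, int],
                  pixel_pitch: float, cadence: float = 20.0,
                  window_length: float = 800.0,
                  cell_mm: float = CELL_MM) -> OccupancyMap:
    """Bin tracked positions (CSV columns frame, id, x, y in px) onto the
    activity grid, per 800 s window; out-of-frame positions are dropped
    and counted."""
    factor = _bin_factor(pixel_pitch, cell_mm)
    hc = frame_shape[0] // factor
    wc = frame_shape[1] // factor
    x = trajectories["x"].to_numpy(float)
    y = trajectories["y"].to_numpy(float)
    fr = trajectories["frame"].to_numpy(int)
    # image convention: x = column, y = row
    j = np.floor(x / factor).astype(int)
    i = np.floor(y / factor).astype(int)
    t = fr * cadence
    w = np.floor(t / window_length).astype(int)
    ok = (i >= 0) & (i < hc) & (j >= 0) & (j < wc) & (w >= 0)
    n_dropped = int((~ok).sum())
    i, j, w = i[ok], j[ok], w[ok]
    nw = int(w.max()) + 1 if w.size else 0
    grids = np.zeros((nw, hc, wc))
    np.add.at(grids, (w, i, j), 1.0)
    cumulative = grids.sum(axis=0) if nw else np.zeros((hc, wc))
    return OccupancyMap(grids, cumulative, window_length, cell_mm, n_dropped)


# ---------------------------------------------------------------------------
# Probability maps
# ---------------------------------------------------------------------------

def normalize_by_mean(grid: np.ndarray, mask: np.ndarray | None = None) -> np.ndarray:
    """Divide by the mean (over ``mask``), so high-activity cells read
    P > 1; the mean of the result over the mask is exactly 1."""
    vals = grid[mask] if mask is not None else grid
    mean = vals.mean()
    if mean == 0:
        raise ValueError("cannot normalize a map with zero mean")
    return grid / mean


def conditional(activity: np.ndarray, occupancy: np.ndarray,
                eps: float = 1e-9) -> ConditionalMap:
    """P(activity | occupancy) = activity / occupancy on cells with
    occupancy >= eps; other cells are masked (NaN)."""
    if activity.shape != occupancy.shape:
        raise ValueError("activity and occupancy grids differ in shape")
    valid = occupancy >= eps
    values = np.full(activity.shape, np.nan)
    values[valid] = activity[valid] / occupancy[valid]
    return ConditionalMap(values, valid)


def radial_density(grid: np.ndarray, center: tuple[float, float],
                   bin_width: float = 1.0, cell_mm: float = CELL_MM):
    """Per-unit-area radial activity profile, normalized to sum to 1.

    ``center`` is in cell coordinates (row, col); bins are in mm.
    """
    from .profiles import RadialProfile

    hc, wc = grid.shape
    if not (0 <= center[0] < hc and 0 <= center[1] < wc):
        raise ValueError("center must lie inside the grid")
    ii, jj = np.meshgrid(np.arange(hc), np.arange(wc), indexing="ij")
    r = np.hypot(ii - center[0], jj - center[1]) * cell_mm
    nbin = int(np.ceil(r.max() / bin_width)) + 1
    which = np.minimum((r / bin_width).astype(int), nbin - 1)
    sums = np.bincount(which.ravel(), weights=grid.ravel(), minlength=nbin)
    counts = np.bincount(which.ravel(), minlength=nbin)
    area = counts * cell_mm ** 2
    dens = np.divide(sums, area, out=np.zeros(nbin), where=area > 0)
    total = dens.sum()
    if total > 0:
        dens = dens / total
    centers = bin_width * (np.arange(nbin) + 0.5)
    return RadialProfile(centers, dens, normalization="sum")


def cross_section(grid: np.ndarray, row: int, center_col: float | None = None,
                  normalize: str = "max", cell_mm: float = CELL_MM):
    """1D profile of the cells along a horizontal cut through the grid.

    Returns a profile over the signed (or absolute, when ``center_col``
    is given) horizontal coordinate in mm; values are max-normalized by
    default.
    """
    from .profiles import RadialProfile

    if not 0 <= row < grid.shape[0]:
        raise ValueError("cut row outside the grid")
    vals = grid[row].astype(float)
    cols = np.arange(grid.shape[1], dtype=float)
    if center_col is not None:
        x = np.abs(cols - center_col) * cell_mm
        order = np.argsort(x, kind="stable")
        x, vals = x[order], vals[order]
    else:
        x = cols * cell_mm
    norm = "none"
    if normalize == "max":
        m = vals.max()
        if m == 0:
            raise ValueError("cut is identically zero; nothing to normalize")
        vals = vals / m
        norm = "max"
    return RadialProfile(x, vals, normalization=norm)
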