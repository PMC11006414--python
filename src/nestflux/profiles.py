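"""Radial/line profiles and figure-level comparison helpers."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class RadialProfile:
    """1D profile over radius (or arclength along a cut).

    ``normalization`` declares the convention: "sum" profiles integrate
    to 1, "max" profiles peak at 1, "none" is raw.
    """

    r: np.ndarray
    values: np.ndarray
    normalization: str = "none"

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.r.shape != self.values.shape or self.r.ndim != 1:
            raise ValueError("r and values must be matching 1D arrays")
        if self.normalization not in ("sum", "max", "none"):
            raise ValueError("normalization must be 'sum', 'max' or 'none'")

    def peak_radius(self, smooth_bins: int = 3) -> float:
        """Location of the profile maximum after boxcar smoothing."""
        v = self.values
        if smooth_bins > 1 and v.size >= smooth_bins:
            kernel = np.ones(smooth_bins) / smooth_bins
            v = np.convolve(v, kernel, mode="same")
        return float(self.r[np.argmax(v)])

    def interp(self, r_new: np.ndarray) -> np.ndarray:
        return np.interp(r_new, self.r, self.values)


def compare_cut(experiment: RadialProfile, curvature: RadialProfile,
                simulated: RadialProfile, smooth_bins: int = 3) -> pd.DataFrame:
    """Align experimental depositions, surface curvature and simulated
    depositions on a common 1D cut.

    Deposition columns are max-normalized; curvature is kept raw (mm^-1).
    The returned frame carries the three aligned columns plus per-column
    peak locations in ``DataFrame.attrs["peaks_mm"]``.
    """
    profiles = {"experiment": experiment, "curvature": curvature,
                "simulated": simulated}
    r0 = max(p.r.min() for p in profiles.values())
    r1 = min(p.r.max() for p in profiles.values())
    if r1 <= r0:
        raise ValueError("profiles do not share a common radial range")
    step = min(np.min(np.diff(p.r)) for p in profiles.values() if p.r.size > 1)
    r = np.arange(r0, r1 + step / 2, step)

    cols = {}
    for name, p in profiles.items():
        v = p.interp(r)
        if name in ("experiment", "simulated"):
            m = np.max(np.abs(v))
            if m == 0:
                raise ValueError(f"{name} profile is identically zero on the cut")
            v = v / m
        cols[name] = v
    out = pd.DataFrame({"R_mm": r, **cols})
    peaks = {name: RadialProfile(r, cols[name]).peak_radius(smooth_bins)
             for name in profiles}
    flat = {name: bool(np.ptp(cols[name]) < 1e-12) for name in profiles}
    out.attrs["peaks_mm"] = peaks
    out.attrs["flat"] = flat
    return out
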