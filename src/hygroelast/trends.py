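"""Moisture-content trend series and their summary statistics.

Bamboo-fiber cell walls respond anisotropically to moisture: the
transverse nanoindentation modulus falls almost linearly with moisture
content, while the longitudinal modulus first rises to a shallow maximum
near 3% MC before declining.  This module packages those published summary
numbers as small (MC, property) series — only values printed as text, no
digitized figure markers — and computes the statistics usually quoted
about them: least-squares linear rates over an MC window and peak
locations.

All moisture contents are dry-basis mass percent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "MoistureSeries",
    "LinearRate",
    "load_paper_dataset",
    "linear_rate",
    "find_peak",
    "series_from_csv",
    "DATASET_NAMES",
]


@dataclass(frozen=True)
class MoistureSeries:
    """A property measured along a moisture-content series.

    ``y`` units are GPa for moduli and a fraction for FFV.  ``direction``
    is the nanoindentation orientation where applicable, else "none".
    ``provenance`` states, in words and numbers, where the points come
    from; ``point_labels`` optionally names individual points.
    """

    mc: np.ndarray
    y: np.ndarray
    label: str
    direction: str = "none"
    provenance: str = ""
    point_labels: tuple[str, ...] = ()

    def __post_init__(self):
        mc = np.asarray(self.mc, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if mc.ndim != 1 or mc.shape != y.shape:
            raise ValueError("mc and y must be equal-length 1-D arrays")
        if np.any(mc < 0):
            raise ValueError("moisture contents must be non-negative")
        if np.any(np.diff(mc) <= 0):
            raise ValueError("moisture contents must be strictly increasing")
        if self.direction not in ("longitudinal", "transverse", "none"):
            raise ValueError(f"unknown direction {self.direction!r}")
        object.__setattr__(self, "mc", mc)
        object.__setattr__(self, "y", y)

    @property
    def n_points(self) -> int:
        return len(self.mc)


@dataclass(frozen=True)
class LinearRate:
    """Least-squares linear trend over an MC window."""

    slope_magnitude: float  # |dy/dMC|, y-units per % MC
    slope: float  # signed
    intercept: float
    mc_range: tuple[float, float]
    n_points: int


def _series() -> dict[str, MoistureSeries]:
    return {
        "longitudinal_modulus": MoistureSeries(
            mc=[0.5, 3.0, 14.5],
            y=[19.1, 19.4, 14.6],
            label="longitudinal nanoindentation modulus (GPa)",
            direction="longitudinal",
            provenance=(
                "Reported longitudinal cell-wall moduli: 19.1 GPa at 0.5% MC, "
                "maximum 19.4 GPa near 3% MC, 14.6 GPa at 14.5% MC; the "
                "peak-to-end decline corresponds to 0.4 GPa per % MC."
            ),
        ),
        "transverse_modulus": MoistureSeries(
            mc=[0.0, 15.0],
            y=[7.9, 2.6],
            label="transverse nanoindentation modulus (GPa)",
            direction="transverse",
            provenance=(
                "Reported transverse cell-wall moduli falling from 7.9 to "
                "2.6 GPa over the 0-15% MC range, a near-linear decline of "
                "0.35 GPa per % MC."
            ),
        ),
        "ffv_summary": MoistureSeries(
            mc=[0.0, 2.5, 30.0],
            y=[0.14, 0.13, 0.20],
            label="lignin fractional free volume",
            direction="none",
            provenance=(
                "Reported lignin FFV: about 0.14 dry, dipping to 0.13 at "
                "2.5% MC, then rising roughly linearly to ~0.20 near 30% MC. "
                "Dry hemicellulose FFV (~0.10) is packaged separately as "
                "ffv_hemicellulose."
            ),
        ),
        "ffv_hemicellulose": MoistureSeries(
            mc=[0.0, 30.0],
            y=[0.10, 0.17],
            label="hemicellulose fractional free volume",
            direction="none",
            provenance=(
                "Reported hemicellulose FFV: about 0.10 dry, rising to ~0.17 "
                "near 30% MC with no low-MC dip."
            ),
        ),
        "sim_peaks": MoistureSeries(
            mc=[2.5, 10.0],
            y=[np.nan, np.nan],
            label="simulated modulus peak locations (% MC)",
            direction="none",
            provenance=(
                "Reported moisture contents at which simulated elastic moduli "
                "peak: 2.5% MC for the lignin-carbohydrate complex and 10% MC "
                "for lignin.  Peak modulus values were not reported, so y is "
                "NaN."
            ),
            point_labels=("LCC", "lignin"),
        ),
    }


DATASET_NAMES = tuple(sorted(_series()))


def load_paper_dataset(name: str) -> MoistureSeries:
    """Return one of the packaged published summary series.

    Names: longitudinal_modulus, transverse_modulus, ffv_summary (lignin
    FFV; alias of the lignin narrative), ffv_hemicellulose, sim_peaks.
    Only sentence-printed values are packaged; intermediate figure markers
    are not digitized.
    """
    table = _series()
    if name not in table:
        raise KeyError(f"unknown dataset {name!r}; choose from {sorted(table)}")
    return table[name]


def linear_rate(series: MoistureSeries, mc_range: tuple[float, float] | None = None) -> LinearRate:
    """Least-squares linear trend of the series inside ``mc_range``.

    The window is inclusive and defaults to the full series.  With exactly
    two points the slope equals the endpoint slope.  Raises ValueError
    with fewer than two points in range.
    """
    if mc_range is None:
        mc_range = (float(series.mc.min()), float(series.mc.max()))
    lo, hi = mc_range
    mask = (series.mc >= lo - 1e-12) & (series.mc <= hi + 1e-12)
    x, y = series.mc[mask], series.y[mask]
    if len(x) < 2:
        raise ValueError(f"need >= 2 points in MC range {mc_range}, found {len(x)}")
    slope, intercept = np.polyfit(x, y, 1)
    return LinearRate(
        slope_magnitude=abs(float(slope)),
        slope=float(slope),
        intercept=float(intercept),
        mc_range=(float(lo), float(hi)),
        n_points=int(len(x)),
    )


def find_peak(series: MoistureSeries) -> tuple[float, float]:
    """(MC, y) of the series maximum; ties break to the smallest MC."""
    if series.n_points == 0:
        raise ValueError("empty series")
    i = int(np.argmax(series.y))  # argmax returns the first maximum
    return float(series.mc[i]), float(series.y[i])


def series_from_csv(path: str | Path, label: str = "", direction: str = "none") -> MoistureSeries:
    """Load a user series from CSV with columns ``mc`` and ``value``."""
    import pandas as pd

    df = pd.read_csv(path)
    missing = {"mc", "value"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df = df.sort_values("mc")
    return MoistureSeries(
        mc=df["mc"].to_numpy(dtype=float),
        y=df["value"].to_numpy(dtype=float),
        label=label or str(path),
        direction=direction,
        provenance=f"user series from {path}",
    )
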