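"""Haplogroup frequency surfaces by distance-decay interpolation.

Point observations (latitude, longitude, sample size n, carrier count k) are
interpolated onto a regular grid: each cell takes the weighted mean of the
frequencies of all samples within a radius of influence (default 1,500 km
great-circle), with the truncated-cone kernel w(d) = ((R - d) / R)^p and
power p = 3 by default. Cells with no sample in radius are NO-DATA. An
inverse-distance kernel d^-p is available as an alternative weighting.

The weighted mean is bounded by the contributing frequencies and reproduces
a sample's frequency exactly at its own coordinates, so the surface is an
interpolator rather than a smoother.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "GeoSample",
    "FrequencySurface",
    "great_circle_km",
    "interpolate_point",
    "build_surface",
]

EARTH_RADIUS_KM = 6371.0
NO_DATA = np.nan


@dataclass(frozen=True)
class GeoSample:
    """One population point sample: k carriers among n sampled."""

    label: str
    lat: float
    lon: float
    n: int
    k: int

    def __post_init__(self):
        if not (-90 <= self.lat <= 90 and -180 <= self.lon <= 180):
            raise ValueError(f"invalid coordinates ({self.lat}, {self.lon})")
        if self.n <= 0 or not 0 <= self.k <= self.n:
            raise ValueError(f"invalid counts k={self.k}, n={self.n}")

    @property
    def frequency(self) -> float:
        return self.k / self.n


def great_circle_km(p1: tuple[float, float], p2: tuple[float, float]) -> float:
    """Haversine great-circle distance in km (Earth radius 6,371 km)."""
    for lat, lon in (p1, p2):
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise ValueError(f"invalid coordinates ({lat}, {lon})")
    lat1, lon1, lat2, lon2 = map(np.radians, (*p1, *p2))
    a = (
        np.sin((lat2 - lat1) / 2) ** 2
        + np.cos(lat1) * np.cos(lat2) * np.sin((lon2 - lon1) / 2) ** 2
    )
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1))))


def _weights(d: np.ndarray, radius: float, power: float, kernel: str) -> np.ndarray:
    if kernel == "cone":
        w = np.where(d < radius, ((radius - d) / radius) ** power, 0.0)
    elif kernel == "idw":
        w = np.where(d < radius, 1.0 / np.maximum(d, 1e-9) ** power, 0.0)
    else:
        raise ValueError(f"unknown kernel {kernel!r}")
    return w


def interpolate_point(
    point: tuple[float, float],
    samples: Sequence[GeoSample],
    radius: float = 1500.0,
    power: float = 3.0,
    kernel: str = "cone",
) -> float:
    """Weighted-mean frequency at one point; NO-DATA (NaN) when no sample
    lies within the radius. A sample exactly at the point (d = 0) returns
    its frequency."""
    if radius <= 0 or power <= 0:
        raise ValueError("radius and power must be positive")
    d = np.array([great_circle_km(point, (s.lat, s.lon)) for s in samples])
    f = np.array([s.frequency for s in samples])
    if np.any(d == 0):
        return float(f[d == 0].mean())
    w = _weights(d, radius, power, kernel)
    if w.sum() == 0:
        return NO_DATA
    return float((w * f).sum() / w.sum())


@dataclass
class FrequencySurface:
    """Interpolated grid; ``values[i, j]`` at (lats[i], lons[j]); NaN = NO-DATA."""

    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray
    radius: float
    power: float
    kernel: str = "cone"
    meta: dict = field(default_factory=dict)

    @property
    def coverage(self) -> float:
        return float(np.isfinite(self.values).mean())

    def to_frame(self) -> pd.DataFrame:
        lon_g, lat_g = np.meshgrid(self.lons, self.lats)
        return pd.DataFrame(
            {
                "lon": lon_g.ravel(),
                "lat": lat_g.ravel(),
                "frequency": self.values.ravel(),
            }
        )

    def plot(self, path: Optional[str] = None):
        """Quick-look rendering (pcolormesh); returns the matplotlib axes."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        fig, ax = plt.subplots(figsize=(8, 5))
        mesh = ax.pcolormesh(self.lons, self.lats, self.values, shading="auto")
        fig.colorbar(mesh, ax=ax, label="frequency")
        ax.set_xlabel("longitude")
        ax.set_ylabel("latitude")
        if path:
            fig.savefig(path, dpi=120)
            plt.close(fig)
        return ax


def build_surface(
    samples: Sequence[GeoSample],
    *,
    bounds: Optional[tuple[float, float, float, float]] = None,
    resolution: float = 0.5,
    radius: float = 1500.0,
    power: float = 3.0,
    kernel: str = "cone",
) -> FrequencySurface:
    """Interpolate every grid cell (vectorised haversine per latitude row).

    ``bounds`` is (lat_min, lat_max, lon_min, lon_max); by default the
    samples' bounding box padded by the radius of influence.
    """
    if not samples:
        raise ValueError("no samples")
    s_lat = np.radians(np.array([s.lat for s in samples]))
    s_lon = np.radians(np.array([s.lon for s in samples]))
    freqs = np.array([s.frequency for s in samples])

    if bounds is None:
        pad = np.degrees(radius / EARTH_RADIUS_KM)
        lat_min = max(min(s.lat for s in samples) - pad, -90)
        lat_max = min(max(s.lat for s in samples) + pad, 90)
        lon_min = max(min(s.lon for s in samples) - pad, -180)
        lon_max = min(max(s.lon for s in samples) + pad, 180)
    else:
        lat_min, lat_max, lon_min, lon_max = bounds
    lats = np.arange(lat_min, lat_max + resolution / 2, resolution)
    lons = np.arange(lon_min, lon_max + resolution / 2, resolution)

    values = np.full((lats.size, lons.size), NO_DATA)
    lon_r = np.radians(lons)
    for i, lat in enumerate(np.radians(lats)):
        a = (
            np.sin((s_lat[None, :] - lat) / 2) ** 2
            + np.cos(lat)
            * np.cos(s_lat[None, :])
            * np.sin((s_lon[None, :] - lon_r[:, None]) / 2) ** 2
        )
        d = 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0, 1)))
        w = _weights(d, radius, power, kernel)
        wsum = w.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row = (w * freqs[None, :]).sum(axis=1) / wsum
        exact = d == 0
        if exact.any():
            hit = exact.any(axis=1)
            row[hit] = np.array(
                [freqs[exact[j]].mean() for j in np.nonzero(hit)[0]]
            )
        row[wsum == 0] = NO_DATA
        values[i] = row
    defined = np.isfinite(values)
    meta = {
        "coverage": float(defined.mean()),
        "min": float(np.nanmin(values)) if defined.any() else None,
        "max": float(np.nanmax(values)) if defined.any() else None,
        "n_samples": len(samples),
        "total_n": int(sum(s.n for s in samples)),
    }
    return FrequencySurface(
        lats=lats, lons=lons, values=values, radius=radius, power=power,
        kernel=kernel, meta=meta,
    )
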