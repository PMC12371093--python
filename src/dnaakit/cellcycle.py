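"""Cell-cycle support calculations: per-cell mobility, geometry, growth.

Covers the arithmetic around the imaging experiments: per-cell mean apparent
diffusion coefficients ordered by cell area (a cell-cycle proxy), rolling
median/quartile profiles (window k = 75 cells), spherocylinder area->volume
conversion using growth-regime aspect ratios, the initiation volume
V* = <V> / (ln2 * n_ori), and turbidostat growth-rate arithmetic
(mu = D = F / V_culture).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .tracking import Track, apparent_D

#: Aspect ratio (length/width) presets per growth regime.
ASPECT_RATIOS = {"slow": 3.43, "intermediate": 4.14, "fast": 4.3}
#: Doubling-time presets (minutes) per growth regime.
DOUBLING_TIMES_MIN = {"slow": 187.0, "intermediate": 62.0, "fast": 31.0}

V_CULTURE_ML = 20.0


@dataclass
class CellRecord:
    cell_id: int
    area: float  # um^2
    mean_D: float  # um^2/s, mean of the cell's track D* values
    n_tracks: int


def per_cell_mean_D(
    tracks: list[Track],
    areas: dict[int, float] | pd.Series | None = None,
    t_frame: float = 0.010,
) -> list[CellRecord]:
    """Unweighted mean D* per cell over its eligible (>= 3 loc) tracks.

    Cells without any eligible track are omitted; ``areas`` maps cell_id to
    area in um^2 (cells with no area get NaN).
    """
    sums: dict[int, list[float]] = {}
    for t in tracks:
        if t.n_locs < 3:
            continue
        sums.setdefault(t.cell_id, []).append(apparent_D(t, t_frame))
    records = []
    for cid in sorted(sums):
        ds = sums[cid]
        area = float("nan")
        if areas is not None and cid in areas:
            area = float(areas[cid])
        records.append(CellRecord(cell_id=cid, area=area,
                                  mean_D=float(np.mean(ds)), n_tracks=len(ds)))
    return records


@dataclass
class RollingProfile:
    """Rolling median and quartiles of mean D* over area-ordered cells."""

    area: np.ndarray  # sorted
    median: np.ndarray
    q25: np.ndarray
    q75: np.ndarray
    k: int

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"area": self.area, "rolling_median": self.median,
                             "q25": self.q25, "q75": self.q75})


def rolling_profile(cells: list[CellRecord] | pd.DataFrame, k: int = 75
                    ) -> RollingProfile:
    """Centered rolling median / 25% / 75% quantiles of mean_D vs area.

    Cells are sorted by area internally; the window is truncated at the
    edges (partial windows allowed).  With fewer than k cells the profile
    degrades to the global summary and a warning is issued.
    """
    if isinstance(cells, pd.DataFrame):
        df = cells[["area", "mean_D"]].copy()
    else:
        df = pd.DataFrame({"area": [c.area for c in cells],
                           "mean_D": [c.mean_D for c in cells]})
    df = df.sort_values("area", kind="stable").reset_index(drop=True)
    if len(df) < k:
        warnings.warn(
            f"only {len(df)} cells for rolling window k={k}; "
            "profile degrades to the global summary", stacklevel=2)
    r = df["mean_D"].rolling(k, center=True, min_periods=1)
    return RollingProfile(
        area=df["area"].to_numpy(),
        median=r.median().to_numpy(),
        q25=r.quantile(0.25).to_numpy(),
        q75=r.quantile(0.75).to_numpy(),
        k=k,
    )


def area_to_volume(area: float, aspect_ratio: float) -> tuple[float, float]:
    """Spherocylinder radius and volume from projected cell area.

    r = sqrt(A / (pi + 4*AR - 4));  V = (2*AR - 0.7) * pi * r^3.
    """
    if area <= 0:
        raise ValueError("area must be > 0")
    if aspect_ratio <= 1:
        raise ValueError("aspect ratio must be > 1")
    r = math.sqrt(area / (math.pi + 4.0 * aspect_ratio - 4.0))
    v = (2.0 * aspect_ratio - 0.7) * math.pi * r**3
    return r, v


def volume_to_area(volume: float, aspect_ratio: float) -> float:
    """Numerical inverse of :func:`area_to_volume` (volume -> area)."""
    if volume <= 0:
        raise ValueError("volume must be > 0")

    def f(a):
        return area_to_volume(a, aspect_ratio)[1] - volume

    hi = 1.0
    while f(hi) < 0:
        hi *= 2.0
    return brentq(f, 1e-12, hi, xtol=1e-15, rtol=1e-14)


def initiation_volume(mean_volume: float, n_ori: float) -> float:
    """Initiation volume per origin, V* = <V> / (ln2 * n_ori)."""
    if mean_volume <= 0:
        raise ValueError("mean volume must be > 0")
    if n_ori <= 0:
        raise ValueError("n_ori must be > 0")
    return mean_volume / (math.log(2.0) * n_ori)


@dataclass
class GrowthRate:
    flow_rate: float  # mL/h
    mu: float  # 1/h (equals the dilution rate in a turbidostat)
    doubling_time_min: float


def growth_rate(v_steadystate_ml: float, t_steadystate_h: float,
                v_culture_ml: float = V_CULTURE_ML) -> GrowthRate:
    """Turbidostat growth rate from dilution bookkeeping.

    F = V_ss / t_ss;  mu = D = F / V_culture;  Td = ln2 / mu.
    """
    if t_steadystate_h <= 0:
        raise ValueError("steady-state time must be > 0")
    if v_steadystate_ml <= 0 or v_culture_ml <= 0:
        raise ValueError("volumes must be > 0")
    f = v_steadystate_ml / t_steadystate_h
    mu = f / v_culture_ml
    return GrowthRate(flow_rate=f, mu=mu,
                      doubling_time_min=math.log(2.0) / mu * 60.0)
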