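"""Single-particle tracking: localisation tables -> tracks -> D* histograms.

Consumes ThunderSTORM-style localisation tables (frame, x, y), assigns
localisations to segmented cells, links them into gap-free tracks by
nearest-neighbour assignment between consecutive frames, computes each
track's apparent diffusion coefficient D* from its mean squared frame
displacement, and bins the D* values into the 85-bin logarithmic histogram
(0.04-10 um^2/s) that the MC-DDA kinetic fit consumes.

D* is apparent: localisation noise of sd sigma per axis inflates it by
sigma^2/t_frame, so strictly immobile molecules appear at ~0.12 um^2/s for
sigma = 0.035 um and 10 ms frames.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.spatial.distance import cdist

DEFAULT_T_FRAME = 0.010  # s
DEFAULT_PIXEL_SIZE_UM = 0.119


def read_localisations(
    source,
    drop_first_frames: int = 500,
    unit: str | None = None,
) -> pd.DataFrame:
    """Read a localisation table into a frame/x/y DataFrame in um.

    Accepts a CSV path or a DataFrame.  ThunderSTORM's ``"x [nm]"`` /
    ``"y [nm]"`` headers are recognised and converted to um; plain ``x``/``y``
    columns need an explicit ``unit`` ("nm" or "um").  The first
    ``drop_first_frames`` frames are discarded (the acquisitions pre-bleach
    contaminants there); the number of dropped rows is recorded in
    ``df.attrs["n_dropped_frames"]``.
    """
    df = pd.read_csv(source) if not isinstance(source, pd.DataFrame) else source.copy()
    cols = {c.strip(): c for c in df.columns}
    if "frame" not in cols:
        raise ValueError("missing required column 'frame'")
    out = pd.DataFrame()
    out["frame"] = _numeric(df[cols["frame"]], "frame").astype(int)
    for axis in ("x", "y"):
        if f"{axis} [nm]" in cols:
            out[axis] = _numeric(df[cols[f"{axis} [nm]"]], f"{axis} [nm]") / 1000.0
        elif axis in cols:
            if unit not in ("nm", "um"):
                raise ValueError(
                    f"column {axis!r} has no unit suffix; pass unit='nm' or 'um'"
                )
            v = _numeric(df[cols[axis]], axis)
            out[axis] = v / 1000.0 if unit == "nm" else v
        else:
            raise ValueError(f"missing required column {axis!r}")
    if (out["frame"] < 0).any():
        raise ValueError("negative frame numbers")
    if not np.isfinite(out[["x", "y"]].to_numpy()).all():
        raise ValueError("non-finite coordinates")
    n0 = len(out)
    out = out[out["frame"] >= drop_first_frames].reset_index(drop=True)
    out.attrs["n_dropped_frames"] = n0 - len(out)
    return out


def _numeric(col: pd.Series, name: str) -> pd.Series:
    v = pd.to_numeric(col, errors="coerce")
    bad = v.index[v.isna() & col.notna()]
    if len(bad):
        raise ValueError(f"non-numeric value in column {name!r} at row {bad[0]}")
    if v.isna().any():
        raise ValueError(f"missing value in column {name!r} at row {v.index[v.isna()][0]}")
    return v


def assign_cells(
    locs: pd.DataFrame,
    regions,
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
) -> pd.DataFrame:
    """Assign each localisation a cell_id; drop localisations outside cells.

    ``regions`` is either a 2-D integer label mask (0 = background; pixel i,j
    covers [j, j+1) x [i, i+1) pixels, scaled by ``pixel_size_um``) or a
    sequence of shapely polygons (cell ids 1..n, which must not overlap).
    The number of discarded localisations is stored in
    ``df.attrs["n_discarded_outside"]``.
    """
    x = locs["x"].to_numpy()
    y = locs["y"].to_numpy()
    if isinstance(regions, np.ndarray):
        if regions.ndim != 2:
            raise ValueError("label mask must be 2-D")
        j = np.floor(x / pixel_size_um).astype(int)
        i = np.floor(y / pixel_size_um).astype(int)
        inside = (i >= 0) & (i < regions.shape[0]) & (j >= 0) & (j < regions.shape[1])
        cell = np.zeros(len(locs), dtype=int)
        cell[inside] = regions[i[inside], j[inside]]
    else:
        from shapely import contains_xy

        polys = list(regions)
        for a in range(len(polys)):
            for b in range(a + 1, len(polys)):
                inter = polys[a].intersection(polys[b])
                if inter.area > 0:
                    raise ValueError(
                        f"cell regions {a + 1} and {b + 1} overlap; "
                        "labels must partition"
                    )
        cell = np.zeros(len(locs), dtype=int)
        for cid, poly in enumerate(polys, start=1):
            hit = contains_xy(poly, x, y)
            cell[hit & (cell == 0)] = cid
    out = locs.copy()
    out["cell_id"] = cell
    kept = out[out["cell_id"] > 0].reset_index(drop=True)
    kept.attrs["n_discarded_outside"] = int((cell == 0).sum())
    return kept


@dataclass
class Track:
    """A gap-free linked trajectory within one cell."""

    track_id: int
    cell_id: int
    frames: np.ndarray  # strictly consecutive
    xy: np.ndarray  # (n, 2) um
    d_star: float | None = field(default=None)

    @property
    def n_locs(self) -> int:
        return len(self.frames)


def link_tracks(
    locs: pd.DataFrame,
    r_max: float = 1.0,
    cell_column: str = "cell_id",
) -> list[Track]:
    """Link localisations into tracks within each cell.

    Between each pair of consecutive frames the assignment of previous track
    ends to new localisations minimises the total displacement (Hungarian
    algorithm) subject to every link being <= ``r_max``; unmatched
    localisations open new tracks and unmatched tracks close.  Frame gaps
    always close a track.
    """
    tracks: list[Track] = []
    next_id = 0
    if cell_column not in locs.columns:
        locs = locs.copy()
        locs[cell_column] = 0
    for cell_id, sub in locs.groupby(cell_column, sort=True):
        sub = sub.sort_values("frame", kind="stable")
        frames = sub["frame"].to_numpy()
        xy = sub[["x", "y"]].to_numpy(dtype=float)
        # open tracks: list of (list_of_row_indices)
        open_tracks: list[list[int]] = []
        open_frame = None
        prev_rows: list[int] = []
        for f in np.unique(frames):
            rows = np.flatnonzero(frames == f)
            if open_frame is not None and f == open_frame + 1 and open_tracks:
                prev_pts = xy[[t[-1] for t in open_tracks]]
                new_pts = xy[rows]
                cost = cdist(prev_pts, new_pts)
                big = 1e6
                cost = np.where(cost <= r_max, cost, big)
                ri, ci = linear_sum_assignment(cost)
                matched_new = set()
                still_open = []
                matched_prev = {}
                for a, b in zip(ri, ci):
                    if cost[a, b] < big:
                        matched_prev[a] = b
                        matched_new.add(b)
                for a, t in enumerate(open_tracks):
                    if a in matched_prev:
                        t.append(rows[matched_prev[a]])
                        still_open.append(t)
                    else:
                        tracks.append(_close(t, next_id, cell_id, frames, xy))
                        next_id += 1
                for k, r in enumerate(rows):
                    if k not in matched_new:
                        still_open.append([r])
                open_tracks = still_open
            else:
                for t in open_tracks:
                    tracks.append(_close(t, next_id, cell_id, frames, xy))
                    next_id += 1
                open_tracks = [[r] for r in rows]
            open_frame = f
        for t in open_tracks:
            tracks.append(_close(t, next_id, cell_id, frames, xy))
            next_id += 1
    return tracks


def _close(rows: list[int], track_id: int, cell_id, frames, xy) -> Track:
    return Track(
        track_id=track_id,
        cell_id=int(cell_id),
        frames=frames[rows].copy(),
        xy=xy[rows].copy(),
    )


def apparent_D(track: Track | np.ndarray, t_frame: float = DEFAULT_T_FRAME) -> float:
    """Apparent diffusion coefficient of one track (um^2/s).

    D* = mean over the track's n = (#localisations - 1) consecutive frame
    steps of the squared displacement, divided by 4*t_frame (2-D estimator;
    only x,y are observed).  Requires >= 3 localisations.
    """
    xy = track.xy if isinstance(track, Track) else np.asarray(track, dtype=float)
    if len(xy) < 3:
        raise ValueError("apparent_D requires >= 3 localisations")
    steps = np.diff(xy, axis=0)
    return float((steps**2).sum(axis=1).mean() / (4.0 * t_frame))


def apparent_D_batch(
    xy: np.ndarray, n_locs: np.ndarray, t_frame: float = DEFAULT_T_FRAME
) -> np.ndarray:
    """Vectorised apparent_D over many tracks stored in a padded array.

    ``xy`` has shape (n_tracks, max_locs, 2); ``n_locs[i]`` gives track i's
    valid localisation count.  Tracks with fewer than 3 localisations get
    NaN (they are ineligible for D*).
    """
    xy = np.asarray(xy, dtype=float)
    n_locs = np.asarray(n_locs)
    steps = np.diff(xy, axis=1)
    sq = (steps**2).sum(axis=2)
    m = np.arange(sq.shape[1])[None, :] < (n_locs - 1)[:, None]
    with np.errstate(invalid="ignore"):
        msd = np.where(m, sq, 0.0).sum(axis=1) / np.maximum(n_locs - 1, 1)
    d = msd / (4.0 * t_frame)
    d[n_locs < 3] = np.nan
    return d


@dataclass
class DiffusionHistogram:
    """85-bin logarithmic apparent-D* histogram, the MC-DDA fit target."""

    edges: np.ndarray  # 86 edges, geometric from d_min to d_max
    fractions: np.ndarray  # length 85, sums to 1 when n_tracks > 0
    n_tracks: int  # tracks retained in range
    n_dropped: int = 0  # out-of-range D* values dropped

    @property
    def centers(self) -> np.ndarray:
        return np.sqrt(self.edges[:-1] * self.edges[1:])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            "edge_lo": self.edges[:-1],
            "edge_hi": self.edges[1:],
            "fraction": self.fractions,
        })

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, n_tracks: int = 0
                       ) -> "DiffusionHistogram":
        edges = np.append(df["edge_lo"].to_numpy(), df["edge_hi"].to_numpy()[-1])
        return cls(edges=edges, fractions=df["fraction"].to_numpy(),
                   n_tracks=n_tracks)


def build_histogram(
    d_values,
    n_bins: int = 85,
    d_min: float = 0.04,
    d_max: float = 10.0,
) -> DiffusionHistogram:
    """Bin D* values into logarithmically spaced bins.

    Values outside [d_min, d_max] are dropped (not clamped) and counted in
    ``n_dropped``; d_min lands in the first bin and d_max in the last
    (closed right edge).  Fractions are normalised over retained values.
    """
    d = np.asarray(list(d_values), dtype=float)
    d = d[np.isfinite(d)]
    edges = np.geomspace(d_min, d_max, n_bins + 1)
    counts, _ = np.histogram(d, bins=edges)
    kept = int(counts.sum())
    fractions = counts / kept if kept > 0 else np.zeros(n_bins)
    return DiffusionHistogram(
        edges=edges, fractions=fractions, n_tracks=kept, n_dropped=len(d) - kept
    )


def tracks_to_histogram(
    tracks: list[Track], t_frame: float = DEFAULT_T_FRAME, **kwargs
) -> DiffusionHistogram:
    """Eligible tracks (>= 3 localisations) -> D* -> histogram."""
    ds = [apparent_D(t, t_frame) for t in tracks if t.n_locs >= 3]
    return build_histogram(ds, **kwargs)


def tracks_to_dataframe(tracks: list[Track]) -> pd.DataFrame:
    rows = []
    for t in tracks:
        for f, (x, y) in zip(t.frames, t.xy):
            rows.append((t.track_id, t.cell_id, int(f), x, y))
    return pd.DataFrame(rows, columns=["track_id", "cell_id", "frame", "x", "y"])
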