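"""Geomorphometric terrain attributes derived from a DEM.

Implements the habitat-proxy operators used by the association scan:
slope/aspect (Horn's method), northness/eastness, vector ruggedness measure,
positive/negative topographic openness, sky-view factor, topographic wetness
index (Freeman multiple-flow-direction), D8 flow-path length, an isotropic
wind-exposure index, and clear-sky monthly solar irradiation (June/December).
All operators take and return :class:`~ridgescan.grid_io.Grid` objects and can
be evaluated on any level of the resolution pyramid.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .grid_io import Grid, extract_at

__all__ = [
    "TerrainConfig",
    "slope_aspect",
    "northness_eastness",
    "vrm",
    "openness",
    "sky_view_factor",
    "fill_sinks",
    "wetness_index",
    "flow_path_length",
    "wind_exposure",
    "solar_radiation",
    "compute_stack",
    "extract_stack",
    "TERRAIN_VARIABLES",
]

#: Derived variable names (measured altitude, Alt, comes from the sample table).
TERRAIN_VARIABLES = (
    "Nor", "Eas", "Slo", "VRM", "TOP", "TON", "SVF",
    "SWI", "FPL", "WEX", "Ti6", "Ti12",
)

FLAT_SLOPE_DEG = 0.01  # below this the aspect is undefined


@dataclass
class TerrainConfig:
    """Operator settings recorded alongside every derived raster.

    Radii are in meters; they are search distances for the profile-walk
    operators (the source method descriptions leave them open, so they are
    exposed here and embedded in output metadata).
    """

    radius_openness: float = 50.0
    n_azimuths_openness: int = 8
    radius_svf: float = 50.0
    n_azimuths_svf: int = 16
    radius_wex: float = 300.0
    n_azimuths_wex: int = 8
    wex_decay: float = 0.01           # per-meter exponential profile weight
    radius_horizon: float = 100.0     # solar shading horizon search
    n_azimuths_horizon: int = 16
    latitude_deg: float = 46.433
    transmittance: float = 0.7
    solar_step_minutes: float = 60.0
    mfd_exponent: float = 1.1
    min_tan_slope: float = 0.001
    fpl_direction: str = "downstream"
    variables: tuple[str, ...] = TERRAIN_VARIABLES


def _azimuths(n: int) -> np.ndarray:
    return np.arange(n) * 2.0 * np.pi / n


# ---------------------------------------------------------------------------
# Gradient-based operators

def slope_aspect(g: Grid) -> tuple[Grid, Grid]:
    """Slope and aspect in degrees by Horn's 3x3 weighted finite differences.

    Aspect is the steepest-descent direction, clockwise from north in
    [0, 360); cells flatter than 0.01 degrees get NaN aspect (flagged flat).
    """
    if g.n_rows < 3 or g.n_cols < 3:
        raise ValueError("slope/aspect needs at least a 3x3 grid")
    z = g.values
    ze = np.pad(z, 1, mode="edge")
    a = ze[:-2, :-2]; b = ze[:-2, 1:-1]; c = ze[:-2, 2:]
    d = ze[1:-1, :-2];                    f = ze[1:-1, 2:]
    gg = ze[2:, :-2]; h = ze[2:, 1:-1]; i = ze[2:, 2:]
    dzdx = ((c + 2 * f + i) - (a + 2 * d + gg)) / (8 * g.cell_size)
    dzdy = ((a + 2 * b + c) - (gg + 2 * h + i)) / (8 * g.cell_size)  # north-positive
    slope = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect[slope < FLAT_SLOPE_DEG] = np.nan
    meta = {"operator": "horn"}
    return g.like(slope, meta=meta), g.like(aspect, meta=meta)


def northness_eastness(aspect: Grid) -> tuple[Grid, Grid]:
    """Nor = cos(aspect), Eas = sin(aspect); flat (NaN-aspect) cells -> 0."""
    rad = np.radians(aspect.values)
    nor = np.cos(rad)
    eas = np.sin(rad)
    flat = np.isnan(aspect.values)
    nor[flat] = 0.0
    eas[flat] = 0.0
    return aspect.like(nor), aspect.like(eas)


def vrm(g: Grid, window: int = 3) -> Grid:
    """Vector ruggedness measure: 1 - |sum of unit normals| / n in a moving
    window (Sappington's method); 0 on planes, toward 1 on broken terrain."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be an odd integer >= 3")
    from scipy.ndimage import uniform_filter

    slope, aspect = slope_aspect(g)
    s = np.radians(slope.values)
    a = np.radians(np.where(np.isnan(aspect.values), 0.0, aspect.values))
    nx = np.sin(s) * np.sin(a)
    ny = np.sin(s) * np.cos(a)
    nz = np.cos(s)
    rx = uniform_filter(nx, size=window, mode="nearest")
    ry = uniform_filter(ny, size=window, mode="nearest")
    rz = uniform_filter(nz, size=window, mode="nearest")
    out = 1.0 - np.sqrt(rx**2 + ry**2 + rz**2)
    return g.like(np.clip(out, 0.0, 1.0), meta={"window": window})


# ---------------------------------------------------------------------------
# Horizon-profile operators

def openness(g: Grid, radius: float = 50.0, n_azimuths: int = 8,
             sign: str = "positive") -> Grid:
    """Topographic openness: mean over azimuths of the zenith (positive) or
    nadir (negative) angle of the line of maximum elevation within ``radius``.

    Radians in (0, pi); a flat plane gives pi/2.
    """
    if radius < g.cell_size:
        raise ValueError("openness radius must be at least one cell")
    z = g.values if sign == "positive" else -g.values
    hor = _kernels.horizon_scan(np.ascontiguousarray(z, dtype=float), g.cell_size,
                                radius, _azimuths(n_azimuths))
    out = (np.pi / 2 - hor).mean(axis=0)
    return g.like(out, meta={"radius": radius, "n_azimuths": n_azimuths, "sign": sign})


def sky_view_factor(g: Grid, radius: float = 50.0, n_azimuths: int = 16) -> Grid:
    """SVF = mean over azimuths of cos^2 of the (non-negative) horizon
    elevation angle within ``radius``; 1 on an unobstructed plane."""
    if radius < g.cell_size:
        raise ValueError("SVF radius must be at least one cell")
    hor = _kernels.horizon_scan(np.ascontiguousarray(g.values, dtype=float),
                                g.cell_size, radius, _azimuths(n_azimuths))
    out = (np.cos(np.clip(hor, 0.0, None)) ** 2).mean(axis=0)
    return g.like(out, meta={"radius": radius, "n_azimuths": n_azimuths})


def _horizon_stack(g: Grid, radius: float, n_azimuths: int) -> np.ndarray:
    return _kernels.horizon_scan(np.ascontiguousarray(g.values, dtype=float),
                                 g.cell_size, radius, _azimuths(n_azimuths))


# ---------------------------------------------------------------------------
# Hydrology

def fill_sinks(g: Grid) -> Grid:
    """Priority-flood depression filling: minimal raising so every cell has a
    non-ascending path to the grid edge. Output >= input everywhere."""
    z = g.values.copy()
    nr, nc = z.shape
    closed = np.zeros_like(z, dtype=bool)
    heap: list[tuple[float, int, int]] = []
    nan = np.isnan(z)
    closed[nan] = True
    for r in range(nr):
        for c in range(nc):
            if (r in (0, nr - 1) or c in (0, nc - 1)) and not closed[r, c]:
                heapq.heappush(heap, (z[r, c], r, c))
                closed[r, c] = True
    # cells adjacent to nodata drain through it, like an edge
    if nan.any():
        rs, cs = np.nonzero(nan)
        for r, c in zip(rs, cs):
            for dr in (-1, 0, 1):
                for dc in (-1, 0, 1):
                    rr, cc = r + dr, c + dc
                    if 0 <= rr < nr and 0 <= cc < nc and not closed[rr, cc]:
                        heapq.heappush(heap, (z[rr, cc], rr, cc))
                        closed[rr, cc] = True
    while heap:
        level, r, c = heapq.heappop(heap)
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if 0 <= rr < nr and 0 <= cc < nc and not closed[rr, cc]:
                    closed[rr, cc] = True
                    if z[rr, cc] < level:
                        z[rr, cc] = level
                    heapq.heappush(heap, (z[rr, cc], rr, cc))
    return g.like(z)


def _tan_slope(g: Grid, floor: float) -> np.ndarray:
    slope, _ = slope_aspect(g)
    return np.maximum(np.tan(np.radians(slope.values)), floor)


def wetness_index(g: Grid, mfd_exponent: float = 1.1,
                  min_tan_slope: float = 0.001, filled: bool = False) -> Grid:
    """Topographic wetness index ln(a / tan beta), with specific catchment
    area a from Freeman multiple-flow-direction accumulation."""
    gf = g if filled else fill_sinks(g)
    z = np.ascontiguousarray(gf.values, dtype=float)
    flat = np.where(np.isnan(z), -np.inf, z).ravel()
    order = np.argsort(-flat, kind="stable").astype(np.int64)
    acc = _kernels.mfd_accumulation(z, g.cell_size, order, mfd_exponent)
    sca = acc * g.cell_size  # cells * cell_size = area / contour width
    out = np.log(sca / _tan_slope(gf, min_tan_slope))
    return g.like(out, meta={"mfd_exponent": mfd_exponent})


def flow_path_length(g: Grid, direction: str = "downstream",
                     filled: bool = False) -> Grid:
    """D8 flow-path length (meters): downstream distance to the grid edge, or
    the longest upstream path reaching the cell. Diagonal steps count
    cell_size * sqrt(2)."""
    if direction not in ("downstream", "upstream"):
        raise ValueError("direction must be 'downstream' or 'upstream'")
    gf = g if filled else fill_sinks(g)
    z = np.ascontiguousarray(gf.values, dtype=float)
    flat = np.where(np.isnan(z), np.inf, z).ravel()
    order_asc = np.argsort(flat, kind="stable").astype(np.int64)
    out = _kernels.d8_flow_path_length(z, g.cell_size, order_asc,
                                       direction == "downstream")
    return g.like(out, meta={"direction": direction})


# ---------------------------------------------------------------------------
# Wind and sun

def wind_exposure(g: Grid, radius: float = 300.0, n_azimuths: int = 8,
                  decay: float = 0.01) -> Grid:
    """Isotropic wind-exposure index: 1 on a plane, > 1 on crests, < 1 in
    sheltered hollows. Averaged over all azimuths (no prevailing wind)."""
    if radius < g.cell_size:
        raise ValueError("WEX radius must be at least one cell")
    out = _kernels.wind_exposure_scan(np.ascontiguousarray(g.values, dtype=float),
                                      g.cell_size, radius, _azimuths(n_azimuths), decay)
    return g.like(out, meta={"radius": radius, "decay": decay})


_MONTH_DAYS = {"june": np.arange(152, 182, dtype=float),
               "december": np.arange(335, 365, dtype=float)}


def solar_radiation(g: Grid, month: str, latitude_deg: float = 46.433,
                    transmittance: float = 0.7, step_minutes: float = 60.0,
                    radius_horizon: float = 100.0, n_azimuths: int = 16,
                    svf: Grid | None = None,
                    horizon: np.ndarray | None = None) -> Grid:
    """Monthly clear-sky direct + isotropic diffuse irradiation, kWh/m2.

    Horizon shading uses per-azimuth profiles out to ``radius_horizon``;
    diffuse is weighted by the sky-view factor (computed here when not
    supplied).  A precomputed ``horizon`` stack (n_azimuths x rows x cols)
    can be passed to share it between months.
    """
    if month not in _MONTH_DAYS:
        raise ValueError("month must be 'june' or 'december'")
    slope, aspect = slope_aspect(g)
    s = np.radians(slope.values)
    a = np.radians(np.where(np.isnan(aspect.values), 0.0, aspect.values))
    hor = horizon if horizon is not None \
        else _horizon_stack(g, radius_horizon, n_azimuths)
    if svf is None:
        svf_vals = (np.cos(np.clip(hor, 0.0, None)) ** 2).mean(axis=0)
    else:
        svf_vals = svf.values
    out = _kernels.solar_total(s, a, hor, _azimuths(n_azimuths), svf_vals,
                               np.radians(latitude_deg), _MONTH_DAYS[month],
                               step_minutes, transmittance)
    return g.like(out, meta={"month": month, "latitude_deg": latitude_deg,
                             "transmittance": transmittance})


# ---------------------------------------------------------------------------
# Stacks

def compute_stack(pyr: dict[float, Grid],
                  config: TerrainConfig | None = None) -> dict[tuple[str, float], Grid]:
    """All configured variables at every pyramid level.

    Returns a map (variable name, resolution) -> Grid.  Shared intermediates
    (slope/aspect, sink-filled surface, SVF) are computed once per level.
    """
    cfg = config or TerrainConfig()
    stack: dict[tuple[str, float], Grid] = {}
    want = set(cfg.variables)
    for res, g in sorted(pyr.items()):
        slope, aspect = slope_aspect(g)
        if "Slo" in want:
            stack[("Slo", res)] = slope
        if want & {"Nor", "Eas"}:
            nor, eas = northness_eastness(aspect)
            if "Nor" in want:
                stack[("Nor", res)] = nor
            if "Eas" in want:
                stack[("Eas", res)] = eas
        if "VRM" in want:
            stack[("VRM", res)] = vrm(g)
        if "TOP" in want:
            stack[("TOP", res)] = openness(g, cfg.radius_openness,
                                           cfg.n_azimuths_openness, "positive")
        if "TON" in want:
            stack[("TON", res)] = openness(g, cfg.radius_openness,
                                           cfg.n_azimuths_openness, "negative")
        svf_grid = None
        if want & {"SVF", "Ti6", "Ti12"}:
            svf_grid = sky_view_factor(g, cfg.radius_svf, cfg.n_azimuths_svf)
            if "SVF" in want:
                stack[("SVF", res)] = svf_grid
        if want & {"SWI", "FPL"}:
            filled = fill_sinks(g)
            if "SWI" in want:
                stack[("SWI", res)] = wetness_index(filled, cfg.mfd_exponent,
                                                    cfg.min_tan_slope, filled=True)
            if "FPL" in want:
                stack[("FPL", res)] = flow_path_length(filled, cfg.fpl_direction,
                                                       filled=True)
        if "WEX" in want:
            stack[("WEX", res)] = wind_exposure(g, cfg.radius_wex,
                                                cfg.n_azimuths_wex, cfg.wex_decay)
        months = [m for v, m in (("Ti6", "june"), ("Ti12", "december")) if v in want]
        if months:
            hor = _horizon_stack(g, cfg.radius_horizon, cfg.n_azimuths_horizon)
            for var, month in (("Ti6", "june"), ("Ti12", "december")):
                if var in want:
                    stack[(var, res)] = solar_radiation(
                        g, month, cfg.latitude_deg, cfg.transmittance,
                        cfg.solar_step_minutes, cfg.radius_horizon,
                        cfg.n_azimuths_horizon, svf=svf_grid, horizon=hor)
    return stack


def extract_stack(stack: dict[tuple[str, float], Grid],
                  samples: pd.DataFrame) -> pd.DataFrame:
    """Long per-sample table with columns ``id, var, res, value``."""
    frames = []
    for (var, res), grid in sorted(stack.items()):
        frames.append(pd.DataFrame({
            "id": samples["id"].to_numpy(),
            "var": var,
            "res": res,
            "value": extract_at(grid, samples),
        }))
    return pd.concat(frames, ignore_index=True)
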