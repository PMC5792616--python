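"""Shared fixtures: small analytic grids and the default synthetic landscape.

The default landscape (DEM, sampling, pyramid, terrain stack restricted to the
variables carrying planted gene-environment links) is expensive, so it is
built once per session and shared by the scan-recovery and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

from ridgescan import synth, terrain
from ridgescan.grid_io import Grid
from ridgescan.pyramid import ResolutionLadder, build_pyramid

# variables carrying planted links in the default scenario (plus Alt)
LINKED_VARS = ("TON", "Nor", "Ti12", "WEX")


def make_plane(n: int = 33, cell: float = 1.0, a: float = 0.0, b: float = 0.0,
               c: float = 100.0) -> Grid:
    """Plane z = a*x + b*y + c on an n x n grid (x east, y north)."""
    x = (np.arange(n) + 0.5) * cell
    y = ((n - np.arange(n)) - 0.5) * cell  # row 0 = northernmost
    z = a * x[None, :] + b * y[:, None] + c
    return Grid(values=z, x_origin=0.0, y_origin=n * cell, cell_size=cell)


def make_cone(n: int = 33, cell: float = 1.0, slope: float = 0.5,
              sign: float = -1.0) -> Grid:
    """Cone z = sign * slope * r around the grid center."""
    i = np.arange(n)
    r = np.hypot(*np.meshgrid((i - n // 2) * cell, (i - n // 2) * cell))
    return Grid(values=1000.0 + sign * slope * r, x_origin=0.0,
                y_origin=n * cell, cell_size=cell)


@pytest.fixture(scope="session")
def default_landscape():
    """Default study-like scenario: DEM, samples, pyramid, linked-variable
    terrain stack, and the long env table."""
    cfg = synth.ScenarioConfig(seed=1)
    dem = synth.make_ridge_dem(cfg)
    samples = synth.make_sampling(cfg, dem)
    pyr = build_pyramid(dem, ResolutionLadder(base_cell_size=cfg.base_res))
    stack = terrain.compute_stack(pyr, terrain.TerrainConfig(variables=LINKED_VARS))
    env = terrain.extract_stack(stack, samples)
    return {"cfg": cfg, "dem": dem, "samples": samples, "pyr": pyr,
            "stack": stack, "env": env}


@pytest.fixture(scope="session")
def small_scenario():
    """Desk-scale two-pool scenario without planted links (structure and
    autocorrelation tests)."""
    cfg = synth.ScenarioConfig(seed=7, ridge_length=400.0, ridge_width=64.0,
                               n_individuals=120, n_loci=80, n_adaptive=0,
                               adaptive_links=(), cline_width=60.0)
    dem = synth.make_ridge_dem(cfg)
    samples = synth.make_sampling(cfg, dem)
    gm, truth = synth.simulate_genotypes(cfg, dem, samples, None)
    return {"cfg": cfg, "dem": dem, "samples": samples, "gm": gm, "truth": truth}
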