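"""Synthetic ridge landscapes, cluster sampling designs, and dominant-marker
genotypes.

The generator emulates the study system the pipeline is built for: a ~1.2 km
alpine ridge (0.5 m DEM, elevations ~1,864-2,043 m), a random cluster sampling
of ~361 individuals (4x4 m areas split into four 2x2 m plots, each holding at
least five plants), and ~233 polymorphic dominant (presence/absence) loci from
two gene pools joined by an admixture cline, with a small minority of
"adaptive" loci whose band-presence probability follows a logistic function of
a terrain variable.  Ground truth (per-individual admixture, per-locus class
and coefficients) is stored alongside the outputs and never consumed by the
analysis modules.

The neutral model is deliberately minimal: there is no explicit gene-flow or
coalescent process, only a logistic cline mixing two pool-specific band
frequencies.  The along-ridge crest elevation follows a full-period cosine
(even about the ridge midpoint) while the cline is odd about the midpoint, so
elevation and neutral structure are close to orthogonal and type-I error on
neutral loci is interpretable — unlike the field situation, where the two may
be confounded.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from .grid_io import Grid

__all__ = ["ScenarioConfig", "TruthRecord", "make_ridge_dem", "make_sampling",
           "simulate_genotypes"]


@dataclass
class AdaptiveLink:
    """A planted gene-environment association.

    ``variable`` is a terrain variable name (with ``resolution`` in meters) or
    ``"Alt"`` (measured altitude; no resolution).  Coefficients are on the
    logit scale for the *standardized* environmental value.
    """

    locus: int
    variable: str
    resolution: float | None
    beta0: float
    beta1: float


@dataclass
class ScenarioConfig:
    seed: int = 0
    ridge_length: float = 1200.0          # m, along-ridge extent
    ridge_width: float = 96.0             # m, across-ridge extent
    elev_range: tuple[float, float] = (1864.0, 2043.0)
    base_res: float = 0.5                 # m
    n_individuals: int = 361
    n_loci: int = 233
    n_adaptive: int = 5
    cline_center: float | None = None     # defaults to ridge midpoint
    cline_width: float = 120.0            # m, logistic scale of the admixture cline
    cline_noise_sd: float = 0.4           # logit-scale individual noise
    pool_divergence: float = 0.3          # SD of the per-locus A-B frequency gap
    adaptive_links: tuple[AdaptiveLink, ...] | None = None
    error_rate: float = 0.0293            # replicate-estimated scoring error
    maf_min: float = 0.05
    area_retain_prob: float = 0.35        # fraction of candidate areas with enough plants
    crest_sigma: float = 25.0             # m, Gaussian cross-profile width
    crest_undulation: float = 20.0        # m, along-ridge cosine amplitude
    noise_amplitude: float = 3.0          # m, correlated micro-topography

    def __post_init__(self) -> None:
        if self.cline_center is None:
            self.cline_center = self.ridge_length / 2.0
        if self.adaptive_links is None:
            self.adaptive_links = default_adaptive_links(self.n_adaptive)
        if len(self.adaptive_links) > self.n_loci:
            raise ValueError("n_adaptive exceeds n_loci")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must be in [0, 0.5)")


def default_adaptive_links(n: int) -> tuple[AdaptiveLink, ...]:
    """Planted links mirroring the kinds of associations the scan targets:
    measured altitude plus terrain variables at specific resolutions."""
    pool = [
        AdaptiveLink(0, "Alt", None, 0.0, 1.2),
        AdaptiveLink(1, "TON", 0.5, 0.0, -1.2),
        AdaptiveLink(2, "Nor", 1.0, 0.0, 1.2),
        AdaptiveLink(3, "Ti12", 1.0, 0.0, -1.2),
        AdaptiveLink(4, "WEX", 0.5, 0.0, 1.5),
    ]
    if n > len(pool):
        raise ValueError(f"no default links beyond {len(pool)} adaptive loci")
    return tuple(pool[:n])


@dataclass
class TruthRecord:
    """Ground truth stored beside the simulated data (never fed to analysis)."""

    q_star: np.ndarray                       # per-individual membership to pool A
    locus_class: list[str]                   # "neutral" | "adaptive"
    links: tuple[AdaptiveLink, ...]
    locus_names: list[str]

    def adaptive_loci(self) -> list[str]:
        return [self.locus_names[l.locus] for l in self.links]

    def to_json(self, path: str) -> None:
        payload = {
            "q_star": np.asarray(self.q_star).round(6).tolist(),
            "locus_class": self.locus_class,
            "links": [asdict(l) for l in self.links],
            "locus_names": self.locus_names,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path: str) -> "TruthRecord":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            q_star=np.asarray(payload["q_star"]),
            locus_class=payload["locus_class"],
            links=tuple(AdaptiveLink(**l) for l in payload["links"]),
            locus_names=payload["locus_names"],
        )


# ---------------------------------------------------------------------------
# Landscape


def _powerlaw_noise(rng: np.random.Generator, shape: tuple[int, int],
                    cell: float, beta: float = 2.0,
                    max_wavelength: float = 50.0) -> np.ndarray:
    """Correlated random field by spectral synthesis (power-law spectrum
    ~ f^-beta), unit variance, band-limited to wavelengths below
    ``max_wavelength`` meters.

    The high-pass matters: unconstrained red noise carries random broad
    trends along the ridge that would confound every smooth terrain variable
    with the (equally smooth) admixture cline.  Micro-topography is kept
    strictly finer-scaled than the cline so the two are separable.
    """
    ky = np.fft.fftfreq(shape[0])[:, None]
    kx = np.fft.rfftfreq(shape[1])[None, :]
    k = np.hypot(ky, kx)
    k[0, 0] = np.inf
    amp = k ** (-beta / 2.0)
    amp[k < cell / max_wavelength] = 0.0
    phase = rng.uniform(0, 2 * np.pi, size=amp.shape)
    spec = amp * np.exp(1j * phase)
    fieldv = np.fft.irfft2(spec, s=shape)
    return (fieldv - fieldv.mean()) / fieldv.std()


def make_ridge_dem(cfg: ScenarioConfig) -> Grid:
    """Elongated ridge: Gaussian cross-profile, gently undulating crest, and
    seedable correlated micro-topography, scaled into ``elev_range``."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 11]))
    nc = int(round(cfg.ridge_length / cfg.base_res))
    nr = int(round(cfg.ridge_width / cfg.base_res))
    nc -= nc % 16
    nr -= nr % 16
    x = (np.arange(nc) + 0.5) * cfg.base_res           # along-ridge (east)
    y = (np.arange(nr) + 0.5) * cfg.base_res           # from north edge southward
    t = y[:, None] - cfg.ridge_width / 2.0             # across-ridge offset from crest
    lo, hi = cfg.elev_range
    drop = (hi - lo) - 2 * cfg.crest_undulation - 2 * cfg.noise_amplitude
    crest = cfg.crest_undulation * np.cos(2 * np.pi * x / cfg.ridge_length)[None, :]
    z = crest + drop * np.exp(-(t ** 2) / (2 * cfg.crest_sigma ** 2))
    z = z + cfg.noise_amplitude * _powerlaw_noise(rng, (nr, nc), cfg.base_res)
    # affine rescale into the configured elevation range
    z = lo + (z - z.min()) * (hi - lo) / (z.max() - z.min())
    return Grid(values=z, x_origin=0.0, y_origin=cfg.ridge_width, cell_size=cfg.base_res,
                crs_label="synthetic-ridge-meters")


# ---------------------------------------------------------------------------
# Sampling design


def make_sampling(cfg: ScenarioConfig, dem: Grid) -> pd.DataFrame:
    """Cluster design: 4x4 m areas at random 0-25 m gaps along the ridge, each
    split into four 2x2 m plots holding >= 5 individuals; areas are retained
    with probability ``area_retain_prob`` (plant presence), and sampling stops
    once ~``n_individuals`` are placed."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 22]))
    xmin, ymin, xmax, ymax = dem.bounds
    records: list[dict] = []
    s = 2.0  # along-ridge cursor (leave a margin)
    area_idx = 0
    crest_y = (ymin + ymax) / 2.0
    # across-ridge area offsets cycle through a shuffled balanced deck, so
    # every stretch of the transect samples the same crest-to-flank profile;
    # purely random offsets would couple across-ridge habitat with position
    # along the ridge at the handful-of-areas scale
    deck = np.array([-28.0, -20.0, -12.0, -5.0, 0.0, 7.0, 14.0, 22.0])
    deck_order = rng.permutation(len(deck))
    while len(records) < cfg.n_individuals:
        s += rng.uniform(0.0, 25.0)
        if s + 4.0 > xmax - 2.0:
            if len(records) < 0.8 * cfg.n_individuals:
                raise ValueError("ridge too short for the target sample size")
            break
        if rng.uniform() > cfg.area_retain_prob:
            s += 4.0
            continue
        if area_idx % len(deck) == 0:
            deck_order = rng.permutation(len(deck))
        t0 = crest_y + deck[deck_order[area_idx % len(deck)]] \
            + rng.uniform(-2.0, 2.0)
        area_idx += 1
        t0 = min(max(t0, ymin + 1.0), ymax - 5.0)
        for k, (dx, dy) in enumerate(((0, 0), (2, 0), (0, 2), (2, 2))):
            n_here = 5 + int(rng.uniform() < 0.4)
            for _ in range(n_here):
                records.append({
                    "x": s + dx + rng.uniform(0.0, 2.0),
                    "y": t0 + dy + rng.uniform(0.0, 2.0),
                    "plot_id": f"A{area_idx:03d}P{k + 1}",
                })
        s += 4.0
    df = pd.DataFrame(records)
    df.insert(0, "id", [f"ind{i + 1:04d}" for i in range(len(df))])
    # field-measured altitude: DEM value + differential-GPS vertical noise
    from .grid_io import extract_at

    df["alt"] = extract_at(dem, df) + rng.normal(0.0, 0.035, size=len(df))
    return df[["id", "x", "y", "alt", "plot_id"]]


# ---------------------------------------------------------------------------
# Genotypes


def _logistic(v: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-v))


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd == 0:
        raise ValueError("adaptive link variable is constant across samples")
    return (v - v.mean()) / sd


def simulate_genotypes(cfg: ScenarioConfig, dem: Grid, samples: pd.DataFrame,
                       stack: dict[tuple[str, float], Grid] | None = None,
                       ) -> tuple[pd.DataFrame, TruthRecord]:
    """Binary genotype matrix (individuals x loci) plus ground truth.

    Neutral locus l:  P(band) = q*_i p_Al + (1 - q*_i) p_Bl, with q* the
    logistic admixture cline along the ridge axis plus individual logit noise.
    Adaptive locus:   P(band) = logistic(beta0 + beta1 z_i) with z the
    standardized linked variable.  Symmetric scoring errors flip bands with
    probability ``error_rate``; loci failing the minor-variant frequency
    filter are resimulated so the matrix holds ``n_loci`` polymorphic loci.
    """
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 33]))
    n = len(samples)
    svals = samples["x"].to_numpy()
    logit_q = (svals - cfg.cline_center) / cfg.cline_width \
        + rng.normal(0.0, cfg.cline_noise_sd, size=n)
    q = _logistic(logit_q)

    links = cfg.adaptive_links
    env: dict[int, np.ndarray] = {}
    for link in links:
        if link.variable == "Alt":
            v = samples["alt"].to_numpy()
        else:
            if stack is None:
                raise ValueError("terrain stack required for adaptive links")
            key = (link.variable, float(link.resolution))
            if key not in stack:
                raise ValueError(f"stack does not cover linked variable {key}")
            from .grid_io import extract_at

            v = extract_at(stack[key], samples)
        env[link.locus] = _standardize(v)

    geno = np.zeros((n, cfg.n_loci), dtype=np.int8)
    locus_class = ["neutral"] * cfg.n_loci
    adaptive_idx = {l.locus for l in links}
    for l in adaptive_idx:
        locus_class[l] = "adaptive"

    def draw_neutral() -> np.ndarray:
        p0 = rng.uniform(0.15, 0.85)
        gap = rng.normal(0.0, cfg.pool_divergence)
        p_a = np.clip(p0 + gap / 2.0, 0.02, 0.98)
        p_b = np.clip(p0 - gap / 2.0, 0.02, 0.98)
        p = q * p_a + (1.0 - q) * p_b
        return (rng.uniform(size=n) < p).astype(np.int8)

    def apply_errors(col: np.ndarray) -> np.ndarray:
        flips = rng.uniform(size=n) < cfg.error_rate
        return np.where(flips, 1 - col, col).astype(np.int8)

    def maf_ok(col: np.ndarray) -> bool:
        f = col.mean()
        return min(f, 1.0 - f) > cfg.maf_min

    for l in range(cfg.n_loci):
        for attempt in range(200):
            if l in adaptive_idx:
                link = next(lk for lk in links if lk.locus == l)
                p = _logistic(link.beta0 + link.beta1 * env[l])
                col = (rng.uniform(size=n) < p).astype(np.int8)
            else:
                col = draw_neutral()
            col = apply_errors(col)
            if maf_ok(col):
                geno[:, l] = col
                break
        else:
            raise ValueError(
                f"locus {l}: cannot reach minor-variant frequency > {cfg.maf_min}")

    names = [f"L{l + 1:04d}" for l in range(cfg.n_loci)]
    gm = pd.DataFrame(geno, index=samples["id"].to_numpy(), columns=names)
    gm.index.name = "id"
    truth = TruthRecord(q_star=q, locus_class=locus_class, links=links,
                        locus_names=names)
    return gm, truth
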