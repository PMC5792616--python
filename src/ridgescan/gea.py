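"""Multiscale gene-environment association scan with binomial mixed models.

For every (locus, environmental variable, resolution) cell a logistic
random-intercept model

    y_i ~ Bernoulli(logit^-1(b0 + b1 x_i + u_g)),   u_g ~ N(0, sigma_u^2)

is fitted by maximizing the Laplace-approximated marginal likelihood, with the
DEM pixel at that resolution as the grouping factor (sampling plot for the
non-raster covariates Alt, X, Y and the population-membership coefficient).
Significance comes from a chi-square(1) likelihood-ratio test against the
constant model, with a single Bonferroni family over all attempted cells.
AIC uses k = (#fixed effects) + 1 variance component, so the identity
lrt_stat = aic_null - aic_full + 2 holds for one added fixed parameter.

An adaptive Gauss-Hermite evaluation of the marginal likelihood is available
as a cross-check of the Laplace approximation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from . import _kernels
from .grid_io import Grid, pixel_ids

__all__ = ["GlmmFit", "AssocRecord", "ScanConfig", "fit_binomial_glmm",
           "lrt_pvalue", "scan", "resolution_profile", "agq_loglik"]

PLOT_EFFECT_VARS = ("Alt", "X", "Y", "membership")


@dataclass
class GlmmFit:
    beta0: float
    beta1: float | None
    sigma_u: float
    loglik: float
    aic: float
    n_groups: int
    converged: bool
    message: str = ""


@dataclass
class AssocRecord:
    locus: str
    variable: str
    resolution: float | None
    beta0: float
    beta1: float
    sigma_u: float
    loglik_full: float
    loglik_null: float
    aic_full: float
    aic_null: float
    lrt_stat: float
    p: float
    n_groups: int
    converged: bool
    freq_A: float = np.nan
    freq_B: float = np.nan
    freq_adm: float = np.nan
    significant: bool = False


@dataclass
class ScanConfig:
    variables: tuple[str, ...] | None = None   # None -> every var in the env table
    resolutions: tuple[float, ...] | None = None
    alpha: float = 0.05
    standardize: bool = True
    include_position: bool = True              # add plot-random-effect models
    position_vars: tuple[str, ...] = PLOT_EFFECT_VARS  # which of Alt/X/Y/membership
    sigma_zero_tol: float = 1e-3               # below this sigma_u reports as boundary 0


SIGMA_BOUNDS_LOG = (-8.0, 1.0)


def _fit(y: np.ndarray, x: np.ndarray | None, gidx: np.ndarray, n_groups: int,
         ls0: float = -1.0, sigma_fixed: float | None = None,
         start: np.ndarray | None = None) -> GlmmFit:
    y = np.ascontiguousarray(y, dtype=float)
    has_x = x is not None
    xv = np.ascontiguousarray(x if has_x else np.zeros_like(y), dtype=float)
    gidx = np.ascontiguousarray(gidx, dtype=np.int64)
    if y.min() == y.max():
        raise ValueError("response is constant; model not estimable")
    if has_x and np.ptp(xv) == 0:
        return GlmmFit(np.nan, np.nan, np.nan, np.nan, np.nan, n_groups, False,
                       "constant covariate: slope inestimable")
    b0, b1, ll_fixed = _kernels.logistic_newton(y, xv, has_x)
    if sigma_fixed is not None:
        if sigma_fixed != 0:
            raise ValueError("only sigma_fixed = 0 is supported")
        # exact sigma_u -> 0 limit of the marginal likelihood: plain logistic
        k = (2 if has_x else 1) + 1
        return GlmmFit(beta0=float(b0), beta1=float(b1) if has_x else None,
                       sigma_u=0.0, loglik=float(ll_fixed),
                       aic=2 * k - 2 * float(ll_fixed), n_groups=n_groups,
                       converged=True, message="sigma_u fixed at 0")
    u = np.zeros(n_groups)
    x0 = np.array([b0, b1, ls0]) if has_x else np.array([b0, ls0])
    if start is not None:
        x0 = np.asarray(start, dtype=float)
    params, nll, conv = _kernels.glmm_fit_nm(
        x0, y, xv, has_x, gidx, n_groups, u, 600, 1e-9, 1e-6)
    # a sigma_u -> 0 fit can never beat the plain logistic likelihood; if the
    # optimizer got stuck above it, restart from the boundary
    if nll > -ll_fixed + 1e-6:
        u[:] = 0.0
        x0b = x0.copy()
        x0b[-1] = -7.0
        params_b, nll_b, conv_b = _kernels.glmm_fit_nm(
            x0b, y, xv, has_x, gidx, n_groups, u, 600, 1e-9, 1e-6)
        if nll_b < nll:
            params, nll, conv = params_b, nll_b, conv_b
    ls = float(np.clip(params[-1], *SIGMA_BOUNDS_LOG))
    sigma = float(np.exp(ls))
    loglik = -float(nll)
    k = (2 if has_x else 1) + 1
    return GlmmFit(
        beta0=float(params[0]),
        beta1=float(params[1]) if has_x else None,
        sigma_u=sigma,
        loglik=loglik,
        aic=2 * k - 2 * loglik,
        n_groups=n_groups,
        converged=bool(conv),
    )


def fit_binomial_glmm(y, x=None, groups=None, sigma_fixed: float | None = None,
                      ) -> GlmmFit:
    """Fit the binomial random-intercept GLMM (Laplace marginal likelihood).

    Parameters
    ----------
    y : binary response vector
    x : covariate vector, or None for the constant (null) model
    groups : group labels (any hashable); singleton-only groupings are legal
        and drive sigma_u to its boundary, where the fit matches plain
        logistic regression.
    """
    y = np.asarray(y, dtype=float)
    if groups is None:
        raise ValueError("groups are required")
    codes, uniques = pd.factorize(np.asarray(groups))
    if len(y) != len(codes) or (x is not None and len(x) != len(y)):
        raise ValueError("y, x and groups must have equal length")
    return _fit(y, None if x is None else np.asarray(x, dtype=float),
                codes, len(uniques), sigma_fixed=sigma_fixed)


def agq_loglik(y, x, groups, beta0: float, beta1: float | None, sigma_u: float,
               n_nodes: int = 9) -> float:
    """Adaptive Gauss-Hermite marginal log-likelihood at fixed parameters.

    Cross-check for the Laplace approximation (which is the n_nodes = 1
    special case); >= 5 nodes is accurate for these group sizes.
    """
    y = np.asarray(y, dtype=float)
    xv = np.zeros_like(y) if x is None else np.asarray(x, dtype=float)
    b1 = 0.0 if beta1 is None else beta1
    codes, uniques = pd.factorize(np.asarray(groups))
    ngroups = len(uniques)
    eta_fix = beta0 + b1 * xv
    sigma2 = max(sigma_u, 1e-8) ** 2
    # per-group mode by Newton
    u = np.zeros(ngroups)
    for _ in range(100):
        eta = eta_fix + u[codes]
        p = 1.0 / (1.0 + np.exp(-eta))
        g1 = np.bincount(codes, y - p, minlength=ngroups) - u / sigma2
        g2 = np.bincount(codes, p * (1 - p), minlength=ngroups) + 1.0 / sigma2
        step = g1 / g2
        u += step
        if np.abs(step).max() < 1e-11:
            break
    eta = eta_fix + u[codes]
    p = 1.0 / (1.0 + np.exp(-eta))
    h = np.bincount(codes, p * (1 - p), minlength=ngroups) + 1.0 / sigma2
    nodes, weights = np.polynomial.hermite.hermgauss(n_nodes)
    scale = np.sqrt(2.0) / np.sqrt(h)
    total = 0.0
    for g in range(ngroups):
        us = u[g] + scale[g] * nodes
        sel = codes == g
        eta_g = eta_fix[sel][:, None] + us[None, :]
        ll_g = (y[sel][:, None] * eta_g - np.logaddexp(0.0, eta_g)).sum(axis=0)
        ll_g = ll_g - us**2 / (2 * sigma2) - 0.5 * np.log(2 * np.pi * sigma2)
        total += np.log((weights * np.exp(nodes**2)
                         * np.exp(ll_g - ll_g.max())).sum() * scale[g]) + ll_g.max()
    return float(total)


def lrt_pvalue(loglik_full: float, loglik_null: float) -> tuple[float, float]:
    """Likelihood-ratio statistic (clipped at 0) and chi-square(1) upper-tail
    p-value for one added fixed parameter."""
    stat = max(0.0, 2.0 * (loglik_full - loglik_null))
    return stat, float(stats.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Scan

def _group_frequencies(y: np.ndarray, labels: np.ndarray | None,
                       ) -> tuple[float, float, float]:
    if labels is None:
        return np.nan, np.nan, np.nan
    out = []
    for lab in ("A", "B", "admixed"):
        sel = labels == lab
        out.append(float(y[sel].mean()) if sel.any() else np.nan)
    return tuple(out)


def scan(gm: pd.DataFrame, env: pd.DataFrame, samples: pd.DataFrame,
         pyr: dict[float, Grid], membership: np.ndarray | None = None,
         cfg: ScanConfig | None = None) -> pd.DataFrame:
    """Run the full association scan; one row per (locus, variable,
    resolution) plus one per (locus, plot-level covariate).

    ``env`` is the long per-sample table (id, var, res, value); groupings are
    DEM pixel ids from ``pyr`` per resolution for raster variables and
    ``plot_id`` for Alt/X/Y/membership.  Loci with missing genotypes drop the
    affected individuals per record (never imputed).  A failed cell is
    flagged, never fatal.
    """
    cfg = cfg or ScanConfig()
    ids = list(samples["id"])
    if list(gm.index) != ids:
        gm = gm.loc[ids]
    xs = samples["x"].to_numpy()
    ys = samples["y"].to_numpy()

    # grouping codes per resolution (pixel) and for plots
    group_codes: dict[float, tuple[np.ndarray, int]] = {}
    for res, grid in pyr.items():
        r, c = pixel_ids(grid, xs, ys)
        codes, uniq = pd.factorize(r * grid.n_cols + c)
        group_codes[res] = (codes.astype(np.int64), len(uniq))
    plot_codes, plot_uniq = pd.factorize(samples["plot_id"].to_numpy())
    plot_codes = plot_codes.astype(np.int64)
    n_plots = len(plot_uniq)

    env_vars = sorted(env["var"].unique()) if cfg.variables is None \
        else [v for v in cfg.variables if v not in PLOT_EFFECT_VARS]
    resolutions = sorted(env["res"].unique()) if cfg.resolutions is None \
        else list(cfg.resolutions)
    env_idx = env.set_index(["var", "res", "id"])["value"]

    position_vars: list[tuple[str, np.ndarray]] = []
    if cfg.include_position:
        candidates = [("Alt", samples["alt"].to_numpy()),
                      ("X", xs.copy()), ("Y", ys.copy())]
        if membership is not None:
            candidates.append(("membership", np.asarray(membership, dtype=float)))
        position_vars = [(n, v) for n, v in candidates if n in cfg.position_vars]

    labels = None
    if membership is not None:
        from .structure import assign
        labels = assign(np.asarray(membership, dtype=float))

    def maybe_std(v: np.ndarray) -> np.ndarray:
        if cfg.standardize:
            sd = v.std()
            return (v - v.mean()) / sd if sd > 0 else v - v.mean()
        return v

    records: list[AssocRecord] = []
    geno = gm.to_numpy(dtype=float)
    for j, locus in enumerate(gm.columns):
        y_full = geno[:, j]
        obs = ~np.isnan(y_full)
        fA, fB, fadm = _group_frequencies(y_full[obs], None if labels is None
                                          else labels[obs])
        null_cache: dict[object, GlmmFit | None] = {}

        def null_fit(key, codes, nuniq):
            if key not in null_cache:
                try:
                    null_cache[key] = _fit(y_full[obs], None,
                                           *_subset_codes(codes, obs))
                except ValueError:
                    null_cache[key] = None
            return null_cache[key]

        cells: list[tuple[str, float | None, np.ndarray, object]] = []
        for var in env_vars:
            for res in resolutions:
                try:
                    v = env_idx.loc[(var, res)].loc[ids].to_numpy()
                except KeyError:
                    continue
                cells.append((var, res, v, res))
        for var, v in position_vars:
            cells.append((var, None, v, "plot"))

        for var, res, v, gkey in cells:
            if gkey == "plot":
                codes, nuniq = plot_codes, n_plots
            else:
                codes, nuniq = group_codes[res]
            ok = obs & np.isfinite(v)
            rec = AssocRecord(locus=locus, variable=var, resolution=res,
                              beta0=np.nan, beta1=np.nan, sigma_u=np.nan,
                              loglik_full=np.nan, loglik_null=np.nan,
                              aic_full=np.nan, aic_null=np.nan,
                              lrt_stat=np.nan, p=np.nan, n_groups=0,
                              converged=False, freq_A=fA, freq_B=fB,
                              freq_adm=fadm)
            try:
                nf = null_fit((gkey, obs.tobytes()), codes, nuniq) if ok.all() \
                    else _fit(y_full[ok], None, *_subset_codes(codes, ok))
                if nf is None:
                    raise ValueError("null model not estimable")
                ls0 = float(np.clip(np.log(max(nf.sigma_u, 1e-3)), -7.0, 1.0))
                xstd = maybe_std(v[ok])
                sub_codes = _subset_codes(codes, ok)
                ff = _fit(y_full[ok], xstd, *sub_codes, ls0=ls0)
                if not np.isnan(ff.loglik) and ff.loglik < nf.loglik - 1e-9:
                    # nested models: the full fit can never be below the null;
                    # rescue a stray optimizer run from the null's solution
                    ff = _fit(y_full[ok], xstd, *sub_codes,
                              start=np.array([nf.beta0, 0.0, ls0]))
                if np.isnan(ff.loglik):
                    rec.converged = False
                else:
                    stat, p = lrt_pvalue(ff.loglik, nf.loglik)
                    rec.beta0 = ff.beta0
                    rec.beta1 = ff.beta1
                    rec.sigma_u = ff.sigma_u
                    rec.loglik_full = ff.loglik
                    rec.loglik_null = nf.loglik
                    rec.aic_full = ff.aic
                    rec.aic_null = nf.aic
                    rec.lrt_stat = stat
                    rec.p = p
                    rec.n_groups = ff.n_groups
                    rec.converged = ff.converged and nf.converged
            except ValueError:
                pass
            records.append(rec)

    df = pd.DataFrame([r.__dict__ for r in records])
    n_tests = len(df)
    threshold = cfg.alpha / n_tests if n_tests else np.nan
    df["significant"] = df["converged"] & (df["p"] < threshold)
    df.attrs["bonferroni_threshold"] = threshold
    df.attrs["n_tests"] = n_tests
    return df


def _subset_codes(codes: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, int]:
    sub = codes[mask]
    recoded, uniq = pd.factorize(sub)
    return recoded.astype(np.int64), len(uniq)


def resolution_profile(records: pd.DataFrame, locus: str, variable: str,
                       ) -> pd.DataFrame:
    """Ordered (resolution, -log10 p) series for one locus x variable, with
    the scan's Bonferroni line attached in ``attrs``."""
    sel = records[(records["locus"] == locus) & (records["variable"] == variable)
                  & records["resolution"].notna()]
    if len(sel) < 2:
        raise ValueError("need records at two or more resolutions")
    out = sel.sort_values("resolution")[["resolution", "p"]].copy()
    out["neglog10_p"] = -np.log10(out["p"])
    out.attrs["bonferroni_threshold"] = records.attrs.get("bonferroni_threshold")
    return out.reset_index(drop=True)
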