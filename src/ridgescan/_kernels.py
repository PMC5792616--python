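"""Numba kernels behind the terrain operators and the binomial GLMM.

Everything here is deterministic, single-threaded, and operates on plain
ndarrays; the public modules wrap these with the Grid/DataFrame interfaces.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# ---------------------------------------------------------------------------
# Profile walks (openness, sky view factor, wind exposure, horizon shading)


@njit(cache=True)
def _bilinear(z, rf, cf):
    """Bilinear sample at fractional (row, col); NaN outside the grid or when
    any supporting cell is NaN."""
    nr, nc = z.shape
    if rf < 0.0 or cf < 0.0 or rf > nr - 1.0 or cf > nc - 1.0:
        return np.nan
    r0 = int(rf)
    c0 = int(cf)
    if r0 == nr - 1:
        r0 -= 1
    if c0 == nc - 1:
        c0 -= 1
    fr = rf - r0
    fc = cf - c0
    z00 = z[r0, c0]
    z01 = z[r0, c0 + 1]
    z10 = z[r0 + 1, c0]
    z11 = z[r0 + 1, c0 + 1]
    return ((1 - fr) * ((1 - fc) * z00 + fc * z01)
            + fr * ((1 - fc) * z10 + fc * z11))


@njit(cache=True)
def horizon_scan(z, cell, radius, azimuths):
    """Maximum elevation angle (radians, signed) seen from every cell along
    each azimuth, sampling the profile bilinearly at one-cell steps out to
    ``radius``.

    Azimuths are clockwise from north; profiles stop at the grid edge.
    Bilinear sampling keeps planes exact (so a plane's openness is pi/2 in
    every azimuth mean).  Returns an array of shape (n_az, n_rows, n_cols).
    """
    nr, nc = z.shape
    na = azimuths.shape[0]
    nstep = int(radius / cell)
    out = np.full((na, nr, nc), -np.pi / 2)
    for a in range(na):
        dx = np.sin(azimuths[a])
        dy = np.cos(azimuths[a])
        for r in range(nr):
            for c in range(nc):
                z0 = z[r, c]
                if np.isnan(z0):
                    out[a, r, c] = np.nan
                    continue
                best = -np.pi / 2
                for k in range(1, nstep + 1):
                    zt = _bilinear(z, r - k * dy, c + k * dx)
                    if np.isnan(zt):
                        break
                    ang = np.arctan2(zt - z0, k * cell)
                    if ang > best:
                        best = ang
                out[a, r, c] = best
    return out


@njit(cache=True)
def wind_exposure_scan(z, cell, radius, azimuths, decay):
    """Isotropic wind-exposure index.

    For each azimuth the distance-weighted mean of the slope angles from the
    focal cell to the profile cells (positive when the focal cell overlooks
    the terrain, negative when the terrain rises above it) is computed with
    weights exp(-decay * distance); the index is
    1 + mean_d (2/pi) * arctan(mean angle_d), i.e. 1 on a plane, > 1 on
    crests and < 1 in sheltered hollows.

    The profile is sampled densely (every cell) out to 100 steps and with
    doubling strides beyond, each sample weighted by the stride it represents
    — a quadrature of the same decaying profile integral that keeps the far
    field cheap.  Opposite azimuths sample identical distances, so the index
    is exactly 1 on any plane.
    """
    nr, nc = z.shape
    na = azimuths.shape[0]
    nstep = int(radius / cell)
    out = np.full((nr, nc), np.nan)
    for r in range(nr):
        for c in range(nc):
            z0 = z[r, c]
            if np.isnan(z0):
                continue
            acc = 0.0
            for a in range(na):
                dx = np.sin(azimuths[a])
                dy = np.cos(azimuths[a])
                wsum = 0.0
                asum = 0.0
                k = 1
                stride = 1
                while k <= nstep:
                    zt = _bilinear(z, r - k * dy, c + k * dx)
                    if np.isnan(zt):
                        break
                    d = k * cell
                    w = np.exp(-decay * d) * stride
                    asum += w * np.arctan2(z0 - zt, d)
                    wsum += w
                    if k >= 400:
                        stride = 8
                    elif k >= 200:
                        stride = 4
                    elif k >= 100:
                        stride = 2
                    k += stride
                if wsum > 0.0:
                    acc += (2.0 / np.pi) * np.arctan(asum / wsum)
            out[r, c] = 1.0 + acc / na
    return out


# ---------------------------------------------------------------------------
# Hydrology

_D8_DR = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)
_D8_DC = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)


@njit(cache=True)
def mfd_accumulation(z, cell, order, exponent):
    """Freeman multiple-flow-direction accumulation (in cell counts).

    ``order`` must list cell indices in descending elevation; flow to each
    lower neighbor is proportional to (positive slope)**exponent.
    """
    nr, nc = z.shape
    acc = np.ones(nr * nc)
    for t in range(order.shape[0]):
        idx = order[t]
        r = idx // nc
        c = idx % nc
        z0 = z[r, c]
        if np.isnan(z0):
            acc[idx] = np.nan
            continue
        wsum = 0.0
        w = np.zeros(8)
        for n in range(8):
            rr = r + _D8_DR[n]
            cc = c + _D8_DC[n]
            if rr < 0 or rr >= nr or cc < 0 or cc >= nc:
                continue
            zt = z[rr, cc]
            if np.isnan(zt) or zt >= z0:
                continue
            dist = cell * np.sqrt(float(_D8_DR[n] ** 2 + _D8_DC[n] ** 2))
            w[n] = ((z0 - zt) / dist) ** exponent
            wsum += w[n]
        if wsum <= 0.0:
            continue
        for n in range(8):
            if w[n] > 0.0:
                rr = r + _D8_DR[n]
                cc = c + _D8_DC[n]
                acc[rr * nc + cc] += acc[idx] * w[n] / wsum
    return acc.reshape(nr, nc)


@njit(cache=True)
def d8_flow_path_length(z, cell, order_asc, downstream):
    """D8 flow-path length in meters.

    ``downstream=True``: distance along the steepest-descent path to the grid
    edge (edge cells are 0); cells with no lower neighbor terminate the path.
    ``downstream=False``: longest upstream flow path arriving at each cell
    (drainage-divide cells are 0).  ``order_asc`` lists indices by ascending
    elevation.
    """
    nr, nc = z.shape
    fpl = np.zeros((nr, nc))
    if downstream:
        for t in range(order_asc.shape[0]):
            idx = order_asc[t]
            r = idx // nc
            c = idx % nc
            if np.isnan(z[r, c]):
                fpl[r, c] = np.nan
                continue
            if r == 0 or r == nr - 1 or c == 0 or c == nc - 1:
                continue  # edge cell: 0
            best = 0.0
            br, bc, bd = -1, -1, 0.0
            for n in range(8):
                rr = r + _D8_DR[n]
                cc = c + _D8_DC[n]
                zt = z[rr, cc]
                if np.isnan(zt):
                    continue
                dist = cell * np.sqrt(float(_D8_DR[n] ** 2 + _D8_DC[n] ** 2))
                s = (z[r, c] - zt) / dist
                if s > best:
                    best = s
                    br, bc, bd = rr, cc, dist
            if br >= 0:
                fpl[r, c] = fpl[br, bc] + bd
    else:
        for t in range(order_asc.shape[0] - 1, -1, -1):
            idx = order_asc[t]
            r = idx // nc
            c = idx % nc
            if np.isnan(z[r, c]):
                continue
            best = 0.0
            br, bc, bd = -1, -1, 0.0
            for n in range(8):
                rr = r + _D8_DR[n]
                cc = c + _D8_DC[n]
                if rr < 0 or rr >= nr or cc < 0 or cc >= nc:
                    continue
                zt = z[rr, cc]
                if np.isnan(zt):
                    continue
                dist = cell * np.sqrt(float(_D8_DR[n] ** 2 + _D8_DC[n] ** 2))
                s = (z[r, c] - zt) / dist
                if s > best:
                    best = s
                    br, bc, bd = rr, cc, dist
            if br >= 0:
                cand = fpl[r, c] + bd
                if cand > fpl[br, bc]:
                    fpl[br, bc] = cand
    return fpl


# ---------------------------------------------------------------------------
# Clear-sky solar radiation


@njit(cache=True)
def solar_total(slope, aspect, horizon, azimuths, svf, lat_rad, days, step_minutes,
                transmittance):
    """Monthly clear-sky irradiation total on the tilted surface, kWh/m2.

    Direct beam: 1.367 kW/m2 * tau**(1/sin h) * cos(incidence), zeroed when
    the sun is below the DEM horizon in its azimuth (linear interpolation
    between scanned azimuths).  Diffuse: isotropic 0.3 * 1.367 * (1 - tau**m)
    weighted by the sky-view factor.  ``days`` are days-of-year; the solar
    position uses the standard declination / hour-angle formulas.
    """
    nr, nc = slope.shape
    na = azimuths.shape[0]
    out = np.zeros((nr, nc))
    sin_lat = np.sin(lat_rad)
    cos_lat = np.cos(lat_rad)
    step_h = step_minutes / 60.0
    nsteps = int(round(24 * 60 / step_minutes))
    sin_s = np.sin(slope)
    cos_s = np.cos(slope)
    for d in range(days.shape[0]):
        decl = np.deg2rad(23.45) * np.sin(2.0 * np.pi * (284.0 + days[d]) / 365.0)
        sin_d = np.sin(decl)
        cos_d = np.cos(decl)
        for t in range(nsteps):
            hour = (t + 0.5) * step_minutes / 60.0
            omega = np.deg2rad(15.0 * (hour - 12.0))
            sinh = sin_lat * sin_d + cos_lat * cos_d * np.cos(omega)
            if sinh <= 1e-3:
                continue
            h_sun = np.arcsin(sinh)
            cosh = np.cos(h_sun)
            e = -cos_d * np.sin(omega)
            n = sin_d * cos_lat - cos_d * sin_lat * np.cos(omega)
            az_sun = np.arctan2(e, n) % (2.0 * np.pi)
            m = 1.0 / sinh
            beam = 1.367 * transmittance ** m
            diff0 = 0.3 * 1.367 * (1.0 - transmittance ** m)
            # azimuth interpolation weights into the horizon stack
            pos = az_sun / (2.0 * np.pi) * na
            a0 = int(pos) % na
            a1 = (a0 + 1) % na
            frac = pos - int(pos)
            for r in range(nr):
                for c in range(nc):
                    if np.isnan(slope[r, c]):
                        continue
                    hor = (1.0 - frac) * horizon[a0, r, c] + frac * horizon[a1, r, c]
                    direct = 0.0
                    if h_sun > hor:
                        cosinc = (cos_s[r, c] * sinh
                                  + sin_s[r, c] * cosh * np.cos(az_sun - aspect[r, c]))
                        if cosinc > 0.0:
                            direct = beam * cosinc
                    out[r, c] += (direct + diff0 * svf[r, c]) * step_h
    return out


# ---------------------------------------------------------------------------
# Binomial random-intercept GLMM: Laplace-approximated marginal likelihood


@njit(cache=True)
def _log1pexp(eta):
    if eta > 0.0:
        return eta + np.log1p(np.exp(-eta))
    return np.log1p(np.exp(eta))


@njit(cache=True)
def glmm_nll(params, y, x, has_x, gidx, ngroups, u):
    """Negative Laplace log-likelihood of logit(p) = b0 [+ b1 x] + u_g.

    ``params`` is (b0, log sigma) or (b0, b1, log sigma).  ``u`` is the
    per-group mode workspace, warm-started across calls.  Inner Newton on the
    concave penalized per-group likelihood.
    """
    n = y.shape[0]
    if has_x:
        b0, b1, ls = params[0], params[1], params[2]
    else:
        b0, ls = params[0], params[1]
        b1 = 0.0
    penalty = 0.0
    if ls < -8.0:
        penalty = 1e-4 * (ls + 8.0) ** 2
        ls = -8.0
    elif ls > 1.0:
        # the Laplace surface for mostly-singleton binary groups grows a
        # spurious optimum at large sigma (the true marginal likelihood does
        # not); keep the optimizer inside the trustworthy region
        penalty = 10.0 * (ls - 1.0) ** 2
        ls = 1.0
    sigma2 = np.exp(2.0 * ls)
    g1 = np.zeros(ngroups)
    g2 = np.zeros(ngroups)
    for _ in range(60):
        for g in range(ngroups):
            g1[g] = 0.0
            g2[g] = 0.0
        for i in range(n):
            eta = b0 + b1 * x[i] + u[gidx[i]]
            p = 1.0 / (1.0 + np.exp(-eta))
            g1[gidx[i]] += y[i] - p
            g2[gidx[i]] += p * (1.0 - p)
        dmax = 0.0
        for g in range(ngroups):
            step = (g1[g] - u[g] / sigma2) / (g2[g] + 1.0 / sigma2)
            u[g] += step
            if abs(step) > dmax:
                dmax = abs(step)
        if dmax < 1e-9:
            break
    # final pass for the log-likelihood and Hessian at the mode
    ll = 0.0
    for g in range(ngroups):
        g2[g] = 0.0
    for i in range(n):
        eta = b0 + b1 * x[i] + u[gidx[i]]
        ll += y[i] * eta - _log1pexp(eta)
        p = 1.0 / (1.0 + np.exp(-eta))
        g2[gidx[i]] += p * (1.0 - p)
    for g in range(ngroups):
        ll -= u[g] * u[g] / (2.0 * sigma2)
        ll -= 0.5 * np.log(sigma2 * (g2[g] + 1.0 / sigma2))
    return -(ll) + penalty


@njit(cache=True)
def logistic_newton(y, x, has_x):
    """Plain logistic regression by Newton; returns (b0, b1, loglik)."""
    n = y.shape[0]
    ybar = 0.0
    for i in range(n):
        ybar += y[i]
    ybar /= n
    if ybar < 1e-6:
        ybar = 1e-6
    if ybar > 1.0 - 1e-6:
        ybar = 1.0 - 1e-6
    b0 = np.log(ybar / (1.0 - ybar))
    b1 = 0.0
    for _ in range(25):
        s0 = 0.0
        s1 = 0.0
        h00 = 0.0
        h01 = 0.0
        h11 = 0.0
        for i in range(n):
            eta = b0 + b1 * x[i]
            p = 1.0 / (1.0 + np.exp(-eta))
            w = p * (1.0 - p)
            r = y[i] - p
            s0 += r
            h00 += w
            if has_x:
                s1 += r * x[i]
                h01 += w * x[i]
                h11 += w * x[i] * x[i]
        if has_x:
            det = h00 * h11 - h01 * h01
            if det < 1e-12:
                break
            d0 = (h11 * s0 - h01 * s1) / det
            d1 = (h00 * s1 - h01 * s0) / det
        else:
            if h00 < 1e-12:
                break
            d0 = s0 / h00
            d1 = 0.0
        # damp large steps to keep Newton stable on separable data
        mx = max(abs(d0), abs(d1))
        if mx > 5.0:
            d0 *= 5.0 / mx
            d1 *= 5.0 / mx
        b0 += d0
        b1 += d1
        if max(abs(d0), abs(d1)) < 1e-10:
            break
    ll = 0.0
    for i in range(n):
        eta = b0 + b1 * x[i]
        ll += y[i] * eta - _log1pexp(eta)
    return b0, b1, ll


@njit(cache=True)
def glmm_fit_nm(x0, y, x, has_x, gidx, ngroups, u, max_iter, fatol, xatol):
    """Nelder-Mead minimization of :func:`glmm_nll`.

    Returns (params, nll, converged flag). Deterministic: fixed initial
    simplex steps, no randomness.
    """
    d = x0.shape[0]
    npts = d + 1
    simplex = np.zeros((npts, d))
    fvals = np.zeros(npts)
    steps = np.full(d, 0.25)
    steps[d - 1] = 0.6  # log-sigma direction
    for j in range(npts):
        simplex[j] = x0.copy()
        if j > 0:
            simplex[j, j - 1] += steps[j - 1]
        fvals[j] = glmm_nll(simplex[j], y, x, has_x, gidx, ngroups, u)
    nfev = npts
    converged = False
    while nfev < max_iter:
        order = np.argsort(fvals)
        simplex = simplex[order]
        fvals = fvals[order]
        fspread = abs(fvals[npts - 1] - fvals[0])
        xspread = 0.0
        for j in range(1, npts):
            for k in range(d):
                diff = abs(simplex[j, k] - simplex[0, k])
                if diff > xspread:
                    xspread = diff
        if fspread < fatol and xspread < xatol:
            converged = True
            break
        centroid = np.zeros(d)
        for j in range(npts - 1):
            centroid += simplex[j]
        centroid /= npts - 1
        xr = centroid + (centroid - simplex[npts - 1])
        fr = glmm_nll(xr, y, x, has_x, gidx, ngroups, u)
        nfev += 1
        if fr < fvals[0]:
            xe = centroid + 2.0 * (centroid - simplex[npts - 1])
            fe = glmm_nll(xe, y, x, has_x, gidx, ngroups, u)
            nfev += 1
            if fe < fr:
                simplex[npts - 1] = xe
                fvals[npts - 1] = fe
            else:
                simplex[npts - 1] = xr
                fvals[npts - 1] = fr
        elif fr < fvals[npts - 2]:
            simplex[npts - 1] = xr
            fvals[npts - 1] = fr
        else:
            if fr < fvals[npts - 1]:
                xc = centroid + 0.5 * (xr - centroid)
            else:
                xc = centroid + 0.5 * (simplex[npts - 1] - centroid)
            fc = glmm_nll(xc, y, x, has_x, gidx, ngroups, u)
            nfev += 1
            if fc < min(fr, fvals[npts - 1]):
                simplex[npts - 1] = xc
                fvals[npts - 1] = fc
            else:
                for j in range(1, npts):
                    simplex[j] = simplex[0] + 0.5 * (simplex[j] - simplex[0])
                    fvals[j] = glmm_nll(simplex[j], y, x, has_x, gidx, ngroups, u)
                    nfev += 1
    order = np.argsort(fvals)
    return simplex[order[0]], fvals[order[0]], converged
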