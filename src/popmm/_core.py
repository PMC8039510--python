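"""Compiled numerical kernels for minimal-model simulation and the MCEM E-step.

Everything here operates on plain float64 arrays so that the hot loops of the
EM engine (hundreds of thousands of forward simulations per fit) run at
native speed.  The public modules wrap these kernels with typed containers
and validation.

Model (Bergman-type glucose minimal model under measured insulin forcing):

    dG/dt = -(GEZI + X(t)) * G(t) + (GEZI + Xb) * Gb,   G(0) = Gb + Dose/V
    dX/dt = -p2 * X(t) + p2 * SI * I(t),                X(0) = SI * Ib

with I(t) the piecewise-linear interpolant of the measured insulin
concentrations (constant extrapolation outside the measured range) and
Xb = SI * Ib the basal remote insulin action.

Because I(t) is piecewise linear, X(t) has a closed form on every forcing
segment; the simulator advances X exactly and integrates the scalar G
equation with classic RK4 sub-steps bounded both by a maximum step and by
the local disappearance rate (step halving on any non-finite/non-positive
intermediate keeps the scheme robust for the extreme parameter draws an
importance sampler can produce).
"""

import math

import numpy as np
from numba import njit

_LOG2PI = math.log(2.0 * math.pi)
_FAIL = -1.0e300


@njit(cache=True)
def interp_linear(ft, fc, t):
    """Piecewise-linear interpolation with constant extrapolation."""
    n = ft.shape[0]
    if t <= ft[0]:
        return fc[0]
    if t >= ft[n - 1]:
        return fc[n - 1]
    j = np.searchsorted(ft, t)
    # ft[j-1] < t <= ft[j]
    w = (t - ft[j - 1]) / (ft[j] - ft[j - 1])
    return fc[j - 1] + w * (fc[j] - fc[j - 1])


@njit(cache=True)
def simulate_mm_gx(gezi, si, p2, v, dose, gb, ib, ft, fc, teval, dt_max):
    """Simulate (G(t), X(t)) at the (sorted, non-negative) times ``teval``.

    X(t) is advanced analytically on each linear forcing segment; G(t) by
    RK4 with sub-steps no larger than ``dt_max`` and no larger than
    0.5 / (GEZI + X).  Returns NaNs if the integration fails outright.
    """
    neval = teval.shape[0]
    out = np.empty(neval)
    outx = np.empty(neval)
    xb = si * ib
    c = (gezi + xb) * gb
    G = gb + dose / v
    X = xb
    t = 0.0
    k = 0
    while k < neval and teval[k] <= 0.0:
        out[k] = G
        outx[k] = X
        k += 1
    if k == neval:
        return out, outx
    tend = teval[neval - 1]
    nf = ft.shape[0]
    j = 0
    eps = 1e-12
    nsteps = 0
    # disappearance rates above ~50/min mean glucose vanishes within
    # seconds -- far outside the physiologic regime; fail fast instead of
    # grinding through microscopic steps
    rate_cap = 50.0
    max_steps = 5000000
    while t < tend - eps:
        # Insulin on the current segment: I(t0 + tau) = a + b*tau.
        if t < ft[0] - eps:
            seg_end = min(ft[0], tend)
            a = fc[0]
            b = 0.0
        elif t >= ft[nf - 1] - eps:
            seg_end = tend
            a = fc[nf - 1]
            b = 0.0
        else:
            while j < nf - 1 and ft[j + 1] <= t + eps:
                j += 1
            slope = (fc[j + 1] - fc[j]) / (ft[j + 1] - ft[j])
            a = fc[j] + slope * (t - ft[j])
            b = slope
            seg_end = min(ft[j + 1], tend)
        # Closed form for X within the segment, tau measured from t0 = t:
        #   X(tau) = SI*(a + b*tau) - SI*b/p2 + d0*exp(-p2*tau)
        xp0 = si * a - si * b / p2
        d0 = X - xp0
        t0 = t
        while t < seg_end - eps:
            t_next = seg_end
            if k < neval and teval[k] < seg_end - eps:
                t_next = teval[k]
            if t_next <= t + eps:
                # coincident time point
                tau = t - t0
                out[k] = G
                outx[k] = si * (a + b * tau) - si * b / p2 + d0 * math.exp(-p2 * tau)
                k += 1
                continue
            # integrate G from t to t_next
            while t < t_next - eps:
                tau = t - t0
                x1 = si * (a + b * tau) - si * b / p2 + d0 * math.exp(-p2 * tau)
                rate = gezi + x1
                nsteps += 1
                if rate > rate_cap or not np.isfinite(rate) or nsteps > max_steps:
                    for kk in range(k, neval):
                        out[kk] = np.nan
                        outx[kk] = np.nan
                    return out, outx
                h = dt_max
                if rate > 0.0 and 0.5 / rate < h:
                    h = 0.5 / rate
                if t + h > t_next:
                    h = t_next - t
                # RK4 with step halving on failure
                ok = False
                for _ in range(60):
                    tau2 = t - t0 + 0.5 * h
                    tau3 = t - t0 + h
                    x2 = si * (a + b * tau2) - si * b / p2 + d0 * math.exp(-p2 * tau2)
                    x3 = si * (a + b * tau3) - si * b / p2 + d0 * math.exp(-p2 * tau3)
                    k1 = -(gezi + x1) * G + c
                    k2 = -(gezi + x2) * (G + 0.5 * h * k1) + c
                    k3 = -(gezi + x2) * (G + 0.5 * h * k2) + c
                    k4 = -(gezi + x3) * (G + h * k3) + c
                    Gn = G + h / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
                    if np.isfinite(Gn) and Gn > 0.0:
                        ok = True
                        break
                    h *= 0.5
                    if h < 1e-14:
                        break
                if not ok:
                    for kk in range(k, neval):
                        out[kk] = np.nan
                        outx[kk] = np.nan
                    return out, outx
                G = Gn
                t = t + h
            t = t_next
            if k < neval and teval[k] <= t + eps:
                tau = t - t0
                out[k] = G
                outx[k] = si * (a + b * tau) - si * b / p2 + d0 * math.exp(-p2 * tau)
                k += 1
        # exact X at segment end
        tau = seg_end - t0
        X = si * (a + b * tau) - si * b / p2 + d0 * math.exp(-p2 * tau)
        t = seg_end
    while k < neval:
        out[k] = G
        outx[k] = X
        k += 1
    return out, outx


@njit(cache=True)
def simulate_mm(gezi, si, p2, v, dose, gb, ib, ft, fc, teval, dt_max):
    """G(t) only; see :func:`simulate_mm_gx`."""
    out, _ = simulate_mm_gx(gezi, si, p2, v, dose, gb, ib, ft, fc, teval, dt_max)
    return out


@njit(cache=True)
def simulate_mm_fixed_step(gezi, si, p2, v, dose, gb, ib, ft, fc, teval, dt):
    """Brute-force fixed-step RK4 on the coupled (G, X) system.

    Independent of :func:`simulate_mm` (numeric X, interpolated insulin at
    every stage); used as a test oracle at very small ``dt``.
    """
    neval = teval.shape[0]
    out = np.empty(neval)
    xb = si * ib
    c = (gezi + xb) * gb
    G = gb + dose / v
    X = xb
    t = 0.0
    k = 0
    while k < neval and teval[k] <= 0.0:
        out[k] = G
        k += 1
    while k < neval:
        target = teval[k]
        while t < target - 1e-12:
            h = dt
            if t + h > target:
                h = target - t
            i1 = interp_linear(ft, fc, t)
            i2 = interp_linear(ft, fc, t + 0.5 * h)
            i3 = interp_linear(ft, fc, t + h)
            # stage 1
            dG1 = -(gezi + X) * G + c
            dX1 = -p2 * X + p2 * si * i1
            # stage 2
            G2 = G + 0.5 * h * dG1
            X2 = X + 0.5 * h * dX1
            dG2 = -(gezi + X2) * G2 + c
            dX2 = -p2 * X2 + p2 * si * i2
            # stage 3
            G3 = G + 0.5 * h * dG2
            X3 = X + 0.5 * h * dX2
            dG3 = -(gezi + X3) * G3 + c
            dX3 = -p2 * X3 + p2 * si * i2
            # stage 4
            G4 = G + h * dG3
            X4 = X + h * dX3
            dG4 = -(gezi + X4) * G4 + c
            dX4 = -p2 * X4 + p2 * si * i3
            G = G + h / 6.0 * (dG1 + 2.0 * dG2 + 2.0 * dG3 + dG4)
            X = X + h / 6.0 * (dX1 + 2.0 * dX2 + 2.0 * dX3 + dX4)
            t = t + h
        out[k] = G
        k += 1
    return out


@njit(cache=True)
def loglik_prop(gezi, si, p2, v, dose, gb, ib, ft, fc, tobs, yobs, sigma, dt_max):
    """Log-likelihood under SD-proportional Gaussian residuals.

    Residual model: y_j ~ N(yhat_j, (sigma*yhat_j)^2).  Returns
    (loglik, sum((y - yhat)/yhat)^2); a failed simulation yields
    (-1e300, inf).
    """
    yhat = simulate_mm(gezi, si, p2, v, dose, gb, ib, ft, fc, tobs, dt_max)
    n = tobs.shape[0]
    ll = 0.0
    ssr = 0.0
    for i in range(n):
        yh = yhat[i]
        if not np.isfinite(yh) or yh <= 0.0:
            return _FAIL, np.inf
        r = (yobs[i] - yh) / yh
        ssr += r * r
        ll += -0.5 * _LOG2PI - math.log(sigma * yh) - 0.5 * (r / sigma) * (r / sigma)
    return ll, ssr


@njit(cache=True)
def _neg_log_post(eta, pm, pprec, dose, gb, ib, ft, fc, tobs, yobs, sigma, dt_max):
    th0 = math.exp(eta[0])
    th1 = math.exp(eta[1])
    th2 = math.exp(eta[2])
    th3 = math.exp(eta[3])
    ll, _ = loglik_prop(th0, th1, th2, th3, dose, gb, ib, ft, fc, tobs, yobs, sigma, dt_max)
    if ll <= _FAIL:
        return 1.0e300
    d = eta - pm
    q = 0.0
    for i in range(4):
        for jj in range(4):
            q += d[i] * pprec[i, jj] * d[jj]
    return -ll + 0.5 * q


@njit(cache=True)
def _nelder_mead(x0, step, pm, pprec, dose, gb, ib, ft, fc, tobs, yobs, sigma,
                 dt_max, maxiter, ftol):
    """Nelder-Mead minimisation of the negative log posterior in 4-D."""
    n = 4
    sim = np.empty((n + 1, n))
    fval = np.empty(n + 1)
    for i in range(n + 1):
        sim[i, :] = x0
        if i > 0:
            sim[i, i - 1] += step
        fval[i] = _neg_log_post(sim[i], pm, pprec, dose, gb, ib, ft, fc,
                                tobs, yobs, sigma, dt_max)
    it = 0
    while it < maxiter:
        order = np.argsort(fval)
        sim = sim[order]
        fval = fval[order]
        if fval[n] - fval[0] < ftol * (abs(fval[0]) + ftol):
            break
        cen = np.zeros(n)
        for i in range(n):
            cen += sim[i]
        cen /= n
        xr = cen + (cen - sim[n])
        fr = _neg_log_post(xr, pm, pprec, dose, gb, ib, ft, fc, tobs, yobs, sigma, dt_max)
        if fr < fval[0]:
            xe = cen + 2.0 * (cen - sim[n])
            fe = _neg_log_post(xe, pm, pprec, dose, gb, ib, ft, fc, tobs, yobs, sigma, dt_max)
            if fe < fr:
                sim[n] = xe
                fval[n] = fe
            else:
                sim[n] = xr
                fval[n] = fr
        elif fr < fval[n - 1]:
            sim[n] = xr
            fval[n] = fr
        else:
            if fr < fval[n]:
                xc = cen + 0.5 * (xr - cen)
            else:
                xc = cen + 0.5 * (sim[n] - cen)
            fc_ = _neg_log_post(xc, pm, pprec, dose, gb, ib, ft, fc, tobs, yobs, sigma, dt_max)
            if fc_ < min(fr, fval[n]):
                sim[n] = xc
                fval[n] = fc_
            else:  # shrink
                for i in range(1, n + 1):
                    sim[i] = sim[0] + 0.5 * (sim[i] - sim[0])
                    fval[i] = _neg_log_post(sim[i], pm, pprec, dose, gb, ib, ft, fc,
                                            tobs, yobs, sigma, dt_max)
        it += 1
    order = np.argsort(fval)
    return sim[order[0]], fval[order[0]]


@njit(cache=True)
def _fd_hessian(x, pm, pprec, dose, gb, ib, ft, fc, tobs, yobs, sigma, dt_max, h):
    n = 4
    H = np.empty((n, n))
    f0 = _neg_log_post(x, pm, pprec, dose, gb, ib, ft, fc, tobs, yobs, sigma, dt_max)
    fp = np.empty(n)
    fm = np.empty(n)
    xt = x.copy()
    for i in range(n):
        xt[i] = x[i] + h
        fp[i] = _neg_log_post(xt, pm, pprec, dose, gb, ib, ft, fc, tobs, yobs, sigma, dt_max)
        xt[i] = x[i] - h
        fm[i] = _neg_log_post(xt, pm, pprec, dose, gb, ib, ft, fc, tobs, yobs, sigma, dt_max)
        xt[i] = x[i]
        H[i, i] = (fp[i] - 2.0 * f0 + fm[i]) / (h * h)
    for i in range(n):
        for jj in range(i + 1, n):
            xt[i] = x[i] + h
            xt[jj] = x[jj] + h
            fpp = _neg_log_post(xt, pm, pprec, dose, gb, ib, ft, fc, tobs, yobs, sigma, dt_max)
            xt[jj] = x[jj] - h
            fpm = _neg_log_post(xt, pm, pprec, dose, gb, ib, ft, fc, tobs, yobs, sigma, dt_max)
            xt[i] = x[i] - h
            xt[jj] = x[jj] + h
            fmp = _neg_log_post(xt, pm, pprec, dose, gb, ib, ft, fc, tobs, yobs, sigma, dt_max)
            xt[jj] = x[jj] - h
            fmm = _neg_log_post(xt, pm, pprec, dose, gb, ib, ft, fc, tobs, yobs, sigma, dt_max)
            xt[i] = x[i]
            xt[jj] = x[jj]
            H[i, jj] = (fpp - fpm - fmp + fmm) / (4.0 * h * h)
            H[jj, i] = H[i, jj]
    return H


@njit(cache=True)
def estep_subject(eta_init, pm, pprec, logdet_prec, sigma,
                  dose, gb, ib, ft, fc, tobs, yobs, dt_max,
                  z, chi2draws, df, nm_maxiter, nm_step, inflate):
    """Importance-sampling E-step for one subject.

    Finds the conditional mode of the log-parameters, builds a multivariate-t
    proposal from the Laplace curvature, and returns importance-weighted
    posterior summaries.

    Returns (mode, post_mean, post_cov, ess, logmarg, e_ssr, mc_var_logmarg,
    fail_flag, samples, normalized_weights, sample_logliks,
    sample_logproposal, sample_ssr).
    """
    mode, _ = _nelder_mead(eta_init, nm_step, pm, pprec, dose, gb, ib, ft, fc,
                           tobs, yobs, sigma, dt_max, nm_maxiter, 1e-9)
    H = _fd_hessian(mode, pm, pprec, dose, gb, ib, ft, fc, tobs, yobs, sigma,
                    dt_max, 1e-3)
    # very peaked posteriors (tiny residual error) need a curvature-scaled
    # refinement: redo the mode search and Hessian at the posterior width
    hmax = 0.0
    for i in range(4):
        if np.isfinite(H[i, i]) and H[i, i] > hmax:
            hmax = H[i, i]
    if hmax > 1e7:
        width = 1.0 / math.sqrt(hmax)
        step2 = max(10.0 * width, 1e-6)
        mode, _ = _nelder_mead(mode, step2, pm, pprec, dose, gb, ib, ft, fc,
                               tobs, yobs, sigma, dt_max, nm_maxiter, 1e-12)
        H = _fd_hessian(mode, pm, pprec, dose, gb, ib, ft, fc, tobs, yobs,
                        sigma, dt_max, max(width, 1e-7))
    # fall back to the prior curvature if differencing hit a failing region
    bad = False
    for i in range(4):
        for jj in range(4):
            if not np.isfinite(H[i, jj]) or abs(H[i, jj]) > 1e14:
                bad = True
    if bad:
        H = pprec.copy()
    # make SPD
    w_eig, V = np.linalg.eigh(0.5 * (H + H.T))
    floor = max(1e-8 * np.max(np.abs(w_eig)), 1e-3)
    for i in range(4):
        if w_eig[i] < floor:
            w_eig[i] = floor
    # proposal covariance = inflate * H^-1
    C = np.zeros((4, 4))
    for i in range(4):
        for jj in range(4):
            s = 0.0
            for kk in range(4):
                s += V[i, kk] * V[jj, kk] / w_eig[kk]
            C[i, jj] = inflate * s
    L = np.linalg.cholesky(C)
    logdet_c = 0.0
    for i in range(4):
        logdet_c += 2.0 * math.log(L[i, i])

    m = z.shape[0]
    logw = np.empty(m)
    xs = np.empty((m, 4))
    ssrs = np.empty(m)
    lls = np.empty(m)
    logqs = np.empty(m)
    lg_const = (math.lgamma((df + 4.0) / 2.0) - math.lgamma(df / 2.0)
                - 2.0 * math.log(df * math.pi) - 0.5 * logdet_c)
    lp_const = 0.5 * logdet_prec - 2.0 * _LOG2PI
    for s_i in range(m):
        scale = math.sqrt(df / chi2draws[s_i])
        z2 = 0.0
        for i in range(4):
            z2 += z[s_i, i] * z[s_i, i]
        x = mode.copy()
        for i in range(4):
            acc = 0.0
            for jj in range(i + 1):
                acc += L[i, jj] * z[s_i, jj]
            x[i] = mode[i] + acc * scale
        xs[s_i] = x
        d2 = z2 * df / chi2draws[s_i]
        logq = lg_const - (df + 4.0) / 2.0 * math.log(1.0 + d2 / df)
        ll, ssr = loglik_prop(math.exp(x[0]), math.exp(x[1]), math.exp(x[2]),
                              math.exp(x[3]), dose, gb, ib, ft, fc, tobs, yobs,
                              sigma, dt_max)
        logqs[s_i] = logq
        if ll <= _FAIL:
            ssrs[s_i] = 0.0  # zero weight; keep 0*inf out of the moments
            lls[s_i] = -np.inf
            logw[s_i] = -np.inf
            continue
        lls[s_i] = ll
        ssrs[s_i] = ssr
        d = x - pm
        q = 0.0
        for i in range(4):
            for jj in range(4):
                q += d[i] * pprec[i, jj] * d[jj]
        lp = lp_const - 0.5 * q
        logw[s_i] = ll + lp - logq

    a = -np.inf
    for s_i in range(m):
        if logw[s_i] > a:
            a = logw[s_i]
    mean = np.zeros(4)
    cov = np.zeros((4, 4))
    if not np.isfinite(a):
        return (mode, mean, cov, 0.0, -np.inf, np.nan, np.nan, 1,
                xs, np.zeros(m), lls, logqs, ssrs)
    sw = 0.0
    sw2 = 0.0
    for s_i in range(m):
        w = math.exp(logw[s_i] - a)
        logw[s_i] = w  # reuse storage for raw weights
        sw += w
        sw2 += w * w
    e_ssr = 0.0
    for s_i in range(m):
        wn = logw[s_i] / sw
        e_ssr += wn * ssrs[s_i]
        for i in range(4):
            mean[i] += wn * xs[s_i, i]
    for s_i in range(m):
        wn = logw[s_i] / sw
        for i in range(4):
            for jj in range(4):
                cov[i, jj] += wn * (xs[s_i, i] - mean[i]) * (xs[s_i, jj] - mean[jj])
    ess = sw * sw / sw2
    logmarg = a + math.log(sw / m)
    # delta-method MC variance of logmarg
    wbar = sw / m
    varw = sw2 / m - wbar * wbar
    mc_var = varw / (m * wbar * wbar)
    wn_out = logw / sw
    return (mode, mean, cov, ess, logmarg, e_ssr, mc_var, 0,
            xs, wn_out, lls, logqs, ssrs)
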