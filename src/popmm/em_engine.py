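"""Maximum-likelihood mixed-effects estimation by Monte-Carlo EM.

Estimation problem: observations y_ij of subject i follow

    y_ij ~ N(yhat_ij(theta_i), (sigma * yhat_ij)^2),        (stage 1)
    log theta_i ~ N(D_i gamma, Sigma),                      (stage 2)

with yhat the minimal-model prediction, D_i the subject's covariate design
matrix (identity columns for the four log typical values plus one column per
covariate effect) and gamma the stacked fixed effects on the log scale.

E-step (per subject): the conditional mode of log theta_i is located by
Nelder-Mead, the Laplace curvature at the mode defines a multivariate-t
importance-sampling proposal, and importance weights give conditional means,
covariances and the marginal likelihood.  Samples are refreshed every
iteration from per-(seed, iteration, subject) random streams, so a fit is a
deterministic function of its settings.

M-step (closed form): generalized least squares for gamma, pooled conditional
second moments for Sigma, and a residual update for sigma.

Standard errors come from the observed Fisher information estimated as the
outer product of per-subject observed-data scores (each score is the
conditional expectation of the complete-data score, so the E-step quantities
suffice); a subject-resampling bootstrap of the scores is available as a
fallback when the information matrix is ill-conditioned.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from . import _core
from .minimal_model import (
    PARAM_NAMES,
    SubjectData,
    filter_early_samples,
)
from .population_model import (
    CovariateSpec,
    PopulationParams,
    individual_mean_log,
)

_PARAM_INDEX = {name: i for i, name in enumerate(PARAM_NAMES)}

#: seed-stream tag for likelihood evaluations (kept distinct from E-step
#: iteration indices so that -2LL evaluations are comparable across models)
_LL_STREAM = 1000003


class NonConvergenceWarning(UserWarning):
    pass


@dataclass(frozen=True)
class FitSettings:
    """Tuning knobs of the Monte-Carlo EM fit.

    ``dt_max`` bounds the RK4 sub-step of the inner ODE solver (min);
    ``proposal_df`` and ``proposal_inflation`` shape the heavy-tailed
    importance proposal.  Because the E-step is Monte Carlo, convergence is
    judged on smoothed traces: the run stops when the mean of every estimate
    over the last ``convergence_window`` iterations differs by less than
    ``convergence_rtol`` (relative) from the mean over the preceding window,
    and the reported estimates are the tail-window averages.
    """

    n_importance_samples: int = 300
    max_iterations: int = 60
    #: EM contracts slowly along weakly identified covariance directions
    #: (the GEZI-p2 block); a generous minimum stops the smoothed
    #: convergence test from firing during an early plateau
    min_iterations: int = 30
    convergence_rtol: float = 6e-3
    seed: int = 0
    dt_max: float = 0.5
    proposal_df: float = 4.0
    proposal_inflation: float = 1.4
    mode_maxiter: int = 120
    #: mode-search budget for marginal-likelihood evaluations, which start
    #: cold from the prior mean (E-steps warm-start from the previous mode)
    ll_mode_maxiter: int = 250
    mode_step: float = 0.15
    convergence_window: int = 5
    n_ll_samples: int = 1000
    ess_warn_fraction: float = 0.02
    #: over-relaxation factor for the Sigma update (1 = plain EM); EM is
    #: slow along weakly identified covariance directions and a modest
    #: extrapolation roughly doubles the convergence speed
    sigma_step_expansion: float = 1.0

    def __post_init__(self):
        if self.n_importance_samples <= 0 or self.max_iterations <= 0:
            raise ValueError("sample and iteration counts must be positive")
        if not 0 < self.convergence_rtol < 1:
            raise ValueError("convergence_rtol must be in (0, 1)")
        if self.dt_max <= 0:
            raise ValueError("dt_max must be positive")


@dataclass
class ConditionalPosterior:
    """Importance-sampling summary of one subject's conditional posterior."""

    mode: np.ndarray          # argmax of loglik + log prior (log scale)
    mean: np.ndarray          # conditional mean of log theta
    cov: np.ndarray           # conditional covariance
    samples: np.ndarray       # (m, 4) proposal draws (log scale)
    weights: np.ndarray       # normalized importance weights
    ess: float                # effective sample size
    log_marginal: float       # IS estimate of log p(y_i)


@dataclass
class FitResult:
    pop: PopulationParams
    minus2LL: float
    minus2LL_mc_se: float
    rse_cv_percent: dict
    subject_ids: list
    conditional_mean_log: np.ndarray   # (n, 4)
    conditional_cov_log: np.ndarray    # (n, 4, 4)
    trace: list                        # per-iteration dicts
    converged: bool
    gamma: np.ndarray = field(default=None)
    ess: np.ndarray = field(default=None)
    n_obs: int = 0
    settings: FitSettings = field(default=None)


# ---------------------------------------------------------------------------
# data preparation
# ---------------------------------------------------------------------------

def _prepare_subject(subject: SubjectData) -> SubjectData:
    return filter_early_samples(subject)


def _design_matrix(subject: SubjectData, effects) -> np.ndarray:
    """4 x (4+K) design: identity block plus one column per effect."""
    K = len(effects)
    D = np.zeros((4, 4 + K))
    D[:, :4] = np.eye(4)
    for k, eff in enumerate(effects):
        D[_PARAM_INDEX[eff.parameter], 4 + k] = eff.design_value(subject.covariates)
    return D


def _gamma_init(init: PopulationParams, effects) -> np.ndarray:
    g = np.empty(4 + len(effects))
    g[:4] = init.mu_logtheta
    for k, eff in enumerate(effects):
        g[4 + k] = eff.log_scale_coefficient()
    return g


def _pop_from_gamma(gamma, Sigma, sigma, effects) -> PopulationParams:
    """Rebuild PopulationParams (natural-scale effect coefficients)."""
    fitted = []
    for k, eff in enumerate(effects):
        psi = gamma[4 + k]
        coeff = float(np.expm1(psi)) if eff.kind == "proportional_shift" else float(psi)
        fitted.append(type(eff)(eff.parameter, eff.covariate, eff.kind,
                                eff.reference, coeff))
    return PopulationParams(gamma[:4].copy(), Sigma.copy(),
                            effects=tuple(fitted), sigma_prop=float(sigma))


def _subject_rng(seed: int, stream: int, index: int) -> np.random.Generator:
    return np.random.default_rng([int(seed), int(stream), int(index)])


def _run_estep(subj: SubjectData, eta_init, pm, prec, logdet_prec, sigma,
               settings: FitSettings, rng, n_samples=None, mode_maxiter=None):
    m = n_samples or settings.n_importance_samples
    z = rng.standard_normal((m, 4))
    u = rng.chisquare(settings.proposal_df, m)
    return _core.estep_subject(
        np.asarray(eta_init, dtype=float), pm, prec, logdet_prec, float(sigma),
        subj.dose, subj.Gbasal, subj.Ibasal,
        subj.forcing.times, subj.forcing.concentrations,
        subj.obs_times, subj.obs_glucose, settings.dt_max,
        z, u, settings.proposal_df, mode_maxiter or settings.mode_maxiter,
        settings.mode_step, settings.proposal_inflation)


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def individual_loglik(subject: SubjectData, logtheta, sigma_prop: float,
                      dt_max: float = 0.5) -> float:
    """Gaussian log-likelihood of one subject's glucose data at log theta."""
    th = np.exp(np.asarray(logtheta, dtype=float))
    ll, _ = _core.loglik_prop(
        th[0], th[1], th[2], th[3], subject.dose, subject.Gbasal,
        subject.Ibasal, subject.forcing.times, subject.forcing.concentrations,
        subject.obs_times, subject.obs_glucose, float(sigma_prop), dt_max)
    return float(ll)


def conditional_posterior(subject: SubjectData, pop: PopulationParams,
                          settings: FitSettings) -> ConditionalPosterior:
    """Mode, importance samples and weights of p(log theta_i | y_i, pop)."""
    subj = _prepare_subject(subject)
    pm = individual_mean_log(pop, subj.covariates)
    prec = np.linalg.inv(pop.Sigma_logtheta)
    logdet_prec = float(np.linalg.slogdet(prec)[1])
    # cold start: restarted Nelder-Mead polishes the mode before the E-step
    # (narrow, curved posteriors need fresh simplexes to escape stalls)
    eta = pm.copy()
    best = np.inf
    for _ in range(5):
        eta, f = _core._nelder_mead(
            eta, settings.mode_step, pm, prec, subj.dose, subj.Gbasal,
            subj.Ibasal, subj.forcing.times, subj.forcing.concentrations,
            subj.obs_times, subj.obs_glucose, pop.sigma_prop,
            settings.dt_max, 400, 1e-12)
        if best - f < 1e-8:
            break
        best = f
    rng = _subject_rng(settings.seed, 0, 0)
    (mode, mean, cov, ess, logmarg, _e_ssr, _mc, fail, xs, wn, *_rest) = _run_estep(
        subj, eta, pm, prec, logdet_prec, pop.sigma_prop, settings, rng,
        mode_maxiter=settings.ll_mode_maxiter)
    if fail:
        raise RuntimeError(
            f"conditional posterior failed for subject {subject.subject_id}: "
            "no importance sample produced a finite likelihood")
    return ConditionalPosterior(mode=mode, mean=mean, cov=cov, samples=xs,
                                weights=wn, ess=float(ess),
                                log_marginal=float(logmarg))


def quick_individual_modes(subjects: Sequence[SubjectData],
                           settings: FitSettings,
                           prior_center=None,
                           prior_var: float = 4.0):
    """Per-subject posterior modes under a weak log-normal prior.

    Used to initialize the population parameters when no explicit initial
    estimate is supplied.  Returns (modes (n,4), mean ssr/n_obs).
    """
    if prior_center is None:
        from .population_model import BASE_TV
        prior_center = np.log([BASE_TV[p] for p in PARAM_NAMES])
    pm = np.asarray(prior_center, dtype=float)
    prec = np.eye(4) / prior_var
    modes = np.empty((len(subjects), 4))
    cvs = []
    for i, subj in enumerate(subjects):
        mode, _f = _core._nelder_mead(
            pm.copy(), 0.5, pm, prec, subj.dose, subj.Gbasal, subj.Ibasal,
            subj.forcing.times, subj.forcing.concentrations,
            subj.obs_times, subj.obs_glucose, 0.1, settings.dt_max,
            300, 1e-10)
        modes[i] = mode
        th = np.exp(mode)
        _ll, ssr = _core.loglik_prop(
            th[0], th[1], th[2], th[3], subj.dose, subj.Gbasal, subj.Ibasal,
            subj.forcing.times, subj.forcing.concentrations,
            subj.obs_times, subj.obs_glucose, 0.1, settings.dt_max)
        cvs.append(ssr / subj.obs_times.size)
    return modes, float(np.sqrt(np.mean(cvs)))


def _initial_population(subjects, spec: CovariateSpec,
                        settings: FitSettings) -> PopulationParams:
    modes, sigma0 = quick_individual_modes(subjects, settings)
    mu0 = modes.mean(axis=0)
    S0 = np.cov(modes.T) + 1e-3 * np.eye(4)
    # temper extreme quick-fit dispersion (individual modes over-disperse)
    S0 = 0.8 * S0 + 0.2 * np.diag(np.diag(S0))
    sigma0 = min(max(sigma0, 0.02), 0.3)
    return PopulationParams(mu0, S0, effects=spec.effects, sigma_prop=sigma0)


def em_fit(dataset: Sequence[SubjectData], spec: CovariateSpec | None = None,
           init: PopulationParams | None = None,
           settings: FitSettings | None = None) -> FitResult:
    """Fit the hierarchical minimal model by Monte-Carlo EM.

    ``spec`` declares the covariate effects of the stage-2 mean model (empty
    for the base model); ``init`` optionally supplies starting population
    values (otherwise quick per-subject fits initialize them).
    """
    settings = settings or FitSettings()
    spec = spec or CovariateSpec()
    if len(dataset) < 10:
        raise ValueError("em_fit requires at least 10 subjects")
    subjects = [_prepare_subject(s) for s in dataset]
    n = len(subjects)
    effects = tuple(spec.effects)
    if init is None:
        init = _initial_population(subjects, spec, settings)
    D = [_design_matrix(s, effects) for s in subjects]
    gamma = _gamma_init(init, effects)
    Sigma = init.Sigma_logtheta.copy()
    sigma = float(init.sigma_prop)
    n_obs = int(sum(s.obs_times.size for s in subjects))

    warm = np.array([Di @ gamma for Di in D])
    trace = []
    converged = False
    history = []  # (gamma, Sigma, sigma) per iteration, for smoothing
    mean_i = np.empty((n, 4))
    cov_i = np.empty((n, 4, 4))
    ess_i = np.empty(n)
    W = settings.convergence_window

    for it in range(settings.max_iterations):
        prec = np.linalg.inv(Sigma)
        logdet_prec = float(np.linalg.slogdet(prec)[1])
        logmarg_tot = 0.0
        e_ssr_tot = 0.0
        for i, subj in enumerate(subjects):
            pm = D[i] @ gamma
            rng = _subject_rng(settings.seed, it + 1, i)
            (mode, mean, cov, ess, logmarg, e_ssr, _mc, fail, *_rest) = _run_estep(
                subj, warm[i], pm, prec, logdet_prec, sigma, settings, rng)
            if fail:
                warnings.warn(
                    f"E-step failed for subject {subj.subject_id} at "
                    f"iteration {it}; using prior moments", NonConvergenceWarning)
                mean, cov = pm, Sigma.copy()
                e_ssr = sigma ** 2 * subj.obs_times.size
                logmarg = 0.0
            else:
                warm[i] = mode
            mean_i[i] = mean
            cov_i[i] = cov
            ess_i[i] = ess
            logmarg_tot += logmarg
            e_ssr_tot += e_ssr
        # ---- M-step ----
        A = np.zeros((gamma.size, gamma.size))
        b = np.zeros(gamma.size)
        for i in range(n):
            DtP = D[i].T @ prec
            A += DtP @ D[i]
            b += DtP @ mean_i[i]
        gamma = np.linalg.solve(A, b)
        S = np.zeros((4, 4))
        for i in range(n):
            r = mean_i[i] - D[i] @ gamma
            S += cov_i[i] + np.outer(r, r)
        Sigma_em = S / n
        # over-relaxation: EM contracts slowly along weakly identified
        # covariance directions, so extrapolate the Sigma step
        alpha = settings.sigma_step_expansion
        Sigma = Sigma + alpha * (Sigma_em - Sigma)
        Sigma = 0.5 * (Sigma + Sigma.T)
        w_eig, V = np.linalg.eigh(Sigma)
        w_eig = np.maximum(w_eig, 1e-6)
        Sigma = (V * w_eig) @ V.T
        sigma = float(np.sqrt(e_ssr_tot / n_obs))
        # ---- bookkeeping ----
        minus2ll = -2.0 * logmarg_tot
        history.append((gamma.copy(), Sigma.copy(), sigma))
        trace.append({"iteration": it, "minus2LL": float(minus2ll),
                      "gamma": gamma.copy(),
                      "iiv_sd": np.sqrt(np.diag(Sigma)).copy(),
                      "sigma": sigma})
        if it + 1 >= max(2 * W, settings.min_iterations):
            cur = np.mean([np.concatenate([g, np.sqrt(np.diag(S)), [s]])
                           for g, S, s in history[-W:]], axis=0)
            prev = np.mean([np.concatenate([g, np.sqrt(np.diag(S)), [s]])
                            for g, S, s in history[-2 * W:-W]], axis=0)
            rel = np.max(np.abs(cur - prev) / np.maximum(np.abs(prev), 1e-3))
            if rel < settings.convergence_rtol:
                converged = True
                break
    if not converged:
        warnings.warn("EM did not reach the convergence criterion within "
                      f"{settings.max_iterations} iterations",
                      NonConvergenceWarning)

    # tail-window averages damp the Monte-Carlo noise of single iterations
    tail = history[-W:]
    gamma = np.mean([g for g, _, _ in tail], axis=0)
    Sigma = np.mean([S for _, S, _ in tail], axis=0)
    Sigma = 0.5 * (Sigma + Sigma.T)
    sigma = float(np.mean([s for _, _, s in tail]))
    pop = _pop_from_gamma(gamma, Sigma, sigma, effects)
    # final conditional pass at the converged estimates (also used for -2LL)
    prec = np.linalg.inv(Sigma)
    logdet_prec = float(np.linalg.slogdet(prec)[1])
    logmarg_tot = 0.0
    mc_var_tot = 0.0
    for i, subj in enumerate(subjects):
        pm = D[i] @ gamma
        rng = _subject_rng(settings.seed, _LL_STREAM, i)
        (mode, mean, cov, ess, logmarg, e_ssr, mc_var, fail, *_rest) = _run_estep(
            subj, warm[i], pm, prec, logdet_prec, sigma, settings, rng,
            n_samples=settings.n_ll_samples,
            mode_maxiter=settings.ll_mode_maxiter)
        if fail:
            mean, cov, ess = pm, Sigma.copy(), 0.0
            logmarg, mc_var = 0.0, 0.0
        mean_i[i] = mean
        cov_i[i] = cov
        ess_i[i] = ess
        logmarg_tot += logmarg
        mc_var_tot += mc_var

    fit = FitResult(
        pop=pop, minus2LL=float(-2.0 * logmarg_tot),
        minus2LL_mc_se=float(2.0 * np.sqrt(max(mc_var_tot, 0.0))),
        rse_cv_percent={}, subject_ids=[s.subject_id for s in subjects],
        conditional_mean_log=mean_i.copy(), conditional_cov_log=cov_i.copy(),
        trace=trace, converged=converged, gamma=gamma.copy(), ess=ess_i.copy(),
        n_obs=n_obs, settings=settings)
    try:
        fit.rse_cv_percent = standard_errors(fit, subjects, settings)
    except Exception as exc:  # SE failure should not void the fit
        warnings.warn(f"standard-error computation failed: {exc}",
                      NonConvergenceWarning)
    return fit


def total_minus2LL(dataset: Sequence[SubjectData], pop: PopulationParams,
                   settings: FitSettings):
    """Importance-sampling estimate of -2 log marginal likelihood.

    Per-subject random streams depend only on (seed, subject index), so two
    nested models evaluated with the same settings share common random
    numbers and their -2LL difference has much smaller Monte-Carlo error
    than either total.  Returns (minus2LL, mc_se).
    """
    subjects = [_prepare_subject(s) for s in dataset]
    effects = tuple(pop.effects)
    prec = np.linalg.inv(pop.Sigma_logtheta)
    logdet_prec = float(np.linalg.slogdet(prec)[1])
    total = 0.0
    mc_var = 0.0
    for i, subj in enumerate(subjects):
        pm = individual_mean_log(pop, subj.covariates)
        rng = _subject_rng(settings.seed, _LL_STREAM, i)
        (mode, mean, cov, ess, logmarg, e_ssr, mv, fail, *_rest) = _run_estep(
            subj, pm, pm, prec, logdet_prec, pop.sigma_prop, settings, rng,
            n_samples=settings.n_ll_samples,
            mode_maxiter=settings.ll_mode_maxiter)
        if fail:
            raise RuntimeError(f"marginal likelihood failed for subject "
                               f"{subj.subject_id}")
        if ess < settings.ess_warn_fraction * settings.n_ll_samples:
            warnings.warn(f"degenerate importance weights for subject "
                          f"{subj.subject_id} (ESS={ess:.1f})")
        total += logmarg
        mc_var += mv
    return float(-2.0 * total), float(2.0 * np.sqrt(max(mc_var, 0.0)))


def paired_minus2LL(dataset: Sequence[SubjectData], pop_reduced: PopulationParams,
                    pop_full: PopulationParams, settings: FitSettings):
    """-2LL of two nested models from one shared set of importance samples.

    Per subject, a single proposal is built under the full model and the
    *same* draws (hence the same expensive per-sample likelihoods) are
    reweighted under each model's stage-2 prior.  The Monte-Carlo error of
    the -2LL *difference* then comes only from the smooth prior ratio and is
    far smaller than that of two independent evaluations — exactly what the
    likelihood-ratio test needs.  Returns (minus2LL_reduced, minus2LL_full).
    """
    subjects = [_prepare_subject(s) for s in dataset]

    def _prior_terms(pop):
        prec = np.linalg.inv(pop.Sigma_logtheta)
        return prec, float(np.linalg.slogdet(prec)[1])

    prec_f, logdet_f = _prior_terms(pop_full)
    prec_r, logdet_r = _prior_terms(pop_reduced)
    m = settings.n_ll_samples
    tot_f = 0.0
    tot_r = 0.0
    for i, subj in enumerate(subjects):
        pm_f = individual_mean_log(pop_full, subj.covariates)
        pm_r = individual_mean_log(pop_reduced, subj.covariates)
        rng = _subject_rng(settings.seed, _LL_STREAM, i)
        (_mode, _mean, _cov, _ess, _lm, _es, _mv, fail, xs, _wn, lls, logqs,
         ssrs) = _run_estep(
            subj, pm_f, pm_f, prec_f, logdet_f, pop_full.sigma_prop,
            settings, rng, n_samples=m,
            mode_maxiter=settings.ll_mode_maxiter)
        if fail:
            raise RuntimeError(f"marginal likelihood failed for subject "
                               f"{subj.subject_id}")
        for pm, prec, logdet, is_full in ((pm_f, prec_f, logdet_f, True),
                                          (pm_r, prec_r, logdet_r, False)):
            d = xs - pm
            quad = np.einsum("sj,jk,sk->s", d, prec, d)
            lp = 0.5 * logdet - 2.0 * np.log(2.0 * np.pi) - 0.5 * quad
            # residual-error scale may differ between the models
            sig = pop_full.sigma_prop if is_full else pop_reduced.sigma_prop
            ll = lls if sig == pop_full.sigma_prop else _rescaled_lls(
                subj.obs_times.size, lls, ssrs, pop_full.sigma_prop, sig)
            logw = ll + lp - logqs
            a = np.max(logw)
            logmarg = a + np.log(np.mean(np.exp(logw - a)))
            if is_full:
                tot_f += logmarg
            else:
                tot_r += logmarg
    return float(-2.0 * tot_r), float(-2.0 * tot_f)


def _rescaled_lls(n_obs, lls, ssrs, sigma_from, sigma_to):
    """Translate per-sample log-likelihoods to a different error scale.

    With SD-proportional error,
    ll = -n/2 log(2 pi) - n log(sigma) - sum(log yhat) - ssr / (2 sigma^2),
    so changing sigma only shifts the normalization and rescales the ssr
    term; both are available per sample.
    """
    out = (lls + n_obs * np.log(sigma_from / sigma_to)
           + 0.5 * ssrs * (1.0 / sigma_from ** 2 - 1.0 / sigma_to ** 2))
    out[~np.isfinite(lls)] = -np.inf
    return out


def profile_lrt_effect(dataset: Sequence[SubjectData],
                       base_pop: PopulationParams, effect, settings: FitSettings):
    """Profile likelihood-ratio test of one added covariate effect.

    All other population parameters stay fixed at ``base_pop`` (their
    reduced-model estimates); the candidate's log-scale coefficient psi only
    shifts each subject's stage-2 prior mean, so with one set of importance
    samples per subject the total -2LL is an exact smooth function of psi
    that can be profiled without refitting.  Because covariate columns are
    centred (power models at the median, indicators vs a baseline level),
    psi is nearly information-orthogonal to the fixed parameters and the
    statistic retains its chi-square(1) null calibration.

    Returns a dict with psi_hat, coefficient (natural scale), delta_m2ll,
    p_value, rse_percent.
    """
    from scipy import optimize

    subjects = [_prepare_subject(s) for s in dataset]
    prec = np.linalg.inv(base_pop.Sigma_logtheta)
    logdet = float(np.linalg.slogdet(prec)[1])
    j = _PARAM_INDEX[effect.parameter]
    stored = []
    for i, subj in enumerate(subjects):
        pm = individual_mean_log(base_pop, subj.covariates)
        x_i = effect.design_value(subj.covariates)
        rng = _subject_rng(settings.seed, _LL_STREAM, i)
        (_m, _me, _c, _e, _lm, _es, _mv, fail, xs, _wn, lls, logqs, _ss) = \
            _run_estep(subj, pm, pm, prec, logdet, base_pop.sigma_prop,
                       settings, rng, n_samples=settings.n_ll_samples,
                       mode_maxiter=settings.ll_mode_maxiter)
        if fail:
            raise RuntimeError(f"profile LRT failed for subject "
                               f"{subj.subject_id}")
        stored.append((xs, lls - logqs, pm, x_i))

    lp_const = 0.5 * logdet - 2.0 * np.log(2.0 * np.pi)

    def m2ll(dmu: float, psi: float) -> float:
        # dmu re-profiles the affected parameter's population mean so the
        # statistic is invariant to its base-fit estimation error (the
        # covariate column is only approximately centred)
        total = 0.0
        for xs, llq, pm, x_i in stored:
            d = xs - pm
            d = d.copy()
            d[:, j] -= dmu + x_i * psi
            quad = np.einsum("sj,jk,sk->s", d, prec, d)
            logw = llq + lp_const - 0.5 * quad
            a = np.max(logw)
            total += a + np.log(np.mean(np.exp(logw - a)))
        return -2.0 * total

    res0 = optimize.minimize_scalar(lambda c: m2ll(c, 0.0),
                                    bounds=(-3.0, 3.0), method="bounded",
                                    options={"xatol": 1e-5})
    m2_null = float(res0.fun)
    res = optimize.minimize(lambda v: m2ll(v[0], v[1]),
                            x0=np.array([float(res0.x), 0.0]),
                            method="Nelder-Mead",
                            options={"xatol": 1e-5, "fatol": 1e-8,
                                     "maxiter": 400})
    psi_hat = float(res.x[1])
    m2_hat = float(res.fun)
    delta = m2_null - m2_hat
    if abs(psi_hat) > 5.9:
        warnings.warn(f"profile optimum at the search boundary for "
                      f"{effect.covariate} on {effect.parameter}")
    p = float(stats.chi2.sf(max(delta, 0.0), 1))
    # Wald curvature of the profile: d2(-2LL)/dpsi2 = 2 / Var(psi_hat)
    h = 0.05
    dmu_hat = float(res.x[0])
    curv = (m2ll(dmu_hat, psi_hat + h) - 2.0 * m2_hat
            + m2ll(dmu_hat, psi_hat - h)) / h ** 2
    se = float(np.sqrt(2.0 / curv)) if curv > 0 else np.inf
    if effect.kind == "proportional_shift":
        coeff = float(np.expm1(psi_hat))
        se_nat = float(np.exp(psi_hat) * se)
    else:
        coeff = psi_hat
        se_nat = se
    rse = 100.0 * se_nat / abs(coeff) if coeff != 0 else np.inf
    return {"psi_hat": psi_hat, "coefficient": coeff,
            "delta_m2ll": float(delta), "p_value": p,
            "rse_percent": float(rse), "se": se_nat,
            "minus2LL_null": float(m2_null), "minus2LL_hat": m2_hat}


def standard_errors(fit: FitResult, dataset: Sequence[SubjectData],
                    settings: FitSettings, method: str = "fisher") -> dict:
    """Relative standard errors (CV%) of all population estimates.

    The observed Fisher information is assembled from per-subject
    observed-data scores (conditional expectations of the complete-data
    scores, available from the E-step moments).  ``method="bootstrap"``
    resamples subjects' score contributions instead.
    """
    subjects = [_prepare_subject(s) for s in dataset]
    n = len(subjects)
    effects = tuple(fit.pop.effects)
    gamma = fit.gamma
    Sigma = fit.pop.Sigma_logtheta
    sigma = fit.pop.sigma_prop
    prec = np.linalg.inv(Sigma)
    D = [_design_matrix(s, effects) for s in subjects]
    pairs = [(j, k) for j in range(4) for k in range(j, 4)]
    p_gamma = gamma.size
    p_total = p_gamma + len(pairs) + 1
    scores = np.zeros((n, p_total))
    logdet_prec = float(np.linalg.slogdet(prec)[1])
    for i, subj in enumerate(subjects):
        pm = D[i] @ gamma
        rng = _subject_rng(settings.seed, _LL_STREAM, i)
        (mode, mean, cov, ess, logmarg, e_ssr, mv, fail, *_rest) = _run_estep(
            subj, fit.conditional_mean_log[i], pm, prec, logdet_prec, sigma,
            settings, rng, n_samples=settings.n_ll_samples,
            mode_maxiter=settings.ll_mode_maxiter)
        if fail:
            continue
        r = mean - pm
        scores[i, :p_gamma] = D[i].T @ (prec @ r)
        M = cov + np.outer(r, r)
        Gm = 0.5 * (prec @ M @ prec - prec)
        for q, (j, k) in enumerate(pairs):
            scores[i, p_gamma + q] = Gm[j, k] * (1.0 if j == k else 2.0)
        scores[i, -1] = e_ssr / sigma ** 3 - subj.obs_times.size / sigma
    if method == "bootstrap":
        rng = np.random.default_rng([settings.seed, 77])
        reps = np.empty((200, p_total))
        for b in range(200):
            idx = rng.integers(0, n, n)
            reps[b] = scores[idx].sum(axis=0)
        F = np.cov(reps.T)
        se = _safe_sqrt_diag_inv(F)
    else:
        F = scores.T @ scores
        se = _safe_sqrt_diag_inv(F)

    out = {}
    for j, name in enumerate(PARAM_NAMES):
        out[f"TV_{name}"] = 100.0 * se[j]  # SE(exp g)/exp g = SE(g)
    for k, eff in enumerate(effects):
        psi = gamma[4 + k]
        if eff.kind == "proportional_shift":
            phi = np.expm1(psi)
            se_phi = np.exp(psi) * se[4 + k]
            out[f"{eff.covariate}_on_{eff.parameter}"] = (
                100.0 * se_phi / abs(phi) if phi != 0 else np.inf)
        else:
            out[f"{eff.covariate}_on_{eff.parameter}"] = (
                100.0 * se[4 + k] / abs(psi) if psi != 0 else np.inf)
    for q, (j, k) in enumerate(pairs):
        if j == k:
            # IIV CV% ~ 100*sqrt(Sigma_jj): RSE = 100*SE(Sjj)/(2*Sjj)
            out[f"IIV_{PARAM_NAMES[j]}"] = (
                100.0 * se[p_gamma + q] / (2.0 * Sigma[j, j]))
    out["sigma_prop"] = 100.0 * se[-1] / sigma
    return out


def _safe_sqrt_diag_inv(F: np.ndarray) -> np.ndarray:
    try:
        cond = np.linalg.cond(F)
    except np.linalg.LinAlgError:
        cond = np.inf
    if not np.isfinite(cond) or cond > 1e12:
        warnings.warn("information matrix is singular or ill-conditioned; "
                      "using pseudo-inverse", NonConvergenceWarning)
        Finv = np.linalg.pinv(F)
    else:
        Finv = np.linalg.inv(F)
    d = np.diag(Finv).copy()
    d[d < 0] = np.nan
    return np.sqrt(d)


def lrt(minus2LL_reduced: float, minus2LL_full: float, df: int,
        tolerance: float = 1.0) -> float:
    """Likelihood-ratio test p-value for nested models.

    ``tolerance`` allows a slightly negative difference (Monte-Carlo noise in
    the two -2LL estimates); beyond it the inputs are considered invalid.
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    diff = minus2LL_reduced - minus2LL_full
    if diff < -tolerance:
        raise ValueError(
            f"full model fits worse than reduced by {-diff:.3f} units; "
            "models are not nested or fits did not converge")
    stat = max(diff, 0.0)
    return float(stats.chi2.sf(stat, df))


def conditional_std_residuals(fit: FitResult, dataset: Sequence[SubjectData]):
    """Per-observation standardized residuals (conditional and population).

    conditional: (y - yhat(E[log theta_i])) / (sigma * yhat);
    population:  same with the subject's covariate-typical parameters.
    """
    import pandas as pd

    from .minimal_model import simulate_glucose, MMParams

    subjects = [_prepare_subject(s) for s in dataset]
    sigma = fit.pop.sigma_prop
    rows = []
    for i, subj in enumerate(subjects):
        cond = MMParams.from_array(np.exp(fit.conditional_mean_log[i]))
        popp = MMParams.from_array(
            np.exp(individual_mean_log(fit.pop, subj.covariates)))
        yc = simulate_glucose(cond, subj.dose, subj.Gbasal, subj.Ibasal,
                              subj.forcing, subj.obs_times)
        yp = simulate_glucose(popp, subj.dose, subj.Gbasal, subj.Ibasal,
                              subj.forcing, subj.obs_times)
        for t, y, c, p in zip(subj.obs_times, subj.obs_glucose, yc, yp):
            rows.append({"subject_id": subj.subject_id, "time_min": t,
                         "observed": y,
                         "cond_pred": c,
                         "cond_std_residual": (y - c) / (sigma * c),
                         "pop_pred": p,
                         "pop_std_residual": (y - p) / (sigma * p)})
    return pd.DataFrame(rows)
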