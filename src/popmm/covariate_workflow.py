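"""Forward covariate-selection workflow for the population minimal model.

The procedure mirrors standard pharmacometric practice: candidate
covariate-parameter relations are screened on the empirical conditional
means (EBEs) of a covariate-free base fit, then added one by one — insulin
sensitivity first (its covariate structure is best established), then the
distribution volume, then glucose effectiveness, then p2 — each retained
only if the likelihood-ratio test against the current model is significant
and the coefficient is estimated with adequate precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .em_engine import (FitResult, FitSettings, em_fit, lrt,
                        profile_lrt_effect)
from .minimal_model import PARAM_NAMES
from .population_model import CovariateEffect, CovariateSpec

#: order in which parameters' candidate effects are tested
PARAMETER_PRIORITY = ("SI", "V", "GEZI", "p2")

#: retention requires the coefficient's relative standard error below this
RSE_RETENTION_PERCENT = 50.0


@dataclass(frozen=True)
class ScreenResult:
    candidate: CovariateEffect
    association_statistic: float
    p_value: float


@dataclass
class ForwardSelectionResult:
    spec: CovariateSpec           # retained effects with fitted coefficients
    steps: pd.DataFrame           # one row per tested candidate
    base_fit: FitResult
    final_fit: FitResult


def _is_categorical(values: pd.Series) -> bool:
    if values.dtype == object or str(values.dtype) == "category":
        return True
    u = pd.unique(values.dropna())
    return len(u) <= 2


def ebe_screen(fit_base: FitResult, covariate_table: pd.DataFrame,
               covariates: Sequence[str] | None = None) -> list[ScreenResult]:
    """Screen covariate-parameter associations on conditional means.

    Continuous covariates: Spearman rank correlation of the conditional-mean
    log-parameter against the log covariate.  Categorical covariates:
    Wilcoxon rank-sum between the two levels (rank-biserial effect size).
    Results are sorted by p-value within each parameter.  Constant covariates
    are skipped with a warning.
    """
    table = covariate_table.set_index("subject_id").loc[fit_base.subject_ids]
    if covariates is None:
        covariates = [c for c in table.columns
                      if c not in ("dose_mmol",)]
    results = []
    for ci, cov in enumerate(covariates):
        col = table[cov]
        if pd.unique(col.dropna()).size < 2:
            warnings.warn(f"covariate {cov!r} is constant; skipped")
            continue
        categorical = _is_categorical(col)
        for pj, param in enumerate(PARAM_NAMES):
            ebe = fit_base.conditional_mean_log[:, pj]
            if categorical:
                levels = pd.unique(col)
                mask = col == levels[0]
                x, y = ebe[mask.values], ebe[~mask.values]
                if x.size < 2 or y.size < 2:
                    continue
                res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                         method="asymptotic")
                effect = 2.0 * res.statistic / (x.size * y.size) - 1.0  # rank-biserial
                pval = float(res.pvalue)
                cand = CovariateEffect(param, cov, "proportional_shift",
                                       0.0, 0.0)
            else:
                vals = col.astype(float)
                if (vals <= 0).any():
                    continue
                rho, pval = stats.spearmanr(ebe, np.log(vals))
                effect = float(rho)
                cand = CovariateEffect(param, cov, "power_centered",
                                       float(vals.median()), 0.0)
            results.append(ScreenResult(cand, float(effect), float(pval)))
    results.sort(key=lambda r: (PARAM_NAMES.index(r.candidate.parameter),
                                r.p_value))
    return results


def _ordered(candidates: Sequence[CovariateEffect]) -> list[CovariateEffect]:
    prio = {p: i for i, p in enumerate(PARAMETER_PRIORITY)}
    return sorted(candidates, key=lambda c: prio[c.parameter])


def forward_select(dataset, candidates: Sequence[CovariateEffect],
                   alpha: float = 0.05,
                   settings: FitSettings | None = None,
                   base_fit: FitResult | None = None) -> ForwardSelectionResult:
    """One-by-one forward addition gated by the likelihood-ratio test.

    Candidates are tested in parameter-priority order (SI, V, GEZI, p2;
    stable within a parameter).  At each step the candidate's coefficient is
    profiled against the current model on shared importance samples (see
    :func:`popmm.em_engine.profile_lrt_effect`), which gives an essentially
    noise-free likelihood-ratio statistic; the effect is retained iff
    p < alpha AND its relative standard error is below 50%.  Retained
    effects trigger a full EM refit (warm-started from the current model)
    that becomes the new current model.
    """
    settings = settings or FitSettings()
    if base_fit is None:
        base_fit = em_fit(dataset, CovariateSpec(), settings=settings)
    current_fit = base_fit
    current_effects: list[CovariateEffect] = []
    rows = []
    for cand in _ordered(candidates):
        label = f"{cand.covariate}_on_{cand.parameter}"
        try:
            prof = profile_lrt_effect(dataset, current_fit.pop, cand, settings)
            p = prof["p_value"]
            rse = prof["rse_percent"]
            retained = bool(p < alpha and rse < RSE_RETENTION_PERCENT)
            if retained:
                fitted_cand = CovariateEffect(cand.parameter, cand.covariate,
                                              cand.kind, cand.reference,
                                              prof["coefficient"])
                trial_spec = CovariateSpec(tuple(current_effects) + (fitted_cand,))
                fit_try = em_fit(dataset, trial_spec, init=current_fit.pop,
                                 settings=settings)
                current_fit = fit_try
                current_effects = list(fit_try.pop.effects)
            rows.append({"step": len(rows) + 1, "effect": label,
                         "minus2LL": prof["minus2LL_hat"],
                         "delta": prof["delta_m2ll"], "df": 1,
                         "p_value": p, "rse_percent": rse,
                         "coefficient": prof["coefficient"],
                         "decision": "retained" if retained else "rejected"})
        except Exception as exc:
            warnings.warn(f"testing {label} failed ({exc}); rejected")
            rows.append({"step": len(rows) + 1, "effect": label,
                         "minus2LL": np.nan, "delta": np.nan, "df": 1,
                         "p_value": np.nan, "rse_percent": np.nan,
                         "coefficient": np.nan,
                         "decision": "rejected (refit failure)"})
    steps = pd.DataFrame(rows)
    return ForwardSelectionResult(
        spec=CovariateSpec(tuple(current_effects)), steps=steps,
        base_fit=base_fit, final_fit=current_fit)


def final_model_report(fit_final: FitResult, fit_base: FitResult) -> dict:
    """Side-by-side population-modeling report (base vs final model).

    Mirrors the customary layout: typical values with RSE, IIV CV%,
    covariate effects, proportional error, -2LL, and the overall LRT of the
    final against the base model.
    """
    from .population_model import iiv_cv, typical_values

    def one(fit: FitResult) -> dict:
        return {
            "typical_values": typical_values(fit.pop),
            "iiv_cv_percent": iiv_cv(fit.pop.Sigma_logtheta),
            "covariate_effects": {
                f"{e.covariate}_on_{e.parameter}": e.coefficient
                for e in fit.pop.effects},
            "sigma_prop": fit.pop.sigma_prop,
            "minus2LL": fit.minus2LL,
            "rse_cv_percent": {k: float(v)
                               for k, v in fit.rse_cv_percent.items()},
            "converged": bool(fit.converged),
        }

    df = len(fit_final.pop.effects) - len(fit_base.pop.effects)
    report = {"base": one(fit_base), "final": one(fit_final)}
    if df >= 1:
        report["overall_lrt"] = {
            "delta_minus2LL": fit_base.minus2LL - fit_final.minus2LL,
            "df": df,
            "p_value": lrt(fit_base.minus2LL, fit_final.minus2LL, df,
                           tolerance=np.inf),
        }
    return report
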