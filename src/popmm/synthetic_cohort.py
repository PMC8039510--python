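"""Virtual IVGTT / IM-IVGTT trial generator.

Emulates the pooled clinical dataset the population analysis was built on:
a mixed cohort of non-diabetic (ND) and type-2-diabetic (T2D) subjects, part
receiving a standard IVGTT (0.3 g/kg glucose bolus) and part an
insulin-modified IVGTT (added short insulin infusion at 20 min), with the
published covariate distributions, sampling designs, log-normal parameter
variability and proportional measurement noise.

What is emulated and what is not: covariate marginals, cohort/test-type
composition, sampling schedules, and the parameter hierarchy follow the
published summaries; the insulin forcing profiles are a parametric invention
(basal level plus bi-exponential endogenous first phase, blunted in T2D,
plus an exogenous second phase for IM-IVGTT) because no measured profiles
are available.  Users with measured insulin data can substitute their own
:class:`~popmm.minimal_model.InsulinForcing` objects.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .minimal_model import (
    InsulinForcing,
    SubjectData,
    TestType,
    dose_to_mmol,
    simulate_glucose,
)
from .population_model import (
    PopulationParams,
    reference_final_population,
    sample_individual,
)

#: standard IVGTT glucose bolus
DOSE_G_PER_KG = 0.3

#: noise floor for simulated glucose observations (mmol/L)
GLUCOSE_FLOOR = 0.1


@dataclass(frozen=True)
class TruncNormSpec:
    """Truncated normal with target *truncated* mean and SD."""

    mean: float
    sd: float
    lower: float
    upper: float

    def __post_init__(self):
        if not self.lower < self.mean < self.upper:
            raise ValueError("target mean must lie inside the truncation bounds")
        if self.sd <= 0:
            raise ValueError("sd must be positive")


@dataclass(frozen=True)
class InsulinProfileParams:
    """Shape parameters of the synthetic insulin forcing, per cohort.

    The endogenous response has two phases: a sharp first-phase spike at
    3-5 min (large in ND, blunted in T2D) and a slower glucose-driven
    second phase peaking at 30-50 min.  In insulin-resistant T2D the second
    phase is the dominant, sustained component (hyperinsulinemia of several
    hundred pmol/L), which is what makes insulin-mediated disposal
    substantial despite the low insulin sensitivity.
    """

    basal_median: float        # pmol/L
    basal_log_sd: float
    first_phase_mult: float    # median peak/basal ratio of the first phase
    first_phase_log_sd: float
    second_phase_mult: float   # median peak/basal ratio of the second phase
    second_phase_log_sd: float


@dataclass(frozen=True)
class CohortSpec:
    """Configuration of a virtual trial.

    Defaults reproduce the published study composition: 497 subjects,
    154/497 T2D, 229/497 IM-IVGTT, and covariate marginals with
    age 41.4 +/- 16.9 yr [9.7, 86], height 169 +/- 10.1 cm [130, 196] and
    BMI 28.0 +/- 6.76 kg/m^2 [15.9, 53.9]; weight is derived as
    BMI * (height/100)^2 so the anthropometrics stay internally consistent.
    """

    n_subjects: int = 497
    frac_T2D: float = 154 / 497
    frac_IM: float = 229 / 497
    age: TruncNormSpec = TruncNormSpec(41.4, 16.9, 9.7, 86.0)
    height: TruncNormSpec = TruncNormSpec(169.0, 10.1, 130.0, 196.0)
    bmi: TruncNormSpec = TruncNormSpec(28.0, 6.76, 15.9, 53.9)
    # observed sex split 239 F / 217 M / 41 missing
    sex_proportions: tuple = (239 / 497, 217 / 497, 41 / 497)  # F, M, NA
    true_pop: PopulationParams = field(default_factory=reference_final_population)
    insulin_nd: InsulinProfileParams = InsulinProfileParams(40.0, 0.35, 7.0, 0.35,
                                                            2.5, 0.4)
    insulin_t2d: InsulinProfileParams = InsulinProfileParams(70.0, 0.35, 2.0, 0.35,
                                                             8.0, 0.4)
    gbasal_nd: TruncNormSpec = TruncNormSpec(5.0, 0.45, 3.8, 6.5)
    gbasal_t2d: TruncNormSpec = TruncNormSpec(8.0, 1.6, 5.5, 14.0)
    #: analytic CV of the basal glucose measurement (assay-level error; the
    #: proportional residual sigma of the hierarchy also absorbs model
    #: misspecification and is larger)
    basal_noise_cv: float = 0.02
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.frac_T2D <= 1 and 0 <= self.frac_IM <= 1):
            raise ValueError("fractions must lie in [0, 1]")


@dataclass
class TrialDataset:
    """Generated subjects plus the generating truth (kept separate)."""

    subjects: list
    truth: dict                     # subject_id -> MMParams
    covariate_table: pd.DataFrame   # what a fitting run is allowed to see


# ---------------------------------------------------------------------------
# truncated normals with matched moments
# ---------------------------------------------------------------------------

@lru_cache(maxsize=64)
def _matched_truncnorm(spec: TruncNormSpec):
    """Truncated-normal frozen dist whose *truncated* mean/SD match spec.

    Truncation shifts the moments of a normal, so the underlying (loc,
    scale) are solved for numerically.
    """
    def eqs(x):
        loc, log_scale = x
        scale = np.exp(log_scale)
        a = (spec.lower - loc) / scale
        b = (spec.upper - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [m - spec.mean, np.sqrt(v) - spec.sd]

    sol = optimize.fsolve(eqs, [spec.mean, np.log(spec.sd)], full_output=False)
    loc, scale = sol[0], float(np.exp(sol[1]))
    a = (spec.lower - loc) / scale
    b = (spec.upper - loc) / scale
    if not np.isfinite([loc, scale]).all() or scale <= 0:
        raise ValueError(f"infeasible truncation bounds for {spec}")
    return stats.truncnorm(a, b, loc=loc, scale=scale)


def _draw_truncnorm(spec: TruncNormSpec, size, rng) -> np.ndarray:
    return _matched_truncnorm(spec).rvs(size=size, random_state=rng)


# ---------------------------------------------------------------------------
# covariates
# ---------------------------------------------------------------------------

def generate_covariates(spec: CohortSpec, rng: np.random.Generator) -> pd.DataFrame:
    """Draw the covariate table of a virtual cohort.

    Age, height and BMI come from moment-matched truncated normals; weight
    is derived from BMI and height; cohort, test type and sex are drawn from
    the configured proportions.  The glucose dose (mmol) is 0.3 g/kg of the
    drawn weight.
    """
    n = spec.n_subjects
    age = _draw_truncnorm(spec.age, n, rng)
    height = _draw_truncnorm(spec.height, n, rng)
    bmi = _draw_truncnorm(spec.bmi, n, rng)
    weight = bmi * (height / 100.0) ** 2
    t2d = rng.random(n) < spec.frac_T2D
    im = rng.random(n) < spec.frac_IM
    sex = rng.choice(np.array(["F", "M", "NA"]), size=n, p=spec.sex_proportions)
    return pd.DataFrame({
        "subject_id": [f"S{i:04d}" for i in range(n)],
        "age_yr": age,
        "weight_kg": weight,
        "height_cm": height,
        "bmi_kg_m2": bmi,
        "sex": sex,
        "cohort": np.where(t2d, "T2D", "ND"),
        "test_type": np.where(im, TestType.IM_IVGTT.value, TestType.IVGTT.value),
        "dose_mmol": [dose_to_mmol(DOSE_G_PER_KG, w) for w in weight],
    })


@dataclass(frozen=True)
class ImputationRules:
    """How to fill covariate gaps (mirrors the source study's procedure)."""

    sex_proportions: tuple = (0.5, 0.5)    # F, M among assignable
    height_normal_f: tuple = (162.0, 7.0)  # cm, virtual-population surrogate
    height_normal_m: tuple = (176.0, 7.0)


def impute_missing(table: pd.DataFrame, rules: ImputationRules,
                   rng: np.random.Generator) -> pd.DataFrame:
    """Fill covariate gaps: study means for continuous covariates, random
    sex assignment from reported proportions, height from weight and mean
    BMI, and a sex-specific-normal surrogate for the anthropomorphic
    generator when both weight and height are missing.
    """
    out = table.copy()
    cont = ["age_yr", "weight_kg", "height_cm", "bmi_kg_m2"]
    means = {c: out[c].mean() for c in cont if c in out}
    # sex first (the anthropometric surrogate is sex-specific)
    if out["sex"].isna().any():
        idx = out.index[out["sex"].isna()]
        out.loc[idx, "sex"] = rng.choice(
            np.array(["F", "M"]), size=len(idx),
            p=np.asarray(rules.sex_proportions) / sum(rules.sex_proportions))
    if "age_yr" in out and out["age_yr"].isna().any():
        if np.isnan(means["age_yr"]):
            raise ValueError("cannot impute age: no observed values")
        out["age_yr"] = out["age_yr"].fillna(means["age_yr"])
    for i in out.index:
        w = out.at[i, "weight_kg"]
        h = out.at[i, "height_cm"]
        b = out.at[i, "bmi_kg_m2"]
        if not (np.isnan(w) or np.isnan(h) or np.isnan(b)):
            continue
        if np.isnan(w) and np.isnan(h) and not np.isnan(b):
            # surrogate for the virtual-population generator: sex-specific
            # height normal, weight back-computed from BMI
            mu, sd = (rules.height_normal_f if out.at[i, "sex"] == "F"
                      else rules.height_normal_m)
            h = float(rng.normal(mu, sd))
            w = b * (h / 100.0) ** 2
        elif np.isnan(h) and not np.isnan(w):
            bmi_ref = b if not np.isnan(b) else means["bmi_kg_m2"]
            if np.isnan(bmi_ref):
                raise ValueError(
                    f"subject {out.at[i, 'subject_id']}: cannot impute height "
                    "(no BMI information)")
            h = 100.0 * np.sqrt(w / bmi_ref)
        elif np.isnan(w) and not np.isnan(h):
            if not np.isnan(b):
                w = b * (h / 100.0) ** 2
            elif not np.isnan(means["weight_kg"]):
                w = means["weight_kg"]
            else:
                raise ValueError(
                    f"subject {out.at[i, 'subject_id']}: cannot impute weight")
        elif np.isnan(w) and np.isnan(h) and np.isnan(b):
            if np.isnan(means["weight_kg"]) or np.isnan(means["height_cm"]):
                raise ValueError(
                    f"subject {out.at[i, 'subject_id']}: all anthropometrics "
                    "missing and no study means available")
            w, h = means["weight_kg"], means["height_cm"]
        if np.isnan(b):
            b = w / (h / 100.0) ** 2
        out.at[i, "weight_kg"] = w
        out.at[i, "height_cm"] = h
        out.at[i, "bmi_kg_m2"] = b
    return out


# ---------------------------------------------------------------------------
# forcing and schedules
# ---------------------------------------------------------------------------

def _biexp_bump(t, onset, k_decay, k_rise):
    """Unit-peak bi-exponential bump starting at ``onset``."""
    tt = np.maximum(np.asarray(t, dtype=float) - onset, 0.0)
    tpk = np.log(k_rise / k_decay) / (k_rise - k_decay)
    peak = np.exp(-k_decay * tpk) - np.exp(-k_rise * tpk)
    return (np.exp(-k_decay * tt) - np.exp(-k_rise * tt)) / peak


def insulin_profile(covariates: Mapping[str, object], test_type: TestType,
                    rng: np.random.Generator, duration: float = 180.0,
                    nd_params: InsulinProfileParams | None = None,
                    t2d_params: InsulinProfileParams | None = None) -> InsulinForcing:
    """Synthetic measured-insulin forcing for one subject.

    Basal level plus an endogenous first-phase peak (~3-5 min, blunted and
    on an elevated basal in T2D), decaying bi-exponentially toward basal;
    IM-IVGTT adds an exogenous second phase starting at 20 min scaled to a
    0.03-0.05 U/kg short infusion.  Knots are spaced 2-10 min apart.  With a
    common random stream the IVGTT and IM-IVGTT profiles of the same subject
    are identical before 20 min.
    """
    t2d = bool(covariates.get("t2d", covariates.get("cohort") == "T2D"))
    prm = (t2d_params or InsulinProfileParams(70.0, 0.35, 2.0, 0.35, 8.0, 0.4)) \
        if t2d else (nd_params or InsulinProfileParams(40.0, 0.35, 7.0, 0.35,
                                                       2.5, 0.4))
    ibasal = float(rng.lognormal(np.log(prm.basal_median), prm.basal_log_sd))
    t_peak = rng.uniform(3.0, 5.0)
    # plasma insulin half-life is ~4-6 min, so the first-phase spike decays
    # fast (its tail is taken over by second-phase secretion)
    k1 = rng.uniform(0.10, 0.18)
    k2 = 8.0 * k1                          # very fast rise
    amp1 = ibasal * rng.lognormal(np.log(prm.first_phase_mult), prm.first_phase_log_sd)
    # second phase: slow glucose-driven secretion peaking at 30-50 min and
    # decayed back to near basal by the end of the test
    t_peak2 = rng.uniform(30.0, 50.0)
    r2 = float(rng.lognormal(np.log(prm.second_phase_mult), prm.second_phase_log_sd))
    amp2nd = ibasal * r2
    # decay chosen so the (peak-normalized) second phase is back to <= 5% of
    # basal at the end of the test; the normalization depends on the decay
    # itself, so iterate the closed form a few times
    kr2 = 0.08
    kd2 = 0.03
    for _ in range(6):
        tpk_b = np.log(kr2 / kd2) / (kr2 - kd2)
        c_norm = np.exp(-kd2 * tpk_b) - np.exp(-kr2 * tpk_b)
        onset = max(t_peak2 - tpk_b, 5.0)
        kd2 = max(0.015, np.log(max(r2 / (0.05 * c_norm), 2.0))
                  / max(duration - onset, 30.0))
    # knot grid: 2-10 min spacing, anchored at 0 and duration
    knots = [0.0]
    while knots[-1] < duration:
        knots.append(knots[-1] + rng.uniform(2.0, 10.0))
    knots[-1] = duration
    knots = np.array(knots)
    # shift the bumps so their peaks land at the drawn peak times
    tpk = np.log(k2 / k1) / (k2 - k1)
    onset1 = max(t_peak - tpk, 0.0)
    tpk2 = np.log(kr2 / kd2) / (kr2 - kd2)
    onset2 = max(t_peak2 - tpk2, 5.0)
    conc = (ibasal + amp1 * _biexp_bump(knots, onset1, k1, k2)
            + amp2nd * _biexp_bump(knots, onset2, kd2, kr2))
    if test_type == TestType.IM_IVGTT:
        u_per_kg = rng.uniform(0.03, 0.05)
        # 1 U ~ 6 nmol distributed in ~0.15 L/kg gives u/kg * 40000 pmol/L
        # (per-kg dosing cancels the weight), damped for clearance during
        # the short infusion
        amp2 = u_per_kg * 40000.0 * float(rng.lognormal(np.log(0.5), 0.2))
        kd = rng.uniform(0.10, 0.17)  # exogenous insulin, ~5 min half-life
        conc = conc + amp2 * _biexp_bump(knots, 20.0, kd, 0.8)
    return InsulinForcing(times=knots, concentrations=conc, Ibasal=ibasal)


_EARLY_CANDIDATES = np.array([2., 3., 4., 5., 6., 7., 8., 10., 12., 14.,
                              16., 18., 20., 22., 25., 28., 30.])


def sampling_schedule(test_type: TestType, rng: np.random.Generator) -> np.ndarray:
    """Observation times: dense early, sparse late, incl. t=0 and endpoint.

    IVGTT: duration 180-360 min, 12-30 samples; IM-IVGTT: 180-240 min,
    12-22 samples.
    """
    if test_type == TestType.IM_IVGTT:
        duration = float(np.round(rng.uniform(180.0, 240.0)))
        n = int(rng.integers(12, 23))
    else:
        duration = float(np.round(rng.uniform(180.0, 360.0)))
        n = int(rng.integers(12, 31))
    n_interior = n - 2
    n_early = min(int(np.ceil(0.55 * n_interior)), _EARLY_CANDIDATES.size)
    n_late = n_interior - n_early
    early = rng.choice(_EARLY_CANDIDATES, size=n_early, replace=False)
    late_candidates = np.arange(40.0, duration - 9.0, 10.0)
    n_late = min(n_late, late_candidates.size)
    late = rng.choice(late_candidates, size=n_late, replace=False)
    times = np.unique(np.concatenate([[0.0], early, late, [duration]]))
    return times


# ---------------------------------------------------------------------------
# full trial
# ---------------------------------------------------------------------------

def _covariate_map(row) -> dict:
    return {
        "age_yr": float(row["age_yr"]),
        "weight_kg": float(row["weight_kg"]),
        "height_cm": float(row["height_cm"]),
        "bmi_kg_m2": float(row["bmi_kg_m2"]),
        "sex": row["sex"],
        "cohort": row["cohort"],
        "test_type": row["test_type"],
        "t2d": 1.0 if row["cohort"] == "T2D" else 0.0,
        "im_ivgtt": 1.0 if row["test_type"] == TestType.IM_IVGTT.value else 0.0,
    }


def simulate_trial(spec: CohortSpec, rng: np.random.Generator | None = None) -> TrialDataset:
    """Generate a full virtual trial from the hierarchy.

    Per subject: covariates -> true parameters from the stage-2 model ->
    dose, schedule, insulin forcing -> noiseless glucose -> proportional
    measurement noise (floored at 0.1 mmol/L).  The generating parameters
    are kept in ``truth``, never in the fitted observation data.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    cov = generate_covariates(spec, rng)
    children = rng.spawn(spec.n_subjects)
    sigma = spec.true_pop.sigma_prop
    subjects = []
    truth = {}
    for i, row in cov.iterrows():
        cmap = _covariate_map(row)
        test_type = TestType(row["test_type"])
        sub_rng = children[i]
        err = None
        for _attempt in range(3):
            try:
                r = sub_rng.spawn(1)[0] if _attempt else sub_rng
                params = sample_individual(spec.true_pop, cmap, r)
                schedule = sampling_schedule(test_type, r)
                duration = schedule[-1]
                forcing = insulin_profile(cmap, test_type, r, duration,
                                          spec.insulin_nd, spec.insulin_t2d)
                gspec = spec.gbasal_t2d if cmap["t2d"] else spec.gbasal_nd
                gb_true = float(_draw_truncnorm(gspec, None, r))
                pred = simulate_glucose(params, float(row["dose_mmol"]),
                                        gb_true, forcing.Ibasal, forcing,
                                        schedule)
                eps = r.standard_normal(schedule.size)
                obs = np.maximum(pred * (1.0 + sigma * eps), GLUCOSE_FLOOR)
                gb_meas = max(gb_true * (1.0 + spec.basal_noise_cv
                                         * r.standard_normal()),
                              GLUCOSE_FLOOR)
                subj = SubjectData(
                    subject_id=row["subject_id"], test_type=test_type,
                    dose=float(row["dose_mmol"]), obs_times=schedule,
                    obs_glucose=obs, forcing=forcing, Gbasal=gb_meas,
                    Ibasal=forcing.Ibasal, covariates=cmap)
                break
            except Exception as exc:  # regenerate with a fresh sub-stream
                err = exc
                subj = None
        if subj is None:
            raise RuntimeError(
                f"failed to generate subject {row['subject_id']} "
                f"after 3 attempts: {err}")
        subjects.append(subj)
        truth[row["subject_id"]] = params
    return TrialDataset(subjects=subjects, truth=truth, covariate_table=cov)
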