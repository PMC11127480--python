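"""Synthetic Medicaid-style claims generator with known counterfactual truth.

The generator emulates the structure of administrative claims used to study
colorectal-cancer screening among insurance beneficiaries aged 50-64: baseline
confounding of HIV status by demographics, time-varying comorbidity burden that
drives both endoscopy uptake and disenrollment, endoscopy that causally lowers
subsequent colon-cancer hazard, competing death, and informative loss of
enrollment.  Because every data-generating parameter is known, the per-protocol
estimand ("risk had everyone followed the every-k-years screening protocol and
never disenrolled") can be computed by Monte Carlo and used as ground truth for
the full censor-and-weight pipeline.

Time is measured in integer months since each beneficiary's 50th birthday
(negative months are pre-50 history).  The simulation step is one month;
downstream analysis bins are three months.  Disease, death and comorbidity
processes run only while a beneficiary is enrolled and aged >=50, so the hazard
at a given age does not depend on when the beneficiary entered -- delayed entry
is exchangeable by construction, which is the assumption the age-timescale
estimator relies on.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .errors import ParameterError
from .risk import RiskCurve, cumulative_incidence

ADMIN_END_MONTH = 180  # age 65
N_BINS = 60  # 3-month bins covering ages [50, 65)

SETTING_IP = "IP"
SETTING_OP = "OP"

CAT_HIV = "HIV"
CAT_COLONOSCOPY = "ENDO_COLONOSCOPY"
CAT_SIGMOIDOSCOPY = "ENDO_SIGMOIDOSCOPY"
CAT_COLON_CA = "COLON_CA"
CAT_ANAL_CA = "ANAL_CA"
CAT_OTHER_CA = "OTHER_CA"
CAT_DEATH = "DEATH"
ENDO_CATEGORIES = (CAT_COLONOSCOPY, CAT_SIGMOIDOSCOPY)
CANCER_CATEGORIES = (CAT_COLON_CA, CAT_ANAL_CA, CAT_OTHER_CA)

_NONE = -(10**6)  # sentinel for "no event month"

# integer claim-category codes used internally during simulation
_C_HIV, _C_COL, _C_SIG, _C_COLCA, _C_ANAL, _C_OTHER, _C_DEATH = range(7)
_C_COMORB_BASE = 100
_CODE_TO_CAT = {
    _C_HIV: CAT_HIV,
    _C_COL: CAT_COLONOSCOPY,
    _C_SIG: CAT_SIGMOIDOSCOPY,
    _C_COLCA: CAT_COLON_CA,
    _C_ANAL: CAT_ANAL_CA,
    _C_OTHER: CAT_OTHER_CA,
    _C_DEATH: CAT_DEATH,
}


def _default_baseline_dist():
    return {
        "sex": {"F": 0.534, "M": 0.466},
        "race": {"white": 0.41, "black": 0.21, "hispanic": 0.14, "other": 0.24},
        "state": {"A": 0.50, "B": 0.30, "C": 0.20},
        "period": {"2001-2005": 0.294, "2006-2010": 0.206, "2011-2015": 0.500},
    }


def _default_hiv_model():
    # logistic model for baseline HIV on demographics; overall prevalence ~5%
    return {
        "intercept": -3.35,
        "sex": {"M": 0.8},
        "race": {"black": 1.2, "hispanic": -0.4, "other": 0.1},
        "state": {"B": 0.2, "C": -0.2},
        "period": {"2006-2010": 0.1, "2011-2015": -0.2},
    }


@dataclass
class GeneratorParams:
    """All knobs of the data-generating process.

    Probabilities are per month unless noted.  ``screen_protect`` is the
    multiplicative colon-cancer hazard factor applied once per past screening
    endoscopy (theta in (0, 1]; 1 = screening has no causal effect).
    """

    n_beneficiaries: int = 1000
    seed: int = 0
    baseline_dist: dict = field(default_factory=_default_baseline_dist)
    hiv_model: dict = field(default_factory=_default_hiv_model)
    entry_model: dict = field(default_factory=lambda: {
        # fraction enrolled before age 50, by HIV status
        "p_before_50": {1: 0.38, 0: 0.15},
        "pre50_span_months": 60,          # pre-50 entry uniform on [-span, -1]
        "late_entry_beta": (1.2, 1.8),    # entry month = floor(170 * Beta(a, b))
        "fixed_entry_month": None,        # overrides everything when set
    })
    comorbidity_model: dict = field(default_factory=lambda: {
        "monthly_gain": 0.0045,
        "hiv_rr": 1.6,
        "per_existing_rr": 1.0,
        "max_conditions": 6,
        "start_month": -60,    # accrual runs on age (from 45), not on coverage
    })
    endoscopy_model: dict = field(default_factory=lambda: {
        "base_logit": -5.3,
        "hiv": 0.25,
        "per_comorb": 0.5,        # per comorbidity category (0/1/2+)
        "ramp_start": 18,         # months since last endoscopy before uptake ramps
        "ramp_slope": 0.12,       # logit increase per month past ramp_start
        "ramp_cap": 3.5,
        "repeat_prob": 0.15,      # diagnostic follow-up 2-4 months later
        "colonoscopy_frac": 0.8,
        "pre50_prob": {1: 0.10, 0: 0.04},
        "protect_washout": 12,    # months; closer repeats add no protection
    })
    cancer_hazard: dict = field(default_factory=lambda: {
        "base_monthly": 6e-5,
        "age_rr_per_year": 1.07,
        "hiv_rr": 0.75,
        "male_rr": 1.2,
        "race_rr": {"black": 1.3, "hispanic": 0.7, "other": 0.9},
        "per_comorb_rr": 1.35,
        "screen_protect": 0.85,
        "protect_cap": 5,
    })
    other_cancer_hazard: dict = field(default_factory=lambda: {
        "base_monthly": 2.5e-4,
        "age_rr_per_year": 1.05,
        "hiv_rr": 1.3,
    })
    anal_cancer_hazard: dict = field(default_factory=lambda: {
        "base_monthly": 1e-5,
        "hiv_rr": 5.0,
    })
    death_hazard: dict = field(default_factory=lambda: {
        "base_monthly": 3e-4,
        "age_rr_per_year": 1.08,
        "hiv_rr": 2.5,
        "male_rr": 1.3,
        "per_comorb_rr": 1.5,
    })
    disenroll_hazard: dict = field(default_factory=lambda: {
        "base_monthly": 0.015,
        "hiv_rr": 0.8,
        "male_rr": 1.1,
        "per_comorb_rr": 0.85,
        "race_rr": {"hispanic": 1.15, "black": 1.05},
    })
    claim_emission: dict = field(default_factory=lambda: {
        "p_inpatient": 0.35,       # two-tier diagnoses: 1 IP claim vs 2 OP claims
        "op_confirm_lag": 1,       # months to the confirming outpatient claim
        "op_repeat_rate": 0.2,     # extra outpatient claim 2-6 months later
        "spurious_op_rate": 0.01,  # lone outpatient claim in disease-free people
        "p_anal_with_colon": 0.04,
    })
    enrollment_structure: dict = field(default_factory=lambda: {
        "p_short_prior_span": 0.04,
        "p_dual": 0.02,
        "p_restricted_benefits": 0.02,
    })

    def replace(self, **updates) -> "GeneratorParams":
        """Return a deep copy with top-level fields replaced / dicts merged."""
        new = copy.deepcopy(self)
        for key, val in updates.items():
            if not hasattr(new, key):
                raise ParameterError(f"unknown GeneratorParams field {key!r}")
            cur = getattr(new, key)
            if isinstance(cur, dict) and isinstance(val, dict):
                cur.update(copy.deepcopy(val))
            else:
                setattr(new, key, val)
        return new

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if self.n_beneficiaries < 0:
            raise ParameterError("n_beneficiaries must be >= 0")
        for name, probs in self.baseline_dist.items():
            total = sum(probs.values())
            if abs(total - 1.0) > 1e-9:
                raise ParameterError(
                    f"baseline_dist[{name!r}] probabilities sum to {total}, not 1")
            for level, p in probs.items():
                if not 0.0 <= p <= 1.0:
                    raise ParameterError(
                        f"baseline_dist[{name!r}][{level!r}]={p} outside [0, 1]")
        for hname in ("cancer_hazard", "other_cancer_hazard",
                      "anal_cancer_hazard", "death_hazard", "disenroll_hazard"):
            base = getattr(self, hname)["base_monthly"]
            if not 0.0 <= base < 1.0:
                raise ParameterError(f"{hname}['base_monthly']={base} outside [0, 1)")
        theta = self.cancer_hazard["screen_protect"]
        if not 0.0 < theta <= 1.0:
            raise ParameterError(
                f"cancer_hazard['screen_protect']={theta} outside (0, 1]")
        for pname in ("p_inpatient", "op_repeat_rate", "spurious_op_rate",
                      "p_anal_with_colon"):
            p = self.claim_emission[pname]
            if not 0.0 <= p <= 1.0:
                raise ParameterError(f"claim_emission[{pname!r}]={p} outside [0, 1]")
        g = self.comorbidity_model["monthly_gain"]
        if not 0.0 <= g <= 1.0:
            raise ParameterError(f"comorbidity_model['monthly_gain']={g} outside [0, 1]")
        for pname in ("p_short_prior_span", "p_dual", "p_restricted_benefits"):
            p = self.enrollment_structure[pname]
            if not 0.0 <= p <= 1.0:
                raise ParameterError(
                    f"enrollment_structure[{pname!r}]={p} outside [0, 1]")
        for hiv in (0, 1):
            p = self.entry_model["p_before_50"][hiv]
            if not 0.0 <= p <= 1.0:
                raise ParameterError(
                    f"entry_model['p_before_50'][{hiv}]={p} outside [0, 1]")


@dataclass
class SyntheticDataset:
    """Observable claims tables plus the hidden ground truth.

    The three observable tables carry no hidden-truth columns; the truth table
    is written to a separate file and may only be consulted by tests and
    oracles, never by the analysis pipeline.
    """

    demographics: pd.DataFrame
    enrollment: pd.DataFrame
    claims: pd.DataFrame
    truth: pd.DataFrame


# ---------------------------------------------------------------------------
# covariate machinery


def _draw_categorical(rng, probs: dict, n: int) -> np.ndarray:
    levels = np.array(list(probs.keys()), dtype=object)
    p = np.array([probs[k] for k in levels], dtype=float)
    return rng.choice(levels, size=n, p=p / p.sum())


def _linear_predictor(model: dict, cov: dict) -> np.ndarray:
    """Evaluate intercept + sum of per-level offsets for categorical covariates."""
    n = len(next(iter(cov.values())))
    lp = np.full(n, float(model.get("intercept", 0.0)))
    for name, offsets in model.items():
        if name == "intercept":
            continue
        vals = cov[name]
        mapped = pd.Series(vals).map(offsets).fillna(0.0).to_numpy()
        lp += mapped
    return lp


def _rr_lookup(rr_map: dict, vals: np.ndarray) -> np.ndarray:
    return pd.Series(vals).map(rr_map).fillna(1.0).to_numpy()


# ---------------------------------------------------------------------------
# core monthly engine


def _draw_population(params: GeneratorParams, rng, n: int, force_hiv=None):
    dist = params.baseline_dist
    cov = {name: _draw_categorical(rng, probs, n) for name, probs in dist.items()}
    p_hiv = expit(_linear_predictor(params.hiv_model, cov))
    if force_hiv is None:
        hiv = (rng.random(n) < p_hiv).astype(np.int8)
    else:
        hiv = np.full(n, int(force_hiv), dtype=np.int8)

    em = params.entry_model
    if em.get("fixed_entry_month") is not None:
        entry = np.full(n, int(em["fixed_entry_month"]), dtype=np.int64)
    else:
        p_pre = np.where(hiv == 1, em["p_before_50"][1], em["p_before_50"][0])
        pre = rng.random(n) < p_pre
        span = int(em["pre50_span_months"])
        entry = np.floor(170 * rng.beta(*em["late_entry_beta"], size=n)).astype(np.int64)
        entry[pre] = rng.integers(-span, 0, size=int(pre.sum()))
    return cov, hiv, p_hiv, entry


def _simulate(params: GeneratorParams, rng, n: int, *, force_hiv=None,
              forced_protocol=None, disenroll=True, collect_claims=True,
              claim_filter=None):
    """Run the monthly engine for n beneficiaries; returns a dict of arrays.

    ``forced_protocol`` (a ProtocolSpec) switches the endoscopy process to the
    protocol-enforced regime: screenings arise from the behavioural uptake
    model whenever they are protocol-compatible (gap since the previous
    screening at least K - b months), are suppressed when they would come too
    soon, and are forced at the last allowed month (K + b since the previous
    screening; the initiation grace since baseline for the first).
    Disenrollment is typically disabled alongside.
    """
    cov, hiv, p_hiv, entry = _draw_population(params, rng, n, force_hiv=force_hiv)
    male = (cov["sex"] == "M")
    baseline = np.maximum(0, entry + 6)

    cm, em_endo = params.comorbidity_model, params.endoscopy_model
    ch, oh, ah = params.cancer_hazard, params.other_cancer_hazard, params.anal_cancer_hazard
    dh, rh = params.death_hazard, params.disenroll_hazard

    # static per-person hazard multipliers
    colon_static = (ch["base_monthly"]
                    * np.where(hiv == 1, ch["hiv_rr"], 1.0)
                    * np.where(male, ch["male_rr"], 1.0)
                    * _rr_lookup(ch["race_rr"], cov["race"]))
    other_static = oh["base_monthly"] * np.where(hiv == 1, oh["hiv_rr"], 1.0)
    anal_static = ah["base_monthly"] * np.where(hiv == 1, ah["hiv_rr"], 1.0)
    death_static = (dh["base_monthly"]
                    * np.where(hiv == 1, dh["hiv_rr"], 1.0)
                    * np.where(male, dh["male_rr"], 1.0))
    dis_static = (rh["base_monthly"]
                  * np.where(hiv == 1, rh["hiv_rr"], 1.0)
                  * np.where(male, rh["male_rr"], 1.0)
                  * _rr_lookup(rh.get("race_rr", {}), cov["race"]))

    alive = np.ones(n, dtype=bool)
    enrolled = np.ones(n, dtype=bool)
    cancer_done = np.zeros(n, dtype=bool)
    comorb = np.zeros(n, dtype=np.int64)
    last_endo = np.full(n, _NONE, dtype=np.int64)
    next_repeat = np.full(n, _NONE, dtype=np.int64)
    nscreen = np.zeros(n, dtype=np.int64)
    colon_m = np.full(n, _NONE, dtype=np.int64)
    other_m = np.full(n, _NONE, dtype=np.int64)
    anal_m = np.full(n, _NONE, dtype=np.int64)
    death_m = np.full(n, _NONE, dtype=np.int64)
    dis_m = np.full(n, _NONE, dtype=np.int64)

    cl_i, cl_m, cl_s, cl_c = [], [], [], []   # immediate claims (idx, month, setting, code)
    df_i, df_m, df_s, df_c = [], [], [], []   # deferred claims, filtered to span later

    def emit(idx, month, setting, code):
        if not collect_claims or idx.size == 0:
            return
        if claim_filter is not None and np.isscalar(code) \
                and code not in claim_filter:
            return
        cl_i.append(idx)
        cl_m.append(np.broadcast_to(month, idx.shape).copy()
                    if np.isscalar(month) else month)
        cl_s.append(np.full(idx.size, setting, dtype=np.int8))
        cl_c.append(np.full(idx.size, code, dtype=np.int64)
                    if np.isscalar(code) else code)

    def defer(idx, month, setting, code):
        if not collect_claims or idx.size == 0:
            return
        df_i.append(idx)
        df_m.append(month)
        df_s.append(np.full(idx.size, setting, dtype=np.int8))
        df_c.append(np.full(idx.size, code, dtype=np.int64))

    ce = params.claim_emission
    protect_cap = int(ch["protect_cap"])
    protect_washout = int(em_endo["protect_washout"])
    if forced_protocol is None:
        K = band = grace = None
    else:
        K = forced_protocol.cadence_months
        band = forced_protocol.bandwidth_months
        grace = forced_protocol.grace_months

    comorb_entry = np.zeros(n, dtype=np.int64)
    m_start = min(int(entry.min()), int(cm["start_month"])) if n else 0
    for m in range(m_start, ADMIN_END_MONTH):
        just_entered = entry == m
        if just_entered.any():
            comorb_entry[just_entered] = comorb[just_entered]
        active = alive & enrolled & (entry <= m)

        if m >= 0:
            at_risk = active & ~cancer_done
            # --- endoscopy ---
            if K is not None:
                # protocol-enforced regime: behavioural uptake within the
                # allowed window, suppressed when too soon, forced at the last
                # allowed month (screenings only; repeats are irrelevant here)
                have_prev = last_endo > _NONE // 2
                since = np.where(have_prev, m - last_endo,
                                 m - np.maximum(entry, 0))
                ramp = np.minimum(
                    em_endo["ramp_slope"] * np.maximum(since - em_endo["ramp_start"], 0),
                    em_endo["ramp_cap"])
                lp = (em_endo["base_logit"] + em_endo["hiv"] * hiv
                      + em_endo["per_comorb"] * np.minimum(comorb, 2) + ramp)
                cand = at_risk & (rng.random(n) < expit(lp))
                cand &= ~(have_prev & (m - last_endo < K - band))
                deadline = np.where(have_prev, last_endo + K + band,
                                    baseline + grace)
                do_endo = at_risk & (cand | (m == deadline))
            else:
                since = m - np.where(last_endo > _NONE // 2, last_endo,
                                     np.maximum(entry, 0))
                ramp = np.minimum(
                    em_endo["ramp_slope"] * np.maximum(since - em_endo["ramp_start"], 0),
                    em_endo["ramp_cap"])
                lp = (em_endo["base_logit"] + em_endo["hiv"] * hiv
                      + em_endo["per_comorb"] * np.minimum(comorb, 2) + ramp)
                do_endo = at_risk & ((rng.random(n) < expit(lp))
                                     | (next_repeat == m))
            if do_endo.any():
                protects = do_endo & (m - last_endo > protect_washout)
                nscreen[protects] = np.minimum(nscreen[protects] + 1, protect_cap)
                last_endo[do_endo] = m
                idx = np.nonzero(do_endo)[0]
                if K is None:
                    rep = idx[rng.random(idx.size) < em_endo["repeat_prob"]]
                    next_repeat[rep] = m + rng.integers(2, 5, size=rep.size)
                    is_col = rng.random(idx.size) < em_endo["colonoscopy_frac"]
                    emit(idx, m, 1, np.where(is_col, _C_COL, _C_SIG))
                else:
                    emit(idx, m, 1, _C_COL)

            # --- cancers (mutually exclusive within a month) ---
            age_yr = m / 12.0
            h_col = (colon_static * ch["age_rr_per_year"] ** age_yr
                     * ch["per_comorb_rr"] ** np.minimum(comorb, 2)
                     * ch["screen_protect"] ** nscreen)
            h_oth = other_static * oh["age_rr_per_year"] ** age_yr
            h_anl = anal_static
            u = rng.random(n)
            colon_ev = at_risk & (u < h_col)
            other_ev = at_risk & ~colon_ev & (u < h_col + h_oth)
            anal_ev = at_risk & ~colon_ev & ~other_ev & (u < h_col + h_oth + h_anl)
            if colon_ev.any():
                colon_m[colon_ev] = m
                idx = np.nonzero(colon_ev)[0]
                ip = rng.random(idx.size) < ce["p_inpatient"]
                emit(idx[ip], m, 0, _C_COLCA)
                op = idx[~ip]
                emit(op, m, 1, _C_COLCA)
                defer(op, np.full(op.size, m + int(ce["op_confirm_lag"])), 1, _C_COLCA)
                extra = idx[rng.random(idx.size) < ce["op_repeat_rate"]]
                defer(extra, m + rng.integers(2, 7, size=extra.size), 1, _C_COLCA)
                anl = idx[rng.random(idx.size) < ce["p_anal_with_colon"]]
                # offsets 0-6: some fall inside the +/-3-month reclassification
                # window, some outside, exercising both branches downstream
                defer(anl, m + rng.integers(0, 7, size=anl.size), 1, _C_ANAL)
            if other_ev.any():
                other_m[other_ev] = m
                emit(np.nonzero(other_ev)[0], m, 1, _C_OTHER)
            if anal_ev.any():
                anal_m[anal_ev] = m
                emit(np.nonzero(anal_ev)[0], m, 1, _C_ANAL)
            cancer_done |= colon_ev | other_ev | anal_ev

            # --- death ---
            h_death = (death_static * dh["age_rr_per_year"] ** age_yr
                       * dh["per_comorb_rr"] ** np.minimum(comorb, 2))
            death_ev = active & (rng.random(n) < h_death)
            if death_ev.any():
                death_m[death_ev] = m
                alive[death_ev] = False
                emit(np.nonzero(death_ev)[0], m, 0, _C_DEATH)

        # --- comorbidity accrual: an age process, independent of coverage, so
        # the comorbidity mix at a given age does not depend on entry age.
        # Gains outside the enrollment span emit no claim here (the span filter
        # drops them); conditions present at entry are revealed by claims then.
        can_gain = alive & (comorb < cm["max_conditions"])
        p_gain = np.minimum(
            cm["monthly_gain"] * np.where(hiv == 1, cm["hiv_rr"], 1.0)
            * cm["per_existing_rr"] ** comorb, 0.95)
        gain = can_gain & (rng.random(n) < p_gain)
        if gain.any():
            comorb[gain] += 1
            idx = np.nonzero(gain)[0]
            emit(idx, m, 1, _C_COMORB_BASE + comorb[idx])

        # --- disenrollment (death takes precedence within the month) ---
        if disenroll:
            h_dis = dis_static * rh["per_comorb_rr"] ** np.minimum(comorb, 2)
            dis_ev = active & alive & (rng.random(n) < h_dis)
            if dis_ev.any():
                dis_m[dis_ev] = m
                enrolled[dis_ev] = False

    span_end = np.full(n, ADMIN_END_MONTH, dtype=np.int64)
    span_end = np.minimum(span_end, np.where(death_m > _NONE // 2, death_m, ADMIN_END_MONTH))
    span_end = np.minimum(span_end, np.where(dis_m > _NONE // 2, dis_m, ADMIN_END_MONTH))

    claims = None
    if collect_claims:
        # conditions already present at entry are revealed by claims at entry
        for kcond in range(1, int(cm["max_conditions"]) + 1):
            idx = np.nonzero(comorb_entry >= kcond)[0]
            emit(idx, entry[idx], 1, _C_COMORB_BASE + kcond)
        # HIV diagnosis claims near entry (IP, or two OP claims a month apart)
        hidx = np.nonzero(hiv == 1)[0]
        if hidx.size:
            ip = rng.random(hidx.size) < 0.5
            emit(hidx[ip], entry[hidx[ip]], 0, _C_HIV)
            op = hidx[~ip]
            emit(op, entry[op], 1, _C_HIV)
            defer(op, entry[op] + 1, 1, _C_HIV)
        # spurious lone outpatient claims in disease-free beneficiaries; at most
        # one per person per category, so they can never satisfy the 2-OP rule
        for code, has_true in ((_C_COLCA, colon_m > _NONE // 2),
                               (_C_HIV, hiv == 1)):
            cand = np.nonzero(~has_true & (span_end > entry))[0]
            pick = cand[rng.random(cand.size) < ce["spurious_op_rate"]]
            if pick.size:
                months = entry[pick] + (
                    rng.random(pick.size) * (span_end[pick] - entry[pick] + 1)
                ).astype(np.int64)
                emit(pick, months, 1, code)
        # pre-50 endoscopy (exclusion-rule exerciser; no hazard effect since
        # the affected beneficiaries are excluded from every cohort)
        pre = np.nonzero(entry < 0)[0]
        if pre.size:
            p50 = np.where(hiv[pre] == 1, em_endo["pre50_prob"][1],
                           em_endo["pre50_prob"][0])
            pick = pre[rng.random(pre.size) < p50]
            if pick.size:
                months = entry[pick] + (
                    rng.random(pick.size) * (-entry[pick])).astype(np.int64)
                emit(pick, np.minimum(months, -1), 1, _C_COL)

        parts_i = cl_i + df_i
        parts_m = cl_m + df_m
        parts_s = cl_s + df_s
        parts_c = cl_c + df_c
        if parts_i:
            ci = np.concatenate(parts_i)
            cmn = np.concatenate(parts_m)
            cs = np.concatenate(parts_s)
            cc = np.concatenate(parts_c)
            keep = (cmn >= entry[ci]) & (cmn <= span_end[ci])
            claims = (ci[keep], cmn[keep], cs[keep], cc[keep])
        else:
            claims = (np.array([], dtype=np.int64),) * 4

    return {
        "cov": cov, "hiv": hiv, "p_hiv": p_hiv, "entry": entry,
        "baseline": baseline, "colon_m": colon_m, "other_m": other_m,
        "anal_m": anal_m, "death_m": death_m, "dis_m": dis_m,
        "span_end": span_end, "nscreen": nscreen, "claims": claims,
    }


# ---------------------------------------------------------------------------
# public operations


def generate_population(params: GeneratorParams) -> SyntheticDataset:
    """Generate the three observable claims tables plus the hidden-truth table.

    Deterministic given ``params.seed``.  Diagnosis claims are emitted through
    the claim-emission model, so the 1-inpatient-or-2-outpatient rule is
    exercised both positively (true diagnoses) and negatively (spurious lone
    claims); death terminates the enrollment span and all later claims.
    """
    params.validate()
    n = params.n_beneficiaries
    rng = np.random.default_rng(params.seed)

    if n == 0:
        demo = pd.DataFrame(columns=["id", "birth_month", "sex", "race_ethnicity",
                                     "state", "period"])
        enr = pd.DataFrame(columns=["id", "span_start_month", "span_end_month",
                                    "full_benefits", "dual_enrolled"])
        clm = pd.DataFrame(columns=["id", "month", "setting", "category"])
        tru = pd.DataFrame(columns=_TRUTH_COLUMNS)
        return SyntheticDataset(demo, enr, clm, tru)

    sim = _simulate(params, rng, n, disenroll=True, collect_claims=True)
    cov, hiv, entry, span_end = sim["cov"], sim["hiv"], sim["entry"], sim["span_end"]
    ids = np.arange(n, dtype=np.int64)

    # calendar anchor: month (since 2001-01) of the 50th birthday, by period
    period_idx = pd.Series(cov["period"]).map(
        {"2001-2005": 0, "2006-2010": 1, "2011-2015": 2}).to_numpy()
    bday_cal = period_idx * 60 + rng.integers(0, 60, size=n)
    demo = pd.DataFrame({
        "id": ids,
        "birth_month": bday_cal - 600,
        "sex": cov["sex"],
        "race_ethnicity": cov["race"],
        "state": cov["state"],
        "period": cov["period"],
    })

    es = params.enrollment_structure
    dual = rng.random(n) < es["p_dual"]
    restricted = ~dual & (rng.random(n) < es["p_restricted_benefits"])
    enr_rows = [pd.DataFrame({
        "id": ids,
        "span_start_month": entry,
        "span_end_month": span_end,
        "full_benefits": ~restricted,
        "dual_enrolled": dual,
    })]
    prior = np.nonzero(rng.random(n) < es["p_short_prior_span"])[0]
    if prior.size:
        length = rng.integers(2, 7, size=prior.size)      # <= 6 months: never qualifies
        gap = rng.integers(2, 13, size=prior.size)
        start = entry[prior] - gap - length
        enr_rows.append(pd.DataFrame({
            "id": prior,
            "span_start_month": start,
            "span_end_month": start + length - 1,
            "full_benefits": True,
            "dual_enrolled": False,
        }))
    enr = (pd.concat(enr_rows, ignore_index=True)
           .sort_values(["id", "span_start_month"], kind="mergesort")
           .reset_index(drop=True))

    ci, cmn, cs, cc = sim["claims"]
    cats = np.array([
        _CODE_TO_CAT.get(code, f"COMORBID_{code - _C_COMORB_BASE}") for code in cc
    ], dtype=object)
    clm = pd.DataFrame({
        "id": ci,
        "month": cmn,
        "setting": np.where(cs == 0, SETTING_IP, SETTING_OP),
        "category": cats,
    }).sort_values(["id", "month", "category", "setting"],
                   kind="mergesort").reset_index(drop=True)

    tru = pd.DataFrame({
        "id": ids,
        "hiv": hiv,
        "entry_month": entry,
        "baseline_month": sim["baseline"],
        "colon_true_month": _clean(sim["colon_m"]),
        "other_true_month": _clean(sim["other_m"]),
        "anal_true_month": _clean(sim["anal_m"]),
        "death_month": _clean(sim["death_m"]),
        "disenroll_month": _clean(sim["dis_m"]),
        "n_screenings": sim["nscreen"],
    })
    return SyntheticDataset(demo, enr, clm, tru)


_TRUTH_COLUMNS = ["id", "hiv", "entry_month", "baseline_month", "colon_true_month",
                  "other_true_month", "anal_true_month", "death_month",
                  "disenroll_month", "n_screenings"]


def _clean(months: np.ndarray) -> np.ndarray:
    out = months.astype(float)
    out[months <= _NONE // 2] = np.nan
    return out


def true_counterfactual_risk(params: GeneratorParams, protocol, exposure: int,
                             n_sim: int, seed=None) -> RiskCurve:
    """Monte-Carlo per-protocol counterfactual risk curve for one exposure group.

    Simulates ``n_sim`` beneficiaries under the protocol-enforced screening
    regime (behavioural uptake at protocol-compatible times, screenings that
    would come sooner than K - b months after the previous one suppressed, and
    a screening forced at the last allowed month so that nobody ever deviates),
    with disenrollment disabled and death retained as a competing event.  It
    then computes the discrete cause-specific hazards on 3-month age bins with
    delayed entry and combines them with the Aalen-Johansen product-sum --
    precisely the estimand the weighted pipeline targets.  Covariates are
    drawn from their marginal distribution and reweighted by
    P(HIV = exposure | X), which samples the covariate mix of the requested
    exposure group without rejection.  Other primary cancers censor, as in the
    analysis.  Monte-Carlo error shrinks as 1/sqrt(n_sim).
    """
    params.validate()
    if n_sim < 1:
        raise ParameterError("n_sim must be >= 1")
    rng = np.random.default_rng(params.seed if seed is None else seed)
    sim = _simulate(params, rng, int(n_sim), force_hiv=exposure,
                    forced_protocol=protocol, disenroll=False,
                    collect_claims=True,
                    claim_filter={_C_COLCA, _C_ANAL, _C_OTHER})
    w = sim["p_hiv"] if exposure == 1 else 1.0 - sim["p_hiv"]

    # outcomes go through the same claims-diagnosis layer as the analysis:
    # the estimand is risk of *diagnosed* colon cancer, so emission misses and
    # the anal-cancer reclassification apply in the counterfactual world too
    from .cohort import ANAL_WINDOW, _diagnose_table
    ci, cmn, cs, cc = sim["claims"]
    clm = pd.DataFrame({
        "id": ci, "month": cmn,
        "setting": np.where(cs == 0, SETTING_IP, SETTING_OP),
        "category": pd.Series(cc).map(_CODE_TO_CAT).to_numpy(),
    })
    n = int(n_sim)
    big = float(ADMIN_END_MONTH + 1)
    def dx(cat, rule):
        s = _diagnose_table(clm, cat, rule)
        return s.reindex(range(n)).fillna(big).to_numpy()
    colon_ = dx(CAT_COLON_CA, "two_tier")
    anal_ = dx(CAT_ANAL_CA, "single")
    other_ = dx(CAT_OTHER_CA, "single")
    reclass = (colon_ < big) & (np.abs(anal_ - colon_) <= ANAL_WINDOW)
    other_eff = np.minimum(other_, anal_)
    other = np.where(reclass, colon_, other_eff)
    colon_ = np.where(reclass | ((other_eff < big) & (other_eff < colon_)),
                      big, colon_)

    baseline = sim["baseline"]
    death = sim["death_m"]
    death_ = np.where(death > _NONE // 2, death, big).astype(float)
    exit_m = np.minimum.reduce([colon_, other, death_,
                                np.full_like(colon_, ADMIN_END_MONTH)])
    # event precedence within a month: colon > other cancer > death
    code = np.zeros(exit_m.shape, dtype=np.int8)          # 0 = administrative
    code[exit_m == death_] = 3
    code[exit_m == other] = 2
    code[exit_m == colon_] = 1

    keep = exit_m > baseline                               # event-free at baseline
    entry_bin = (baseline[keep] // 3).astype(np.int64)
    exit_bin = np.minimum(exit_m[keep] // 3, N_BINS - 1).astype(np.int64)
    wk, ck = w[keep], code[keep]

    at_risk = np.zeros(N_BINS + 1)
    np.add.at(at_risk, entry_bin, wk)
    np.add.at(at_risk, exit_bin + 1, -wk)
    at_risk = np.cumsum(at_risk)[:N_BINS]
    ev_c = np.bincount(exit_bin[ck == 1], weights=wk[ck == 1], minlength=N_BINS)
    ev_d = np.bincount(exit_bin[ck == 3], weights=wk[ck == 3], minlength=N_BINS)
    with np.errstate(invalid="ignore", divide="ignore"):
        h_c = np.where(at_risk > 0, ev_c / np.maximum(at_risk, 1e-300), 0.0)
        h_d = np.where(at_risk > 0, ev_d / np.maximum(at_risk, 1e-300), 0.0)
    label = "with_hiv" if exposure == 1 else "without_hiv"
    return cumulative_incidence(h_c, h_d, group=f"truth_{label}")


def write_dataset(data: SyntheticDataset, directory) -> dict:
    """Write the observable tables plus the separate hidden-truth table as CSV.

    Returns the mapping of table name to file path; round-trips losslessly
    through :func:`screenpp.cohort.read_tables`.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, df in (("demographics", data.demographics),
                     ("enrollment", data.enrollment),
                     ("claims", data.claims),
                     ("hidden_truth", data.truth)):
        path = directory / f"{name}.csv"
        df.to_csv(path, index=False)
        paths[name] = path
    return paths
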