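"""Claims-based cohort construction: eligibility, baseline, diagnoses, exclusions.

Reproduces the standard administrative-claims workflow for a screening
emulation: find each beneficiary's first continuous full-benefit enrollment
period longer than 6 months, set the analytic baseline at the later of the
50th birthday (month 0) and 6 months after the eligibility start, ascertain
diagnoses with the 1-inpatient-or-2-outpatient-claims-within-2-years rule,
reclassify colon cancers with a nearby anal-cancer claim, apply the exclusion
cascade, and down-sample unexposed controls.

Conventions (month-resolution data): "within 2 years" for the two-outpatient
rule means a gap of at most 24 months inclusive; "within 90 days" for the anal
reclassification means +/-3 months inclusive; the diagnosis month is the first
claim of the qualifying pair.  Claims at months <= baseline count as
pre-baseline history.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import IntegrityError

ADMIN_END_MONTH = 180

TWO_TIER_WINDOW = 24   # months between the two outpatient claims, inclusive
ANAL_WINDOW = 3        # months around the colon diagnosis, inclusive

END_COLON = "colon_cancer"
END_OTHER = "other_cancer"
END_DEATH = "death"
END_DISENROLL = "disenrollment"
END_ADMIN = "administrative"

# exclusion reasons, in the fixed order in which they are assigned
EXCL_NO_SPAN = "no_qualifying_span"
EXCL_BASELINE_PAST_SPAN = "baseline_at_or_after_span_end"
EXCL_AGE_65 = "age_65_or_older_at_baseline"
EXCL_PRIOR_CANCER = "cancer_claim_before_baseline"
EXCL_PRE50_ENDO = "endoscopy_before_age_50"
EXCLUSION_ORDER = (EXCL_NO_SPAN, EXCL_BASELINE_PAST_SPAN, EXCL_AGE_65,
                   EXCL_PRIOR_CANCER, EXCL_PRE50_ENDO)


@dataclass
class EnrollmentSpan:
    beneficiary_id: int
    start: int
    end: int
    full_benefits: bool = True
    dual_enrolled: bool = False

    def __post_init__(self):
        if self.start > self.end:
            raise IntegrityError(
                f"span start {self.start} after end {self.end} "
                f"for beneficiary {self.beneficiary_id}")

    @property
    def length(self) -> int:
        """Covered months, inclusive of both endpoints."""
        return self.end - self.start + 1


@dataclass
class BaselineRecord:
    beneficiary_id: int
    baseline_month: int
    exposed: int
    sex: str
    race_ethnicity: str
    state: str
    period: str
    enrolled_before_50: bool
    followup_end_month: int
    end_reason: str

    def __post_init__(self):
        if not 0 <= self.baseline_month < self.followup_end_month:
            raise IntegrityError(
                f"baseline {self.baseline_month} not before follow-up end "
                f"{self.followup_end_month} for beneficiary {self.beneficiary_id}")


def read_tables(directory):
    """Read demographics.csv, enrollment.csv, claims.csv from a directory."""
    directory = Path(directory)
    demo = pd.read_csv(directory / "demographics.csv")
    enr = pd.read_csv(directory / "enrollment.csv")
    clm = pd.read_csv(directory / "claims.csv")
    for col in ("full_benefits", "dual_enrolled"):
        if enr[col].dtype != bool:
            enr[col] = enr[col].astype(str).str.lower().isin(["true", "1"])
    return demo, enr, clm


def first_eligibility_period(spans: list) -> Optional[EnrollmentSpan]:
    """Earliest maximal contiguous full-benefit, non-dual span of > 6 months.

    Back-to-back qualifying spans (next start = previous end + 1) are merged
    before the length test.  Overlapping spans are an input-integrity error.
    """
    spans = sorted(spans, key=lambda s: s.start)
    for a, b in zip(spans, spans[1:]):
        if b.start <= a.end:
            raise IntegrityError(
                f"overlapping enrollment spans for beneficiary {a.beneficiary_id}")
    merged = []
    for s in spans:
        if not (s.full_benefits and not s.dual_enrolled):
            continue
        if merged and s.start == merged[-1].end + 1:
            merged[-1] = EnrollmentSpan(s.beneficiary_id, merged[-1].start, s.end,
                                        True, False)
        else:
            merged.append(EnrollmentSpan(s.beneficiary_id, s.start, s.end, True, False))
    for s in merged:
        if s.length > 6:
            return s
    return None


def diagnose(claims: pd.DataFrame, category: str, rule: str = "two_tier"
             ) -> Optional[int]:
    """Diagnosis month for one beneficiary under the stated claims rule.

    two_tier: earliest month m with an inpatient claim at m, or two outpatient
    claims at m <= m' with m' - m <= 24 months (diagnosis at the first of the
    pair).  single: month of the first claim of the category.
    """
    sub = claims[claims["category"] == category]
    if sub.empty:
        return None
    months = np.sort(sub["month"].to_numpy())
    if rule == "single":
        return int(months[0])
    if rule != "two_tier":
        raise ValueError(f"unknown diagnosis rule {rule!r}")
    ip = np.sort(sub.loc[sub["setting"] == "IP", "month"].to_numpy())
    op = np.sort(sub.loc[sub["setting"] == "OP", "month"].to_numpy())
    best = None
    if ip.size:
        best = int(ip[0])
    if op.size >= 2:
        gaps_ok = (op[1:] - op[:-1]) <= TWO_TIER_WINDOW
        if gaps_ok.any():
            pair_month = int(op[:-1][gaps_ok][0])
            best = pair_month if best is None else min(best, pair_month)
    return best


def _diagnose_table(claims: pd.DataFrame, category: str, rule: str) -> pd.Series:
    """Vectorized ``diagnose`` across beneficiaries; Series id -> month."""
    sub = claims[claims["category"] == category]
    if sub.empty:
        return pd.Series(dtype=float)
    sub = sub.sort_values(["id", "month"], kind="mergesort")
    if rule == "single":
        return sub.groupby("id")["month"].min().astype(float)
    ip_first = (sub[sub["setting"] == "IP"].groupby("id")["month"].min())
    op = sub[sub["setting"] == "OP"]
    op_next = op.groupby("id")["month"].shift(-1)
    ok = (op_next - op["month"]) <= TWO_TIER_WINDOW
    op_pair = op[ok.fillna(False)].groupby("id")["month"].min()
    both = pd.concat([ip_first, op_pair], axis=1)
    return both.min(axis=1).dropna().astype(float)


def classify_first_cancer(colon_month, other_month, anal_month):
    """First-primary-cancer outcome with anal-cancer reclassification.

    A colon cancer with an anal-cancer diagnosis within +/-3 months (inclusive,
    either order) is reclassified as other cancer, keeping the colon diagnosis
    month.  Otherwise the earliest cancer wins; standalone anal cancer counts
    as other cancer; ties go to colon cancer.  Returns (label, month) with
    label in {colon_cancer, other_cancer} or (None, None).
    """
    if colon_month is not None and anal_month is not None \
            and abs(anal_month - colon_month) <= ANAL_WINDOW:
        return END_OTHER, colon_month
    other_eff = min((m for m in (other_month, anal_month) if m is not None),
                    default=None)
    if colon_month is None and other_eff is None:
        return None, None
    if other_eff is None or (colon_month is not None and colon_month <= other_eff):
        return END_COLON, colon_month
    return END_OTHER, other_eff


def sample_controls(unexposed_ids, fraction: float, seed: int) -> set:
    """Simple random sample (without replacement) of control beneficiaries.

    Keeps floor(fraction * n) ids; deterministic given the seed.  Exposed
    beneficiaries are always retained by the caller.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    ids = np.sort(np.asarray(list(unexposed_ids)))
    k = int(np.floor(fraction * ids.size))
    rng = np.random.default_rng(seed)
    return set(rng.choice(ids, size=k, replace=False).tolist())


def build_baseline(spans: list, claims: pd.DataFrame, demographics: dict,
                   admin_end: int = ADMIN_END_MONTH):
    """BaselineRecord for one beneficiary, or (None, exclusion reason).

    Baseline = max(month 0, eligibility start + 6).  Exclusions, in order: no
    qualifying span; baseline at/after span end; age >= 65 at baseline; any
    cancer-related claim at or before baseline; any endoscopy claim before
    month 0.  Follow-up ends at the first of colon cancer, other cancer,
    death, disenrollment (span end) and the administrative end, with tie
    precedence in that order.
    """
    if not demographics:
        raise IntegrityError("missing demographics for beneficiary")
    span = first_eligibility_period(spans)
    if span is None:
        return None, EXCL_NO_SPAN
    baseline = max(0, span.start + 6)
    if baseline >= span.end:
        return None, EXCL_BASELINE_PAST_SPAN
    if baseline >= admin_end:
        return None, EXCL_AGE_65

    cancer_claims = claims[claims["category"].isin(
        ["COLON_CA", "ANAL_CA", "OTHER_CA"])]
    if (cancer_claims["month"] <= baseline).any():
        return None, EXCL_PRIOR_CANCER
    endo = claims[claims["category"].isin(
        ["ENDO_COLONOSCOPY", "ENDO_SIGMOIDOSCOPY"])]
    if (endo["month"] < 0).any():
        return None, EXCL_PRE50_ENDO

    colon = diagnose(claims, "COLON_CA", "two_tier")
    other = diagnose(claims, "OTHER_CA", "single")
    anal = diagnose(claims, "ANAL_CA", "single")
    label, cancer_month = classify_first_cancer(colon, other, anal)
    death = diagnose(claims, "DEATH", "single")

    candidates = []
    if label is not None and cancer_month > baseline:
        candidates.append((cancer_month, 0 if label == END_COLON else 1, label))
    if death is not None:
        candidates.append((death, 2, END_DEATH))
    if span.end < admin_end:
        candidates.append((span.end, 3, END_DISENROLL))
    candidates.append((admin_end, 4, END_ADMIN))
    end_month, _, reason = min(candidates)

    hiv = diagnose(claims, "HIV", "two_tier")
    exposed = int(hiv is not None and hiv <= baseline)
    record = BaselineRecord(
        beneficiary_id=int(demographics["id"]),
        baseline_month=baseline,
        exposed=exposed,
        sex=demographics["sex"],
        race_ethnicity=demographics["race_ethnicity"],
        state=demographics["state"],
        period=demographics["period"],
        enrolled_before_50=span.start < 0,
        followup_end_month=int(end_month),
        end_reason=reason,
    )
    return record, None


def build_cohort(demographics: pd.DataFrame, enrollment: pd.DataFrame,
                 claims: pd.DataFrame, admin_end: int = ADMIN_END_MONTH,
                 control_fraction: float = 1.0, sampling_seed: int = 0):
    """Vectorized cohort construction over all beneficiaries.

    Returns (cohort, exclusions): one BaselineRecord-shaped row per retained
    beneficiary and one (id, reason) row per excluded beneficiary.  Exclusion
    reasons are mutually exclusive (first matching reason in the documented
    order).  ``control_fraction`` < 1 applies simple random sampling of the
    unexposed after all exclusions; exposed beneficiaries are always kept.
    """
    enr = enrollment.sort_values(["id", "span_start_month"], kind="mergesort")
    # overlap check within beneficiary
    nxt = enr.groupby("id")["span_start_month"].shift(-1)
    if ((nxt <= enr["span_end_month"]).fillna(False)).any():
        bad = enr.loc[(nxt <= enr["span_end_month"]).fillna(False), "id"].iloc[0]
        raise IntegrityError(f"overlapping enrollment spans for beneficiary {bad}")

    # merge back-to-back qualifying spans, then pick the first > 6 months
    q = enr[enr["full_benefits"] & ~enr["dual_enrolled"]].copy()
    prev_end = q.groupby("id")["span_end_month"].shift(1)
    new_block = (q["span_start_month"] != prev_end + 1) | prev_end.isna()
    q["block"] = new_block.groupby(q["id"]).cumsum()
    blocks = q.groupby(["id", "block"]).agg(
        start=("span_start_month", "min"), end=("span_end_month", "max")).reset_index()
    blocks = blocks[(blocks["end"] - blocks["start"] + 1) > 6]
    elig = blocks.sort_values(["id", "start"], kind="mergesort").groupby("id").first()

    demo = demographics.set_index("id")
    missing = elig.index.difference(demo.index)
    if len(missing):
        raise IntegrityError(f"missing demographics for beneficiary {missing[0]}")

    all_ids = demo.index.to_numpy()
    no_span = demo.index.difference(elig.index).to_numpy()
    df = demo.loc[elig.index].copy()
    df["span_start"] = elig["start"]
    df["span_end"] = elig["end"]
    df["baseline"] = np.maximum(0, df["span_start"] + 6)

    # claims-derived quantities
    colon = _diagnose_table(claims, "COLON_CA", "two_tier")
    other = _diagnose_table(claims, "OTHER_CA", "single")
    anal = _diagnose_table(claims, "ANAL_CA", "single")
    hiv = _diagnose_table(claims, "HIV", "two_tier")
    death = _diagnose_table(claims, "DEATH", "single")
    cancer_first_claim = (claims[claims["category"].isin(
        ["COLON_CA", "ANAL_CA", "OTHER_CA"])].groupby("id")["month"].min())
    endo_first_claim = (claims[claims["category"].isin(
        ["ENDO_COLONOSCOPY", "ENDO_SIGMOIDOSCOPY"])].groupby("id")["month"].min())
    for name, series in (("colon_dx", colon), ("other_dx", other), ("anal_dx", anal),
                         ("hiv_dx", hiv), ("death_m", death),
                         ("first_cancer_claim", cancer_first_claim),
                         ("first_endo_claim", endo_first_claim)):
        df[name] = series.reindex(df.index)

    # exclusion cascade, first matching reason wins
    reasons = pd.Series(index=pd.Index(all_ids, name="id"), dtype=object)
    reasons.loc[no_span] = EXCL_NO_SPAN
    in_df = df
    cond2 = in_df["baseline"] >= in_df["span_end"]
    cond3 = ~cond2 & (in_df["baseline"] >= admin_end)
    cond4 = ~cond2 & ~cond3 & (in_df["first_cancer_claim"] <= in_df["baseline"])
    cond5 = ~cond2 & ~cond3 & ~cond4.fillna(False) & (in_df["first_endo_claim"] < 0)
    for cond, why in ((cond2, EXCL_BASELINE_PAST_SPAN), (cond3, EXCL_AGE_65),
                      (cond4, EXCL_PRIOR_CANCER), (cond5, EXCL_PRE50_ENDO)):
        reasons.loc[cond[cond.fillna(False)].index] = why
    keep = df[~df.index.isin(reasons.dropna().index)].copy()

    # outcome classification (vectorized classify_first_cancer)
    colon_m = keep["colon_dx"].to_numpy()
    anal_m = keep["anal_dx"].to_numpy()
    other_m = keep["other_dx"].to_numpy()
    reclass = (~np.isnan(colon_m) & ~np.isnan(anal_m)
               & (np.abs(anal_m - colon_m) <= ANAL_WINDOW))
    other_eff = np.fmin(other_m, anal_m)
    cancer_month = np.where(reclass, colon_m, np.fmin(colon_m, other_eff))
    is_colon = (~reclass & ~np.isnan(colon_m)
                & (np.isnan(other_eff) | (colon_m <= other_eff)))

    big = float(admin_end + 10)
    cancer_month_f = np.where(np.isnan(cancer_month), big, cancer_month)
    cancer_month_f = np.where(cancer_month_f <= keep["baseline"].to_numpy(),
                              big, cancer_month_f)  # pre-baseline handled above
    death_f = np.where(np.isnan(keep["death_m"].to_numpy()), big,
                       keep["death_m"].to_numpy())
    span_end_f = keep["span_end"].to_numpy().astype(float)
    dis_f = np.where(span_end_f < admin_end, span_end_f, big)
    admin_f = np.full(len(keep), float(admin_end))
    stack = np.stack([
        np.where(is_colon, cancer_month_f, big),          # colon cancer
        np.where(~is_colon, cancer_month_f, big),          # other cancer
        death_f, dis_f, admin_f])
    end_month = stack.min(axis=0)
    reason_idx = stack.argmin(axis=0)  # argmin ties -> lowest index = precedence
    reason_names = np.array([END_COLON, END_OTHER, END_DEATH,
                             END_DISENROLL, END_ADMIN])

    cohort = pd.DataFrame({
        "id": keep.index.to_numpy(),
        "baseline_month": keep["baseline"].to_numpy().astype(np.int64),
        "exposed": ((~keep["hiv_dx"].isna())
                    & (keep["hiv_dx"] <= keep["baseline"])).astype(np.int64).to_numpy(),
        "sex": keep["sex"].to_numpy(),
        "race_ethnicity": keep["race_ethnicity"].to_numpy(),
        "state": keep["state"].to_numpy(),
        "period": keep["period"].to_numpy(),
        "enrolled_before_50": (keep["span_start"] < 0).to_numpy(),
        "followup_end_month": end_month.astype(np.int64),
        "end_reason": reason_names[reason_idx],
    }).reset_index(drop=True)

    if control_fraction < 1.0:
        controls = cohort.loc[cohort["exposed"] == 0, "id"]
        kept = sample_controls(controls, control_fraction, sampling_seed)
        dropped = set(controls) - kept
        cohort = cohort[~cohort["id"].isin(dropped)].reset_index(drop=True)

    exclusions = (reasons.dropna().rename("reason").reset_index()
                  .sort_values("id").reset_index(drop=True))
    return cohort, exclusions
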