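"""Screening identification, protocol-deviation censoring, 3-month discretization.

A screening protocol requires one endoscopy every k years with a bandwidth of
b months: writing K = 12k, consecutive screenings must fall K-b to K+b months
apart (21-27 months for the 2-year protocol).  Follow-up is artificially
censored at the first deviation:

(a) too late -- the beneficiary is observed for more than K + b months since
    the last screening (or, before the first screening, since baseline, with a
    configurable initiation grace defaulting to K + b) without a new screening;
(b) too soon -- a screening arrives less than K - b months after the previous
    screening (the first screening is exempt: baseline is not an endoscopy).

Endoscopies are classified as *screening* by a greedy left-to-right washout
scan: the first observed endoscopy is screening, and each later endoscopy is
screening only if more than ``washout_months`` (default 12; sensitivity 6)
have passed since the last *observed* endoscopy of any kind -- closer repeats
are taken to be diagnostic or follow-up procedures and are dropped.
Screenings observed after age 50 but before baseline advance the protocol
clock.

Follow-up is discretized into 3-month person-intervals on the age time scale
(bin t covers months [3t, 3t+3), i.e. ages [50 + t/4, 50 + (t+1)/4)); events
take precedence over censoring within a bin.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import IntegrityError, ParameterError
from .risk import (STATUS_ADMIN, STATUS_COLON, STATUS_DEATH, STATUS_DISENROLL,
                   STATUS_OTHER, STATUS_PROTOCOL)

N_BINS = 60
ADMIN_END_MONTH = 180

_REASON_TO_STATUS = {
    "colon_cancer": STATUS_COLON,
    "other_cancer": STATUS_OTHER,
    "death": STATUS_DEATH,
    "disenrollment": STATUS_DISENROLL,
    "administrative": STATUS_ADMIN,
}


@dataclass
class ProtocolSpec:
    """Cadence k in years (2, 4 or 10), bandwidth and washout in months."""

    cadence_years: int = 10
    bandwidth_months: int = 3
    washout_months: int = 12
    colonoscopy_only: bool = False
    initiation_grace_months: Optional[int] = None  # default: cadence + bandwidth

    def __post_init__(self):
        if self.cadence_years not in (2, 4, 10):
            raise ParameterError(f"cadence_years={self.cadence_years} not in {{2, 4, 10}}")
        if self.bandwidth_months >= 12 * self.cadence_years:
            raise ParameterError("bandwidth_months must be smaller than the cadence")
        if self.washout_months < 1:
            raise ParameterError("washout_months must be >= 1")

    @property
    def cadence_months(self) -> int:
        return 12 * self.cadence_years

    @property
    def grace_months(self) -> int:
        if self.initiation_grace_months is not None:
            return int(self.initiation_grace_months)
        return self.cadence_months + self.bandwidth_months


def screening_endoscopies(endoscopy_months: Sequence[int],
                          spec: ProtocolSpec) -> list:
    """Greedy washout scan over sorted endoscopy months -> screening months."""
    screenings = []
    last_observed = None
    for m in sorted(set(int(x) for x in endoscopy_months)):
        if last_observed is None or m - last_observed > spec.washout_months:
            screenings.append(m)
        last_observed = m
    return screenings


def protocol_censor_month(screenings: Sequence[int], baseline_month: int,
                          spec: ProtocolSpec) -> int:
    """Month of the first protocol deviation (always defined in the future).

    Screenings at or before baseline initialize the clock; the deviation month
    is the screening month for rule (b) and anchor + allowed + 1 for rule (a).
    """
    K, b = spec.cadence_months, spec.bandwidth_months
    grace = spec.grace_months
    screenings = sorted(int(s) for s in screenings)
    anchor, have_prev = baseline_month, False
    for s in screenings:
        if s <= baseline_month:
            anchor, have_prev = s, True
    allowed = K + b if have_prev else grace
    # a stale pre-baseline clock cannot censor before follow-up starts
    clamp = baseline_month + 1
    for s in screenings:
        if s <= baseline_month:
            continue
        if s - anchor > allowed:
            return max(anchor + allowed + 1, clamp)
        if have_prev and s - anchor < K - b:
            return s
        anchor, have_prev, allowed = s, True, K + b
    return max(anchor + allowed + 1, clamp)


def protocol_censor_time(screenings: Sequence[int], baseline_month: int,
                         spec: ProtocolSpec,
                         end_month: Optional[int] = None) -> Optional[int]:
    """3-month interval index of the protocol deviation, or None if it falls
    after the observed follow-up end."""
    month = protocol_censor_month(screenings, baseline_month, spec)
    if end_month is not None and month > end_month:
        return None
    return month // 3


def discretize(record, screenings: Sequence[int],
               comorbidity_gain_months: Sequence[int],
               censor_interval: Optional[int]) -> pd.DataFrame:
    """Person-intervals for one beneficiary (reference implementation).

    ``record`` is a mapping with the BaselineRecord fields.  The terminal
    status is set with precedence colon cancer > other-cancer censor > death >
    disenrollment censor > protocol censor > administrative censor within a
    bin; the comorbidity category (0, 1, >=2) reflects condition-gain claims
    strictly before each bin start.
    """
    baseline = int(record["baseline_month"])
    end = int(record["followup_end_month"])
    if baseline >= end:
        raise IntegrityError("baseline must precede follow-up end")
    entry_bin = baseline // 3
    end_bin = min(end // 3, N_BINS - 1)
    reason = record["end_reason"]
    status = _REASON_TO_STATUS[reason]
    if censor_interval is not None:
        if censor_interval < entry_bin:
            raise IntegrityError("protocol censor interval precedes entry")
        if censor_interval < end_bin:
            end_bin, status = censor_interval, STATUS_PROTOCOL
        elif censor_interval == end_bin and status == STATUS_ADMIN:
            status = STATUS_PROTOCOL
    t = np.arange(entry_bin, end_bin + 1)
    gains = np.sort(np.asarray(list(comorbidity_gain_months), dtype=float))
    comorb = np.minimum(np.searchsorted(gains, 3 * t, side="left"), 2)
    scr = np.sort(np.asarray(list(screenings), dtype=float))
    screened = (np.searchsorted(scr, 3 * t + 2, side="right")
                - np.searchsorted(scr, 3 * t, side="left")) > 0
    out = pd.DataFrame({
        "id": record["id"],
        "t": t,
        "age_start": 50.0 + 0.25 * t,
        "exposed": record["exposed"],
        "sex": record["sex"],
        "race_ethnicity": record["race_ethnicity"],
        "state": record["state"],
        "period": record["period"],
        "comorb_cat": comorb.astype(np.int64),
        "screened": screened,
        "status": 0,
    })
    out.loc[out.index[-1], "status"] = status
    return out


def build_person_intervals(cohort: pd.DataFrame, claims: pd.DataFrame,
                           spec: ProtocolSpec) -> pd.DataFrame:
    """Vectorized person-interval table for a whole cohort.

    Applies the washout scan, the protocol-deviation rule and the 3-month
    discretization to every beneficiary; returns the long-format table with
    one row per person-interval, sorted by (id, t).
    """
    endo_cats = ["ENDO_COLONOSCOPY"] if spec.colonoscopy_only else \
        ["ENDO_COLONOSCOPY", "ENDO_SIGMOIDOSCOPY"]
    ids = cohort["id"].to_numpy()
    baseline = cohort["baseline_month"].to_numpy()
    end = cohort["followup_end_month"].to_numpy()
    n = len(cohort)
    pos = pd.Series(np.arange(n), index=ids)

    endo = claims[claims["category"].isin(endo_cats) & (claims["month"] >= 0)
                  & claims["id"].isin(pos.index)]
    endo = endo.sort_values(["id", "month"], kind="mergesort")
    screen_months = {}     # person position -> np.array of screening months
    censor_month = baseline + spec.grace_months + 1   # never-screened rule (a)
    for pid, grp in endo.groupby("id")["month"]:
        p = pos.loc[pid]
        scr = [s for s in screening_endoscopies(grp.to_numpy(), spec)
               if s <= end[p]]
        screen_months[p] = np.asarray(scr, dtype=np.int64)
        censor_month[p] = protocol_censor_month(scr, baseline[p], spec)

    entry_bin = baseline // 3
    end_bin = np.minimum(end // 3, N_BINS - 1)
    status = (pd.Series(cohort["end_reason"]).map(_REASON_TO_STATUS)
              .to_numpy(dtype=np.int64))
    pc_bin = censor_month // 3
    if (pc_bin < entry_bin).any():
        raise IntegrityError("protocol censor interval precedes entry")
    cut = pc_bin < end_bin
    end_bin = np.where(cut, pc_bin, end_bin)
    status = np.where(cut, STATUS_PROTOCOL, status)
    status = np.where((pc_bin == end_bin) & (status == STATUS_ADMIN),
                      STATUS_PROTOCOL, status)

    # expand to rows
    length = end_bin - entry_bin + 1
    total = int(length.sum())
    person_row = np.repeat(np.arange(n), length)
    row_start = np.concatenate([[0], np.cumsum(length)[:-1]])
    t = (np.arange(total) - np.repeat(row_start, length)
         + np.repeat(entry_bin, length))
    status_col = np.zeros(total, dtype=np.int64)
    status_col[np.cumsum(length) - 1] = status

    # per-row comorbidity category: distinct-condition gains before bin start
    stride = 2048
    month_off = 256            # months range over [-60, 180]; keep keys positive
    com = claims[claims["category"].str.startswith("COMORBID")
                 & claims["id"].isin(pos.index)]
    gains = (com.groupby(["id", "category"])["month"].min()
             .reset_index())
    gain_keys = np.sort(pos.loc[gains["id"]].to_numpy() * stride
                        + gains["month"].to_numpy() + month_off)
    gain_base = np.searchsorted(gain_keys, person_row * stride)
    row_key = person_row * stride + 3 * t + month_off
    comorb = np.minimum(
        np.searchsorted(gain_keys, row_key, side="left") - gain_base, 2)

    # per-row screened-this-interval flag
    if screen_months:
        scr_p = np.concatenate([np.full(v.size, p)
                                for p, v in screen_months.items()])
        scr_m = np.concatenate(list(screen_months.values()))
        scr_keys = np.sort(scr_p * stride + scr_m + month_off)
        lo = np.searchsorted(scr_keys, row_key, side="left")
        hi = np.searchsorted(scr_keys, row_key + 2, side="right")
        screened = hi > lo
    else:
        screened = np.zeros(total, dtype=bool)

    take = lambda col: cohort[col].to_numpy()[person_row]  # noqa: E731
    return pd.DataFrame({
        "id": ids[person_row],
        "t": t,
        "age_start": 50.0 + 0.25 * t,
        "exposed": take("exposed"),
        "sex": take("sex"),
        "race_ethnicity": take("race_ethnicity"),
        "state": take("state"),
        "period": take("period"),
        "comorb_cat": comorb.astype(np.int64),
        "screened": screened,
        "status": status_col,
    })
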