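"""Weighted discrete-time competing-risks estimation on the age time scale.

Follow-up is discretized into 3-month age bins t = 0..59 (bin t covers ages
[50 + t/4, 50 + (t+1)/4)).  For each exposure group the cause-specific discrete
hazards of colon cancer and of death are estimated as weighted event counts
over weighted risk sets, and combined with the discrete Aalen-Johansen
product-sum:

    S(t)     = prod_{s<=t} (1 - h_c(s) - h_d(s))
    CIF_c(t) = sum_{s<=t} S(s-1) * h_c(s)        (death analogous)

Beneficiaries enter the risk set at their baseline age bin (delayed entry), so
risks are conditional on being alive and cancer-free at cohort entry.
Contrasts between exposure groups are reported as risk-difference and
risk-ratio functions; confidence bands come from a nonparametric bootstrap that
resamples beneficiaries, not person-intervals.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .errors import BootstrapError, IntegrityError

logger = logging.getLogger(__name__)

N_BINS = 60

# person-interval terminal status codes (shared with screenpp.protocol)
STATUS_AT_RISK = 0
STATUS_COLON = 1
STATUS_OTHER = 2
STATUS_DEATH = 3
STATUS_DISENROLL = 4
STATUS_PROTOCOL = 5
STATUS_ADMIN = 6


@dataclass
class RiskCurve:
    """Age-indexed cumulative incidence of colon cancer and death.

    ``age_grid`` holds the upper edge of each 3-month bin in years
    (50.25 ... 65.00).  Invariant: cif_cancer + cif_death + survival = 1 at
    every grid point.
    """

    age_grid: np.ndarray
    cif_cancer: np.ndarray
    cif_death: np.ndarray
    survival: np.ndarray
    group: str = ""
    ci_lower: dict = field(default_factory=dict)
    ci_upper: dict = field(default_factory=dict)

    def at_age(self, age: float, quantity: str = "cif_cancer") -> float:
        """Value of a quantity at the bin whose upper edge equals ``age``."""
        idx = int(np.argmin(np.abs(self.age_grid - age)))
        if abs(self.age_grid[idx] - age) > 1e-9:
            raise IntegrityError(f"age {age} is not a bin edge of this curve")
        return float(getattr(self, quantity)[idx])


@dataclass
class Contrast:
    """Risk difference (exposed - unexposed) and risk ratio by age."""

    age_grid: np.ndarray
    rd: np.ndarray
    rr: np.ndarray          # NaN where the unexposed risk is 0
    ci_lower: dict = field(default_factory=dict)
    ci_upper: dict = field(default_factory=dict)
    table: Optional[pd.DataFrame] = None


def weighted_hazards(status: np.ndarray, t: np.ndarray,
                     weights: Optional[np.ndarray] = None,
                     n_bins: int = N_BINS):
    """Per-bin cause-specific hazards (cancer, death) from person-interval rows.

    Every row is one person-interval in which the beneficiary was at risk at
    the bin start; ``status`` is 0 except in a beneficiary's final row.  Empty
    risk sets yield zero hazards (logged once).
    """
    status = np.asarray(status)
    t = np.asarray(t)
    if weights is None:
        weights = np.ones(status.shape, dtype=float)
    else:
        weights = np.asarray(weights, dtype=float)
        if (weights < 0).any():
            raise IntegrityError("negative weights in risk set")
    at_risk = np.bincount(t, weights=weights, minlength=n_bins)[:n_bins]
    ev_c = np.bincount(t[status == STATUS_COLON],
                       weights=weights[status == STATUS_COLON], minlength=n_bins)[:n_bins]
    ev_d = np.bincount(t[status == STATUS_DEATH],
                       weights=weights[status == STATUS_DEATH], minlength=n_bins)[:n_bins]
    empty = at_risk <= 0
    if empty.any():
        logger.debug("empty risk set in %d of %d bins", int(empty.sum()), n_bins)
    denom = np.where(empty, 1.0, at_risk)
    h_c = np.where(empty, 0.0, ev_c / denom)
    h_d = np.where(empty, 0.0, ev_d / denom)
    return h_c, h_d


def cumulative_incidence(h_cancer: np.ndarray, h_death: np.ndarray,
                         group: str = "") -> RiskCurve:
    """Discrete Aalen-Johansen product-sum from per-bin cause-specific hazards."""
    h_c = np.asarray(h_cancer, dtype=float)
    h_d = np.asarray(h_death, dtype=float)
    if ((h_c < 0) | (h_c > 1) | (h_d < 0) | (h_d > 1)).any():
        raise IntegrityError("hazards must lie in [0, 1]")
    if ((h_c + h_d) > 1 + 1e-12).any():
        raise IntegrityError("h_cancer + h_death exceeds 1 in some interval")
    n = h_c.size
    surv = np.cumprod(1.0 - h_c - h_d)
    s_prev = np.concatenate([[1.0], surv[:-1]])
    cif_c = np.cumsum(s_prev * h_c)
    cif_d = np.cumsum(s_prev * h_d)
    age_grid = 50.0 + 0.25 * np.arange(1, n + 1)
    return RiskCurve(age_grid=age_grid, cif_cancer=cif_c, cif_death=cif_d,
                     survival=surv, group=group)


REPORT_AGES = (55.0, 60.0, 65.0)


def contrast_curves(curve_exposed: RiskCurve, curve_unexposed: RiskCurve,
                    report_ages=REPORT_AGES) -> Contrast:
    """RD and RR functions plus a table at the requested report ages."""
    if (curve_exposed.age_grid.shape != curve_unexposed.age_grid.shape
            or not np.allclose(curve_exposed.age_grid, curve_unexposed.age_grid)):
        raise IntegrityError("age grids of the two curves do not match")
    r1, r0 = curve_exposed.cif_cancer, curve_unexposed.cif_cancer
    rd = r1 - r0
    with np.errstate(divide="ignore", invalid="ignore"):
        rr = np.where(r0 > 0, r1 / np.where(r0 > 0, r0, 1.0), np.nan)
    rows = []
    for age in report_ages:
        idx = int(np.argmin(np.abs(curve_exposed.age_grid - age)))
        if abs(curve_exposed.age_grid[idx] - age) > 1e-9:
            raise IntegrityError(f"report age {age} is not on the age grid")
        rows.append({"age": age, "risk_exposed": r1[idx], "risk_unexposed": r0[idx],
                     "rd": rd[idx], "rr": rr[idx]})
    return Contrast(age_grid=curve_exposed.age_grid, rd=rd, rr=rr,
                    table=pd.DataFrame(rows))


def published_contrast_check(rows: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic-consistency check of a published risk/contrast table.

    ``rows`` has columns ``risk_exposed``, ``risk_unexposed`` (percent, printed
    at 1 decimal), ``printed_rd`` and ``printed_rr``.  Recomputes RD and RR from
    the printed risks and reports, per row:

    - ``rr_consistent``: the printed RR lies within the interval attainable
      given that each printed risk is a 1-decimal rounding of the true value;
    - ``rd_rounding_flag``: the recomputed RD differs from the printed RD in
      the last printed digit, but the printed RD is attainable under the same
      rounding of the inputs -- a flag, not an error.
    """
    out = rows.copy()
    r1, r0 = out["risk_exposed"].to_numpy(), out["risk_unexposed"].to_numpy()
    out["rd_computed"] = r1 - r0
    out["rr_computed"] = r1 / r0
    lo1, hi1 = r1 - 0.05, r1 + 0.05
    lo0, hi0 = r0 - 0.05, r0 + 0.05
    rr_lo, rr_hi = lo1 / hi0, hi1 / np.maximum(lo0, 1e-12)
    rr_round = out["printed_rr"].round(2)
    out["rr_consistent"] = ((np.round(rr_lo, 2) - 1e-9 <= rr_round)
                            & (rr_round <= np.round(rr_hi, 2) + 1e-9))
    rd_lo, rd_hi = lo1 - hi0, hi1 - lo0
    printed_rd = out["printed_rd"].to_numpy()
    mismatch = np.abs(np.round(out["rd_computed"], 1) - printed_rd) > 1e-9
    attainable = (rd_lo - 1e-9 <= printed_rd) & (printed_rd <= rd_hi + 1e-9)
    out["rd_rounding_flag"] = mismatch & attainable
    out["rd_inconsistent"] = mismatch & ~attainable
    return out


def bootstrap_ci(estimate_fn: Callable[[pd.DataFrame], dict],
                 data: pd.DataFrame, reps: int = 200, seed: int = 0,
                 level: float = 95.0, id_col: str = "id",
                 max_failure_frac: float = 0.2) -> dict:
    """Percentile bootstrap bands, resampling beneficiaries with replacement.

    ``estimate_fn`` maps a resampled person-interval table to a dict of named
    arrays (risk curves, RD/RR functions...).  Replicates that raise are logged
    and skipped; more than ``max_failure_frac`` failures aborts.  Deterministic
    given ``seed``.
    """
    if reps < 2:
        raise IntegrityError("bootstrap needs reps >= 2")
    rng = np.random.default_rng(seed)
    ids = data[id_col].to_numpy()
    uniq, inverse = np.unique(ids, return_inverse=True)
    order = np.argsort(inverse, kind="stable")
    counts = np.bincount(inverse, minlength=uniq.size)
    starts = np.concatenate([[0], np.cumsum(counts)])
    samples, failures = [], 0
    for _ in range(reps):
        pick = rng.integers(0, uniq.size, size=uniq.size)
        row_idx = np.concatenate([order[starts[p]:starts[p + 1]] for p in pick])
        boot = data.iloc[row_idx].copy()
        # fresh person key so duplicated beneficiaries stay distinct blocks
        boot["_bid"] = np.repeat(np.arange(pick.size), counts[pick])
        try:
            samples.append(estimate_fn(boot))
        except Exception as exc:  # noqa: BLE001 - replicate failures are data-driven
            failures += 1
            logger.warning("bootstrap replicate failed: %s", exc)
    if failures > max_failure_frac * reps:
        raise BootstrapError(f"{failures}/{reps} bootstrap replicates failed")
    if failures:
        logger.info("bootstrap: %d/%d replicates failed and were skipped",
                    failures, reps)
    alpha = (100.0 - level) / 2.0
    bands = {}
    import warnings as _warnings
    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)
        for key in samples[0]:
            stacked = np.stack([np.asarray(s[key], dtype=float)
                                for s in samples])
            bands[key] = {
                "lower": np.nanpercentile(stacked, alpha, axis=0),
                "upper": np.nanpercentile(stacked, 100.0 - alpha, axis=0),
            }
    bands["_n_failed"] = failures
    return bands


def run_stratified(data: pd.DataFrame, stratum_col: str,
                   estimate_fn: Callable[[pd.DataFrame], dict]) -> dict:
    """Run the full estimation per stratum (weights are refit within stratum)."""
    results = {}
    for level, sub in data.groupby(stratum_col, observed=True):
        if len(sub) == 0:
            logger.info("stratum %s=%r is empty; skipped", stratum_col, level)
            continue
        try:
            results[level] = estimate_fn(sub.reset_index(drop=True))
        except Exception as exc:  # noqa: BLE001
            logger.warning("stratum %s=%r failed: %s", stratum_col, level, exc)
    return results


def plot_risk_curves(curves: dict, path, title: str = "") -> None:
    """Plain risk-curve plot: solid = colon cancer, dashed = death, per group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    for label, curve in curves.items():
        line, = ax.plot(curve.age_grid, 100 * curve.cif_cancer, label=f"{label}: colon cancer")
        ax.plot(curve.age_grid, 100 * curve.cif_death, linestyle="--",
                color=line.get_color(), label=f"{label}: death")
        if "cif_cancer" in curve.ci_lower:
            ax.fill_between(curve.age_grid, 100 * curve.ci_lower["cif_cancer"],
                            100 * curve.ci_upper["cif_cancer"],
                            color=line.get_color(), alpha=0.2)
    ax.set_xlabel("Age (years)")
    ax.set_ylabel("Cumulative incidence (%)")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
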