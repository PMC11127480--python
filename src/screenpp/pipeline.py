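"""End-to-end orchestration: generate -> cohort -> protocol -> weights -> risks.

`PerProtocolAnalysis` is the workhorse estimator: it pre-builds all design
matrices from a person-interval table once, then re-estimates weights and
weighted cumulative incidence for arbitrary beneficiary resamples, which makes
beneficiary-level bootstrap confidence bands affordable.  `run` wires the full
pipeline from a declarative `RunConfig` and writes every intermediate table
plus a manifest, deterministically for a fixed configuration.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from . import cohort as cohort_mod
from . import ipw, risk, synthetic_claims
from .errors import ConfigError
from .protocol import ProtocolSpec, build_person_intervals

logger = logging.getLogger(__name__)

REPORT_AGES = (55.0, 60.0, 65.0)


class PerProtocolAnalysis:
    """Weighted per-protocol risk estimation with fast beneficiary resampling.

    The person-interval table must be sorted by (id, t).  ``estimate`` refits
    the exposure model and the four censoring models (protocol/disenrollment x
    exposure stratum) on the requested beneficiary sample and returns risk
    curves and contrasts; ``estimate(weighted=False)`` gives the unweighted
    protocol-censored estimator on the same risk sets.
    """

    def __init__(self, intervals: pd.DataFrame,
                 wspec: Optional[ipw.WeightModelSpec] = None):
        wspec = wspec or ipw.WeightModelSpec()
        self.wspec = wspec
        intervals = intervals.sort_values(["id", "t"], kind="mergesort") \
            .reset_index(drop=True)
        self.intervals = intervals
        ids = intervals["id"].to_numpy()
        starts = np.empty(len(ids), dtype=bool)
        if len(ids):
            starts[0] = True
            starts[1:] = ids[1:] != ids[:-1]
        self.block_starts = starts
        start_idx = np.nonzero(starts)[0]
        self.person_start = start_idx
        self.person_stop = np.append(start_idx[1:], len(ids))
        self.n_persons = start_idx.size

        self.t = intervals["t"].to_numpy()
        self.status = intervals["status"].to_numpy()
        self.exposed_row = intervals["exposed"].to_numpy()
        baseline = intervals.loc[starts]
        self.exposed_person = baseline["exposed"].to_numpy().astype(float)

        exp_levels = ipw.infer_levels(baseline, ipw.EXPOSURE_COVARIATES)
        self.Xb, self.xb_names = ipw.build_design(
            baseline, ipw.EXPOSURE_COVARIATES, exp_levels)
        cen_levels = ipw.infer_levels(intervals, wspec.denominator_covariates)
        self.Xd, self.xd_names = ipw.build_design(
            intervals, wspec.denominator_covariates, cen_levels, wspec.time_spec)
        self.Xn, self.xn_names = ipw.build_design(
            intervals, wspec.numerator_covariates, cen_levels, wspec.time_spec)
        self.y_prot = (self.status == risk.STATUS_PROTOCOL).astype(float)
        self.y_dis = (self.status == risk.STATUS_DISENROLL).astype(float)
        self._warm = {}

    # -- internals --------------------------------------------------------
    def _rows_for(self, person_pick: Optional[np.ndarray]):
        if person_pick is None:
            n_rows = len(self.t)
            return np.arange(n_rows), self.block_starts
        lengths = self.person_stop[person_pick] - self.person_start[person_pick]
        total = int(lengths.sum())
        if total == 0:
            return np.array([], dtype=int), np.array([], dtype=bool)
        first = np.concatenate([[0], np.cumsum(lengths)[:-1]])
        rows = (np.repeat(self.person_start[person_pick], lengths)
                + np.arange(total) - np.repeat(first, lengths))
        starts = np.zeros(total, dtype=bool)
        starts[first] = True
        return rows, starts

    def _weights(self, rows, starts, person_pick):
        wspec = self.wspec
        pick = np.arange(self.n_persons) if person_pick is None else person_pick
        exposed_p = self.exposed_person[pick]
        full_fit = person_pick is None
        beta_b = ipw.fit_logit(self.Xb[pick], exposed_p,
                               beta0=self._warm.get("exposure"),
                               names=self.xb_names)
        if full_fit:
            self._warm["exposure"] = beta_b
        p1 = expit(self.Xb[pick] @ beta_b)
        p_own = np.where(exposed_p == 1, p1, 1.0 - p1)
        if (p_own <= 0).any():
            raise ipw.PositivityError("zero exposure probability in resample")
        marg = exposed_p.mean()
        w_exp_p = np.where(exposed_p == 1, marg, 1.0 - marg) / p_own
        person_of_row = np.cumsum(starts) - 1
        w_exp = w_exp_p[person_of_row]

        ratio_prot = np.ones(rows.size)
        ratio_dis = np.ones(rows.size)
        exp_row = self.exposed_row[rows]
        for label, y_all, out in (("prot", self.y_prot, ratio_prot),
                                  ("dis", self.y_dis, ratio_dis)):
            for g in (0, 1):
                mask = exp_row == g
                if not mask.any():
                    continue
                rsub = rows[mask]
                y = y_all[rsub]
                if y.sum() == 0:
                    continue
                key_d, key_n = f"{label}_d{g}", f"{label}_n{g}"
                bd = ipw.fit_logit(self.Xd[rsub], y,
                                   beta0=self._warm.get(key_d),
                                   names=self.xd_names)
                bn = ipw.fit_logit(self.Xn[rsub], y,
                                   beta0=self._warm.get(key_n),
                                   names=self.xn_names)
                if full_fit:  # warm starts come from full-data fits only
                    self._warm[key_d], self._warm[key_n] = bd, bn
                p_unc_d = 1.0 - expit(self.Xd[rsub] @ bd)
                p_unc_n = 1.0 - expit(self.Xn[rsub] @ bn)
                if (p_unc_d <= 0).any():
                    raise ipw.PositivityError(
                        "censoring model predicts zero uncensored probability")
                out[mask] = p_unc_n / p_unc_d
        w_adh = ipw.segmented_cumprod(ratio_prot, starts)
        w_dis = ipw.segmented_cumprod(ratio_dis, starts)
        combined = w_exp * w_adh * w_dis
        truncated, trunc = ipw.truncate_weights(
            combined, self.wspec.truncation_percentile)
        report = {"mean_exposure_weight": float(w_exp_p.mean()),
                  "truncation": trunc,
                  "components": {"exposure": w_exp, "adherence": w_adh,
                                 "disenrollment": w_dis, "combined": combined}}
        return truncated, report

    # -- public -----------------------------------------------------------
    def estimate(self, person_pick: Optional[np.ndarray] = None,
                 weighted: bool = True, full_output: bool = False):
        """Risk curves per exposure group and their contrast.

        Returns a flat dict of arrays (bootstrap-friendly); with
        ``full_output`` also RiskCurve/Contrast objects and the weight report.
        """
        rows, starts = self._rows_for(person_pick)
        if weighted:
            w, report = self._weights(rows, starts, person_pick)
        else:
            w, report = np.ones(rows.size), {}
        curves = {}
        for g in (0, 1):
            mask = self.exposed_row[rows] == g
            h_c, h_d = risk.weighted_hazards(self.status[rows][mask],
                                             self.t[rows][mask], w[mask])
            curves[g] = risk.cumulative_incidence(
                h_c, h_d, group="with_hiv" if g else "without_hiv")
        contrast = risk.contrast_curves(curves[1], curves[0], REPORT_AGES)
        out = {
            "risk_cancer_exposed": curves[1].cif_cancer,
            "risk_cancer_unexposed": curves[0].cif_cancer,
            "risk_death_exposed": curves[1].cif_death,
            "risk_death_unexposed": curves[0].cif_death,
            "rd": contrast.rd,
            "rr": contrast.rr,
        }
        if full_output:
            return {"arrays": out, "curves": curves, "contrast": contrast,
                    "weight_report": report}
        return out

    def bootstrap(self, reps: int = 200, seed: int = 0, level: float = 95.0,
                  weighted: bool = True, max_failure_frac: float = 0.2):
        """Percentile bootstrap over beneficiaries; deterministic given seed."""
        if reps < 2:
            raise ValueError("bootstrap needs reps >= 2")
        if weighted and not self._warm:
            self.estimate()          # seed replicate warm starts once
        rng = np.random.default_rng(seed)
        samples, failures = [], 0
        for _ in range(reps):
            pick = rng.integers(0, self.n_persons, size=self.n_persons)
            try:
                samples.append(self.estimate(pick, weighted=weighted))
            except Exception as exc:  # noqa: BLE001
                failures += 1
                logger.warning("bootstrap replicate failed: %s", exc)
        if failures > max_failure_frac * reps:
            raise risk.BootstrapError(f"{failures}/{reps} replicates failed")
        alpha = (100.0 - level) / 2.0
        bands = {}
        import warnings
        with warnings.catch_warnings():
            # risk ratios are NaN wherever the reference risk is still 0
            warnings.simplefilter("ignore", RuntimeWarning)
            for key in samples[0]:
                stacked = np.stack([s[key] for s in samples])
                bands[key] = {
                    "lower": np.nanpercentile(stacked, alpha, axis=0),
                    "upper": np.nanpercentile(stacked, 100 - alpha, axis=0)}
        bands["_n_failed"] = failures
        return bands


# ---------------------------------------------------------------------------
# configuration


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results"
    input_dir: Optional[str] = None
    generator: dict = field(default_factory=dict)    # GeneratorParams overrides
    protocols: list = field(default_factory=lambda: [2, 10])
    bandwidth_months: int = 3
    washout_months: int = 12
    colonoscopy_only: bool = False
    initiation_grace_months: Optional[int] = None
    control_fraction: float = 0.25
    sampling_seed: Optional[int] = None
    bootstrap_reps: int = 0
    bootstrap_seed: Optional[int] = None
    strata: list = field(default_factory=list)
    truncation_percentile: float = 99.5
    time_spec: str = "quadratic"
    write_plots: bool = False


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def validate_config(raw) -> RunConfig:
    """Validate a raw config mapping (or YAML text); report every violation.

    Raises ConfigError carrying the full list of problems; never fails on the
    first one.
    """
    if isinstance(raw, str):
        import yaml
        raw = yaml.safe_load(raw) or {}
    errors = []
    unknown = set(raw) - _CONFIG_FIELDS
    if unknown:
        errors.append(f"unknown config keys: {sorted(unknown)}")
    cfg = RunConfig(**{k: v for k, v in raw.items() if k in _CONFIG_FIELDS})
    if "seed" not in raw:
        errors.append("seed must be given explicitly (no wall-clock seeding)")
    for k in cfg.protocols:
        if k not in (2, 4, 10):
            errors.append(f"protocols: cadence {k} not in {{2, 4, 10}}")
        elif cfg.bandwidth_months >= 12 * k:
            errors.append(f"bandwidth_months={cfg.bandwidth_months} must be "
                          f"smaller than the cadence ({12 * k} months)")
    if cfg.washout_months < 1:
        errors.append("washout_months must be >= 1")
    if not 0 < cfg.control_fraction <= 1:
        errors.append("control_fraction must be in (0, 1]")
    if not 50 < cfg.truncation_percentile <= 100:
        errors.append("truncation_percentile must be in (50, 100]")
    if cfg.bootstrap_reps < 0:
        errors.append("bootstrap_reps must be >= 0")
    if cfg.input_dir is not None and str(Path(cfg.out_dir).resolve()) == \
            str(Path(cfg.input_dir).resolve()):
        errors.append("out_dir must differ from input_dir")
    for s in cfg.strata:
        if s not in ("sex", "race_ethnicity", "period"):
            errors.append(f"strata: unknown stratum {s!r}")
    if errors:
        raise ConfigError(errors)
    return cfg


# ---------------------------------------------------------------------------
# full run


def _curves_frame(curves: dict, bands=None) -> pd.DataFrame:
    frames = []
    for g, curve in curves.items():
        df = pd.DataFrame({
            "group": curve.group,
            "age": curve.age_grid,
            "risk_cancer": curve.cif_cancer,
            "risk_death": curve.cif_death,
            "survival": curve.survival,
        })
        if bands is not None:
            tag = "exposed" if g == 1 else "unexposed"
            df["risk_cancer_lo"] = bands[f"risk_cancer_{tag}"]["lower"]
            df["risk_cancer_hi"] = bands[f"risk_cancer_{tag}"]["upper"]
            df["risk_death_lo"] = bands[f"risk_death_{tag}"]["lower"]
            df["risk_death_hi"] = bands[f"risk_death_{tag}"]["upper"]
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def _contrast_frame(contrast, bands=None) -> pd.DataFrame:
    df = pd.DataFrame({"age": contrast.age_grid, "rd": contrast.rd,
                       "rr": contrast.rr})
    if bands is not None:
        df["rd_lo"], df["rd_hi"] = bands["rd"]["lower"], bands["rd"]["upper"]
        df["rr_lo"], df["rr_hi"] = bands["rr"]["lower"], bands["rr"]["upper"]
    return df


def run(config: RunConfig) -> dict:
    """Execute the whole pipeline per the configuration; write tables+manifest.

    Re-running with an identical configuration produces identical outputs.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": dataclasses.asdict(config), "stages": {}}
    try:
        if config.input_dir:
            demo, enr, clm = cohort_mod.read_tables(config.input_dir)
        else:
            params = synthetic_claims.GeneratorParams(
                seed=config.seed).replace(**config.generator)
            data = synthetic_claims.generate_population(params)
            synthetic_claims.write_dataset(data, out / "synthetic")
            demo, enr, clm = data.demographics, data.enrollment, data.claims
        manifest["stages"]["input"] = {"beneficiaries": int(len(demo)),
                                       "claims": int(len(clm))}

        sampling_seed = config.sampling_seed if config.sampling_seed is not None \
            else config.seed + 1
        cohort, exclusions = cohort_mod.build_cohort(
            demo, enr, clm, control_fraction=config.control_fraction,
            sampling_seed=sampling_seed)
        cohort.to_csv(out / "cohort.csv", index=False)
        exclusions.to_csv(out / "exclusions.csv", index=False)
        manifest["stages"]["cohort"] = {
            "analyzed": int(len(cohort)),
            "exposed": int(cohort["exposed"].sum()),
            "excluded_by_reason":
                exclusions["reason"].value_counts().sort_index().to_dict(),
        }

        wspec = ipw.WeightModelSpec(
            truncation_percentile=config.truncation_percentile,
            time_spec=config.time_spec)
        results = {}
        for k in config.protocols:
            spec = ProtocolSpec(
                cadence_years=k, bandwidth_months=config.bandwidth_months,
                washout_months=config.washout_months,
                colonoscopy_only=config.colonoscopy_only,
                initiation_grace_months=config.initiation_grace_months)
            intervals = build_person_intervals(cohort, clm, spec)
            intervals.to_csv(out / f"person_intervals_k{k}.csv", index=False)
            analysis = PerProtocolAnalysis(intervals, wspec)
            est = analysis.estimate(full_output=True)
            weights = pd.DataFrame({
                "id": analysis.intervals["id"], "t": analysis.intervals["t"],
                **{name: est["weight_report"]["components"][comp]
                   for name, comp in (("exposure_weight", "exposure"),
                                      ("adherence_weight", "adherence"),
                                      ("disenrollment_weight", "disenrollment"),
                                      ("combined_weight", "combined"))}})
            weights.to_csv(out / f"weights_k{k}.csv", index=False)
            combined = est["weight_report"]["components"]["combined"]
            trunc = est["weight_report"]["truncation"]
            report_lines = [
                f"protocol: endoscopy every {k} years",
                f"mean stabilized exposure weight: "
                f"{est['weight_report']['mean_exposure_weight']:.4f}",
                "combined weight percentiles:",
            ] + [f"  p{q}: {np.percentile(combined, q):.4f}"
                 for q in (1, 50, 99, 99.5)] + [
                f"  max: {combined.max():.4f}",
                f"truncation: percentile {trunc['percentile']}, "
                f"cut {trunc['cut']}, rows affected {trunc['n_truncated']}",
            ]
            (out / f"weight_report_k{k}.txt").write_text(
                "\n".join(report_lines) + "\n")
            bands = None
            if config.bootstrap_reps >= 2:
                boot_seed = config.bootstrap_seed if config.bootstrap_seed \
                    is not None else config.seed + 2
                bands = analysis.bootstrap(config.bootstrap_reps, boot_seed)
            _curves_frame(est["curves"], bands).to_csv(
                out / f"results_risks_k{k}.csv", index=False)
            _contrast_frame(est["contrast"], bands).to_csv(
                out / f"results_contrasts_k{k}.csv", index=False)
            if config.write_plots:
                risk.plot_risk_curves(
                    {c.group: c for c in est["curves"].values()},
                    out / f"risk_curves_k{k}.png",
                    title=f"Endoscopy every {k} years")
            stratum_results = {}
            for stratum in config.strata:
                for level, sub in cohort.groupby(stratum):
                    sub_int = build_person_intervals(sub.reset_index(drop=True),
                                                     clm, spec)
                    if sub_int.empty or sub_int["exposed"].nunique() < 2:
                        logger.info("stratum %s=%r skipped", stratum, level)
                        continue
                    sub_est = PerProtocolAnalysis(sub_int, wspec).estimate(
                        full_output=True)
                    tag = f"{stratum}={level}"
                    stratum_results[tag] = sub_est
                    _curves_frame(sub_est["curves"]).to_csv(
                        out / f"results_risks_k{k}_{stratum}_{level}.csv",
                        index=False)
            manifest["stages"][f"protocol_k{k}"] = {
                "person_intervals": int(len(intervals)),
                "protocol_censored":
                    int((intervals["status"] == risk.STATUS_PROTOCOL).sum()),
                "colon_events": int((intervals["status"] == risk.STATUS_COLON).sum()),
                "mean_exposure_weight":
                    est["weight_report"]["mean_exposure_weight"],
            }
            results[k] = {"estimate": est, "bands": bands,
                          "strata": stratum_results}
    except Exception as exc:
        manifest["failed_stage"] = repr(exc)
        (out / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True, default=str))
        raise
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return {"manifest": manifest, "results": results,
            "cohort": cohort, "exclusions": exclusions}
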