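"""End-to-end synthetic study: simulate → synthesize → analyze → infer.

``run_study`` reproduces the structure of the three-load within-subject
experiment: every subject completes a 180-s multitasking run in each load
condition (order counterbalanced by Latin-square rotation), yields a behavior
log, an RR series, an 8-channel fNIRS recording, and a NASA-TLX sheet; the
analysis chain turns these into per-subject × per-condition measures, and the
inferential layer runs one repeated-measures ANOVA with Bonferroni post-hocs
per measure plus the cross-family Pearson correlations within each condition.

Load couplings are explicit synthesis parameters (heart-rate slope in
bpm/step, activation slope in μM/step, tracking-noise slope in mm·s^-1/2 per
step, per-dimension NASA-TLX slopes); zeroing them all (and freezing the task
set at the low-load configuration) yields an exact null study for type-I
calibration.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._streams import STAGE_BEHAVIOR, STAGE_FNIRS, STAGE_RR, STAGE_TLX, child_seed, rng_from
from .errors import StageError, ValidationError
from .fnirs_glm import estimate_activation
from .hemodynamics import HRFParams
from .hrv_features import extract_features
from .nasa_tlx import ALL_PAIRS, DIMENSIONS, TLXRating, compute_weights, weighted_score
from .optics import OpticsConfig
from .physio_synth import AutonomicParams, NoiseModel, add_noise, synthesize_activation, synthesize_rr
from .snirf_io import read_snirf, write_snirf  # re-exported study I/O surface
from .task_engine import (CONDITIONS, OperatorProfile, TaskConfig,
                          score_performance, simulate_session)
from .workload_stats import (RepeatedMeasuresTable, bonferroni_pairwise,
                             pearson_corr, rm_anova_oneway)

__all__ = ["StudyConfig", "StudyResults", "run_study", "make_report",
           "write_snirf", "read_snirf", "ANOVA_MEASURES", "MEASURE_FAMILIES"]

ANOVA_MEASURES = ("tlx_total", "avg_distance_mm", "n_alarms", "n_numeral_responses",
                  "mean_hr_bpm", "sdnn_ms", "rmssd_ms", "lf_hf", "mean_beta")

# correlation families: ECG-internal and performance-internal pairings are
# excluded from the correlation analysis
MEASURE_FAMILIES = {
    "tlx_total": "subjective",
    "avg_distance_mm": "performance", "n_alarms": "performance",
    "n_numeral_responses": "performance",
    "mean_hr_bpm": "ecg", "sdnn_ms": "ecg", "rmssd_ms": "ecg", "lf_hf": "ecg",
    "mean_beta": "brain",
}

# NASA-TLX synthesis: latent rating = base + slope·load + subject intercept + noise
_TLX_DIMENSION_PARAMS = {
    "md": (35.0, 18.0), "pd": (20.0, 4.0), "td": (30.0, 20.0),
    "op": (40.0, 8.0), "ef": (45.0, 6.0), "fr": (25.0, 5.0),
}


@dataclass(frozen=True)
class StudyConfig:
    """All tunables of one synthetic study (defaults = the modeled protocol)."""

    n_subjects: int = 26
    conditions: tuple = CONDITIONS
    run_duration_s: float = 180.0
    rest_s: float = 60.0
    tick_hz: float = 20.0
    root_seed: int = 0

    # operator (population means; per-subject lognormal variation below)
    operator: OperatorProfile = field(default_factory=OperatorProfile)
    operator_noise_cv: float = 0.15      # between-subject sd of log tracking noise
    operator_latency_cv: float = 0.10
    tracking_noise_load_slope: float = 2.0   # mm/sqrt(s) per load step

    # autonomic model
    autonomic: AutonomicParams = field(default_factory=AutonomicParams)
    mean_rr_subject_sd_ms: float = 90.0
    autonomic_amp_cv: float = 0.30
    autonomic_white_cv: float = 0.25

    # fNIRS forward model
    optics: OpticsConfig = field(default_factory=OpticsConfig)
    noise: NoiseModel = field(default_factory=NoiseModel)
    hrf: HRFParams = field(default_factory=HRFParams)
    beta_base_um: float = 0.20
    beta_load_slope_um: float = 0.25
    beta_subject_sd_um: float = 0.10
    beta_channel_sd_um: float = 0.05
    fnirs_pre_rest_s: float = 30.0
    fnirs_post_rest_s: float = 30.0

    # NASA-TLX synthesis
    tlx_dimension_params: dict = field(default_factory=lambda: dict(_TLX_DIMENSION_PARAMS))
    tlx_subject_sd: float = 8.0
    tlx_noise_sd: float = 7.0

    # analysis settings
    precolor: bool = True
    denoise: bool = True
    drift_order: int = 1

    # calibration mode: all load couplings zero, task set frozen at low load
    null_effects: bool = False

    # stage seed offsets (stream-isolation hooks; leave at 0 normally)
    seed_offsets: dict = field(default_factory=lambda: {
        "behavior": 0, "rr": 0, "fnirs": 0, "tlx": 0})

    def __post_init__(self):
        if self.n_subjects < 3:
            raise ValidationError("need >= 3 subjects")
        if set(self.conditions) - set(CONDITIONS):
            raise ValidationError(f"conditions must be among {CONDITIONS}")

    def zero_load_effects(self) -> "StudyConfig":
        """A copy with every load coupling removed (null study)."""
        return dataclasses.replace(self, null_effects=True)

    def condition_orders(self):
        """Latin-square rotation of the condition sequence across subjects."""
        k = len(self.conditions)
        base = list(self.conditions)
        return tuple(tuple(base[(i + s) % k] for i in range(k))
                     for s in range(self.n_subjects))


@dataclass(frozen=True)
class StudyResults:
    table: pd.DataFrame            # subject x condition measures, long-wide
    anovas: dict                   # measure -> AnovaResult
    posthocs: dict                 # measure -> PairwiseResult
    correlations: pd.DataFrame     # condition, measure pair, r, n, p
    orders: tuple
    config: StudyConfig

    def save(self, out_dir) -> None:
        """Deterministic CSV/JSON snapshot of the results."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.table.to_csv(out / "measures.csv", index=False, float_format="%.10g")
        rows = [{"measure": m, "F": a.F, "df_num": a.df_num, "df_den": a.df_den,
                 "p": a.p, "ss_condition": a.ss_condition, "ss_subject": a.ss_subject,
                 "ss_error": a.ss_error} for m, a in self.anovas.items()]
        pd.DataFrame(rows).to_csv(out / "anova.csv", index=False, float_format="%.10g")
        ph_rows = []
        for m, res in self.posthocs.items():
            for c in res.comparisons:
                ph_rows.append({"measure": m, "pair": "-".join(c.pair),
                                "mean_diff": c.mean_diff, "t": c.t, "p_raw": c.p_raw,
                                "threshold": res.threshold,
                                "threshold_display": res.threshold_display,
                                "significant": c.significant})
        pd.DataFrame(ph_rows).to_csv(out / "posthoc.csv", index=False, float_format="%.10g")
        self.correlations.to_csv(out / "correlations.csv", index=False, float_format="%.10g")
        meta = {"n_subjects": self.config.n_subjects, "root_seed": self.config.root_seed,
                "conditions": list(self.config.conditions),
                "orders": [list(o) for o in self.orders]}
        (out / "study.json").write_text(json.dumps(meta, indent=2, sort_keys=True))


def _subject_effects(cfg: StudyConfig, subject: int) -> dict:
    rng = rng_from(cfg.root_seed, 100, subject)
    return {
        "noise_mult": float(np.exp(rng.normal(0.0, cfg.operator_noise_cv))),
        "latency_mult": float(np.exp(rng.normal(0.0, cfg.operator_latency_cv))),
        "mean_rr_shift": float(rng.normal(0.0, cfg.mean_rr_subject_sd_ms)),
        "amp_mult": float(np.exp(rng.normal(0.0, cfg.autonomic_amp_cv))),
        "white_mult": float(np.exp(rng.normal(0.0, cfg.autonomic_white_cv))),
        "beta_intercept": float(rng.normal(0.0, cfg.beta_subject_sd_um)),
        "tlx_intercept": float(rng.normal(0.0, cfg.tlx_subject_sd)),
    }


def _run_cell(cfg: StudyConfig, subject: int, condition: str, eff: dict) -> dict:
    """One subject × condition cell: simulate, synthesize, analyze."""
    load = cfg.conditions.index(condition)
    null = cfg.null_effects
    eff_load = 0 if null else load
    off = cfg.seed_offsets

    # --- behavior ---------------------------------------------------------
    task_cfg = TaskConfig(
        condition="low" if null else condition,
        duration_s=cfg.run_duration_s, tick_hz=cfg.tick_hz,
        rng_seed=child_seed(cfg.root_seed + off["behavior"], STAGE_BEHAVIOR, subject, load),
    )
    base_op = cfg.operator
    profile = dataclasses.replace(
        base_op,
        tracking_noise_sd=(base_op.tracking_noise_sd * eff["noise_mult"]
                           + cfg.tracking_noise_load_slope * eff_load),
        meter_latency_s=base_op.meter_latency_s * eff["latency_mult"],
        emergency_latency_s=base_op.emergency_latency_s * eff["latency_mult"],
        numeral_latency_s=base_op.numeral_latency_s * eff["latency_mult"],
    )
    try:
        log = simulate_session(task_cfg, profile)
        perf = score_performance(log, task_cfg)
    except Exception as exc:  # noqa: BLE001
        raise StageError("behavior", f"subject {subject} {condition}: {exc}") from exc

    # --- heart ------------------------------------------------------------
    auto = dataclasses.replace(
        cfg.autonomic,
        mean_rr_ms=max(cfg.autonomic.mean_rr_ms + eff["mean_rr_shift"], 400.0),
        lf_amp_ms=cfg.autonomic.lf_amp_ms * eff["amp_mult"],
        hf_amp_ms=cfg.autonomic.hf_amp_ms * eff["amp_mult"],
        white_sd_ms=cfg.autonomic.white_sd_ms * eff["white_mult"],
        load_hr_slope=0.0 if null else cfg.autonomic.load_hr_slope,
    )
    try:
        rr = synthesize_rr(auto, load_step=eff_load, duration_s=cfg.run_duration_s,
                           seed=child_seed(cfg.root_seed + off["rr"], STAGE_RR, subject, load),
                           condition=condition)
        # the generator injects no ectopic artifacts: its white beat-to-beat
        # jitter is legitimate variability, so artifact rejection (meant for
        # real recordings) is skipped here
        hrv = extract_features(rr, clean=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("hrv", f"subject {subject} {condition}: {exc}") from exc

    # --- brain ------------------------------------------------------------
    fnirs_seed_root = cfg.root_seed + off["fnirs"]
    rng_beta = rng_from(fnirs_seed_root, STAGE_FNIRS, subject, load, 1)
    slope = 0.0 if null else cfg.beta_load_slope_um
    beta_true = (cfg.beta_base_um + eff["beta_intercept"] + slope * load
                 + rng_beta.normal(0.0, cfg.beta_channel_sd_um, size=cfg.optics.n_channels))
    run_len = cfg.fnirs_pre_rest_s + cfg.run_duration_s + cfg.fnirs_post_rest_s
    try:
        hemo = synthesize_activation(
            beta_true, onsets=[cfg.fnirs_pre_rest_s], durations=[cfg.run_duration_s],
            hrf_params=cfg.hrf, fs=cfg.optics.sampling_hz, duration_s=run_len,
            condition=condition)
        noisy = add_noise(hemo, cfg.noise,
                          seed=child_seed(fnirs_seed_root, STAGE_FNIRS, subject, load, 2))
        act = estimate_activation(
            noisy, cfg.optics, onsets=[cfg.fnirs_pre_rest_s],
            durations=[cfg.run_duration_s], hrf_params=cfg.hrf,
            drift_order=cfg.drift_order, denoise=cfg.denoise, precolor=cfg.precolor)
    except Exception as exc:  # noqa: BLE001
        raise StageError("fnirs", f"subject {subject} {condition}: {exc}") from exc

    # --- subjective -------------------------------------------------------
    rng_tlx = rng_from(cfg.root_seed + off["tlx"], STAGE_TLX, subject, load)
    latent, ratings = {}, {}
    for d in DIMENSIONS:
        base, dim_slope = cfg.tlx_dimension_params[d]
        lv = (base + (0.0 if null else dim_slope) * load + eff["tlx_intercept"]
              + rng_tlx.normal(0.0, cfg.tlx_noise_sd))
        latent[d] = lv
        ratings[d] = float(np.clip(lv, 0.0, 100.0))
    choices = {}
    for a, b in ALL_PAIRS:
        ja = latent[a] + rng_tlx.normal(0.0, 1.0)
        jb = latent[b] + rng_tlx.normal(0.0, 1.0)
        choices[(a, b)] = a if ja >= jb else b
    try:
        weights = compute_weights(choices)
        score = weighted_score(TLXRating(**ratings), weights)
    except Exception as exc:  # noqa: BLE001
        raise StageError("tlx", f"subject {subject} {condition}: {exc}") from exc

    row = {
        "subject": subject, "condition": condition,
        "tlx_total": score.overall,
        "avg_distance_mm": perf.avg_distance_mm,
        "n_alarms": perf.n_alarms,
        "n_numeral_responses": perf.n_numeral_responses,
        "meter_rt_s": perf.meter_rt_s,
        "meter_accuracy_pct": perf.meter_accuracy_pct,
        "emergency_rt_s": perf.emergency_rt_s,
        "emergency_accuracy_pct": perf.emergency_accuracy_pct,
        "mean_hr_bpm": hrv.mean_hr_bpm, "sdnn_ms": hrv.sdnn_ms,
        "rmssd_ms": hrv.rmssd_ms, "lf_hf": hrv.lf_hf_ratio,
        "mean_beta": act.mean_beta,
    }
    row.update({f"tlx_{d}": ratings[d] for d in DIMENSIONS})
    return row


def run_study(config: StudyConfig = StudyConfig()) -> StudyResults:
    """Run the full synthetic study; fully reproducible from ``root_seed``."""
    rows = []
    orders = config.condition_orders()
    for s in range(config.n_subjects):
        eff = _subject_effects(config, s)
        for condition in orders[s]:
            rows.append(_run_cell(config, s, condition, eff))
    table = pd.DataFrame(rows).sort_values(["subject", "condition"],
                                           key=lambda c: c.map(
                                               {v: i for i, v in enumerate(config.conditions)})
                                           if c.name == "condition" else c)
    table = table.reset_index(drop=True)

    anovas, posthocs = {}, {}
    for measure in ANOVA_MEASURES:
        wide = table.pivot(index="subject", columns="condition", values=measure)
        wide = wide[list(config.conditions)]
        rm = RepeatedMeasuresTable(subjects=tuple(wide.index),
                                   conditions=tuple(wide.columns),
                                   values=wide.to_numpy(float), measure=measure)
        anovas[measure] = rm_anova_oneway(rm)
        posthocs[measure] = bonferroni_pairwise(rm)

    corr_rows = []
    measures = list(MEASURE_FAMILIES)
    for condition in config.conditions:
        sub = table[table["condition"] == condition].sort_values("subject")
        for i, mx in enumerate(measures):
            for my in measures[i + 1:]:
                if MEASURE_FAMILIES[mx] == MEASURE_FAMILIES[my]:
                    continue  # within-family pairings excluded
                x = sub[mx].to_numpy(float)
                y = sub[my].to_numpy(float)
                if np.std(x) == 0 or np.std(y) == 0:
                    continue
                c = pearson_corr(x, y)
                corr_rows.append({"condition": condition, "measure_x": mx,
                                  "measure_y": my, "r": c.r, "n": c.n, "p": c.p})
    correlations = pd.DataFrame(corr_rows)
    return StudyResults(table=table, anovas=anovas, posthocs=posthocs,
                        correlations=correlations, orders=orders, config=config)


def make_report(results: StudyResults, out_dir, make_figures: bool = True) -> dict:
    """Write the tidy result tables (and optional figures); returns file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    required = set(ANOVA_MEASURES)
    missing = required - set(results.table.columns)
    if missing or results.table[list(required)].isna().any().any():
        bad = sorted(missing) or sorted(
            c for c in required if results.table[c].isna().any())
        raise ValidationError(f"incomplete results; missing cells in {bad}")
    results.save(out)

    conditions = list(results.config.conditions)
    perf_features = ["avg_distance_mm", "n_alarms", "n_numeral_responses",
                     "meter_rt_s", "meter_accuracy_pct",
                     "emergency_rt_s", "emergency_accuracy_pct"]
    perf_rows = []
    for feat in perf_features:
        row = {"feature": feat}
        for cond in conditions:
            vals = results.table.loc[results.table["condition"] == cond, feat]
            if vals.isna().all():
                row[cond] = "none"  # subtask inactive in this condition
            else:
                row[cond] = f"{vals.mean():.2f} ± {vals.std(ddof=1):.2f}"
        perf_rows.append(row)
    pd.DataFrame(perf_rows).to_csv(out / "performance_table.csv", index=False)

    hrv_rows = []
    for feat in ("mean_hr_bpm", "sdnn_ms", "rmssd_ms", "lf_hf"):
        row = {"feature": feat}
        for cond in conditions:
            vals = results.table.loc[results.table["condition"] == cond, feat]
            row[cond] = f"{vals.mean():.2f} ± {vals.std(ddof=1):.2f}"
        hrv_rows.append(row)
    pd.DataFrame(hrv_rows).to_csv(out / "hrv_table.csv", index=False)

    files = {name: str(out / f"{name}.csv") for name in
             ("measures", "anova", "posthoc", "correlations",
              "performance_table", "hrv_table")}

    if make_figures:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt

        for measure, fname in (("tlx_total", "tlx_by_condition"),
                               ("mean_beta", "activation_by_condition"),
                               ("mean_hr_bpm", "hr_by_condition")):
            fig, ax = plt.subplots(figsize=(4, 3))
            means = [results.table.loc[results.table["condition"] == c, measure].mean()
                     for c in conditions]
            sems = [results.table.loc[results.table["condition"] == c, measure].sem()
                    for c in conditions]
            ax.bar(conditions, means, yerr=sems, capsize=4, color="#4878a8")
            ax.set_ylabel(measure)
            ax.set_xlabel("task load")
            fig.tight_layout()
            fig.savefig(out / f"{fname}.png", dpi=120)
            plt.close(fig)
            files[fname] = str(out / f"{fname}.png")

        sig = results.correlations[results.correlations["p"] < 0.05]
        for _, rec in sig.head(6).iterrows():
            sub = results.table[results.table["condition"] == rec["condition"]]
            fig, ax = plt.subplots(figsize=(4, 3))
            ax.scatter(sub[rec["measure_x"]], sub[rec["measure_y"]], s=18)
            ax.set_xlabel(rec["measure_x"])
            ax.set_ylabel(rec["measure_y"])
            ax.set_title(f"{rec['condition']}: r={rec['r']:.2f}")
            fig.tight_layout()
            name = f"corr_{rec['condition']}_{rec['measure_x']}_{rec['measure_y']}"
            fig.savefig(out / f"{name}.png", dpi=120)
            plt.close(fig)
            files[name] = str(out / f"{name}.png")
    return files
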