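"""End-to-end orchestration: trial-table I/O, the two analysis modes, and
machine-readable reports.

The canonical trials CSV has one row per trial with columns
observer_id, experiment, session, duration_ms, target_location,
target_letter, report_order, reported_location, reported_letter,
loc_correct, id_correct — indices 0-based, booleans written as 0/1, absent
values empty. ``read_trials`` accepts a ``column_map`` so externally
deposited data with different column names can be loaded without editing
files.

``run_analysis`` reproduces the full analysis structure of a dual-report
study (independence analysis, per-order and pooled psychometric fits,
feature contrasts, 2x2 ANOVA on threshold and speed with Holm post-hocs,
within-subject CIs) or of a blocked-report study (blocked fits, contrasts,
CIs).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import independence as indep
from . import stats as gstats
from .model import (
    FitConfig,
    FitResult,
    PsychometricParams,
    ValidationError,
    aggregate_params,
    counts_from_trials,
    fit_psychometric,
)
from .simulate import DEFAULT_DURATIONS_MS, TRIAL_COLUMNS

log = logging.getLogger("tvareport")

FEATURES = ("location", "identity")
ORDERS = ("location_first", "identity_first")


@dataclass(frozen=True)
class AnalysisConfig:
    mode: str = "exp1"  # exp1: dual report; exp2: blocked report
    chance: float = 1.0 / 12.0
    fit: FitConfig = field(default_factory=FitConfig)
    independence_cells: str = "four"  # or "two"
    fisher_z: bool = False
    ci_level: float = 0.95
    per_order_fits: bool = True
    prior_scale_r: float = 0.707
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("exp1", "exp2"):
            raise ValidationError(f"mode must be 'exp1' or 'exp2', got {self.mode!r}")
        if not (0 < self.chance < 1):
            raise ValidationError("chance must be in (0,1)")


@dataclass
class ReportBundle:
    mode: str
    fits: pd.DataFrame  # observer_id, feature, condition, t0_s, v_per_s, nll, converged
    aggregate: dict[str, PsychometricParams]
    contrasts: dict[str, gstats.GroupTestResult]
    independence: indep.IndependenceResult | None
    anova: dict[str, gstats.AnovaResult]
    posthoc: dict[str, dict[str, float]]
    cis: dict[str, gstats.CIResult]
    accuracy_advantage: float
    excluded: list[str]
    independence_tables: pd.DataFrame | None = None


# --------------------------------------------------------------------------
# trial table I/O


def write_trials(trials: pd.DataFrame, path) -> None:
    """Write the canonical trials CSV (booleans as 0/1, absent values empty)."""
    out = trials.copy()
    for col in ("loc_correct", "id_correct"):
        if col in out:
            out[col] = out[col].map(lambda x: "" if pd.isna(x) else str(int(bool(x))))
    for col in ("reported_location", "reported_letter"):
        if col in out:
            out[col] = out[col].map(lambda x: "" if pd.isna(x) else str(int(x)))
    out.to_csv(path, index=False)


def read_trials(
    path,
    column_map: dict[str, str] | None = None,
    canonical_durations_ms=DEFAULT_DURATIONS_MS,
    n_locations: int = 12,
    n_letters: int = 12,
) -> pd.DataFrame:
    """Read and validate a trials CSV.

    ``column_map`` maps file column names to canonical ones (for externally
    deposited data). Durations are snapped to the nearest canonical value
    within 0.5 ms; correctness flags are recomputed from target/report and
    cross-checked against any flags present in the file. Violations are hard
    errors that name the offending rows.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    required = [c for c in TRIAL_COLUMNS if c not in ("loc_correct", "id_correct")]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns {missing} in {path}")

    canon = np.asarray(canonical_durations_ms, dtype=float)
    dur = df["duration_ms"].astype(float).to_numpy()
    nearest = canon[np.abs(dur[:, None] - canon[None, :]).argmin(axis=1)]
    off = np.abs(dur - nearest) > 0.5
    if off.any():
        raise ValidationError(
            f"durations not within 0.5 ms of canonical values at rows {np.where(off)[0][:20].tolist()}"
        )
    df = df.copy()
    df["duration_ms"] = nearest

    for col, n_alt in (("target_location", n_locations), ("target_letter", n_letters),
                       ("reported_location", n_locations), ("reported_letter", n_letters)):
        vals = pd.to_numeric(df[col], errors="coerce")
        present = vals.notna()
        bad = present & ((vals < 0) | (vals >= n_alt) | (vals % 1 != 0))
        if bad.any():
            raise ValidationError(
                f"{col} out of range 0..{n_alt - 1} at rows {df.index[bad][:20].tolist()}"
            )
        df[col] = vals.astype("Int64")

    for flag, rep, tgt in (
        ("loc_correct", "reported_location", "target_location"),
        ("id_correct", "reported_letter", "target_letter"),
    ):
        computed = pd.Series(pd.NA, index=df.index, dtype="boolean")
        mask = df[rep].notna() & df[tgt].notna()
        computed[mask] = df.loc[mask, rep].astype(int).to_numpy() == df.loc[
            mask, tgt
        ].astype(int).to_numpy()
        if flag in df.columns:
            provided = df[flag].map(
                lambda x: pd.NA if (pd.isna(x) or x == "") else bool(int(float(x)))
            ).astype("boolean")
            both = computed.notna() & provided.notna()
            clash = both & (computed != provided)
            if clash.any():
                raise ValidationError(
                    f"{flag} contradicts target/report at rows {df.index[clash][:20].tolist()}"
                )
        df[flag] = computed

    log.info("read_trials: %d rows, %d observers from %s",
             len(df), df["observer_id"].nunique(), path)
    return df[TRIAL_COLUMNS]


# --------------------------------------------------------------------------
# analysis


def _fit_cell(trials: pd.DataFrame, feature: str, chance: float, cfg: FitConfig) -> FitResult:
    counts = counts_from_trials(trials, feature)
    return fit_psychometric(counts, chance=chance, config=cfg)


def fit_observers(
    trials: pd.DataFrame,
    chance: float = 1.0 / 12.0,
    fit_config: FitConfig | None = None,
    per_order: bool = False,
) -> pd.DataFrame:
    """Fit (t0, v) per observer x feature (x report order when ``per_order``).

    Returns a tidy frame with one row per fit; failed cells are recorded
    with converged=False rather than raised.
    """
    cfg = fit_config or FitConfig()
    rows = []
    for obs, grp in trials.groupby("observer_id", sort=True):
        for feature in FEATURES:
            cells: list[tuple[str, pd.DataFrame]] = [("pooled", grp)]
            if per_order:
                cells += [(o, grp[grp["report_order"] == o]) for o in ORDERS]
            for condition, sub in cells:
                flag = "loc_correct" if feature == "location" else "id_correct"
                if sub.dropna(subset=[flag]).empty:
                    continue
                fit = _fit_cell(sub, feature, chance, cfg)
                rows.append(
                    {
                        "observer_id": obs,
                        "feature": feature,
                        "condition": condition,
                        "t0_s": fit.params.t0_s,
                        "v_per_s": fit.params.v_per_s,
                        "chance": chance,
                        "nll": fit.nll,
                        "converged": fit.converged,
                        "n_starts": fit.n_starts,
                        "at_bound": ",".join(sorted(fit.at_bound)),
                    }
                )
    return pd.DataFrame(rows)


def _contrast(wide: pd.DataFrame, col: str, r: float) -> gstats.GroupTestResult:
    return gstats.paired_t_test(
        wide[("location", col)].to_numpy(), wide[("identity", col)].to_numpy(), prior_scale_r=r
    )


def run_analysis(trials: pd.DataFrame, config: AnalysisConfig) -> ReportBundle:
    """Run the full analysis for one experiment's trial table."""
    n_obs = trials["observer_id"].nunique()
    if n_obs < 2:
        raise ValidationError("run_analysis needs >= 2 observers")
    dual = trials.dropna(subset=["loc_correct", "id_correct"])
    if config.mode == "exp1" and dual.empty:
        raise ValidationError("exp1 mode requires dual-report data (both flags per trial)")
    if config.mode == "exp2" and not dual.empty:
        raise ValidationError("exp2 mode expects blocked data, got dual-report trials")
    log.info("run_analysis mode=%s: %d trials, %d observers", config.mode, len(trials), n_obs)

    per_order = config.mode == "exp1" and config.per_order_fits
    fits = fit_observers(trials, config.chance, config.fit, per_order=per_order)
    pooled = fits[fits["condition"] == "pooled"]
    excluded = sorted(
        set(trials["observer_id"].astype(str))
        - set(pooled.loc[pooled["converged"], "observer_id"].astype(str))
    )
    for obs in excluded:
        log.warning("observer %s excluded from group stats (fit did not converge)", obs)
    ok = pooled[~pooled["observer_id"].isin(excluded)]
    wide = ok.pivot(index="observer_id", columns="feature", values=["t0_s", "v_per_s"])
    wide.columns = wide.columns.swaplevel()

    aggregate = {
        feat: aggregate_params(
            [
                PsychometricParams(r.t0_s, r.v_per_s, r.chance)
                for r in ok[ok["feature"] == feat].itertuples()
            ]
        )
        for feat in FEATURES
    }

    contrasts = {
        "t0_location_vs_identity": _contrast(wide, "t0_s", config.prior_scale_r),
        "v_location_vs_identity": _contrast(wide, "v_per_s", config.prior_scale_r),
    }
    acc_adv = gstats.mean_accuracy_difference(trials)
    acc_by_obs = _per_observer_accuracy_advantage(trials)
    contrasts["accuracy_location_vs_identity"] = gstats.paired_t_test(
        acc_by_obs, prior_scale_r=config.prior_scale_r
    )

    independence_result = None
    indep_frame = None
    anova: dict[str, gstats.AnovaResult] = {}
    posthoc: dict[str, dict[str, float]] = {}
    if config.mode == "exp1":
        independence_result = indep.independence_analysis(
            trials, cells=config.independence_cells, fisher_z=config.fisher_z
        )
        observed = indep.observed_joint(trials)
        predicted = [indep.predicted_joint(t) for t in observed]
        indep_frame = indep.joint_tables_frame(observed, predicted)
        if per_order:
            cells = fits[fits["condition"].isin(ORDERS)]
            cells = cells[~cells["observer_id"].isin(excluded)]
            for param in ("t0_s", "v_per_s"):
                anova[param] = gstats.rm_anova_2x2(
                    cells.rename(columns={"condition": "report_order"}),
                    dv=param,
                    subject="observer_id",
                    factor_a="feature",
                    factor_b="report_order",
                )
                posthoc[param] = _holm_posthoc(cells, param, config.prior_scale_r)

    cis = _within_cis(trials, ok, config)

    return ReportBundle(
        mode=config.mode,
        fits=fits,
        aggregate=aggregate,
        contrasts=contrasts,
        independence=independence_result,
        anova=anova,
        posthoc=posthoc,
        cis=cis,
        accuracy_advantage=acc_adv,
        excluded=excluded,
        independence_tables=indep_frame,
    )


def _per_observer_accuracy_advantage(trials: pd.DataFrame) -> np.ndarray:
    vals = []
    for _, grp in trials.groupby("observer_id", sort=True):
        acc_loc = grp.dropna(subset=["loc_correct"]).groupby("duration_ms")["loc_correct"].mean()
        acc_id = grp.dropna(subset=["id_correct"]).groupby("duration_ms")["id_correct"].mean()
        common = acc_loc.index.intersection(acc_id.index)
        if len(common):
            vals.append(float((acc_loc[common] - acc_id[common]).mean()))
    return np.asarray(vals)


def _holm_posthoc(cells: pd.DataFrame, param: str, r: float) -> dict[str, float]:
    """Holm family: the four feature-related pairwise comparisons of the 2x2 cells."""
    wide = cells.pivot(index="observer_id", columns=["feature", "condition"], values=param)
    pairs = [
        (("location", "location_first"), ("identity", "location_first")),
        (("location", "identity_first"), ("identity", "identity_first")),
        (("location", "location_first"), ("identity", "identity_first")),
        (("location", "identity_first"), ("identity", "location_first")),
    ]
    raw, names = [], []
    for a, b in pairs:
        res = gstats.paired_t_test(wide[a].to_numpy(), wide[b].to_numpy(), prior_scale_r=r)
        raw.append(res.p)
        names.append(f"{a[0]}@{a[1]} vs {b[0]}@{b[1]}")
    adj = gstats.holm_adjust(raw)
    return dict(zip(names, adj))


def _within_cis(trials: pd.DataFrame, ok_fits: pd.DataFrame, config: AnalysisConfig):
    cis: dict[str, gstats.CIResult] = {}
    # per-duration accuracy, one condition column per feature x duration
    acc = {}
    for feature, flag in (("location", "loc_correct"), ("identity", "id_correct")):
        sub = trials.dropna(subset=[flag])
        acc[feature] = sub.groupby(["observer_id", "duration_ms"])[flag].mean().unstack()
    for feature, tab in acc.items():
        tab = tab.dropna(axis=0)
        if len(tab) >= 2 and tab.shape[1] >= 2:
            cis[f"accuracy_{feature}"] = gstats.within_subject_ci(
                tab.astype(float), level=config.ci_level
            )
    for param in ("t0_s", "v_per_s"):
        wide = ok_fits.pivot(index="observer_id", columns="feature", values=param)
        if len(wide) >= 2:
            cis[param] = gstats.within_subject_ci(wide.astype(float), level=config.ci_level)
    return cis


# --------------------------------------------------------------------------
# reporting


def _round_floats(obj, ndigits: int = 10):
    if isinstance(obj, float):
        return round(obj, ndigits) if math.isfinite(obj) else None
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    return obj


def bundle_to_dict(bundle: ReportBundle) -> dict:
    d: dict = {
        "mode": bundle.mode,
        "accuracy_advantage": bundle.accuracy_advantage,
        "aggregate": {k: asdict(v) for k, v in bundle.aggregate.items()},
        "contrasts": {k: asdict(v) for k, v in bundle.contrasts.items()},
        "excluded_observers": bundle.excluded,
        "cis": {k: asdict(v) for k, v in bundle.cis.items()},
        "anova": {
            k: {eff: asdict(res) for eff, res in v.effects.items()}
            for k, v in bundle.anova.items()
        },
        "posthoc_holm": bundle.posthoc,
    }
    if bundle.independence is not None:
        d["independence"] = {
            "per_observer_r": bundle.independence.per_observer_r,
            "mean_r": bundle.independence.mean_r,
            "sd_r": bundle.independence.sd_r,
            "group_test": asdict(bundle.independence.group_test),
        }
    return d


def write_report(bundle: ReportBundle, out_dir) -> dict[str, str]:
    """Write the report bundle deterministically; returns the file manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}

    report = _round_floats(bundle_to_dict(bundle))
    (out / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")
    manifest["report"] = "report.json"

    fits = bundle.fits.sort_values(["observer_id", "feature", "condition"]).reset_index(drop=True)
    fits.to_csv(out / "fits.csv", index=False, float_format="%.10g")
    manifest["fits"] = "fits.csv"

    tests = pd.DataFrame(
        [
            {"comparison": name, "t": res.t, "df": res.df, "p": res.p,
             "d_z": res.d_z, "bf10": res.bf10}
            for name, res in sorted(bundle.contrasts.items())
        ]
    )
    tests.to_csv(out / "tests.csv", index=False, float_format="%.10g")
    manifest["tests"] = "tests.csv"

    if bundle.independence_tables is not None:
        bundle.independence_tables.to_csv(
            out / "independence.csv", index=False, float_format="%.10g"
        )
        manifest["independence"] = "independence.csv"
    else:
        manifest["independence"] = "absent (blocked mode has no joint outcomes)"

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest
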