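"""Stochastic independence of location and identity reports.

For each observer and exposure duration, the four joint report outcomes
(location correct/wrong x identity correct/wrong) are tabulated as observed
relative frequencies, and predicted probabilities are formed from the
products of the observed marginals — the joint distribution the data would
have if the two features' reports were stochastically independent. The
per-observer Pearson correlation between observed and predicted cell
probabilities (across durations) then quantifies how well independence
describes that observer, and a one-sample t test of the correlations
against zero gives the group-level statistic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import ValidationError
from .stats import GroupTestResult, paired_t_test

CELLS = ("cc", "cw", "wc", "ww")  # location x identity, c=correct w=wrong


@dataclass(frozen=True)
class JointOutcomeTable:
    """Joint report-outcome probabilities at one observer x duration."""

    observer_id: str
    duration_s: float
    p_cc: float
    p_cw: float
    p_wc: float
    p_ww: float
    n_trials: int

    def __post_init__(self) -> None:
        ps = (self.p_cc, self.p_cw, self.p_wc, self.p_ww)
        if any(p < -1e-12 for p in ps) or abs(sum(ps) - 1.0) > 1e-12:
            raise ValidationError(f"cell probabilities must be >= 0 and sum to 1, got {ps}")

    @property
    def probs(self) -> tuple[float, float, float, float]:
        return (self.p_cc, self.p_cw, self.p_wc, self.p_ww)

    @property
    def marginal_location(self) -> float:
        return self.p_cc + self.p_cw

    @property
    def marginal_identity(self) -> float:
        return self.p_cc + self.p_wc


@dataclass(frozen=True)
class IndependenceResult:
    per_observer_r: dict[str, float]
    mean_r: float
    sd_r: float
    group_test: GroupTestResult


def observed_joint(trials: pd.DataFrame) -> list[JointOutcomeTable]:
    """Tabulate observed joint outcome frequencies per observer x duration.

    Requires dual-report trials (both correctness flags present); rows
    missing either flag are dropped with a warning.
    """
    both = trials.dropna(subset=["loc_correct", "id_correct"])
    if len(both) < len(trials):
        warnings.warn(
            f"dropping {len(trials) - len(both)} trials without both correctness flags"
        )
    if both.empty:
        raise ValidationError("no dual-report trials with both correctness flags")
    out = []
    for (obs, dur_ms), grp in both.groupby(["observer_id", "duration_ms"], sort=True):
        n = len(grp)
        loc = grp["loc_correct"].astype(bool).to_numpy()
        ident = grp["id_correct"].astype(bool).to_numpy()
        out.append(
            JointOutcomeTable(
                observer_id=str(obs),
                duration_s=float(dur_ms) / 1000.0,
                p_cc=float((loc & ident).mean()),
                p_cw=float((loc & ~ident).mean()),
                p_wc=float((~loc & ident).mean()),
                p_ww=float((~loc & ~ident).mean()),
                n_trials=n,
            )
        )
    return out


def predicted_joint(observed: JointOutcomeTable) -> JointOutcomeTable:
    """Joint probabilities under independence, from the observed marginals.

    With a = P(location correct) and b = P(identity correct), the predicted
    cells are (ab, a(1-b), (1-a)b, (1-a)(1-b)); marginals are preserved
    exactly and the cells sum to 1.
    """
    a = observed.marginal_location
    b = observed.marginal_identity
    return JointOutcomeTable(
        observer_id=observed.observer_id,
        duration_s=observed.duration_s,
        p_cc=a * b,
        p_cw=a * (1.0 - b),
        p_wc=(1.0 - a) * b,
        p_ww=(1.0 - a) * (1.0 - b),
        n_trials=observed.n_trials,
    )


def observer_correlation(
    observed: list[JointOutcomeTable],
    predicted: list[JointOutcomeTable],
    cells: str = "four",
) -> float:
    """Pearson r between observed and predicted cell probabilities.

    Pools all durations of one observer into a single vector (four cells per
    duration, or just the CC and WW cells with ``cells="two"``). Returns NaN
    with a warning when either vector has zero variance.
    """
    if len(observed) != len(predicted):
        raise ValidationError("observed and predicted lists must match")
    idx = {"four": slice(None), "two": [0, 3]}.get(cells)
    if idx is None:
        raise ValidationError(f"cells must be 'four' or 'two', got {cells!r}")
    obs_vec, pred_vec = [], []
    for o, p in zip(observed, predicted):
        if o.observer_id != p.observer_id or o.duration_s != p.duration_s:
            raise ValidationError("mismatched observer/duration between tables")
        obs_vec.extend(np.asarray(o.probs)[idx])
        pred_vec.extend(np.asarray(p.probs)[idx])
    obs_vec = np.asarray(obs_vec)
    pred_vec = np.asarray(pred_vec)
    if np.allclose(obs_vec, obs_vec[0]) or np.allclose(pred_vec, pred_vec[0]):
        warnings.warn("zero variance in probability vector; correlation undefined")
        return math.nan
    r, _ = sps.pearsonr(obs_vec, pred_vec)
    return float(r)


def independence_group_test(rs, fisher_z: bool = False) -> GroupTestResult:
    """One-sample t test of per-observer correlations against zero.

    ``fisher_z`` applies the variance-stabilising transform before testing
    (off by default: the headline statistic is a t on raw correlations).
    A constant nonzero vector has no finite t and comes back degenerate.
    """
    rs = [r for r in np.asarray(rs, dtype=float) if math.isfinite(r)]
    if len(rs) < 2:
        raise ValidationError("independence_group_test needs >= 2 valid correlations")
    vals = np.arctanh(np.asarray(rs)) if fisher_z else np.asarray(rs)
    return paired_t_test(vals)


def independence_analysis(
    trials: pd.DataFrame, cells: str = "four", fisher_z: bool = False
) -> IndependenceResult:
    """Full pipeline: tabulate, predict, correlate per observer, test at group level."""
    tables = observed_joint(trials)
    by_obs: dict[str, list[JointOutcomeTable]] = {}
    for t in tables:
        by_obs.setdefault(t.observer_id, []).append(t)
    per_r = {}
    for obs, obs_tables in sorted(by_obs.items()):
        preds = [predicted_joint(t) for t in obs_tables]
        r = observer_correlation(obs_tables, preds, cells=cells)
        if math.isnan(r):
            warnings.warn(f"observer {obs}: undefined correlation, excluded from group test")
        per_r[obs] = r
    valid = [r for r in per_r.values() if math.isfinite(r)]
    group = independence_group_test(valid, fisher_z=fisher_z)
    return IndependenceResult(
        per_observer_r=per_r,
        mean_r=float(np.mean(valid)),
        sd_r=float(np.std(valid, ddof=1)),
        group_test=group,
    )


def joint_tables_frame(
    observed: list[JointOutcomeTable], predicted: list[JointOutcomeTable]
) -> pd.DataFrame:
    """Tidy long-format frame: observer, duration_ms, cell, observed_p, predicted_p."""
    rows = []
    for o, p in zip(observed, predicted):
        for cell, po, pp in zip(CELLS, o.probs, p.probs):
            rows.append(
                {
                    "observer_id": o.observer_id,
                    "duration_ms": o.duration_s * 1000.0,
                    "cell": cell,
                    "observed_p": po,
                    "predicted_p": pp,
                    "n_trials": o.n_trials,
                }
            )
    return pd.DataFrame(rows)
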