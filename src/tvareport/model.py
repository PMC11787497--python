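"""TVA psychometric function and its maximum-likelihood estimation.

The model describes single-target report accuracy in a backward-masking
paradigm as a function of exposure duration ``t`` (seconds)::

    p(t) = chance                                   if t <  t0
    p(t) = 1 - exp(-v (t - t0)) (1 - chance)        ... rearranged:
         = p_enc + (1 - p_enc) * chance             if t >= t0

with ``p_enc = 1 - exp(-v (t - t0))`` the probability that the feature is
encoded into visual working memory before the mask interrupts processing.
``t0`` is the temporal threshold of perception (the minimum exposure before
processing starts), ``v`` the processing speed in objects per second, and
``chance`` the guessing probability on non-encoded trials (1/12 for twelve
response alternatives).

Estimation is binomial maximum likelihood on per-duration correct counts,
with a coarse multi-start grid refined by Nelder-Mead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize
from scipy.special import xlog1py, xlogy

_P_MAX = float(np.nextafter(1.0, 0.0))  # keep p strictly below 1 in floats


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


# --------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class PsychometricParams:
    """Parameters of one observer x feature psychometric function.

    t0_s : temporal threshold of perception, seconds (>= 0)
    v_per_s : processing speed, objects per second (> 0)
    chance : guessing probability, in (0, 1)
    """

    t0_s: float
    v_per_s: float
    chance: float = 1.0 / 12.0

    def __post_init__(self) -> None:
        if not (self.t0_s >= 0):
            raise ValidationError(f"t0_s must be >= 0, got {self.t0_s}")
        if not (self.v_per_s > 0):
            raise ValidationError(f"v_per_s must be > 0, got {self.v_per_s}")
        if not (0 < self.chance < 1):
            raise ValidationError(f"chance must be in (0, 1), got {self.chance}")


@dataclass(frozen=True)
class DurationCounts:
    """Binomial sufficient statistic at one exposure duration."""

    duration_s: float
    n_trials: int
    n_correct: int

    def __post_init__(self) -> None:
        if not (self.duration_s > 0):
            raise ValidationError(f"duration_s must be > 0, got {self.duration_s}")
        if not (0 <= self.n_correct <= self.n_trials):
            raise ValidationError(
                f"need 0 <= n_correct <= n_trials, got {self.n_correct}/{self.n_trials}"
            )


@dataclass(frozen=True)
class FitConfig:
    """Multi-start grid and refinement settings for fit_psychometric."""

    t0_bounds_s: tuple[float, float] = (0.0, 0.150)
    v_bounds: tuple[float, float] = (0.5, 500.0)
    t0_starts_s: tuple[float, ...] = tuple(x / 1000.0 for x in range(0, 130, 10))
    v_starts: tuple[float, ...] = (5.0, 10.0, 20.0, 40.0, 80.0, 160.0)
    n_refine: int = 10
    tol: float = 1e-8


@dataclass(frozen=True)
class FitResult:
    params: PsychometricParams
    nll: float
    converged: bool
    n_starts: int
    at_bound: frozenset[str] = field(default_factory=frozenset)


# --------------------------------------------------------------------------
# model evaluation


def encoding_probability(params: PsychometricParams, t):
    """P(feature encoded before the mask) at exposure duration ``t`` seconds.

    Zero below the threshold t0, then an exponential approach to 1 at rate v.
    Accepts scalars or arrays; vectorised over ``t``.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValidationError("exposure duration t must be >= 0")
    dt = np.maximum(t_arr - params.t0_s, 0.0)
    p = np.minimum(-np.expm1(-params.v_per_s * dt), _P_MAX)
    return p if t_arr.ndim else float(p)


def evaluate_psychometric(params: PsychometricParams, t):
    """Probability of correct report at duration ``t``: encoding + guessing.

    chance below t0; above, p_enc + (1 - p_enc) * chance. Continuous at t0,
    bounded in [chance, 1).
    """
    p_enc = encoding_probability(params, t)
    return p_enc + (1.0 - p_enc) * params.chance


def neg_log_likelihood(params: PsychometricParams, data: list[DurationCounts]) -> float:
    """Binomial negative log likelihood, constant binomial coefficients omitted.

    Zero-trial rows are skipped; data with no trials at all is an error.
    Finite for any valid params because p is bounded inside (0, 1).
    """
    rows = [d for d in data if d.n_trials > 0]
    if not rows:
        raise ValidationError("neg_log_likelihood needs at least one row with trials")
    t = np.array([d.duration_s for d in rows])
    n = np.array([d.n_trials for d in rows], dtype=float)
    k = np.array([d.n_correct for d in rows], dtype=float)
    p = evaluate_psychometric(params, t)
    return float(-np.sum(xlogy(k, p) + xlog1py(n - k, -p)))


# --------------------------------------------------------------------------
# fitting


def _nll_vec(theta: np.ndarray, t, n, k, chance: float) -> float:
    t0, v = theta
    dt = np.maximum(t - t0, 0.0)
    p_enc = np.minimum(-np.expm1(-v * dt), _P_MAX)
    p = p_enc + (1.0 - p_enc) * chance
    return float(-np.sum(xlogy(k, p) + xlog1py(n - k, -p)))


def grid_nll(
    data: list[DurationCounts],
    chance: float,
    t0_grid_s,
    v_grid,
):
    """Exhaustive NLL surface over a (t0, v) grid. Brute-force oracle helper.

    Returns (nll_matrix, t0_grid, v_grid) with nll_matrix[i, j] the NLL at
    (t0_grid[i], v_grid[j]). Vectorised; usable at 1 ms x 0.5 /s resolution.
    """
    rows = [d for d in data if d.n_trials > 0]
    t = np.array([d.duration_s for d in rows])
    n = np.array([d.n_trials for d in rows], dtype=float)
    k = np.array([d.n_correct for d in rows], dtype=float)
    t0g = np.asarray(t0_grid_s, dtype=float)
    vg = np.asarray(v_grid, dtype=float)
    dt = np.maximum(t[None, :] - t0g[:, None], 0.0)  # (T0, D)
    # (T0, V, D)
    p_enc = np.minimum(-np.expm1(-vg[None, :, None] * dt[:, None, :]), _P_MAX)
    p = p_enc + (1.0 - p_enc) * chance
    nll = -np.sum(xlogy(k, p) + xlog1py(n - k, -p), axis=-1)
    return nll, t0g, vg


def fit_psychometric(
    data: list[DurationCounts],
    chance: float = 1.0 / 12.0,
    config: FitConfig | None = None,
) -> FitResult:
    """Maximum-likelihood fit of (t0, v) to per-duration correct counts.

    Starts are a coarse (t0, v) grid; the best ``n_refine`` starts are
    polished by bounded Nelder-Mead. Ties broken by lower NLL, then lower
    t0. ``at_bound`` flags parameters landing within tolerance of a bound;
    a fit pinned to the lower speed bound (accuracy flat at chance carries
    no information about v) is reported with converged=False rather than
    raising.
    """
    cfg = config or FitConfig()
    rows = [d for d in data if d.n_trials > 0]
    if len({d.duration_s for d in rows}) < 3:
        raise ValidationError("fit_psychometric needs >= 3 distinct durations with trials")
    t = np.array([d.duration_s for d in rows])
    n = np.array([d.n_trials for d in rows], dtype=float)
    k = np.array([d.n_correct for d in rows], dtype=float)
    if k.sum() == 0 and n.sum() == 0:
        raise ValidationError("no trials in data")

    obj = lambda th: _nll_vec(th, t, n, k, chance)

    nll_grid, t0g, vg = grid_nll(rows, chance, cfg.t0_starts_s, cfg.v_starts)
    order = np.argsort(nll_grid, axis=None, kind="stable")
    starts = [
        (t0g[i // len(vg)], vg[i % len(vg)]) for i in order[: cfg.n_refine]
    ]

    bounds = [cfg.t0_bounds_s, cfg.v_bounds]
    candidates: list[tuple[float, float, float, bool]] = []  # (nll, t0, v, success)
    for start in starts:
        res = optimize.minimize(
            obj,
            x0=np.array(start),
            method="Nelder-Mead",
            bounds=bounds,
            options={"xatol": cfg.tol, "fatol": cfg.tol, "maxiter": 2000},
        )
        candidates.append((float(res.fun), float(res.x[0]), float(res.x[1]), bool(res.success)))
    # lower NLL wins; within numerical ties (1e-10), lower t0 wins
    nll_min = min(c[0] for c in candidates)
    nll_best, t0_hat, v_hat, success = min(
        (c for c in candidates if c[0] <= nll_min + 1e-10), key=lambda c: c[1]
    )
    at_bound = set()
    t0_tol = 1e-6 * (cfg.t0_bounds_s[1] - cfg.t0_bounds_s[0]) + 1e-12
    v_tol = 1e-6 * (cfg.v_bounds[1] - cfg.v_bounds[0]) + 1e-12
    if min(abs(t0_hat - b) for b in cfg.t0_bounds_s) <= t0_tol:
        at_bound.add("t0_s")
    if min(abs(v_hat - b) for b in cfg.v_bounds) <= v_tol:
        at_bound.add("v_per_s")
    v_at_floor = abs(v_hat - cfg.v_bounds[0]) <= v_tol
    params = PsychometricParams(t0_s=t0_hat, v_per_s=v_hat, chance=chance)
    return FitResult(
        params=params,
        nll=float(nll_best),
        converged=success and not v_at_floor,
        n_starts=len(starts),
        at_bound=frozenset(at_bound),
    )


def aggregate_params(fits: list[PsychometricParams]) -> PsychometricParams:
    """Aggregate-observer curve: arithmetic mean of t0 and v across fits.

    All fits must share the same chance level (it is a design constant,
    never estimated).
    """
    if not fits:
        raise ValidationError("aggregate_params needs a nonempty list")
    chances = {p.chance for p in fits}
    if len(chances) != 1:
        raise ValidationError(f"mixed chance values: {sorted(chances)}")
    return PsychometricParams(
        t0_s=float(np.mean([p.t0_s for p in fits])),
        v_per_s=float(np.mean([p.v_per_s for p in fits])),
        chance=fits[0].chance,
    )


def counts_from_trials(trials, feature: str) -> list[DurationCounts]:
    """Aggregate a trial table into per-duration counts for one feature.

    ``feature`` is "location" or "identity"; rows whose correctness flag for
    that feature is missing (blocked designs) are ignored.
    """
    col = {"location": "loc_correct", "identity": "id_correct"}.get(feature)
    if col is None:
        raise ValidationError(f"unknown feature {feature!r}")
    sub = trials.dropna(subset=[col])
    out = []
    for dur_ms, grp in sub.groupby("duration_ms", sort=True):
        out.append(
            DurationCounts(
                duration_s=float(dur_ms) / 1000.0,
                n_trials=int(len(grp)),
                n_correct=int(grp[col].astype(bool).sum()),
            )
        )
    return out
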