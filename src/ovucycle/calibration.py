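"""Calibration of the cycle model against the printed event anchors.

The anchors are: a 28-day period, a 5.87-fold LH surge over the
follicular plateau (41.19/7.02), 36.22% post-surge retention
(100 x 14.92/41.19), progesterone peak at relative day +7, luteal LH
minimum at day +11, LOW->HIGH switch at day -1 and HIGH->LOW at day +10.
The loss is a weighted sum of squared relative errors over these fields,
day-valued targets being compared in days and scaled by the 28-day
period.  Search is derivative-free (Nelder-Mead over log-transformed
parameters) over a small identifiable subset: surge height (g_high,
sigma_LH), surge decay (beta_R), PgR induction delay (alpha_PgR), switch
timing (theta_on, theta_off, tau_on) and luteolysis speed (mu_L).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .cycle_model import ModelParams, default_initial_state, simulate
from .errors import CoverageError, FormatError, InvalidConfigError
from .events import EventTable, event_table

__all__ = [
    "CalibrationTargets",
    "default_targets",
    "calibration_loss",
    "calibrate",
    "FREE_PARAMS",
    "targets_to_toml",
    "targets_from_toml",
]

logger = logging.getLogger(__name__)

#: Fields of EventTable that carry calibration targets.
TARGET_FIELDS = (
    "period_days", "surge_ratio", "retention_pct",
    "pg_peak_day", "lh_min_day", "mode_on_day", "mode_off_day",
)

_DAY_FIELDS = frozenset({"pg_peak_day", "lh_min_day", "mode_on_day", "mode_off_day"})

#: Free parameters of the search; ``alpha_PgR`` scales the hypothalamic and
#: pituitary induction constants jointly.
FREE_PARAMS = (
    "g_high", "beta_R", "alpha_PgR", "theta_on", "theta_off",
    "tau_on", "sigma_LH", "mu_L",
)

#: Relative error charged for a target the simulation failed to produce
#: (no second surge, no mode switch, ...).
_MISSING_PENALTY = 5.0

#: Simulated horizon (days) used by the loss.
LOSS_HORIZON_DAYS = 120.0


@dataclass(frozen=True)
class CalibrationTargets:
    """Target values and nonnegative weights for the anchor fields."""

    values: dict = field(default_factory=dict)
    weights: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        unknown = (set(self.values) | set(self.weights)) - set(TARGET_FIELDS)
        if unknown:
            raise InvalidConfigError(f"unknown target field(s) {sorted(unknown)}")
        weights = {f: float(self.weights.get(f, 1.0)) for f in self.values}
        if any(w < 0 for w in weights.values()):
            raise InvalidConfigError("weights must be >= 0")
        if not any(w > 0 for w in weights.values()):
            raise InvalidConfigError("at least one weight must be positive")
        object.__setattr__(self, "values", dict(self.values))
        object.__setattr__(self, "weights", weights)


def default_targets() -> CalibrationTargets:
    """The published anchors of the idealized cycle."""
    return CalibrationTargets(
        values={
            "period_days": 28.0,
            "surge_ratio": 41.19 / 7.02,
            "retention_pct": 100.0 * 14.92 / 41.19,
            "pg_peak_day": 7.0,
            "lh_min_day": 11.0,
            "mode_on_day": -1.0,
            "mode_off_day": 10.0,
        }
    )


def _relative_errors(table: EventTable, targets: CalibrationTargets) -> dict:
    period_scale = float(targets.values.get("period_days", 28.0))
    errors = {}
    for name, target in targets.values.items():
        value = getattr(table, name)
        if value is None:
            errors[name] = _MISSING_PENALTY
        elif name in _DAY_FIELDS:
            errors[name] = (float(value) - float(target)) / period_scale
        else:
            errors[name] = (float(value) - float(target)) / float(target)
    return errors


def calibration_loss(params: ModelParams, targets: CalibrationTargets) -> float:
    """Weighted sum of squared relative errors of a 120-day simulation.

    The event table is computed on the last full cycle so the initial
    transient is discarded.  Parameter sets that never produce a full
    cycle are charged the missing-field penalty on every target, which
    keeps the loss finite for the derivative-free search.
    """
    try:
        sim = simulate(params, LOSS_HORIZON_DAYS, default_initial_state())
    except Exception as exc:
        raise type(exc)(f"{exc} (params: {params})") from exc
    try:
        table = event_table(sim.series, sim.events)
    except CoverageError:
        return float(
            sum(targets.weights[f] * _MISSING_PENALTY**2 for f in targets.values)
        )
    errors = _relative_errors(table, targets)
    return float(sum(targets.weights[f] * errors[f] ** 2 for f in targets.values))


def _get_free(params: ModelParams) -> np.ndarray:
    out = []
    for name in FREE_PARAMS:
        out.append(params.alpha_PgR_h if name == "alpha_PgR" else getattr(params, name))
    return np.array(out, dtype=float)


def _set_free(params: ModelParams, values: np.ndarray) -> ModelParams:
    changes = {}
    for name, value in zip(FREE_PARAMS, values):
        if name == "alpha_PgR":
            changes["alpha_PgR_h"] = value
            changes["alpha_PgR_p"] = value
        else:
            changes[name] = value
    return params.replace(**changes)


def calibrate(
    initial: ModelParams,
    targets: CalibrationTargets | None = None,
    budget: int = 2000,
    seed: int = 0,
) -> ModelParams:
    """Nelder-Mead search over log-transformed free parameters.

    ``budget`` bounds the total number of loss evaluations across seeded
    restarts; budget 0 returns ``initial`` unchanged.  The result never
    has a higher loss than the input.
    """
    if targets is None:
        targets = default_targets()
    if budget <= 0:
        return initial
    rng = np.random.default_rng(seed)
    x0 = np.log(_get_free(initial))
    evaluations = [0]
    best = [calibration_loss(initial, targets), initial]
    evaluations[0] += 1

    def objective(x: np.ndarray) -> float:
        if evaluations[0] >= budget:
            return best[0] + 1.0  # budget spent; make further moves unattractive
        evaluations[0] += 1
        try:
            candidate = _set_free(initial, np.exp(x))
        except InvalidConfigError:
            return 1e6
        try:
            loss = calibration_loss(candidate, targets)
        except Exception:
            return 1e6
        if loss < best[0]:
            best[0] = loss
            best[1] = candidate
            logger.info("calibrate: eval %d loss %.6g", evaluations[0], loss)
        return loss

    start = x0
    while evaluations[0] < budget:
        remaining = budget - evaluations[0]
        minimize(
            objective,
            start,
            method="Nelder-Mead",
            options={
                "maxfev": remaining,
                "xatol": 1e-4,
                "fatol": 1e-8,
                "adaptive": True,
            },
        )
        # seeded restart around the best point found so far
        start = np.log(_get_free(best[1])) + rng.normal(0.0, 0.05, size=x0.size)
    logger.info("calibrate: finished after %d evaluations, loss %.6g", evaluations[0], best[0])
    return best[1]


# ---------------------------------------------------------------------------
# TOML target files (flat: value keys plus optional "w_"-prefixed weights)

def targets_to_toml(targets: CalibrationTargets, path) -> None:
    lines = [f"{k} = {float(v)!r}" for k, v in targets.values.items()]
    lines += [f"w_{k} = {float(v)!r}" for k, v in targets.weights.items()]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def targets_from_toml(path) -> CalibrationTargets:
    import tomllib

    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise FormatError(f"cannot parse TOML at {path}: {exc}") from exc
    values = {k: v for k, v in raw.items() if not k.startswith("w_")}
    weights = {k[2:]: v for k, v in raw.items() if k.startswith("w_")}
    try:
        return CalibrationTargets(values=values, weights=weights)
    except InvalidConfigError as exc:
        raise FormatError(f"{exc} (from {path})") from exc
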