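"""Two-mode GnRH / receptor-downregulation model of the ovulatory cycle.

The model replaces the textbook "positive feedback" explanation of the
gonadotropin surge with three receptor-level mechanisms:

* the hypothalamus secretes GnRH in one of two modes (LOW during the
  follicular phase, HIGH from the preovulatory days to luteolysis),
  switched by the estrogen signal it senses through its own ER pool;
* pituitary GnRH receptors accumulate under LOW exposure and downregulate
  rapidly under HIGH exposure, so the surge is transient by construction;
* estrogen induces progesterone receptors while progesterone represses
  both ER and PgR, which delays the luteal LH-progesterone negative
  feedback and eventually blinds the hypothalamus to estrogen, ending the
  luteal phase.

State advances by midpoint (second-order Runge-Kutta) steps with linear
sub-step localization of the threshold events (default dt = 0.002 day);
the inner loop is JIT-compiled so that calibration sweeps over 120-day
simulations remain fast.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit

from .errors import FormatError, InvalidConfigError, NumericalInstabilityError, ScenarioError
from .reference_data import HormoneSeries

__all__ = [
    "ModelParams",
    "ModelState",
    "SimOutput",
    "default_params",
    "default_initial_state",
    "step",
    "simulate",
    "apply_scenario",
    "SCENARIOS",
    "params_to_toml",
    "params_from_toml",
]

LOW, HIGH = 0, 1

_EVENT_NAMES = {1: "ovulation", 2: "mode_on", 3: "mode_off"}

#: Parameter fields in kernel order.
PARAM_FIELDS = (
    "g_low", "g_high",
    "alpha_R", "beta_R",
    "theta_on", "theta_off", "tau_on",
    "sigma_LH", "sigma_FSH", "gamma_LH", "gamma_FSH", "gamma_E", "gamma_Pg",
    "kappa_P", "kappa_E",
    "alpha_ER_h", "beta_ER_h", "kappa_up_h",
    "alpha_PgR_h", "beta_PgR_h", "delta_PgR_h",
    "alpha_ER_p", "beta_ER_p", "kappa_up_p",
    "alpha_PgR_p", "beta_PgR_p", "delta_PgR_p",
    "phi_F", "mu_F", "F_max", "F0", "LH_ov", "F_ov",
    "mu_L", "kappa_L",
    "e_F", "e_L", "p_L",
    "B_max", "K_B",
    "pg_infusion", "lock_high",
    "dt",
    "G_sat", "g_agonist",
)

#: Fields allowed to be exactly zero (gonadal secretion is switched off in
#: the menopause preset; the infusion and mode lock are scenario knobs).
_NONNEG_FIELDS = frozenset({"g_low", "e_F", "e_L", "p_L", "pg_infusion", "lock_high"})

STATE_FIELDS = (
    "mode", "R", "ERh", "PgRh", "ERp", "PgRp",
    "F", "L", "E_tot", "Pg", "FSH", "LH", "t_above", "L_ref",
)

_FRACTION_FIELDS = ("R", "ERh", "PgRh", "ERp", "PgRp")


@dataclass(frozen=True)
class ModelParams:
    """Rate constants, thresholds and capacities of the canonical dynamics.

    Units: rates 1/day; secretion coefficients in the output hormone's
    concentration unit per day per source unit; thresholds in signal units
    (free estradiol x receptor fraction); dt in days.  The shipped
    defaults are calibration products, not measured quantities.
    """

    g_low: float          # GnRH drive, LOW mode (dimensionless)
    g_high: float         # GnRH drive, HIGH mode
    alpha_R: float        # GnRHR resynthesis rate (1/day)
    beta_R: float         # GnRHR downregulation rate per unit drive (1/day)
    theta_on: float       # hypothalamic estrogen signal for LOW->HIGH
    theta_off: float      # signal below which HIGH->LOW (hysteresis)
    tau_on: float         # sustained exposure required before LOW->HIGH (day)
    sigma_LH: float       # maximal LH secretion coefficient (IU/L/day)
    sigma_FSH: float      # maximal FSH secretion coefficient (IU/L/day)
    gamma_LH: float       # LH clearance (1/day)
    gamma_FSH: float      # FSH clearance (1/day)
    gamma_E: float        # free-estradiol clearance (1/day)
    gamma_Pg: float       # progesterone clearance (1/day)
    kappa_P: float        # half-inhibition of LH secretion by Pg x PgRp
    kappa_E: float        # half-inhibition of FSH secretion by free E2
    alpha_ER_h: float     # hypothalamic ER synthesis (1/day)
    beta_ER_h: float      # hypothalamic ER loss per unit Pg signal (1/day)
    kappa_up_h: float     # free E2 halving hypothalamic ER synthesis
    alpha_PgR_h: float    # hypothalamic PgR induction per unit E2 signal
    beta_PgR_h: float     # hypothalamic PgR loss per unit Pg signal
    delta_PgR_h: float    # hypothalamic PgR basal turnover (1/day)
    alpha_ER_p: float     # pituitary analogues of the six constants above
    beta_ER_p: float
    kappa_up_p: float
    alpha_PgR_p: float
    beta_PgR_p: float
    delta_PgR_p: float
    phi_F: float          # follicle growth coefficient (per IU/L per day)
    mu_F: float           # follicle decay (1/day)
    F_max: float          # follicle carrying capacity (arbitrary units)
    F0: float             # recruitment seed (arbitrary units)
    LH_ov: float          # LH threshold for ovulation (IU/L)
    F_ov: float           # follicle-activity threshold for ovulation
    mu_L: float           # luteal decay rate (1/day)
    kappa_L: float        # LH level halving luteal decay (IU/L)
    e_F: float            # estradiol secretion per follicle unit (pmol/L/day)
    e_L: float            # estradiol secretion per luteal unit (pmol/L/day)
    p_L: float            # progesterone secretion per luteal unit (nmol/L/day)
    B_max: float          # SHBG pool capacity (pmol/L)
    K_B: float            # SHBG half-saturation (pmol/L)
    pg_infusion: float = 0.0   # exogenous progesterone infusion (nmol/L/day)
    lock_high: float = 0.0     # 1.0 locks the drive at g_agonist (agonist preset)
    dt: float = 0.002          # Euler step (day)
    G_sat: float = 60.0        # drive half-saturating gonadotropin secretion
    g_agonist: float = 500.0   # continuous agonist-equivalent drive (overexposure)

    def __post_init__(self) -> None:
        for name in PARAM_FIELDS:
            value = float(getattr(self, name))
            object.__setattr__(self, name, value)
            if not math.isfinite(value):
                raise InvalidConfigError(f"parameter {name} must be finite, got {value}")
            if name in _NONNEG_FIELDS:
                if value < 0:
                    raise InvalidConfigError(f"parameter {name} must be >= 0, got {value}")
            elif value <= 0:
                raise InvalidConfigError(f"parameter {name} must be > 0, got {value}")
        if self.g_high <= self.g_low:
            raise InvalidConfigError("g_high must exceed g_low")
        if self.theta_off >= self.theta_on:
            raise InvalidConfigError("theta_off must be below theta_on")
        if self.dt > 0.05:
            raise InvalidConfigError(f"dt must be <= 0.05 day, got {self.dt}")
        if self.lock_high not in (0.0, 1.0):
            raise InvalidConfigError("lock_high must be 0 or 1")

    def replace(self, **changes) -> "ModelParams":
        return dataclasses.replace(self, **changes)

    def to_array(self) -> np.ndarray:
        return np.array([getattr(self, f) for f in PARAM_FIELDS], dtype=float)


@dataclass(frozen=True)
class ModelState:
    """Instantaneous model state.

    ``mode`` is 0 (LOW) or 1 (HIGH); receptor pools are availability
    fractions in [0, 1]; F and L are follicle / corpus-luteum activities
    in arbitrary units; ``L_ref`` remembers the luteal activity set at the
    last ovulation (it gates follicle recruitment); ``t_above`` is the
    consecutive time (days) the hypothalamic estrogen signal has exceeded
    theta_on.
    """

    mode: int
    R: float
    ERh: float
    PgRh: float
    ERp: float
    PgRp: float
    F: float
    L: float
    E_tot: float
    Pg: float
    FSH: float
    LH: float
    t_above: float = 0.0
    L_ref: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in (LOW, HIGH):
            raise InvalidConfigError(f"mode must be {LOW} or {HIGH}")
        for name in STATE_FIELDS[1:]:
            value = float(getattr(self, name))
            object.__setattr__(self, name, value)
            if not math.isfinite(value) or value < 0:
                raise InvalidConfigError(f"state field {name} must be finite and >= 0")
        for name in _FRACTION_FIELDS:
            if getattr(self, name) > 1:
                raise InvalidConfigError(f"state field {name} must be <= 1")

    def to_array(self) -> np.ndarray:
        return np.array([float(getattr(self, f)) for f in STATE_FIELDS], dtype=float)

    @classmethod
    def from_array(cls, arr: np.ndarray) -> "ModelState":
        values = dict(zip(STATE_FIELDS, (float(v) for v in arr)))
        values["mode"] = int(values["mode"])
        return cls(**values)


@dataclass(frozen=True)
class SimOutput:
    """Simulation result sampled at integer days."""

    series: HormoneSeries
    state_trace: pd.DataFrame       # one row per sampled day, STATE_FIELDS columns
    events: list                    # [(time_days, event_name), ...]

    def event_times(self, name: str) -> list[float]:
        return [t for t, n in self.events if n == name]


# ---------------------------------------------------------------------------
# JIT kernel

_I = {name: i for i, name in enumerate(PARAM_FIELDS)}
_S = {name: i for i, name in enumerate(STATE_FIELDS)}


@njit(cache=False)
def _deriv(s: np.ndarray, p: np.ndarray, d: np.ndarray) -> None:
    """Time-derivatives of the continuous state under the current regime.

    Indices 1..11 (receptor pools, compartments, hormones) are filled;
    mode, t_above and L_ref carry no continuous dynamics."""
    mode = s[0]
    R = s[1]; ERh = s[2]; PgRh = s[3]; ERp = s[4]; PgRp = s[5]
    F = s[6]; L = s[7]; E_tot = s[8]; Pg = s[9]; FSH = s[10]; LH = s[11]

    if p[41] > 0.5:
        G = p[44]
    elif mode > 0.5:
        G = p[1]
    else:
        G = p[0]
    # secretion saturates in drive (finite releasable capacity) while
    # receptor downregulation stays linear: overexposure is hypogonadal
    G_sec = G / (1.0 + G / p[43])

    E_f = E_tot - p[38] * E_tot / (p[39] + E_tot)
    if E_f < 0.0:
        E_f = 0.0
    Q = Pg * PgRp

    d[0] = 0.0
    d[1] = p[2] * (1.0 - R) - p[3] * G * R
    d[2] = p[15] * (1.0 - ERh) / (1.0 + E_f / p[17]) - p[16] * (Pg * PgRh) * ERh
    d[3] = p[18] * (E_f * ERh) * (1.0 - PgRh) - p[19] * (Pg * PgRh) - p[20] * PgRh
    d[4] = p[21] * (1.0 - ERp) / (1.0 + E_f / p[23]) - p[22] * (Pg * PgRp) * ERp
    d[5] = p[24] * (E_f * ERp) * (1.0 - PgRp) - p[25] * (Pg * PgRp) - p[26] * PgRp
    d[6] = p[27] * FSH * F * (1.0 - F / p[29]) - p[28] * F
    d[7] = -p[33] * L / (1.0 + LH / p[34])
    d[8] = p[35] * F + p[36] * L - p[11] * E_f
    d[9] = p[37] * L + p[40] - p[12] * Pg
    d[10] = p[8] * G_sec * R / (1.0 + E_f / p[14]) - p[10] * FSH
    d[11] = p[7] * G_sec * R / (1.0 + Q / p[13]) - p[9] * LH
    d[12] = 0.0
    d[13] = 0.0


@njit(cache=False)
def _clip_state(s: np.ndarray) -> None:
    for i in range(1, 6):       # receptor availability fractions
        if s[i] < 0.0:
            s[i] = 0.0
        elif s[i] > 1.0:
            s[i] = 1.0
    for i in range(6, 12):      # compartments and concentrations
        if s[i] < 0.0:
            s[i] = 0.0


@njit(cache=False)
def _signal(s: np.ndarray, p: np.ndarray) -> float:
    """Hypothalamic estrogen signal S = free E2 x hypothalamic ER."""
    E_tot = s[8]
    E_f = E_tot - p[38] * E_tot / (p[39] + E_tot)
    if E_f < 0.0:
        E_f = 0.0
    return E_f * s[2]


@njit(cache=False)
def _step_kernel(s: np.ndarray, p: np.ndarray, d: np.ndarray, st: np.ndarray,
                 ev_codes: np.ndarray, ev_fracs: np.ndarray) -> int:
    """One in-place step of length dt: midpoint (RK2) for the continuous
    dynamics with sub-step event localization.

    Threshold events (ovulation 1, LOW->HIGH 2, HIGH->LOW 3) are located
    by linear interpolation inside the step and the regime change is
    applied at the interpolated time, so neither the O(dt) Euler bias nor
    the discontinuities dominate the error.  Event codes and their
    fractional times within the step are written to ev_codes/ev_fracs;
    returns their count.
    """
    dt = p[42]
    n_ev = 0
    lock = p[41] > 0.5

    # recruitment: a hard reseed gated on luteal regression (slow dynamics,
    # checked once per step)
    if s[7] < 0.01 * s[13] and s[6] < p[30]:
        s[6] = p[30]

    c = 0.0
    for _ in range(4):
        if c >= 1.0:
            break
        h = (1.0 - c) * dt
        # midpoint rule: evaluate the slope halfway along the Euler segment
        _deriv(s, p, d)
        for i in range(14):
            st[i] = s[i] + 0.5 * h * d[i]
        _clip_state(st)
        _deriv(st, p, d)
        for i in range(14):
            st[i] = s[i] + h * d[i]
        _clip_state(st)
        S0 = _signal(s, p)
        S1 = _signal(st, p)

        theta = 2.0
        ev = 0
        # ovulation: LH and follicle activity both above threshold
        if s[11] > p[31] and s[6] > p[32]:
            theta = 0.0
            ev = 1
        elif st[11] > p[31] and st[6] > p[32]:
            th = 0.0
            if s[11] <= p[31] and st[11] > s[11]:
                th_lh = (p[31] - s[11]) / (st[11] - s[11])
                if th_lh > th:
                    th = th_lh
            if s[6] <= p[32] and st[6] > s[6]:
                th_f = (p[32] - s[6]) / (st[6] - s[6])
                if th_f > th:
                    th = th_f
            if th < theta:
                theta = th
                ev = 1
        if not lock:
            if s[0] < 0.5:
                # LOW: t_above accumulates while S exceeds theta_on
                t_ab = s[12]
                if S0 > p[4]:
                    if S1 > p[4]:
                        if t_ab + h >= p[6]:
                            th = (p[6] - t_ab) / h
                            if th < theta:
                                theta = th
                                ev = 2
                    else:
                        thc = (S0 - p[4]) / (S0 - S1)
                        if t_ab + thc * h >= p[6]:
                            th = (p[6] - t_ab) / h
                            if th < theta:
                                theta = th
                                ev = 2
                elif S1 > p[4]:
                    thc = (p[4] - S0) / (S1 - S0)
                    if (1.0 - thc) * h >= p[6]:
                        th = thc + p[6] / h
                        if th < theta:
                            theta = th
                            ev = 2
            else:
                # HIGH: switches back the moment S falls below theta_off
                if S0 < p[5]:
                    theta = 0.0
                    ev = 3
                elif S1 < p[5]:
                    th = (S0 - p[5]) / (S0 - S1)
                    if th < theta:
                        theta = th
                        ev = 3

        if ev == 0 or theta > 1.0:
            # no event in this sub-interval: accept the trial state
            if not lock and s[0] < 0.5:
                if S1 > p[4]:
                    if S0 > p[4]:
                        st[12] = s[12] + h
                    else:
                        st[12] = (1.0 - (p[4] - S0) / (S1 - S0)) * h
                else:
                    st[12] = 0.0
            else:
                st[12] = s[12]
            for i in range(14):
                s[i] = st[i]
            c = 1.0
        else:
            if theta < 0.0:
                theta = 0.0
            for i in range(1, 12):
                s[i] = s[i] + theta * h * d[i]
            _clip_state(s)
            if ev == 1:
                if not lock and s[0] < 0.5 and S0 > p[4]:
                    s[12] += theta * h
                s[7] = s[6]
                s[13] = s[6]
                s[6] = 0.0
            elif ev == 2:
                s[0] = 1.0
                s[12] = p[6]
            else:
                s[0] = 0.0
                s[12] = 0.0
            c = c + theta * (1.0 - c)
            ev_codes[n_ev] = ev
            ev_fracs[n_ev] = c
            n_ev += 1
    return n_ev


@njit(cache=False)
def _simulate_kernel(s0: np.ndarray, p: np.ndarray, n_days: int):
    dt = p[42]
    spd = int(round(1.0 / dt))
    n_steps = n_days * spd
    trace = np.empty((n_days + 1, 14))
    trace[0] = s0
    ev_time = np.empty(4 * n_days + 16)
    ev_code = np.empty(4 * n_days + 16, dtype=np.int64)
    n_ev = 0
    codes = np.empty(4, dtype=np.int64)
    fracs = np.empty(4)
    d = np.empty(14)
    st = np.empty(14)
    s = s0.copy()
    ok = True
    for k in range(n_steps):
        m = _step_kernel(s, p, d, st, codes, fracs)
        for j in range(m):
            if n_ev < ev_time.shape[0]:
                ev_time[n_ev] = k * dt + fracs[j] * dt
                ev_code[n_ev] = 1 if codes[j] == 1 else (2 if codes[j] == 2 else 3)
                n_ev += 1
        if (k + 1) % spd == 0:
            day = (k + 1) // spd
            trace[day] = s
            for v in s:
                if not np.isfinite(v):
                    ok = False
            if not ok:
                break
    return trace, ev_time[:n_ev], ev_code[:n_ev], ok


# ---------------------------------------------------------------------------
# Public API

def step(state: ModelState, params: ModelParams) -> ModelState:
    """Advance the model by one integration step of length ``params.dt``."""
    s = state.to_array()
    _step_kernel(s, params.to_array(), np.empty(14), np.empty(14),
                 np.empty(4, dtype=np.int64), np.empty(4))
    if not np.all(np.isfinite(s)):
        raise NumericalInstabilityError(
            "non-finite state after one step; use a smaller dt"
        )
    return ModelState.from_array(s)


def simulate(
    params: ModelParams, n_days: float, init: ModelState | None = None
) -> SimOutput:
    """Integrate the model for ``n_days`` days, sampling at integer days.

    Deterministic: identical inputs give bit-identical output.  Events
    (ovulation, LOW->HIGH ``mode_on``, HIGH->LOW ``mode_off``) are recorded
    at the continuous step time at which they fire.
    """
    if n_days <= 0:
        raise InvalidConfigError("n_days must be positive")
    if init is None:
        init = default_initial_state()
    whole_days = int(math.floor(n_days))
    trace, ev_time, ev_code, ok = _simulate_kernel(
        init.to_array(), params.to_array(), whole_days
    )
    if not ok:
        raise NumericalInstabilityError(
            "simulation diverged to non-finite values; use a smaller dt"
        )
    days = np.arange(whole_days + 1)
    series = HormoneSeries(
        days=days,
        fsh=trace[:, _S["FSH"]],
        lh=trace[:, _S["LH"]],
        estradiol=trace[:, _S["E_tot"]],
        progesterone=trace[:, _S["Pg"]],
    )
    state_trace = pd.DataFrame(trace, columns=list(STATE_FIELDS))
    state_trace.insert(0, "day", days)
    events = [(float(t), _EVENT_NAMES[int(c)]) for t, c in zip(ev_time, ev_code)]
    return SimOutput(series=series, state_trace=state_trace, events=events)


def default_initial_state() -> ModelState:
    """Packaged initial state: early follicular, just after a luteolysis."""
    return ModelState(
        mode=LOW, R=0.25, ERh=0.70, PgRh=0.05, ERp=0.70, PgRp=0.05,
        F=0.05, L=0.01, E_tot=120.0, Pg=0.6, FSH=7.0, LH=6.0,
        t_above=0.0, L_ref=1.0,
    )


# Calibrated default parameter set (see the calibration module); frozen so
# that simulations are reproducible across releases.
_DEFAULTS = dict(
    g_low=1.0, g_high=13.24,
    alpha_R=0.03775, beta_R=0.165705,
    theta_on=577.362, theta_off=70.6131, tau_on=1.78289,
    sigma_LH=110.453, sigma_FSH=30.0,
    gamma_LH=1.71765, gamma_FSH=1.5, gamma_E=1.5, gamma_Pg=0.175163,
    kappa_P=2.57567, kappa_E=350.0,
    alpha_ER_h=0.25, beta_ER_h=0.0140506, kappa_up_h=300.0,
    alpha_PgR_h=0.000229116, beta_PgR_h=0.002, delta_PgR_h=0.03,
    alpha_ER_p=0.25, beta_ER_p=0.0140506, kappa_up_p=300.0,
    alpha_PgR_p=0.000229116, beta_PgR_p=0.002, delta_PgR_p=0.03,
    phi_F=0.235081, mu_F=0.00969779, F_max=1.5, F0=0.05,
    LH_ov=20.0, F_ov=0.5,
    mu_L=2.4636, kappa_L=0.327038,
    e_F=1200.0, e_L=1500.0, p_L=7.0,
    B_max=250.0, K_B=150.0,
    pg_infusion=0.0, lock_high=0.0, dt=0.002,
    G_sat=197.758, g_agonist=500.0,
)


def default_params() -> ModelParams:
    """Return the packaged calibrated parameter set."""
    return ModelParams(**_DEFAULTS)


#: Progesterone-only infusion rates (nmol/L/day) for the contraception
#: presets; packaged constants chosen during calibration.
PG_INFUSION_LOW = 1.0
PG_INFUSION_HIGH = 12.0

SCENARIOS = ("baseline", "menopause", "gnrh_agonist", "pg_low", "pg_high")


def apply_scenario(params: ModelParams, name: str) -> ModelParams:
    """Return a parameter set for a named physiological scenario.

    baseline      identity.
    menopause     no gonadal secretion (e_F = e_L = p_L = 0): the exhausted
                  ovary stops producing estradiol and progesterone.
    gnrh_agonist  continuous agonist overexposure: the GnRH drive is locked
                  at g_high and the hypothalamic switch is disabled.
    pg_low        constant low-dose exogenous progesterone infusion.
    pg_high       constant high-dose exogenous progesterone infusion.
    """
    if name == "baseline":
        return params
    if name == "menopause":
        return params.replace(e_F=0.0, e_L=0.0, p_L=0.0)
    if name == "gnrh_agonist":
        return params.replace(lock_high=1.0)
    if name == "pg_low":
        return params.replace(pg_infusion=PG_INFUSION_LOW)
    if name == "pg_high":
        return params.replace(pg_infusion=PG_INFUSION_HIGH)
    raise ScenarioError(f"unknown scenario {name!r}; known: {SCENARIOS}")


# ---------------------------------------------------------------------------
# TOML parameter files

def params_to_toml(params: ModelParams, path) -> None:
    """Write a flat TOML file with one key per parameter field."""
    lines = [f"{name} = {getattr(params, name)!r}" for name in PARAM_FIELDS]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\n".join(lines) + "\n")


def params_from_toml(path) -> ModelParams:
    """Read a flat TOML parameter file, validating every invariant."""
    with open(path, "rb") as fh:
        try:
            raw = tomllib.load(fh)
        except tomllib.TOMLDecodeError as exc:
            raise FormatError(f"cannot parse TOML at {path}: {exc}") from exc
    unknown = set(raw) - set(PARAM_FIELDS)
    if unknown:
        raise FormatError(f"unknown parameter key(s) {sorted(unknown)} in {path}")
    missing = [k for k in PARAM_FIELDS if k not in raw and k not in ("pg_infusion", "lock_high", "dt", "G_sat", "g_agonist")]
    if missing:
        raise FormatError(f"missing parameter key(s) {missing} in {path}")
    try:
        return ModelParams(**raw)
    except InvalidConfigError as exc:
        raise InvalidConfigError(f"{exc} (from {path})") from exc
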