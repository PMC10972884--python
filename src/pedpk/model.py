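"""Structural pharmacokinetic model: one compartment, first-order absorption.

The model is parameterized the way pediatric cetirizine data are usually
described: apparent clearance CL/F and apparent volume V/F carry linear age
covariates (and a fractional sex effect on CL/F), inter-individual
variability is lognormal on CL/F and V/F, and the absorption rate constant
is tied to elimination through a flip-flop construction

    ka = theta_ka + CL/V,

which guarantees ka > ke for any covariate/eta combination as long as
theta_ka > 0.

Units: dose in mg, volume in L, time in h.  Concentrations are returned in
ug/L (equivalently ng/mL); with doses of a few mg and volumes of tens of
litres this puts single-dose peaks in the tens-to-hundreds of ug/L, the
range reported for therapeutic drug monitoring of cetirizine in children.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "CONC_SCALE",
    "SUPPORTED_AGE_RANGE",
    "PARAMETER_NAMES",
    "PopulationParameters",
    "Covariates",
    "IndividualParameters",
    "DoseEvent",
    "Regimen",
    "ExposureMetrics",
    "typical_params",
    "individual_params",
    "conc_single_dose",
    "conc_history",
    "conc_steady_state",
    "exposure_metrics_ss",
]

#: mg/L -> reported concentration unit (ug/L by default).
CONC_SCALE = 1000.0

#: Age range (years) over which covariate multipliers must stay positive.
SUPPORTED_AGE_RANGE = (0.5, 14.0)

#: Names of the scalar population parameters, in canonical order.
PARAMETER_NAMES = (
    "tvcl", "cl_age", "cl_sex", "tvv", "v_age", "tvka",
    "omega2_cl", "omega2_v", "sigma2_prop", "sigma2_add",
)

# Relative tolerance below which ka ~= ke switches to the L'Hopital limit.
# The expm1 formulation keeps the closed form stable to machine-level gaps,
# so the switch can sit far below any practically reachable gap; the limit
# form's first-order truncation error (~gap*t/2) is then negligible.
_FLIPFLOP_TOL = 1e-12


class InvalidCovariateError(ValueError):
    """A covariate combination drives a structural parameter non-positive."""


@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects, variance components and fix-flags of the population model.

    Parameters
    ----------
    tvcl : typical CL/F (L/h) for a male of age ``age_ref``.
    cl_age : linear age scaling factor on CL/F (1/yr), multiplicative
        centered form ``(1 + cl_age * (age - age_ref))``.
    cl_sex : fractional sex effect on CL/F for females (dimensionless).
    tvv : typical V/F (L) at ``age_ref``.
    v_age : linear age scaling factor on V/F (1/yr).
    tvka : additive typical absorption constant theta_ka (1/h).
    omega2_cl, omega2_v : variances of the lognormal inter-individual
        random effects on CL/F and V/F.
    sigma2_prop : proportional residual-error variance (dimensionless).
    sigma2_add : additive residual-error variance, in (ug/L)^2.
    age_ref : centering age (yr) for the covariate terms.
    fixed : mapping name -> bool; parameters flagged True are never touched
        by estimation.
    """

    tvcl: float
    cl_age: float
    cl_sex: float
    tvv: float
    v_age: float
    tvka: float
    omega2_cl: float
    omega2_v: float
    sigma2_prop: float
    sigma2_add: float = 0.0
    age_ref: float = 0.0
    fixed: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in ("tvcl", "tvv", "tvka"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0, got {getattr(self, name)!r}")
        for name in ("omega2_cl", "omega2_v", "sigma2_prop", "sigma2_add"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)!r}")
        lo, hi = SUPPORTED_AGE_RANGE
        for a in (lo, hi):
            if 1.0 + self.cl_age * (a - self.age_ref) <= 0:
                raise ValueError(
                    f"CL/F age multiplier non-positive at age {a} y (cl_age={self.cl_age})"
                )
            if 1.0 + self.v_age * (a - self.age_ref) <= 0:
                raise ValueError(
                    f"V/F age multiplier non-positive at age {a} y (v_age={self.v_age})"
                )
        if 1.0 + self.cl_sex <= 0:
            raise ValueError(f"sex multiplier non-positive (cl_sex={self.cl_sex})")

    def is_fixed(self, name: str) -> bool:
        return bool(self.fixed.get(name, False))

    def omega_matrix(self) -> np.ndarray:
        """Diagonal covariance of (eta_cl, eta_v)."""
        return np.diag([self.omega2_cl, self.omega2_v])

    def with_values(self, **updates) -> "PopulationParameters":
        """Return a copy with the given scalar parameters replaced."""
        return replace(self, **updates)


@dataclass(frozen=True)
class Covariates:
    """Demographics of one subject.

    Only age and sex enter the structural model; weight is used for mg/kg
    dose accounting and height is descriptive.
    """

    age: float
    sex: str  # "male" | "female"
    weight: float | None = None
    height: float | None = None

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError(f"age must be > 0, got {self.age}")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        if self.weight is not None and self.weight <= 0:
            raise ValueError(f"weight must be > 0, got {self.weight}")

    @property
    def is_female(self) -> bool:
        return self.sex == "female"


@dataclass(frozen=True)
class IndividualParameters:
    """Subject-level PK parameters after covariates and random effects."""

    cl: float
    v: float
    ka: float
    ke: float
    t_half: float
    eta_cl: float = 0.0
    eta_v: float = 0.0


@dataclass(frozen=True)
class DoseEvent:
    """A single oral administration at ``time`` hours after first dose."""

    time: float
    amount: float
    is_error_dose: bool = False

    def __post_init__(self):
        if self.time < 0:
            raise ValueError(f"dose time must be >= 0, got {self.time}")
        if self.amount < 0:
            raise ValueError(f"dose amount must be >= 0, got {self.amount}")


@dataclass(frozen=True)
class Regimen:
    """A repeated-dosing schedule: ``dose`` mg every ``interval`` hours."""

    dose: float
    interval: float
    n_doses: int | None = None  # None = to steady state

    def __post_init__(self):
        if self.interval <= 0:
            raise ValueError(f"interval must be > 0, got {self.interval}")
        if self.dose < 0:
            raise ValueError(f"dose must be >= 0, got {self.dose}")

    def dose_events(self, n_doses: int | None = None) -> list[DoseEvent]:
        n = n_doses if n_doses is not None else self.n_doses
        if n is None:
            raise ValueError("n_doses must be given for an open-ended regimen")
        return [DoseEvent(i * self.interval, self.dose) for i in range(n)]


@dataclass(frozen=True)
class ExposureMetrics:
    """Steady-state exposure summary for one dosing interval."""

    cmax_ss: float
    tmax_ss: float
    cmin_ss: float
    auc_tau: float


def typical_params(pop: PopulationParameters, cov: Covariates) -> tuple[float, float, float]:
    """Covariate-adjusted typical values (tvcl_i, tvv_i, tvka_i); no random effects."""
    da = cov.age - pop.age_ref
    cl_mult = (1.0 + pop.cl_age * da) * (1.0 + (pop.cl_sex if cov.is_female else 0.0))
    v_mult = 1.0 + pop.v_age * da
    tvcl_i = pop.tvcl * cl_mult
    tvv_i = pop.tvv * v_mult
    if tvcl_i <= 0:
        raise InvalidCovariateError(
            f"CL/F multiplier non-positive for age={cov.age}, sex={cov.sex}"
        )
    if tvv_i <= 0:
        raise InvalidCovariateError(f"V/F multiplier non-positive for age={cov.age}")
    return tvcl_i, tvv_i, pop.tvka


def individual_params(
    pop: PopulationParameters,
    cov: Covariates,
    eta_cl: float = 0.0,
    eta_v: float = 0.0,
) -> IndividualParameters:
    """Apply lognormal random effects and the flip-flop absorption construction."""
    if not (math.isfinite(eta_cl) and math.isfinite(eta_v)):
        raise ValueError("random effects must be finite")
    tvcl_i, tvv_i, tvka_i = typical_params(pop, cov)
    cl = tvcl_i * math.exp(eta_cl)
    v = tvv_i * math.exp(eta_v)
    ke = cl / v
    ka = tvka_i + ke
    return IndividualParameters(
        cl=cl, v=v, ka=ka, ke=ke, t_half=math.log(2.0) / ke,
        eta_cl=eta_cl, eta_v=eta_v,
    )


def _profile(ind, dose, t, ka, ke):
    """Single-dose profile in mg/L for t >= 0 (array-safe).

    Written as -e^(-ke t) expm1(-(ka-ke) t) / (ka-ke), which is free of the
    catastrophic cancellation of e^(-ke t) - e^(-ka t) when ka ~= ke; the
    explicit limit form covers the exactly-degenerate case.
    """
    if abs(ka - ke) < _FLIPFLOP_TOL * ke:
        return dose * ka * t * np.exp(-ka * t) / ind.v
    delta = ka - ke
    return -dose * ka / (ind.v * delta) * np.exp(-ke * t) * np.expm1(-delta * t)


def conc_single_dose(ind: IndividualParameters, dose: float, t):
    """Concentration (ug/L) at time ``t`` h after a single oral dose (mg).

    Scalar or array ``t``; negative times raise.  The degenerate ka ~= ke
    case switches continuously to the L'Hopital limit form.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    out = CONC_SCALE * _profile(ind, dose, t_arr, ind.ka, ind.ke)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def conc_history(ind: IndividualParameters, doses, t):
    """Superposed concentration (ug/L) from an arbitrary dosing history.

    ``doses`` must be sorted ascending in time (no silent sorting); linear
    PK makes each contribution additive.
    """
    times = [d.time for d in doses]
    if any(b < a for a, b in zip(times, times[1:])):
        raise ValueError("dose events must be sorted ascending in time")
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be >= 0")
    total = np.zeros_like(t_arr)
    for d in doses:
        dt = t_arr - d.time
        mask = dt > 0
        if np.any(mask):
            total = total + np.where(mask, _profile(ind, d.amount, np.maximum(dt, 0.0), ind.ka, ind.ke), 0.0)
    out = CONC_SCALE * total
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def conc_steady_state(ind: IndividualParameters, dose: float, tau: float, t):
    """Steady-state concentration (ug/L) at ``t`` h into a dosing interval.

    Closed-form accumulation of the single-dose profile under dosing every
    ``tau`` h; requires 0 <= t <= tau.
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    t_arr = np.asarray(t, dtype=float)
    if np.any((t_arr < 0) | (t_arr > tau)):
        raise ValueError("t must lie within [0, tau]")
    ka, ke, v = ind.ka, ind.ke, ind.v
    if abs(ka - ke) < _FLIPFLOP_TOL * ke:
        e_tau = math.exp(-ka * tau)
        acc = np.exp(-ka * t_arr) * (t_arr / (1 - e_tau) + tau * e_tau / (1 - e_tau) ** 2)
        out = CONC_SCALE * dose * ka / v * acc
    else:
        # cancellation-free split: a e^(-ke t) - b e^(-ka t)
        #   = a [e^(-ke t) - e^(-ka t)] + (a - b) e^(-ka t),
        # with both bracketed factors carrying an explicit expm1(-delta *).
        delta = ka - ke
        a = 1.0 / -math.expm1(-ke * tau)
        b = 1.0 / -math.expm1(-ka * tau)
        a_minus_b = -a * b * math.exp(-ke * tau) * math.expm1(-delta * tau)
        body = (
            -a * np.exp(-ke * t_arr) * np.expm1(-delta * t_arr)
            + a_minus_b * np.exp(-ka * t_arr)
        )
        out = CONC_SCALE * dose * ka / (v * delta) * body
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def exposure_metrics_ss(ind: IndividualParameters, dose: float, tau: float) -> ExposureMetrics:
    """Steady-state Cmax/Tmax/Cmin/AUC_tau for dosing every ``tau`` h.

    Tmax solves dC_ss/dt = 0 in closed form,
    t* = ln[(ka*b)/(ke*a)] / (ka - ke) with a, b the accumulation factors of
    the elimination and absorption exponentials; Cmin is the pre-dose trough
    C_ss(tau); AUC over the interval is dose/CL (linear PK mass balance).
    """
    if tau <= 0:
        raise ValueError(f"tau must be > 0, got {tau}")
    ka, ke = ind.ka, ind.ke
    if dose == 0.0:
        return ExposureMetrics(0.0, 0.0, 0.0, 0.0)
    if abs(ka - ke) < _FLIPFLOP_TOL * ke:
        # degenerate: locate the peak numerically on a fine grid + refinement
        from scipy.optimize import minimize_scalar

        res = minimize_scalar(
            lambda x: -conc_steady_state(ind, dose, tau, x),
            bounds=(0.0, tau), method="bounded",
            options={"xatol": 1e-10},
        )
        tmax = float(res.x)
    else:
        a = 1.0 / (1.0 - math.exp(-ke * tau))
        b = 1.0 / (1.0 - math.exp(-ka * tau))
        tmax = math.log((ka * b) / (ke * a)) / (ka - ke)
        tmax = min(max(tmax, 0.0), tau)
    cmax = float(conc_steady_state(ind, dose, tau, tmax))
    cmin = float(conc_steady_state(ind, dose, tau, tau))
    auc = CONC_SCALE * dose / ind.cl
    return ExposureMetrics(cmax_ss=cmax, tmax_ss=tmax, cmin_ss=cmin, auc_tau=auc)
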