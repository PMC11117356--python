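"""Final covariate population-PK model for meropenem and closed-form
one-compartment infusion kinetics.

The structural model is a one-compartment disposition with first-order
elimination.  Individual parameters are obtained from the population
(typical) values by body-weight scaling, a binary CRRT shift on the volume
of distribution, and log-normal inter-individual variability:

    CL_i = CLp * (BW_i / BW_ref) * exp(eta_CL),   eta_CL ~ N(0, omega2_cl)
    V_i  = Vp  * (BW_i / BW_ref) * (1 + theta_CRRT)^CRRT_i * exp(eta_V)

Concentrations follow the analytic constant-rate-infusion solution,
superposed over all dose events.  Residual (observation) variability is
proportional: y = f * (1 + eps), eps ~ N(0, sigma2_prop).

Units throughout: time h, concentration mg/L, amounts mg, body weight kg.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml

__all__ = [
    "PopulationParameters",
    "SubjectCovariates",
    "IndividualParameters",
    "DoseEvent",
    "Regimen",
    "ConcentrationProfile",
    "load_final_model",
    "individual_params",
    "conc_at",
    "profile",
    "ft_above_mic",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PopulationParameters:
    """Fixed effects and variance components of the final covariate model.

    Parameters
    ----------
    clp : population clearance at the reference body weight, L/h.
    vp : population volume of distribution at the reference body weight
        off CRRT, L.
    theta_crrt : fractional increase in Vd while on CRRT (dimensionless);
        Vd is multiplied by ``(1 + theta_crrt)**crrt_on``.
    omega2_cl, omega2_v : variances of the log-normal inter-individual
        random effects on CL and Vd.
    sigma2_prop : variance of the proportional residual error.
    bw_ref : reference (cohort median) body weight, kg.
    """

    clp: float
    vp: float
    theta_crrt: float = 0.0
    omega2_cl: float = 0.0
    omega2_v: float = 0.0
    sigma2_prop: float = 0.0
    bw_ref: float = 7.88

    def __post_init__(self) -> None:
        if not (self.clp > 0 and np.isfinite(self.clp)):
            raise ValueError(f"clp must be positive, got {self.clp}")
        if not (self.vp > 0 and np.isfinite(self.vp)):
            raise ValueError(f"vp must be positive, got {self.vp}")
        if not (self.theta_crrt > -1):
            raise ValueError(f"theta_crrt must exceed -1, got {self.theta_crrt}")
        for name in ("omega2_cl", "omega2_v", "sigma2_prop"):
            v = getattr(self, name)
            if not (v >= 0 and np.isfinite(v)):
                raise ValueError(f"{name} must be a finite non-negative variance, got {v}")
        if not (self.bw_ref > 0):
            raise ValueError(f"bw_ref must be positive, got {self.bw_ref}")

    def as_dict(self) -> dict:
        return {
            "clp": self.clp,
            "vp": self.vp,
            "theta_crrt": self.theta_crrt,
            "omega2_cl": self.omega2_cl,
            "omega2_v": self.omega2_v,
            "sigma2_prop": self.sigma2_prop,
            "bw_ref": self.bw_ref,
        }


def load_final_model() -> PopulationParameters:
    """Load the packaged final-model parameter estimates."""
    text = resources.files("neoperem.data").joinpath("final_model.yaml").read_text()
    raw = yaml.safe_load(text)
    return PopulationParameters(**raw)


@dataclass(frozen=True)
class SubjectCovariates:
    """Per-subject covariates entering (or screened for) the model.

    ``extras`` holds covariates used only by covariate search and data
    synthesis (PNA, CrCL, ECMO descriptors, labs, PIM3 ...).
    """

    bw: float
    crrt_on: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (self.bw > 0 and np.isfinite(self.bw)):
            raise ValueError(f"bw must be positive, got {self.bw}")
        if self.crrt_on not in (0, 1):
            raise ValueError(f"crrt_on must be 0 or 1, got {self.crrt_on}")
        for k, v in self.extras.items():
            if not np.isfinite(v):
                raise ValueError(f"extra covariate {k!r} is not finite: {v}")


@dataclass(frozen=True)
class IndividualParameters:
    """Realized individual clearance and volume; ke is derived as cl/v."""

    cl: float
    v: float

    def __post_init__(self) -> None:
        if not (self.cl > 0 and np.isfinite(self.cl)):
            raise ValueError(f"cl must be positive, got {self.cl}")
        if not (self.v > 0 and np.isfinite(self.v)):
            raise ValueError(f"v must be positive, got {self.v}")

    @property
    def ke(self) -> float:
        """First-order elimination rate constant, 1/h."""
        return self.cl / self.v


@dataclass(frozen=True)
class DoseEvent:
    """Constant-rate infusion: starts at `start` h, runs `duration` h at `rate` mg/h."""

    start: float
    rate: float
    duration: float

    def __post_init__(self) -> None:
        if not (self.start >= 0 and np.isfinite(self.start)):
            raise ValueError(f"start must be >= 0, got {self.start}")
        if not (self.rate > 0 and np.isfinite(self.rate)):
            raise ValueError(f"rate must be positive, got {self.rate}")
        if not (self.duration > 0 and np.isfinite(self.duration)):
            raise ValueError(f"duration must be positive, got {self.duration}")
        if not np.isfinite(self.rate * self.duration):
            raise ValueError("dose amount rate*duration is not finite")

    @property
    def amount(self) -> float:
        """Total infused amount, mg."""
        return self.rate * self.duration


@dataclass(frozen=True)
class Regimen:
    """Ordered collection of infusion events."""

    events: tuple
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "events", tuple(self.events))
        starts = [ev.start for ev in self.events]
        if any(b < a for a, b in zip(starts, starts[1:])):
            raise ValueError("regimen events must be sorted by start time")


@dataclass(frozen=True)
class ConcentrationProfile:
    """Concentration-time profile evaluated on a fixed grid."""

    times: np.ndarray
    conc: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "conc", np.asarray(self.conc, dtype=float))
        if self.times.shape != self.conc.shape:
            raise ValueError("times and conc must have the same shape")


# ---------------------------------------------------------------------------
# Covariate model
# ---------------------------------------------------------------------------

def individual_params(
    pop: PopulationParameters,
    cov: SubjectCovariates,
    eta_cl: float = 0.0,
    eta_v: float = 0.0,
) -> IndividualParameters:
    """Realize individual CL and Vd from the covariate model and random effects.

    CL = CLp*(BW/BW_ref)*exp(eta_cl);
    V  = Vp*(BW/BW_ref)*(1+theta_crrt)**crrt_on*exp(eta_v).
    """
    if not (np.isfinite(eta_cl) and np.isfinite(eta_v)):
        raise ValueError("random effects eta_cl/eta_v must be finite")
    scale = cov.bw / pop.bw_ref
    cl = pop.clp * scale * math.exp(eta_cl)
    v = pop.vp * scale * (1.0 + pop.theta_crrt) ** cov.crrt_on * math.exp(eta_v)
    return IndividualParameters(cl=cl, v=v)


# ---------------------------------------------------------------------------
# Closed-form infusion kinetics
# ---------------------------------------------------------------------------

def _superpose(cl, ke, events, t):
    """Vectorized superposition of infusion events.

    cl, ke : scalars or arrays of shape (n,); t : scalar or array of shape (m,).
    Returns concentrations of shape (n, m).  During an active infusion the
    contribution is (R/CL)(1-exp(-ke*tau)); afterwards it decays
    mono-exponentially from the end-of-infusion value.
    """
    cl = np.atleast_1d(np.asarray(cl, dtype=float))[:, None]
    ke = np.atleast_1d(np.asarray(ke, dtype=float))[:, None]
    tt = np.atleast_1d(np.asarray(t, dtype=float))[None, :]
    out = np.zeros(np.broadcast_shapes(cl.shape, ke.shape, tt.shape), dtype=float)
    for ev in events:
        rel = tt - ev.start
        tau1 = np.clip(rel, 0.0, ev.duration)       # time infused so far
        tau2 = np.clip(rel - ev.duration, 0.0, None)  # time since infusion end
        out = out + (ev.rate / cl) * (-np.expm1(-ke * tau1)) * np.exp(-ke * tau2)
    return out


def conc_at(ind: IndividualParameters, reg: Regimen, t):
    """Concentration (mg/L) at time(s) ``t`` h for one individual under ``reg``.

    Accepts a scalar or array ``t``; all times must be >= 0.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0) or not np.all(np.isfinite(t_arr)):
        raise ValueError("times must be finite and >= 0")
    c = _superpose(ind.cl, ind.ke, reg.events, t_arr)[0]
    if np.isscalar(t) or t_arr.ndim == 0:
        return float(c[0])
    return c


def profile(ind: IndividualParameters, reg: Regimen, grid) -> ConcentrationProfile:
    """Evaluate the concentration-time profile on a strictly increasing grid."""
    g = np.asarray(grid, dtype=float)
    if g.ndim != 1 or g.size < 1:
        raise ValueError("grid must be a 1-D array with at least one point")
    if np.any(np.diff(g) <= 0):
        raise ValueError("grid must be strictly increasing")
    return ConcentrationProfile(times=g, conc=conc_at(ind, reg, g))


def ft_above_mic(prof: ConcentrationProfile, mic: float) -> float:
    """Fraction of grid points with concentration strictly above the MIC.

    The time-above-MIC statistic is deliberately computed on the discrete
    evaluation grid (default spacing 0.25 h elsewhere in the package) so
    that it is auditable point by point.
    """
    if not (mic > 0 and np.isfinite(mic)):
        raise ValueError(f"mic must be positive, got {mic}")
    if prof.conc.size == 0:
        raise ValueError("profile is empty")
    return float(np.mean(prof.conc > mic))
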