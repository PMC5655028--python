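"""Phytochrome B photoconversion and decay kinetics.

PhyB interconverts between an inactive red-absorbing form (Pr) and an active
far-red-absorbing form (Pfr).  In light the two forms equilibrate fast, with
Pfr:Pr ratio set by the photoequilibrium constant ``K_Pfr``; because Pfr
decays faster than Pr, total PhyB relaxes from its dark stationary level
toward a lower light-phase plateau.  Scaling total PhyB by its dark
stationary concentration collapses the model to a single linear ODE

    d[PhyB]/dt = gamma_Pr * (1 - Q_Pfr * [PhyB]),    [PhyB](0) = 1

with composite decay factor ``Q_Pfr = (1 + Gamma_Pfr*K_Pfr)/(1 + K_Pfr)``
and Pfr fraction ``R_Pfr = K_Pfr/(1 + K_Pfr)``, solved in closed form here.
The full two-variable Pr/Pfr system is kept as a numerical oracle.

Time unit is days throughout; helpers convert tagged hour/minute inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.integrate import solve_ivp

from .trajectory import Trajectory

__all__ = [
    "PhotoParams",
    "to_days",
    "calibrate_rate_from_halflife",
    "kpfr_from_pr_fraction",
    "derive_photo_composites",
    "phyb_closed_form",
    "pfr_level",
    "integrate_two_state_ode",
    "DEFAULT_PHOTO",
    "MUTANT_Q",
]

_DAYS_PER_UNIT = {
    "d": 1.0,
    "day": 1.0,
    "days": 1.0,
    "h": 1.0 / 24.0,
    "hr": 1.0 / 24.0,
    "hours": 1.0 / 24.0,
    "hour": 1.0 / 24.0,
    "min": 1.0 / 1440.0,
    "minute": 1.0 / 1440.0,
    "minutes": 1.0 / 1440.0,
    "s": 1.0 / 86400.0,
    "sec": 1.0 / 86400.0,
    "seconds": 1.0 / 86400.0,
}

# PhyB-abundance scaling matching phyB-deficient mutant expression profiles
MUTANT_Q = 0.25


def to_days(value: float, unit: str = "days") -> float:
    """Convert a tagged duration to days (units: days/hours/minutes/seconds)."""
    try:
        factor = _DAYS_PER_UNIT[unit.lower()]
    except KeyError:
        raise ValueError(f"unknown time unit {unit!r}") from None
    return float(value) * factor


def calibrate_rate_from_halflife(half_life: float, unit: str = "days") -> float:
    """First-order rate constant (per day) from a half-life.

    Used to pin the pooled light-phase PhyB decay rate ``Q_Pfr*gamma_Pr``
    from the observed ~8 h half-life of PhyB in red light: 8 h gives
    3*ln(2) per day.
    """
    hl_days = to_days(half_life, unit)
    if hl_days <= 0:
        raise ValueError("half-life must be positive")
    return math.log(2.0) / hl_days


def kpfr_from_pr_fraction(pr_fraction: float) -> float:
    """Photoequilibrium constant implied by the residual Pr fraction in light.

    Pfr absorbs some red light, so ~13% of PhyB stays in Pr even under red
    light; K_Pfr = (1 - f_Pr)/f_Pr ≈ 6.7 ≈ 7.
    """
    if not 0.0 < pr_fraction < 1.0:
        raise ValueError("Pr fraction must lie in (0, 1)")
    return (1.0 - pr_fraction) / pr_fraction


# default calibration: K_Pfr = 7 and Q_Pfr = 8.75 (so Gamma_Pfr = 69/7),
# with the pooled rate Q_Pfr*gamma_Pr fixed by the 8-hour PhyB half-life
_Q_DEFAULT = 8.75
_POOLED_RATE = 3.0 * math.log(2.0)  # Q_Pfr * gamma_Pr, per day


@dataclass(frozen=True)
class PhotoParams:
    """Phytochrome photoconversion and decay constants.

    Parameters
    ----------
    K_Pfr : float
        Photoequilibrium constant Pfr:Pr in light (>= 0; 0 means darkness).
    Gamma_Pfr : float
        Decay-rate ratio gamma_Pfr/gamma_Pr (> 0).
    gamma_Pr : float
        Pr decay rate, per day (> 0).
    q : float
        PhyB-abundance scaling for phyB-deficient mutants, multiplying the
        whole PhyB (and hence Pfr) trajectory; 0 < q <= 1, wild type 1.
    k_Pr, k_Pfr_plus, k_Pfr_minus, k_dark : float, optional
        Absolute-scale constants of the two-state Pr/Pfr system (synthesis,
        photoconversion forward/backward, dark reversion).  When all four
        are given, k_Pfr_plus/(k_Pfr_minus + k_dark) must equal K_Pfr.
    """

    K_Pfr: float = 7.0
    Gamma_Pfr: float = 69.0 / 7.0
    gamma_Pr: float = _POOLED_RATE / _Q_DEFAULT
    q: float = 1.0
    k_Pr: float | None = None
    k_Pfr_plus: float | None = None
    k_Pfr_minus: float | None = None
    k_dark: float | None = None

    def __post_init__(self) -> None:
        if self.K_Pfr < 0:
            raise ValueError("K_Pfr must be >= 0")
        if self.Gamma_Pfr <= 0:
            raise ValueError("Gamma_Pfr must be > 0")
        if self.gamma_Pr <= 0:
            raise ValueError("gamma_Pr must be > 0")
        if not 0.0 < self.q <= 1.0:
            raise ValueError("q must lie in (0, 1]")
        absolute = [self.k_Pr, self.k_Pfr_plus, self.k_Pfr_minus, self.k_dark]
        if any(v is not None for v in absolute):
            if any(v is None for v in absolute):
                raise ValueError("give all four absolute constants or none")
            if any(v < 0 for v in absolute):
                raise ValueError("absolute rate constants must be >= 0")
            denom = self.k_Pfr_minus + self.k_dark
            if denom <= 0:
                raise ValueError("k_Pfr_minus + k_dark must be > 0")
            implied = self.k_Pfr_plus / denom
            scale = max(abs(self.K_Pfr), 1.0)
            if abs(implied - self.K_Pfr) > 1e-9 * scale:
                raise ValueError(
                    f"K_Pfr={self.K_Pfr} inconsistent with "
                    f"k_Pfr_plus/(k_Pfr_minus+k_dark)={implied}"
                )

    @property
    def Q_Pfr(self) -> float:
        return (1.0 + self.Gamma_Pfr * self.K_Pfr) / (1.0 + self.K_Pfr)

    @property
    def R_Pfr(self) -> float:
        return self.K_Pfr / (1.0 + self.K_Pfr)

    @property
    def gamma_Pfr(self) -> float:
        return self.Gamma_Pfr * self.gamma_Pr

    def with_q(self, q: float) -> "PhotoParams":
        return replace(self, q=q)

    @classmethod
    def dark(cls) -> "PhotoParams":
        """Darkness: no photoconversion, PhyB pinned at its dark level."""
        return cls(K_Pfr=0.0)

    @classmethod
    def mutant(cls, q: float = MUTANT_Q) -> "PhotoParams":
        return cls(q=q)

    def to_dict(self) -> dict:
        d = {
            "K_Pfr": self.K_Pfr,
            "Gamma_Pfr": self.Gamma_Pfr,
            "gamma_Pr": self.gamma_Pr,
            "q": self.q,
            "Q_Pfr": self.Q_Pfr,
            "R_Pfr": self.R_Pfr,
        }
        if self.k_Pr is not None:
            d.update(
                k_Pr=self.k_Pr,
                k_Pfr_plus=self.k_Pfr_plus,
                k_Pfr_minus=self.k_Pfr_minus,
                k_dark=self.k_dark,
            )
        return d


DEFAULT_PHOTO = PhotoParams()


def derive_photo_composites(params: PhotoParams) -> tuple[float, float]:
    """Return (Q_Pfr, R_Pfr) for the given photoconversion parameters."""
    return params.Q_Pfr, params.R_Pfr


def _check_times(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0 (light switch at t = 0)")
    return t


def phyb_closed_form(t, params: PhotoParams = DEFAULT_PHOTO):
    """Total PhyB relative to dark at time t (days) after the light switch.

    ``q * (1/Q_Pfr + (1 - 1/Q_Pfr) * exp(-Q_Pfr*gamma_Pr*t))`` — exponential
    relaxation from the dark level q to the light plateau q/Q_Pfr.
    """
    t = _check_times(t)
    Q = params.Q_Pfr
    out = params.q * (1.0 / Q + (1.0 - 1.0 / Q) * np.exp(-Q * params.gamma_Pr * t))
    return out if out.ndim else float(out)


def pfr_level(t, params: PhotoParams = DEFAULT_PHOTO):
    """Active Pfr relative to dark total PhyB: R_Pfr * [PhyB](t)."""
    return params.R_Pfr * phyb_closed_form(t, params)


def integrate_two_state_ode(
    params: PhotoParams,
    grid,
    form: str = "reduced",
    y0: tuple[float, float] | None = None,
) -> Trajectory:
    """Numerically integrate the PhyB kinetics; oracle for the closed form.

    ``form="reduced"`` integrates the scaled one-variable equation
    d[PhyB]/dt = gamma_Pr*(1 - Q_Pfr*[PhyB]) from [PhyB](0)=1.
    ``form="two_state"`` integrates the explicit Pr/Pfr pair (requires the
    absolute constants) from the dark stationary state Pr = k_Pr/gamma_Pr,
    Pfr = 0 unless ``y0`` overrides it; output is rescaled by the dark
    stationary concentration.  Both forms apply the mutant scaling q.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or grid[0] != 0.0:
        raise ValueError("grid must start at 0")
    opts = dict(method="LSODA", rtol=1e-8, atol=1e-10, dense_output=True)

    if form == "reduced":
        Q, g = params.Q_Pfr, params.gamma_Pr

        sol = solve_ivp(
            lambda t, y: [g * (1.0 - Q * y[0])], (0.0, grid[-1]), [1.0], **opts
        )
        if not sol.success:
            raise RuntimeError(f"PhyB integration failed: {sol.message}")
        phyb = params.q * sol.sol(grid)[0]
        pfr = params.R_Pfr * phyb
    elif form == "two_state":
        if params.k_Pr is None:
            raise ValueError("two_state form needs the absolute rate constants")
        kp, kf_p, kf_m, kd = (
            params.k_Pr,
            params.k_Pfr_plus,
            params.k_Pfr_minus,
            params.k_dark,
        )
        g_pr, g_pfr = params.gamma_Pr, params.gamma_Pfr

        def rhs(t, y):
            pr, pfr = y
            return [
                kp + (kf_m + kd) * pfr - (kf_p + g_pr) * pr,
                kf_p * pr - (kf_m + kd + g_pfr) * pfr,
            ]

        dark_stationary = kp / g_pr
        start = (dark_stationary, 0.0) if y0 is None else y0
        sol = solve_ivp(rhs, (0.0, grid[-1]), list(start), **opts)
        if not sol.success:
            raise RuntimeError(f"Pr/Pfr integration failed: {sol.message}")
        pr_t, pfr_t = sol.sol(grid)
        phyb = params.q * (pr_t + pfr_t) / dark_stationary
        pfr = params.q * pfr_t / dark_stationary
    else:
        raise ValueError(f"unknown form {form!r}; use 'reduced' or 'two_state'")

    return Trajectory(times=grid, species={"phyb": phyb, "pfr": pfr})
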