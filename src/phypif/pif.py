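"""PIF3 dynamics under Pfr-induced phosphorylation and degradation.

PIF3 accumulates in darkness and represses photomorphogenesis genes.  On
light exposure, Pfr dimers phosphorylate PIF3 dimers, which are then removed
by the 26S proteasome.  The full mechanism (monomer, dimer, phosphorylated
dimer) is a three-variable system; with fast dimerization, fast degradation
of the phosphorylated pool and negligible de-phosphorylation it reduces to
one equation for the PIF3 level relative to dark,

    d[PIF]/dt = gamma_PIF * (1 - [PIF] - R_PP * [PhyB]^2 * [PIF]^2),

where ``R_PP`` lumps phosphorylation rate, dimer equilibria, the Pfr
fraction and the dark PIF level into a single interaction strength.  Two
closed-form regimes bracket the behaviour: a hyperbolic fast decay at the
light switch (PhyB still ~1) and a slow quasi-steady branch riding on the
declining PhyB level; their combination gives an explicit approximation for
the whole time course.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp

from .phytochrome import DEFAULT_PHOTO, PhotoParams, phyb_closed_form
from .trajectory import Trajectory

__all__ = [
    "PIFParams",
    "PIFFullParams",
    "DEFAULT_PIF",
    "REGIME_FIXTURE",
    "pif_reduced_rhs",
    "integrate_pif",
    "solve_pif",
    "integrate_full_pif",
    "pif_fast",
    "pif_slow",
    "pif_closed_form",
]

# gamma_PIF * R_PP = 96/day reproduces the measured ~15-minute PIF3 half-life
_FAST_RATE = 96.0
_RPP_DEFAULT = 350.0

# R_PP lumps the squared Pfr fraction of the red-light photoequilibrium
# (R_Pfr = 0.875 at K_Pfr = 7); under a different light quality the
# interaction strength rescales as (R_Pfr / 0.875)^2 — zero in darkness.
CALIBRATION_R_PFR = 0.875


def _effective_rpp(params: "PIFParams", photo: PhotoParams) -> float:
    return params.R_PP * (photo.R_Pfr / CALIBRATION_R_PFR) ** 2


@dataclass(frozen=True)
class PIFParams:
    """Reduced PIF3 model parameters.

    R_PP is the dimensionless PhyB–PIF3 interaction strength; gamma_PIF the
    basal (dark) PIF3 turnover rate per day.  The product gamma_PIF*R_PP
    sets the initial light-phase decay scale (96/day = 1/(15 min) at the
    defaults).
    """

    R_PP: float = _RPP_DEFAULT
    gamma_PIF: float = _FAST_RATE / _RPP_DEFAULT

    def __post_init__(self) -> None:
        if self.R_PP < 0:
            raise ValueError("R_PP must be >= 0")
        if self.gamma_PIF <= 0:
            raise ValueError("gamma_PIF must be > 0")

    @property
    def fast_rate(self) -> float:
        """gamma_PIF * R_PP, per day — the hyperbolic fast-decay scale."""
        return self.gamma_PIF * self.R_PP

    def to_dict(self) -> dict:
        return {"R_PP": self.R_PP, "gamma_PIF": self.gamma_PIF}


DEFAULT_PIF = PIFParams()


@dataclass(frozen=True)
class PIFFullParams:
    """Parameters of the explicit three-variable PIF3 system.

    Species: monomer [PIF], dimer [PIF2], phosphorylated dimer [PIF2*].
    Monomers are produced constitutively (k_PIF), decay at gamma_PIF, and
    dimerize with on/off rates k_PIF2_plus/minus; Pfr dimers (equilibrium
    K_dim_Pfr) phosphorylate PIF2 at rate k_PR; epsilon reverses the
    phosphorylation and gamma_star degrades the phosphorylated pool;
    gamma_2PIF is the decay of unphosphorylated dimers.
    """

    k_PIF: float
    gamma_PIF: float
    k_PIF2_plus: float
    k_PIF2_minus: float
    k_PR: float
    K_dim_Pfr: float
    epsilon: float
    gamma_star: float
    gamma_2PIF: float
    PIF_dark: float | None = None

    def __post_init__(self) -> None:
        for name in (
            "k_PIF",
            "gamma_PIF",
            "k_PIF2_plus",
            "k_PIF2_minus",
            "K_dim_Pfr",
            "gamma_star",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.k_PR < 0 or self.epsilon < 0 or self.gamma_2PIF < 0:
            raise ValueError("k_PR, epsilon and gamma_2PIF must be >= 0")

    @property
    def K_dim_PIF(self) -> float:
        return self.k_PIF2_plus / self.k_PIF2_minus

    def dark_steady_state(self) -> tuple[float, float, float]:
        """Dark fixed point (Pfr = 0): phosphorylated pool empty, monomer
        from the quadratic balance of synthesis, decay and dimer leak."""
        leak = self.k_PIF2_plus * self.gamma_2PIF / (self.k_PIF2_minus + self.gamma_2PIF)
        if leak == 0.0:
            pif = self.k_PIF / self.gamma_PIF
        else:
            pif = (
                -self.gamma_PIF
                + math.sqrt(self.gamma_PIF**2 + 4.0 * leak * self.k_PIF)
            ) / (2.0 * leak)
        pif2 = self.k_PIF2_plus * pif**2 / (self.k_PIF2_minus + self.gamma_2PIF)
        return pif, pif2, 0.0

    def regime_flags(self, pfr_typical: float) -> dict[str, bool]:
        """Whether the stated reduction regime holds at a typical Pfr level:
        epsilon small vs phosphorylation and vs gamma_star, dimer decay
        small vs monomer decay, dimerization fast vs monomer turnover."""
        phos = self.k_PR * self.K_dim_Pfr * pfr_typical**2
        return {
            "epsilon_small_vs_phosphorylation": self.epsilon < 0.1 * phos,
            "epsilon_small_vs_gamma_star": self.epsilon < 0.1 * self.gamma_star,
            "dimer_decay_small": self.gamma_2PIF < 0.1 * self.gamma_PIF,
            "dimerization_fast": self.k_PIF2_minus > 10.0 * self.gamma_PIF,
        }

    def reduced_equivalent(self, photo: PhotoParams = DEFAULT_PHOTO) -> PIFParams:
        """The PIFParams whose reduced equation this system collapses to
        when driven by pfr(t) = R_Pfr * [PhyB](t) in relative units."""
        pif_dark = self.PIF_dark or self.dark_steady_state()[0]
        r_pp = (
            self.k_PR
            * self.K_dim_PIF
            * self.K_dim_Pfr
            * photo.R_Pfr**2
            * pif_dark
            / self.gamma_PIF
        )
        return PIFParams(R_PP=r_pp, gamma_PIF=self.gamma_PIF)


# Illustrative parameter set satisfying the reduction regime (synthetic,
# not a measured calibration): fast dimerization, small epsilon and dimer
# decay, fast proteasomal removal; collapses to the default reduced model.
def _regime_fixture() -> PIFFullParams:
    gamma_pif = DEFAULT_PIF.gamma_PIF
    # small dimer fraction: the dimer pool would otherwise buffer the fast
    # monomer decay and pull the full system off the reduced solution
    k_dim_pif = 0.02
    # with PIF_dark ~ k_PIF/gamma_PIF = 1 and pfr_fn = R_Pfr*phyb,
    # k_PR*K_dim_Pfr*k_dim_PIF*R_Pfr^2*PIF_dark/gamma_PIF = R_PP = 350
    r_fr = DEFAULT_PHOTO.R_Pfr
    k_pr = DEFAULT_PIF.R_PP * gamma_pif / (k_dim_pif * r_fr**2 * 1.0)
    return PIFFullParams(
        k_PIF=gamma_pif,
        gamma_PIF=gamma_pif,
        k_PIF2_plus=2e4,
        k_PIF2_minus=1e6,
        k_PR=k_pr,
        K_dim_Pfr=1.0,
        epsilon=0.01,
        gamma_star=1e4,
        gamma_2PIF=1e-3 * gamma_pif,
        PIF_dark=1.0,
    )


REGIME_FIXTURE = _regime_fixture()


def pif_reduced_rhs(pif: float, phyb: float, params: PIFParams = DEFAULT_PIF) -> float:
    """Right-hand side of the reduced PIF3 equation (per day)."""
    return params.gamma_PIF * (1.0 - pif - params.R_PP * phyb**2 * pif**2)


def solve_pif(params: PIFParams = DEFAULT_PIF, photo: PhotoParams = DEFAULT_PHOTO,
              t_max: float = 7.0):
    """Dense numerical solution of the reduced PIF3 equation on [0, t_max].

    Returns a callable t -> [PIF](t) (vectorised); the PhyB drive is the
    closed-form trajectory and the interaction strength is rescaled by
    (R_Pfr/0.875)^2 when the photoequilibrium differs from the red-light
    calibration (so darkness gives no drive).  Used by the expression and
    fitting stages.
    """
    Q, g_pr, q = photo.Q_Pfr, photo.gamma_Pr, photo.q
    eff = PIFParams(R_PP=_effective_rpp(params, photo), gamma_PIF=params.gamma_PIF)

    def phyb(t):
        return q * (1.0 / Q + (1.0 - 1.0 / Q) * math.exp(-Q * g_pr * t))

    def rhs(t, y):
        return [pif_reduced_rhs(y[0], phyb(t), eff)]

    sol = solve_ivp(
        rhs, (0.0, t_max), [1.0],
        method="LSODA", rtol=1e-8, atol=1e-10, dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"PIF integration failed: {sol.message}")

    def pif_fn(t):
        out = sol.sol(np.atleast_1d(np.asarray(t, dtype=float)))[0]
        out = np.clip(out, 0.0, None)
        return out if np.ndim(t) else float(out[0])

    return pif_fn


def integrate_pif(
    params: PIFParams = DEFAULT_PIF,
    photo: PhotoParams = DEFAULT_PHOTO,
    grid=None,
) -> Trajectory:
    """Numerical PIF3 trajectory (relative to dark) on the given grid."""
    if grid is None:
        grid = np.linspace(0.0, 7.0, 701)
    grid = np.asarray(grid, dtype=float)
    pif_fn = solve_pif(params, photo, t_max=float(grid[-1]) if grid[-1] > 0 else 1.0)
    phyb = phyb_closed_form(grid, photo)
    return Trajectory(
        times=grid,
        species={
            "phyb": np.atleast_1d(phyb),
            "pfr": photo.R_Pfr * np.atleast_1d(phyb),
            "pif": pif_fn(grid),
        },
    )


def integrate_full_pif(
    params: PIFFullParams,
    pfr_fn,
    grid,
) -> Trajectory:
    """Integrate the explicit three-variable PIF3 system.

    ``pfr_fn`` maps time (days) to the Pfr concentration in the units the
    rate constants expect.  Starts from the dark steady state.  Returns
    absolute concentrations plus the monomer level relative to dark
    (species "pif_rel"), which tracks the reduced model in its regime.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or grid[0] != 0.0:
        raise ValueError("grid must start at 0 at the dark steady state")
    y0 = params.dark_steady_state()

    kp, g, k2p, k2m = params.k_PIF, params.gamma_PIF, params.k_PIF2_plus, params.k_PIF2_minus
    kpr_eff = params.k_PR * params.K_dim_Pfr
    eps, g_star, g2 = params.epsilon, params.gamma_star, params.gamma_2PIF

    def rhs(t, y):
        pif, pif2, pif2s = y
        pfr2 = pfr_fn(t) ** 2
        dim_on = k2p * pif * pif
        return [
            kp - g * pif - dim_on + k2m * pif2,
            dim_on - k2m * pif2 - kpr_eff * pfr2 * pif2 - g2 * pif2 + eps * pif2s,
            kpr_eff * pfr2 * pif2 - eps * pif2s - g_star * pif2s,
        ]

    sol = solve_ivp(
        rhs, (0.0, grid[-1]), list(y0),
        method="Radau", rtol=1e-8, atol=1e-12, dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"full PIF integration failed: {sol.message}")
    pif, pif2, pif2s = np.clip(sol.sol(grid), 0.0, None)
    return Trajectory(
        times=grid,
        species={
            "pif": pif,
            "pif2": pif2,
            "pif2_star": pif2s,
            "pif_rel": pif / y0[0],
        },
    )


def pif_fast(t, params: PIFParams = DEFAULT_PIF):
    """Fast-limit PIF3 decay right after the light switch (PhyB ~ 1):
    hyperbolic decay 1/(1 + gamma_PIF*R_PP*t) with half-value time
    1/(gamma_PIF*R_PP) — 15 minutes at the defaults."""
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    out = 1.0 / (1.0 + params.fast_rate * t)
    return out if out.ndim else float(out)


def pif_slow(phyb, params: PIFParams = DEFAULT_PIF):
    """Quasi-steady PIF3 branch: the positive root of
    1 - p - R_PP*phyb^2*p^2 = 0, in (0, 1]; returns 1 when the quadratic
    coefficient vanishes (darkness or R_PP = 0)."""
    phyb = np.asarray(phyb, dtype=float)
    a = params.R_PP * phyb**2
    with np.errstate(invalid="ignore", divide="ignore"):
        root = (np.sqrt(1.0 + 4.0 * a) - 1.0) / (2.0 * a)
    # series 1 - a + 2a^2 for tiny a avoids 0/0
    small = a < 1e-8
    out = np.where(small, 1.0 - a + 2.0 * a**2, root)
    return out if out.ndim else float(out)


def pif_closed_form(
    t,
    params: PIFParams = DEFAULT_PIF,
    photo: PhotoParams = DEFAULT_PHOTO,
):
    """Explicit fast+slow approximation of the PIF3 time course.

    Sum of the hyperbolic fast decay and a slow term tied to the PhyB
    relaxation; valid when 4*R_PP/Q_Pfr >> 1 (a warning is issued below 10).
    Long-time limit: Q_Pfr*(sqrt(R_PP) - Q_Pfr/2)/R_PP.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    r_pp = _effective_rpp(params, photo)
    if r_pp == 0:
        out = np.ones_like(t)
        return out if out.ndim else float(out)
    Q = photo.Q_Pfr
    if 4.0 * r_pp / Q < 10.0:
        warnings.warn(
            "closed-form PIF approximation requires 4*R_PP/Q_Pfr >> 1",
            stacklevel=2,
        )
    fast = 1.0 / (1.0 + params.gamma_PIF * r_pp * t)
    relax = 1.0 + (Q - 1.0) * np.exp(-Q * photo.gamma_Pr * t)
    slow = Q * (math.sqrt(r_pp) - Q / 2.0) / (r_pp * relax**2)
    out = fast + slow
    return out if out.ndim else float(out)
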