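"""Expression of PIF3-repressed nuclear genes (SIGs, PAPs, PRIN2).

PIF3 binds target promoters as a dimer; the synthesis rate of a repressed
gene X is proportional to the probability that its promoter is free,
V_max/(1 + [PIF]^2/K_PIF).  After rescaling transcript level and the
dissociation constant by their dark values, the relative expression obeys
the linear ODE

    d[X]/dt = gamma * (phi(t) - [X]),   phi = (K_PIF + 1)/(K_PIF + [PIF]^2),

with [X](0) = 1.  phi is the relative synthesis rate: 1 in darkness, up to
(K_PIF+1)/K_PIF when PIF3 is fully depleted — so smaller K_PIF (stronger
dark repression) means a larger light response.  Transcript turnover gamma
defaults to a 6-hour half-life for every gene, leaving K_PIF as the single
gene-specific parameter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.integrate import quad, solve_ivp
from scipy.interpolate import PchipInterpolator

from .phytochrome import DEFAULT_PHOTO, PhotoParams
from .pif import DEFAULT_PIF, PIFParams, pif_slow
from .trajectory import Trajectory

__all__ = [
    "GeneParams",
    "DEFAULT_GENES",
    "GAMMA_TRANSCRIPT",
    "phi",
    "absolute_dark_stationary",
    "integrate_expression",
    "expression_by_quadrature",
    "expression_short_time",
    "expression_stationary",
    "peak_metrics",
]

# all transcripts share a 6-hour half-life => gamma = 4*ln2 per day
GAMMA_TRANSCRIPT = 4.0 * math.log(2.0)


@dataclass(frozen=True)
class GeneParams:
    """One PIF3-repressed gene: relative dissociation constant and turnover.

    K_PIF is the PIF3-promoter dissociation constant after rescaling by the
    dark PIF3 level (dimensionless, > 0; smaller = stronger dark
    repression).  gamma is the transcript decay rate per day.  V_max and
    K_PIF_raw document the absolute-scale model behind the rescaling.
    """

    gene_id: str
    K_PIF: float
    gamma: float = GAMMA_TRANSCRIPT
    V_max: float | None = None
    K_PIF_raw: float | None = None

    def __post_init__(self) -> None:
        if self.K_PIF <= 0:
            raise ValueError("K_PIF must be > 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")


# relative dissociation constants reproducing the measured light-induction
# profiles of the six assayed PEP-associated genes
DEFAULT_GENES: dict[str, GeneParams] = {
    g: GeneParams(g, k)
    for g, k in [
        ("SIG2", 0.32),
        ("SIG6", 0.22),
        ("PAP1", 0.35),
        ("PAP2", 0.12),
        ("PAP5", 0.48),
        ("PRIN2", 0.09),
    ]
}


def phi(pif, K_PIF: float):
    """Relative synthesis rate (K_PIF + 1)/(K_PIF + pif^2).

    Equals 1 in darkness (pif = 1); rises to (K_PIF + 1)/K_PIF as PIF3 is
    depleted; strictly decreasing in pif.
    """
    if K_PIF <= 0:
        raise ValueError("K_PIF must be > 0")
    pif = np.asarray(pif, dtype=float)
    if np.any(pif < 0):
        raise ValueError("pif must be >= 0")
    out = (K_PIF + 1.0) / (K_PIF + pif**2)
    return out if out.ndim else float(out)


def absolute_dark_stationary(V_max: float, gamma: float, K_PIF_raw: float) -> float:
    """Dark stationary transcript level on the absolute scale:
    (V_max/gamma) * K/(K + 1).  Documents the rescaling that yields the
    relative-to-dark model; not used by the simulation itself."""
    if V_max <= 0 or gamma <= 0 or K_PIF_raw <= 0:
        raise ValueError("all arguments must be > 0")
    return (V_max / gamma) * K_PIF_raw / (K_PIF_raw + 1.0)


def _pif_interp(pif_traj: Trajectory):
    if "pif" not in pif_traj:
        raise ValueError("trajectory lacks a 'pif' species")
    return PchipInterpolator(pif_traj.times, pif_traj["pif"])


def integrate_expression(gene: GeneParams, pif_traj: Trajectory, pif_fn=None) -> Trajectory:
    """Relative expression [X](t) on the trajectory grid, from [X](0) = 1.

    The PIF3 drive is a monotone (PCHIP) interpolant of the trajectory
    unless a dense callable ``pif_fn`` is supplied.
    """
    fn = pif_fn if pif_fn is not None else _pif_interp(pif_traj)
    g, K = gene.gamma, gene.K_PIF

    def rhs(t, y):
        p = float(fn(t))
        return [g * ((K + 1.0) / (K + p * p) - y[0])]

    grid = pif_traj.times
    sol = solve_ivp(
        rhs, (0.0, grid[-1]), [1.0],
        method="LSODA", rtol=1e-9, atol=1e-11, dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"expression integration failed for {gene.gene_id}: {sol.message}")
    x = np.clip(sol.sol(grid)[0], 0.0, None)
    species = dict(pif_traj.species)
    species[gene.gene_id] = x
    return Trajectory(times=grid, species=species)


def expression_by_quadrature(
    gene: GeneParams, pif_traj: Trajectory, t: float, pif_fn=None
) -> float:
    """[X](t) by the convolution integral
    exp(-gamma*t) + gamma * int_0^t phi(s) exp(-gamma*(t-s)) ds,
    evaluated by adaptive quadrature; independent oracle for the ODE route.
    """
    if t < 0 or t > pif_traj.times[-1]:
        raise ValueError("t outside the trajectory span")
    if t == 0:
        return 1.0
    fn = pif_fn if pif_fn is not None else _pif_interp(pif_traj)
    g, K = gene.gamma, gene.K_PIF

    def integrand(s):
        p = float(fn(s))
        return (K + 1.0) / (K + p * p) * math.exp(-g * (t - s))

    val, _ = quad(integrand, 0.0, t, epsabs=1e-11, epsrel=1e-9, limit=200)
    return math.exp(-g * t) + g * val


def expression_short_time(t, gene: GeneParams) -> float:
    """Early-time expansion of the expression response:
    (1 + ((K+1)/K) * (gamma*t + (gamma*t)^2/2)) * exp(-gamma*t),
    valid for t below ~1/sqrt(gamma_Pfr * gamma) (about 9.4 h at defaults).
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    bound = 1.0 / math.sqrt(DEFAULT_PHOTO.gamma_Pfr * gene.gamma)
    if np.any(t > bound):
        warnings.warn(
            f"short-time expansion used beyond its validity bound ({bound:.3f} days)",
            stacklevel=2,
        )
    gt = gene.gamma * t
    out = (1.0 + (gene.K_PIF + 1.0) / gene.K_PIF * (gt + gt**2 / 2.0)) * np.exp(-gt)
    return out if out.ndim else float(out)


def expression_stationary(
    gene: GeneParams,
    pif_params: PIFParams = DEFAULT_PIF,
    photo: PhotoParams = DEFAULT_PHOTO,
    mode: str = "limit",
) -> float:
    """Stationary relative expression under constant light.

    mode "limit" (default): phi evaluated at the long-time limit of the
    explicit PIF3 approximation, PIF_inf = Q*(sqrt(R_PP) - Q/2)/R_PP.
    mode "slow_manifold": phi at the exact quasi-steady PIF3 level for the
    stationary PhyB plateau 1/Q (matches the numeric engine's long-time
    state).
    mode "as_printed": the typeset stationary formula with inner term
    (Q/sqrt(R_PP) + Q^2/2)^2, kept verbatim for comparison; it is not
    consistent with the explicit solution's limit.
    """
    K = gene.K_PIF
    if pif_params.R_PP == 0:
        return 1.0
    Q, R = photo.Q_Pfr, pif_params.R_PP
    if mode == "limit":
        pif_inf = Q * (math.sqrt(R) - Q / 2.0) / R
        return (K + 1.0) / (K + pif_inf**2)
    if mode == "slow_manifold":
        pif_inf = pif_slow(photo.q / Q, pif_params)
        return (K + 1.0) / (K + pif_inf**2)
    if mode == "as_printed":
        inner = Q / math.sqrt(R) + Q**2 / 2.0
        return (K + 1.0) / (K + inner**2)
    raise ValueError(f"unknown mode {mode!r}")


def peak_metrics(traj: Trajectory, gene_id: str) -> tuple[float, float]:
    """(time, value) of the expression maximum on the grid; ties go to the
    earliest time."""
    if gene_id not in traj:
        raise ValueError(f"trajectory has no species {gene_id!r}")
    values = traj[gene_id]
    if values.size == 0:
        raise ValueError("empty trajectory")
    i = int(np.argmax(values))  # argmax returns the first maximum
    return float(traj.times[i]), float(values[i])
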