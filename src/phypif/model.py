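"""Forward model orchestration: light switch -> PhyB -> PIF3 -> expression.

Bundles the stage parameters into one configuration and provides the dense
forward evaluations the fitting and synthetic-data stages share.  The PIF3
engine is numeric integration of the reduced equation by default; the
explicit closed-form approximation is available behind ``engine``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import solve_ivp

from .expression import GeneParams
from .phytochrome import DEFAULT_PHOTO, PhotoParams, phyb_closed_form
from .pif import DEFAULT_PIF, PIFParams, pif_closed_form, solve_pif
from .trajectory import Trajectory

__all__ = ["ModelConfig", "pif_function", "forward_gene", "simulate_genes"]


@dataclass(frozen=True)
class ModelConfig:
    """Full parameterisation of the forward model.

    engine: "numeric" integrates the reduced PIF3 ODE (the default used for
    fitting); "closed_form" uses the explicit fast+slow approximation.
    """

    photo: PhotoParams = DEFAULT_PHOTO
    pif: PIFParams = DEFAULT_PIF
    engine: str = "numeric"

    def __post_init__(self) -> None:
        if self.engine not in ("numeric", "closed_form"):
            raise ValueError(f"unknown engine {self.engine!r}")

    def with_q(self, q: float) -> "ModelConfig":
        return replace(self, photo=self.photo.with_q(q))

    def to_dict(self) -> dict:
        return {
            "photo": self.photo.to_dict(),
            "pif": self.pif.to_dict(),
            "engine": self.engine,
        }


def pif_function(config: ModelConfig, t_max: float):
    """Callable t -> [PIF](t) for the configured engine."""
    if config.engine == "numeric":
        return solve_pif(config.pif, config.photo, t_max=t_max)
    return lambda t: pif_closed_form(t, config.pif, config.photo)


def forward_gene(gene: GeneParams, config: ModelConfig, times) -> np.ndarray:
    """Relative expression of one gene at the requested times (days)."""
    times = np.asarray(times, dtype=float)
    if np.any(times < 0):
        raise ValueError("times must be >= 0")
    t_max = float(times.max()) if times.size else 1.0
    pif_fn = pif_function(config, t_max=max(t_max, 1e-6))
    g, K = gene.gamma, gene.K_PIF

    def rhs(t, y):
        p = float(pif_fn(t))
        return [g * ((K + 1.0) / (K + p * p) - y[0])]

    sol = solve_ivp(
        rhs, (0.0, max(t_max, 1e-6)), [1.0],
        method="LSODA", rtol=1e-8, atol=1e-10, dense_output=True,
    )
    if not sol.success:
        raise RuntimeError(f"forward model failed for {gene.gene_id}: {sol.message}")
    return np.clip(sol.sol(times)[0], 0.0, None)


def simulate_genes(
    genes: dict[str, GeneParams] | list[GeneParams],
    config: ModelConfig = ModelConfig(),
    grid=None,
) -> Trajectory:
    """Simulate PhyB, Pfr, PIF3 and every gene on a common grid."""
    if grid is None:
        grid = np.linspace(0.0, 7.0, 701)
    grid = np.asarray(grid, dtype=float)
    gene_list = list(genes.values()) if isinstance(genes, dict) else list(genes)
    phyb = np.atleast_1d(phyb_closed_form(grid, config.photo))
    species = {"phyb": phyb, "pfr": config.photo.R_Pfr * phyb}
    pif_fn = pif_function(config, t_max=float(grid[-1]) if grid[-1] > 0 else 1.0)
    species["pif"] = np.atleast_1d(pif_fn(grid))
    for gene in gene_list:
        species[gene.gene_id] = forward_gene(gene, config, grid)
    return Trajectory(times=grid, species=species)
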