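"""Synthetic inputs with the statistical structure the pipeline assumes.

Emulates the study's data products without any download: qPCR-style
fold-change time courses (multiplicative lognormal replicate noise around
the forward model, >= 9 replicates per point with mean +/- SE), decay
curves of PhyB or PIF3 for half-life calibration, and promoter sequences
with motifs planted at known offsets on an otherwise motif-free background.
Everything is seeded and bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .expression import DEFAULT_GENES, GeneParams
from .fitting import ExpressionSeries
from .model import ModelConfig, forward_gene, pif_function
from .motifs import DEFAULT_MOTIFS, PromoterRecord, reverse_complement
from .phytochrome import phyb_closed_form

__all__ = [
    "SyntheticConfig",
    "DEFAULT_TIMES",
    "default_promoter_plants",
    "gen_expression_series",
    "gen_all_series",
    "gen_decay_series",
    "gen_promoters",
]

DEFAULT_TIMES = (0.0, 0.125, 0.25, 0.5, 1.0, 2.0, 3.0, 5.0, 7.0)


def default_promoter_plants() -> dict[str, list[tuple[str, int]]]:
    """A 13-gene fixture mirroring the qualitative published pattern:
    PBE-box in every promoter, G-box in a subset, positions clustered in
    three upstream regions."""
    regions = (-2900, -1500, -200)
    g_box_genes = {"PAP1", "PAP2", "PAP11", "PRIN2", "SIG4", "SIG5"}
    genes = [
        "SIG1", "SIG2", "SIG3", "SIG4", "SIG5", "SIG6",
        "PAP1", "PAP2", "PAP3", "PAP5", "PAP6", "PAP11", "PRIN2",
    ]
    plants: dict[str, list[tuple[str, int]]] = {}
    for i, g in enumerate(genes):
        pos = regions[i % 3]
        plants[g] = [("PBE-box", pos)]
        if g in g_box_genes:
            plants[g].append(("G-box", regions[(i + 1) % 3] - 50))
    return plants


@dataclass
class SyntheticConfig:
    """Generator settings; defaults emulate the study conditions."""

    seed: int = 0
    sampling_times: tuple[float, ...] = DEFAULT_TIMES
    n_replicates: int = 9
    noise_cv: float = 0.15
    genes: dict[str, GeneParams] = field(default_factory=lambda: dict(DEFAULT_GENES))
    q: float = 1.0
    promoter_length: int = 3000
    gc_fraction: float = 0.36
    plants: dict[str, list[tuple[str, int]]] = field(
        default_factory=default_promoter_plants
    )

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")
        if self.noise_cv < 0:
            raise ValueError("noise_cv must be >= 0")
        t = np.asarray(self.sampling_times, dtype=float)
        if t[0] != 0 or np.any(np.diff(t) <= 0):
            raise ValueError("sampling_times must be sorted and start at 0")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must lie in (0, 1)")

    def rng(self, *key: int) -> np.random.Generator:
        """Deterministic per-purpose stream: seed + stable integer key."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=key))

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "sampling_times": list(self.sampling_times),
            "n_replicates": self.n_replicates,
            "noise_cv": self.noise_cv,
            "genes": {g: p.K_PIF for g, p in self.genes.items()},
            "q": self.q,
            "promoter_length": self.promoter_length,
            "gc_fraction": self.gc_fraction,
        }


def _lognormal_factors(rng, cv: float, shape) -> np.ndarray:
    """Multiplicative noise with mean exactly 1: sigma^2 = ln(1+cv^2),
    mu = -sigma^2/2."""
    if cv == 0:
        return np.ones(shape)
    sigma2 = math.log(1.0 + cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=shape)


def gen_expression_series(
    config: SyntheticConfig,
    gene: GeneParams,
    model_config: ModelConfig = ModelConfig(),
    gene_index: int = 0,
    model_vals=None,
) -> ExpressionSeries:
    """Noisy replicate fold-changes around the forward model for one gene.

    The t = 0 model value is 1 by construction and noise is applied there
    too, as in a real normalised experiment.  Precomputed ``model_vals`` on
    the sampling grid skip the forward solve (useful when generating many
    seeded series under one configuration).
    """
    times = np.asarray(config.sampling_times, dtype=float)
    if model_vals is None:
        model_vals = forward_gene(gene, model_config.with_q(config.q), times)
    else:
        model_vals = np.asarray(model_vals, dtype=float)
        if model_vals.shape != times.shape:
            raise ValueError("model_vals must match sampling_times")
    rng = config.rng(1, gene_index)
    noise = _lognormal_factors(rng, config.noise_cv, (times.size, config.n_replicates))
    return ExpressionSeries(
        gene_id=gene.gene_id,
        times=times,
        replicates=model_vals[:, None] * noise,
    )


def gen_all_series(
    config: SyntheticConfig, model_config: ModelConfig = ModelConfig()
) -> list[ExpressionSeries]:
    return [
        gen_expression_series(config, gene, model_config, gene_index=i)
        for i, gene in enumerate(config.genes.values())
    ]


def gen_decay_series(
    config: SyntheticConfig,
    which: str = "phyb",
    noise_sd: float = 0.0,
    grid=None,
    model_config: ModelConfig = ModelConfig(),
):
    """(time, value) decay samples of PhyB or PIF3 with additive Gaussian
    noise; the PhyB curve is the closed form, PIF3 the numeric solution."""
    if grid is None:
        grid = np.linspace(0.0, 1.0, 25)
    grid = np.asarray(grid, dtype=float)
    if which == "phyb":
        vals = np.atleast_1d(phyb_closed_form(grid, model_config.photo.with_q(config.q)))
    elif which == "pif":
        pif_fn = pif_function(model_config, t_max=float(grid[-1]))
        vals = np.atleast_1d(pif_fn(grid))
    else:
        raise ValueError("which must be 'phyb' or 'pif'")
    if noise_sd > 0:
        vals = vals + config.rng(2).normal(0.0, noise_sd, vals.shape)
        vals = np.clip(vals, 1e-9, None)
    return grid, vals


_BASES = np.array(list("ACGT"))


def _background(rng, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(4, size=length, p=p)


def gen_promoters(config: SyntheticConfig, motifs: dict[str, str] | None = None):
    """Promoters with motifs planted at exact offsets on a clean background.

    The background is i.i.d. at the configured GC fraction with every
    spontaneous occurrence of the target motifs (either strand) rewritten,
    so a scan recovers exactly the planted set.  Plant offsets are
    positions of the motif's 5'-most base relative to ATG.
    """
    if motifs is None:
        motifs = DEFAULT_MOTIFS
    targets = {m.upper() for m in motifs.values()}
    targets |= {reverse_complement(m) for m in targets}
    length = config.promoter_length
    records = []
    for idx, (seq_id, plant_list) in enumerate(config.plants.items()):
        spans = []
        for motif_name, offset in plant_list:
            if motif_name not in motifs:
                raise ValueError(f"unknown motif {motif_name!r} planted in {seq_id}")
            m = len(motifs[motif_name])
            if not -length <= offset <= -m:
                raise ValueError(
                    f"plant offset {offset} outside [-{length}, -{m}] in {seq_id}"
                )
            start = length + offset
            spans.append((start, start + m, motifs[motif_name].upper()))
        spans.sort()
        for (s1, e1, _), (s2, _, _) in zip(spans, spans[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping plant positions in {seq_id}")
        rng = config.rng(3, idx)
        codes = _background(rng, length, config.gc_fraction)
        seq = _scrub(codes, targets, rng, protected=[])
        for start, end, motif in spans:
            seq[start:end] = [_BASES.tolist().index(b) for b in motif]
        # planting can create junction occurrences; rewrite any stray ones
        protected = [(s, e) for s, e, _ in spans]
        seq = _scrub(seq, targets, rng, protected=protected)
        records.append(PromoterRecord(seq_id, "".join(_BASES[seq])))
    return records


def _scrub(codes, targets: set[str], rng, protected, max_rounds: int = 200):
    """Rewrite every non-protected target-motif occurrence until none remain."""
    codes = np.asarray(codes).copy()
    k = len(next(iter(targets)))
    for _ in range(max_rounds):
        text = "".join(_BASES[codes])
        dirty = []
        for i in range(len(text) - k + 1):
            if text[i : i + k] in targets and not any(
                s <= i and i + k <= e for s, e in protected
            ):
                if any(i < e and s < i + k for s, e in protected):
                    # overlaps a plant edge: only rewrite bases outside it
                    free = [
                        j for j in range(i, i + k)
                        if not any(s <= j < e for s, e in protected)
                    ]
                    dirty.extend(free)
                else:
                    dirty.extend(range(i, i + k))
        if not dirty:
            return codes
        dirty = sorted(set(dirty))
        codes[dirty] = rng.integers(0, 4, size=len(dirty))
    raise RuntimeError("could not scrub background of target motifs")
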