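"""Synthetic-data generator: determinism, noise statistics, planted motifs."""

import math

import numpy as np
import pytest

from phypif.expression import DEFAULT_GENES
from phypif.fitting import fit_exponential_halflife
from phypif.model import forward_gene
from phypif.motifs import scan_motifs
from phypif.synthetic import (
    SyntheticConfig,
    default_promoter_plants,
    gen_decay_series,
    gen_expression_series,
    gen_promoters,
)

SEED = 1234


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            SyntheticConfig(n_replicates=0)
        with pytest.raises(ValueError):
            SyntheticConfig(noise_cv=-0.1)
        with pytest.raises(ValueError):
            SyntheticConfig(sampling_times=(0.5, 1.0))


class TestExpressionSeries:
    def test_zero_noise_equals_model(self, default_config):
        gene = DEFAULT_GENES["SIG6"]
        cfg = SyntheticConfig(seed=SEED, noise_cv=0.0, n_replicates=3)
        s = gen_expression_series(cfg, gene, default_config)
        model = forward_gene(gene, default_config, s.times)
        np.testing.assert_allclose(
            s.replicates, np.tile(model[:, None], (1, 3)), rtol=1e-12
        )

    def test_same_seed_bit_identical(self, default_config):
        gene = DEFAULT_GENES["SIG2"]
        a = gen_expression_series(SyntheticConfig(seed=SEED), gene, default_config)
        b = gen_expression_series(SyntheticConfig(seed=SEED), gene, default_config)
        assert np.array_equal(a.replicates, b.replicates)
        c = gen_expression_series(SyntheticConfig(seed=SEED + 1), gene, default_config)
        assert not np.array_equal(a.replicates, c.replicates)

    def test_se_is_sd_over_sqrt_n(self, default_config):
        cfg = SyntheticConfig(seed=SEED, n_replicates=9)
        s = gen_expression_series(cfg, DEFAULT_GENES["SIG2"], default_config)
        sd = s.replicates.std(axis=1, ddof=1)
        np.testing.assert_allclose(s.se, sd / 3.0)
        assert np.all(s.n_replicates == 9)

    def test_sample_mean_unbiased_around_model(self, default_config):
        """Lognormal factors have mean exactly 1, so across many seeded
        series the sample means are unbiased around the model and the
        studentised deviation |mean-model|/SE rarely exceeds 3 (the
        statistic is heavy-tailed for lognormal replicates at n = 9)."""
        gene = DEFAULT_GENES["SIG2"]
        times = np.array(SyntheticConfig(seed=0).sampling_times)
        model = forward_gene(gene, default_config, times)
        z, ratio = [], []
        for seed in range(100):
            cfg = SyntheticConfig(seed=seed, noise_cv=0.15, n_replicates=9)
            s = gen_expression_series(cfg, gene, default_config, model_vals=model)
            z.append(np.abs(s.mean - model) / s.se)
            ratio.append(s.mean / model)
        assert np.mean(np.asarray(z) > 3.0) < 0.05
        assert np.mean(ratio) == pytest.approx(1.0, abs=0.01)

    def test_replicate_cv_matches_configured(self, default_config):
        """Across many seeded series the empirical replicate CV at each time
        point should track the configured noise CV."""
        from phypif.model import ModelConfig

        gene = DEFAULT_GENES["SIG2"]
        cv_target = 0.15
        times = (0.0, 1.0, 7.0)
        model = forward_gene(gene, ModelConfig(), np.array(times))
        ratios = []
        for seed in range(200):
            cfg = SyntheticConfig(
                seed=seed, noise_cv=cv_target, n_replicates=9, sampling_times=times
            )
            s = gen_expression_series(cfg, gene, model_vals=model)
            ratios.append(s.replicates.std(axis=1, ddof=1) / s.replicates.mean(axis=1))
        emp = np.mean(ratios, axis=0)
        np.testing.assert_allclose(emp, cv_target, rtol=0.20)


class TestDecaySeries:
    def test_zero_noise_phyb_value(self):
        cfg = SyntheticConfig(seed=SEED)
        t, v = gen_decay_series(cfg, "phyb", grid=np.array([0.0, 1.0]))
        assert v[0] == pytest.approx(1.0)
        assert v[1] == pytest.approx(0.225)

    def test_zero_noise_pif_half_at_fifteen_minutes(self):
        cfg = SyntheticConfig(seed=SEED)
        t, v = gen_decay_series(cfg, "pif", grid=np.array([0.0, 1.0 / 96.0]))
        assert v[1] == pytest.approx(0.5, abs=0.02)

    def test_halflife_round_trip(self):
        cfg = SyntheticConfig(seed=SEED)
        t, v = gen_decay_series(cfg, "phyb", grid=np.linspace(0, 1.5, 20))
        fit = fit_exponential_halflife(t, v)
        assert fit.rate == pytest.approx(3 * math.log(2), rel=1e-6)

    def test_unknown_species_rejected(self):
        with pytest.raises(ValueError):
            gen_decay_series(SyntheticConfig(seed=SEED), "chlorophyll")


class TestPromoters:
    def test_planted_gbox_recovered_exactly(self):
        cfg = SyntheticConfig(seed=SEED, plants={"g1": [("G-box", -500)]})
        (rec,) = gen_promoters(cfg)
        hits = scan_motifs(rec)
        assert [(h.motif_name, h.strand, h.offset) for h in hits] == [
            ("G-box", "+", -500),
            ("G-box", "-", -500),
        ]

    def test_no_plants_means_no_hits(self):
        cfg = SyntheticConfig(seed=SEED, plants={"empty": []})
        (rec,) = gen_promoters(cfg)
        assert scan_motifs(rec) == []
        assert len(rec) == 3000

    def test_default_fixture_matches_published_pattern(self):
        """13 genes, PBE-box planted in all, G-box in a subset, positions in
        three upstream blocks."""
        from phypif.motifs import histogram_modes, position_histogram, presence_table

        cfg = SyntheticConfig(seed=SEED)
        records = gen_promoters(cfg)
        assert len(records) == 13
        hits = [h for r in records for h in scan_motifs(r)]
        table = presence_table(hits, seq_ids=[r.seq_id for r in records])
        assert table["PBE-box"].all()
        assert table.loc["PRIN2", "G-box"] and not table.loc["SIG1", "G-box"]
        modes = histogram_modes(position_histogram(hits))
        assert len(modes) == 3

    def test_same_seed_identical_sequences(self):
        a = gen_promoters(SyntheticConfig(seed=SEED))
        b = gen_promoters(SyntheticConfig(seed=SEED))
        assert [r.sequence for r in a] == [r.sequence for r in b]

    def test_overlapping_plants_rejected(self):
        cfg = SyntheticConfig(
            seed=SEED, plants={"g": [("G-box", -500), ("PBE-box", -503)]}
        )
        with pytest.raises(ValueError, match="overlap"):
            gen_promoters(cfg)

    def test_out_of_range_plant_rejected(self):
        cfg = SyntheticConfig(seed=SEED, plants={"g": [("G-box", -3)]})
        with pytest.raises(ValueError, match="outside"):
            gen_promoters(cfg)

    def test_plants_validated_against_known_motifs(self):
        cfg = SyntheticConfig(seed=SEED, plants={"g": [("X-box", -500)]})
        with pytest.raises(ValueError, match="unknown motif"):
            gen_promoters(cfg)


def test_default_plants_cover_thirteen_genes():
    plants = default_promoter_plants()
    assert len(plants) == 13
    assert all(any(m == "PBE-box" for m, _ in v) for v in plants.values())
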