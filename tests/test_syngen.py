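"""Scenario generator and endorsement-stream unit tests."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from prefcal import syngen
from prefcal.errors import ConfigError, IntegrityError


class TestGenerateScenarios:
    def test_default_config_emits_ten_thousand_cases(self):
        sset = syngen.generate_scenarios(syngen.GeneratorConfig())
        assert sset.n == 10_000
        assert sset.comm_embed.shape == (10_000, 64)
        assert sset.phys_embed.shape == (10_000, 64)

    def test_outcomes_binarize_to_labels(self, small_set):
        assert np.array_equal(small_set.labels, (small_set.outcomes >= 0.5).astype(int))
        assert set(np.unique(small_set.outcomes)) <= {0.1, 0.9}

    def test_split_partition(self, small_set):
        tr, te = small_set.train_idx, small_set.test_idx
        assert len(np.intersect1d(tr, te)) == 0
        assert len(tr) + len(te) == small_set.n
        assert len(te) == round(0.2 * small_set.n)

    def test_same_seed_bitwise_identical(self, small_gen):
        a = syngen.generate_scenarios(small_gen)
        b = syngen.generate_scenarios(small_gen)
        assert np.array_equal(a.comm_embed, b.comm_embed)
        assert np.array_equal(a.phys_embed, b.phys_embed)
        assert np.array_equal(a.labels, b.labels)
        assert np.array_equal(a.split, b.split)

    def test_different_seed_differs(self, small_gen):
        import dataclasses
        other = dataclasses.replace(small_gen, seed=small_gen.seed + 1)
        a = syngen.generate_scenarios(small_gen)
        b = syngen.generate_scenarios(other)
        assert not np.array_equal(a.comm_embed, b.comm_embed)

    def test_cross_stream_noise_correlation(self):
        # with snr=0 the embeddings are the raw noise; sample-correlation oracle
        cfg = syngen.GeneratorConfig(n_cases=10_000, embed_dim=16, snr=0.0,
                                     cross_corr=0.5, seed=5)
        sset = syngen.generate_scenarios(cfg)
        cors = [np.corrcoef(sset.comm_embed[:, j], sset.phys_embed[:, j])[0, 1]
                for j in range(16)]
        assert abs(np.mean(cors) - 0.5) < 0.02

    def test_snr_zero_embeddings_uninformative(self):
        cfg = syngen.GeneratorConfig(n_cases=4000, embed_dim=8, snr=0.0, seed=2)
        sset = syngen.generate_scenarios(cfg)
        # signal direction absent: class-conditional means coincide
        mu1 = sset.comm_embed[sset.labels == 1].mean(axis=0)
        mu0 = sset.comm_embed[sset.labels == 0].mean(axis=0)
        assert np.linalg.norm(mu1 - mu0) < 0.15  # ~3 sigma of the mean gap

    def test_signal_monotonicity_of_probe_accuracy(self):
        # held-out accuracy of a least-squares probe is nondecreasing in snr
        accs = []
        for snr in (0.0, syngen.DEFAULT_SNR, 2 * syngen.DEFAULT_SNR):
            cfg = syngen.GeneratorConfig(n_cases=3000, embed_dim=16, snr=snr, seed=9)
            s = syngen.generate_scenarios(cfg)
            tr, te = s.train_idx, s.test_idx
            X, yz = s.comm_embed, 2.0 * s.labels - 1.0
            w, *_ = np.linalg.lstsq(X[tr], yz[tr], rcond=None)
            accs.append(((X[te] @ w > 0) == (s.labels[te] == 1)).mean())
        assert accs[0] < 0.56  # chance at snr=0
        assert accs[0] <= accs[1] + 0.02 <= accs[2] + 0.04
        assert accs[2] > 0.9

    @pytest.mark.parametrize("field,value", [
        ("n_cases", 1), ("embed_dim", 1), ("y_lo", 0.6), ("y_hi", 0.4),
        ("base_rate", 1.5), ("snr", -1.0), ("cross_corr", 2.0),
        ("test_fraction", 0.0),
    ])
    def test_invalid_config_names_field(self, field, value):
        with pytest.raises(ConfigError, match=field):
            syngen.GeneratorConfig(**{field: value})


class TestCommunityLabels:
    def test_no_noise_matches_labels(self, small_set, rng):
        lab = syngen.draw_community_labels(small_set, 0.0, rng)
        assert np.array_equal(lab, small_set.labels)

    def test_full_noise_inverts_labels(self, small_set, rng):
        lab = syngen.draw_community_labels(small_set, 1.0, rng)
        assert np.array_equal(lab, 1 - small_set.labels)

    def test_flip_fraction_binomial(self, rng):
        sset = syngen.generate_scenarios(syngen.GeneratorConfig(
            n_cases=10_000, embed_dim=4, seed=1))
        lab = syngen.draw_community_labels(sset, 0.3, rng)
        frac = (lab != sset.labels).mean()
        assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 10_000)

    def test_out_of_range_sigma_rejected(self, small_set, rng):
        with pytest.raises(ConfigError):
            syngen.draw_community_labels(small_set, 1.2, rng)


class TestPhysicianStream:
    def test_query_whole_batch(self, rng):
        batch = np.arange(10, 20)
        q = syngen.query_physician(batch, 10, rng)
        assert sorted(q) == list(batch)

    def test_query_singleton_in_batch(self, rng):
        batch = np.arange(50)
        q = syngen.query_physician(batch, 1, rng)
        assert len(q) == 1 and q[0] in batch

    def test_query_uniformity(self, rng):
        batch = np.arange(50)
        counts = np.zeros(50)
        n_draws = 10_000
        for _ in range(n_draws):
            counts[syngen.query_physician(batch, 5, rng)] += 1
        freq = counts / n_draws
        # per-index se = sqrt(0.1*0.9/n) ~ 0.003; 5-sigma bound over 50 indices
        assert np.all(np.abs(freq - 0.1) < 0.015)
        assert abs(freq.mean() - 0.1) < 1e-12  # k/|batch| exactly on average

    def test_query_larger_than_batch_rejected(self, rng):
        with pytest.raises(ConfigError):
            syngen.query_physician(np.arange(5), 6, rng)

    def test_no_bias_returns_underlying(self, rng):
        z = np.array([0, 1, 0, 1, 1])
        assert np.array_equal(syngen.draw_physician_labels(z, 0.0, rng), z)

    def test_full_bias_forces_adherence(self, rng):
        z = np.zeros(20, dtype=int)
        assert np.all(syngen.draw_physician_labels(z, 1.0, rng) == 1)

    def test_bias_fraction_binomial(self, rng):
        z = np.zeros(10_000, dtype=int)
        lab = syngen.draw_physician_labels(z, 0.4, rng)
        assert abs(lab.mean() - 0.4) < 0.015

    @given(beta=st.floats(min_value=0.0, max_value=1.0))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_bias_only_flips_upward(self, beta):
        # forcing to "adherence" can never turn a 1 into a 0
        local = np.random.default_rng(0)
        z = local.integers(0, 2, size=200)
        lab = syngen.draw_physician_labels(z, beta, local)
        assert np.all(lab >= z)


class TestPersistence:
    def test_round_trip_identity(self, tmp_path):
        cfg = syngen.GeneratorConfig(n_cases=10, embed_dim=5, seed=42)
        sset = syngen.generate_scenarios(cfg)
        syngen.save_scenarios(sset, tmp_path / "s")
        back = syngen.load_scenarios(tmp_path / "s")
        assert np.array_equal(back.outcomes, sset.outcomes)
        assert np.array_equal(back.labels, sset.labels)
        assert np.array_equal(back.comm_embed, sset.comm_embed)
        assert np.array_equal(back.phys_embed, sset.phys_embed)
        assert np.array_equal(back.split, sset.split)
        assert back.provenance == cfg

    def test_tampered_row_count_detected(self, tmp_path):
        import json
        sset = syngen.generate_scenarios(
            syngen.GeneratorConfig(n_cases=10, embed_dim=4, seed=0))
        syngen.save_scenarios(sset, tmp_path / "s")
        meta = json.loads((tmp_path / "s" / "meta.json").read_text())
        meta["n_rows"] = 11
        (tmp_path / "s" / "meta.json").write_text(json.dumps(meta))
        with pytest.raises(IntegrityError):
            syngen.load_scenarios(tmp_path / "s")

    def test_missing_directory_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            syngen.load_scenarios(tmp_path / "nope")
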