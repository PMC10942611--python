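"""Tests for the synthetic experiment generator."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from barnet import cell_calling, network_inference
from barnet.synthetic_data import (
    NO_SOURCE,
    LOST_SOURCE,
    SimulationConfig,
    corrupt_reads,
    sample_library,
    simulate_convergence_networks,
    simulate_retrograde,
    simulate_transsynaptic,
    tune_skew_sigma,
    write_experiment,
)


class TestSampleLibrary:
    def test_zero_sigma_uniform(self):
        lib = sample_library(100, 0.0, seed=0)
        assert np.allclose(lib.frequencies, 0.01)

    def test_deterministic_under_seed(self):
        a = sample_library(50, 1.5, seed=3)
        b = sample_library(50, 1.5, seed=3)
        assert a.barcodes == b.barcodes
        assert np.array_equal(a.frequencies, b.frequencies)

    def test_barcodes_unique_20nt(self):
        lib = sample_library(200, 1.0, seed=1)
        assert len(set(lib.barcodes)) == 200
        assert all(len(b) == 20 and set(b) <= set("ACGT") for b in lib.barcodes)

    def test_frequencies_sum_to_one(self):
        lib = sample_library(77, 2.5, seed=9)
        assert lib.frequencies.sum() == pytest.approx(1.0, abs=1e-12)
        assert (lib.frequencies > 0).all()

    def test_too_many_barcodes_rejected(self):
        with pytest.raises(ValueError):
            sample_library(5, 1.0, seed=0, barcode_len=1)

    def test_tuned_sigma_reproduces_library_shape(self):
        # top ~14% of barcodes should carry ~82% of the mass
        sigma = tune_skew_sigma(top_fraction=1820 / 13211, mass_fraction=0.819)
        assert sigma == pytest.approx(2.0, abs=0.05)
        lib = sample_library(13211, sigma, seed=4)
        f = np.sort(lib.frequencies)[::-1]
        assert f[:1820].sum() == pytest.approx(0.819, abs=0.06)


class TestSimulateTranssynaptic:
    def test_no_direct_infection_means_no_no_source(self, base_config, skewed_library):
        base_config.p_direct_infection = 0.0
        _, _, truth = simulate_transsynaptic(base_config, skewed_library)
        assert all(nt.truth_class != NO_SOURCE for nt in truth.networks.values())

    def test_no_death_means_no_lost_source(self, base_config, skewed_library):
        base_config.p_source_death = 0.0
        _, _, truth = simulate_transsynaptic(base_config, skewed_library)
        assert all(nt.truth_class != LOST_SOURCE for nt in truth.networks.values())
        assert truth.dead_cells == []

    def test_every_read_barcode_in_truth(self, base_config, skewed_library):
        _, reads, truth = simulate_transsynaptic(base_config, skewed_library)
        assert set(reads["barcode"]) <= set(truth.networks)

    def test_sources_subset_of_members(self, base_config, skewed_library):
        _, _, truth = simulate_transsynaptic(base_config, skewed_library)
        for nt in truth.networks.values():
            assert set(nt.source_cells) <= set(nt.member_cells)

    def test_dead_sources_removed_but_spread_retained(self, base_config, skewed_library):
        base_config.p_source_death = 1.0
        base_config.p_direct_infection = 0.0
        base_config.p_intersource_connection = 0.0
        cells, reads, truth = simulate_transsynaptic(base_config, skewed_library)
        assert not set(truth.dead_cells) & set(cells["cell_id"])
        # all-sources-dead barcodes still have presynaptic members
        assert any(nt.member_cells for nt in truth.networks.values())
        assert all(
            nt.truth_class == LOST_SOURCE for nt in truth.networks.values()
        )

    def test_bad_subclass_proportions_rejected(self, base_config, skewed_library):
        base_config.subclass_proportions = {"A": 0.5, "B": 0.2}
        with pytest.raises(ValueError):
            simulate_transsynaptic(base_config, skewed_library)

    def test_double_label_rate_matches_binomial_collision_oracle(self):
        """Mean count of multiply-hit barcodes equals sum_b P(X_b >= 2),
        X_b ~ Binomial(n_infections, f_b)."""
        lib = sample_library(300, 1.5, seed=21)
        n_inf, reps = 76, 200
        expected = sum(
            stats.binom.sf(1, n_inf, f) for f in lib.frequencies
        )
        counts = []
        for rep in range(reps):
            cfg = SimulationConfig(
                seed=1000 + rep,
                n_library_barcodes=300,
                n_infections=n_inf,
                n_tva_cells=10_000,  # avoid same-cell event collapse
                p_source_death=0.0,
                p_direct_infection=0.0,
                p_intersource_connection=0.0,
                presyn_mean=1.0,
                presyn_dispersion=1.0,
            )
            _, _, truth = simulate_transsynaptic(cfg, lib)
            counts.append(
                sum(len(nt.event_ids) >= 2 for nt in truth.networks.values())
            )
        mean = np.mean(counts)
        sem = np.std(counts, ddof=1) / np.sqrt(reps)
        assert abs(mean - expected) < 5 * sem + 0.05

    def test_network_sizes_match_negative_binomial(self):
        """Single-source presynaptic network sizes follow the configured NB
        (chi-square GOF not rejected at alpha=0.01 over ~10^3 networks)."""
        mean_, r = 12.0, 2.0
        cfg = SimulationConfig(
            seed=5,
            n_library_barcodes=40_000,
            library_skew_sigma=0.0,
            n_infections=1000,
            n_tva_cells=50_000,
            p_source_death=0.0,
            p_direct_infection=0.0,
            p_intersource_connection=0.0,
            presyn_mean=mean_,
            presyn_dispersion=r,
        )
        lib = sample_library(40_000, 0.0, seed=5)
        _, _, truth = simulate_transsynaptic(cfg, lib)
        sizes = np.array(
            [
                len(nt.member_cells) - 1  # presynaptic members only
                for nt in truth.networks.values()
                if nt.truth_class == "single_source" and len(nt.event_ids) == 1
            ]
        )
        assert len(sizes) > 900
        p_nb = r / (r + mean_)
        edges = [0, 2, 5, 9, 14, 20, 30, np.inf]
        observed, _ = np.histogram(sizes, bins=edges)
        cdf = stats.nbinom.cdf(np.array(edges[1:]) - 1, r, p_nb)
        probs = np.diff(np.concatenate([[0.0], cdf]))
        probs[-1] = 1 - cdf[-2]
        chi = stats.chisquare(observed, probs * len(sizes))
        assert chi.pvalue > 0.01

    def test_clean_config_recovers_all_labels(self, skewed_library):
        """With every confound off, classification downstream is perfect."""
        cfg = SimulationConfig(
            seed=17,
            n_library_barcodes=10_000,
            library_skew_sigma=0.0,
            n_infections=40,
            n_tva_cells=500,
            p_source_death=0.0,
            p_direct_infection=0.0,
            p_intersource_connection=0.0,
            presyn_mean=12.0,
            presyn_dispersion=5.0,
            g_count_leak_mean=0.0,
            g_count_source_mean=25.0,
        )
        lib = sample_library(cfg.n_library_barcodes, 0.0, seed=17)
        cells, reads, truth = simulate_transsynaptic(cfg, lib)
        calls = cell_calling.run_calling_pipeline(reads, cells, "transsynaptic")
        nets = {n.barcode: n for n in network_inference.build_networks(calls)}
        for barcode, nt in truth.networks.items():
            assert nets[barcode].network_class == nt.observable_class


class TestSimulateRetrograde:
    def _probs(self, cfg, p1, p2):
        return {
            (area, f"{sub}_t{k}"): (p1, p2)
            for area in cfg.areas
            for sub in cfg.subclass_proportions
            for k in (1, 2)
        }

    def test_zero_probability_zero_cells(self, base_config):
        lib1 = sample_library(50, 0.0, seed=1, library_id="l1")
        lib2 = sample_library(50, 0.0, seed=2, library_id="l2")
        _, reads, truth = simulate_retrograde(
            base_config, (lib1, lib2), self._probs(base_config, 0.0, 0.0)
        )
        assert len(reads) == 0
        assert truth.networks == {}

    def test_overlapping_libraries_rejected(self, base_config):
        lib = sample_library(50, 0.0, seed=1)
        with pytest.raises(ValueError, match="disjoint"):
            simulate_retrograde(
                base_config, (lib, lib), self._probs(base_config, 0.1, 0.1)
            )

    def test_zero_error_barcodes_match_truth_library(self, base_config):
        lib1 = sample_library(100, 1.0, seed=1, library_id="l1")
        lib2 = sample_library(100, 1.0, seed=2, library_id="l2")
        base_config.per_base_error = 0.0
        _, reads, truth = simulate_retrograde(
            base_config, (lib1, lib2), self._probs(base_config, 0.3, 0.3)
        )
        lut = truth.extra["barcode_library"]
        for barcode in reads["barcode"]:
            assert lut[barcode] in ("l1", "l2")
            assert (barcode in lib1.barcodes) == (lut[barcode] == "l1")

    def test_labeled_fraction_within_binomial_ci(self):
        cfg = SimulationConfig(seed=23, n_tva_cells=5000)
        lib1 = sample_library(400, 1.0, seed=3, library_id="l1")
        lib2 = sample_library(400, 1.0, seed=4, library_id="l2")
        p = 0.3
        probs = {
            (area, f"{sub}_t{k}"): (p, 0.0)
            for area in cfg.areas
            for sub in cfg.subclass_proportions
            for k in (1, 2)
        }
        _, _, truth = simulate_retrograde(cfg, (lib1, lib2), probs)
        n_labeled = len(truth.cell_barcodes)
        lo, hi = stats.binom.interval(0.99, 5000, p)
        assert lo <= n_labeled <= hi


class TestCorruptReads:
    def _reads(self):
        return pd.DataFrame(
            {
                "cell_id": ["c1", "c1", "c2"],
                "barcode": ["ACGTACGTACGTACG", "TTTTGGGGCCCCAAA", "ACGTACGTACGTACG"],
                "count": [10, 5, 3],
            }
        )

    def test_zero_error_is_identity(self):
        reads = self._reads()
        out = corrupt_reads(reads, 0.0, seed=1)
        pd.testing.assert_frame_equal(out, reads)

    def test_deterministic_under_seed(self):
        reads = self._reads()
        a = corrupt_reads(reads, 0.05, seed=9)
        b = corrupt_reads(reads, 0.05, seed=9)
        pd.testing.assert_frame_equal(a, b)

    def test_counts_preserved(self):
        reads = self._reads()
        out = corrupt_reads(reads, 0.1, seed=2)
        assert out["count"].sum() == reads["count"].sum()

    def test_mean_hamming_matches_expectation(self):
        """per_base_error=0.01 on 15-nt barcodes: mean distance ~ 0.15."""
        n = 10_000
        reads = pd.DataFrame(
            {"cell_id": ["c"] * n, "barcode": ["ACGTACGTACGTACG"] * n, "count": [1] * n}
        )
        out = corrupt_reads(reads, 0.01, seed=3)
        truth = "ACGTACGTACGTACG"
        total_mismatch = sum(
            cnt * sum(a != b for a, b in zip(bc, truth))
            for bc, cnt in zip(out["barcode"], out["count"])
        )
        mean_d = total_mismatch / n
        # binomial(15, 0.01): sd of the mean over 1e4 reads ~ 0.004
        assert mean_d == pytest.approx(0.15, abs=0.02)


class TestConvergenceNetworkGenerator:
    def test_null_has_no_planted_structure(self):
        nets, sub_of = simulate_convergence_networks(
            50, {"A": 0.5, "B": 0.5}, seed=0
        )
        assert len(nets) == 50
        assert all(n.n_cells >= 5 for n in nets)
        assert set(sub_of.values()) <= {"A", "B"}

    def test_planted_preserves_approximate_marginals(self):
        props = {"A": 0.15, "B": 0.15, "C": 0.4, "D": 0.3}
        _, null_sub = simulate_convergence_networks(400, props, seed=1)
        _, plant_sub = simulate_convergence_networks(
            400, props, seed=1, planted_pair=("A", "B")
        )
        null_frac = np.mean([s in ("A", "B") for s in null_sub.values()])
        plant_frac = np.mean([s in ("A", "B") for s in plant_sub.values()])
        assert plant_frac == pytest.approx(null_frac, abs=0.05)

    def test_planted_factor_bounds(self):
        with pytest.raises(ValueError):
            simulate_convergence_networks(
                10, {"A": 0.5, "B": 0.5}, seed=0, planted_pair=("A", "B"),
                planted_factor=3.0,
            )


def test_write_experiment_round_trip(tmp_path, base_config, skewed_library):
    cells, reads, truth = simulate_transsynaptic(base_config, skewed_library)
    write_experiment(tmp_path, cells, reads, truth, library=skewed_library)
    assert (tmp_path / "cells.tsv").exists()
    assert (tmp_path / "barcode_reads.tsv").exists()
    from barnet.synthetic_data import GroundTruth

    truth2 = GroundTruth.from_json(tmp_path / "truth.json")
    assert set(truth2.networks) == set(truth.networks)
    for bc in truth.networks:
        assert truth2.networks[bc].truth_class == truth.networks[bc].truth_class
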