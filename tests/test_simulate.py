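"""Generator correctness: Bessel-ratio inversion, prescribed PLV,
artifact injection, cohort effects and determinism."""

import numpy as np
import pytest
from scipy import signal as sps
from scipy import special

from plvnet.connectivity import plv, plv_matrix
from plvnet.core import DataError
from plvnet.simulate import (
    ArtifactSpec,
    CohortSpec,
    OscillatorSpec,
    expected_plv,
    inject_artifacts,
    kappa_for_plv,
    simulate_cohort,
    simulate_edge_cohort,
    simulate_region_phases,
    simulate_region_signals,
)
from plvnet.stats import ttest_ind


class TestKappaForPlv:
    def test_zero_target_gives_zero_concentration(self):
        assert kappa_for_plv(0.0) == 0.0

    def test_inverts_bessel_ratio_at_kappa_two(self):
        rho = float(special.i1(2.0) / special.i0(2.0))  # ≈ 0.69777
        assert kappa_for_plv(rho) == pytest.approx(2.0, abs=1e-5)

    @pytest.mark.parametrize("rho", [0.1, 0.3, 0.5, 0.7, 0.9, 0.99])
    def test_round_trip_tolerance(self, rho):
        assert expected_plv(kappa_for_plv(rho)) == pytest.approx(rho, abs=1e-6)

    @pytest.mark.parametrize("rho", [1.0, 1.5, -0.1])
    def test_domain_errors(self, rho):
        with pytest.raises(DataError):
            kappa_for_plv(rho)

    def test_monte_carlo_plv_matches_target(self):
        """Von Mises phase differences at κ(0.5) empirically lock at 0.5."""
        rng = np.random.default_rng(42)
        diffs = rng.vonmises(0.0, kappa_for_plv(0.5), size=10**6)
        assert np.abs(np.exp(1j * diffs).mean()) == pytest.approx(0.5, abs=0.002)


class TestSimulateRegionSignals:
    def test_perfect_coupling_is_identical_phase(self):
        spec = OscillatorSpec(n_regions=2, duration=2.0, seed=0,
                              pair_plv={(0, 1): 1.0})
        _, ph = simulate_region_signals(spec, return_phases=True)
        np.testing.assert_array_equal(ph[0], ph[1])
        assert plv(ph[0], ph[1]) == 1.0

    def test_pair_target_recovered_empirically(self):
        spec = OscillatorSpec(n_regions=3, fs=256.0, duration=120.0, seed=7,
                              pair_plv={(0, 1): 0.7})
        _, ph = simulate_region_signals(spec, return_phases=True)
        assert plv(ph[0], ph[1]) == pytest.approx(0.7, abs=0.02)

    def test_base_plv_for_unlinked_pairs(self):
        spec = OscillatorSpec(n_regions=2, fs=256.0, duration=120.0,
                              base_plv=0.36, seed=11)
        _, ph = simulate_region_signals(spec, return_phases=True)
        assert plv(ph[0], ph[1]) == pytest.approx(0.36, abs=0.03)

    def test_convergence_bound_at_thirty_thousand_samples(self):
        """|empirical − target| < 3/√T for every generated pair at T=30720."""
        T = 30720
        spec = OscillatorSpec(n_regions=4, fs=256.0, duration=T / 256.0,
                              seed=5, pair_plv={(0, 1): 0.6, (2, 3): 0.3})
        ph = simulate_region_phases(spec)
        bound = 3.0 / np.sqrt(T)
        assert abs(plv(ph[0], ph[1]) - 0.6) < bound
        assert abs(plv(ph[2], ph[3]) - 0.3) < bound

    def test_seed_determinism_bit_identical(self):
        spec = OscillatorSpec(n_regions=3, duration=5.0, seed=9,
                              pair_plv={(0, 2): 0.5})
        a = simulate_region_signals(spec)
        b = simulate_region_signals(spec)
        np.testing.assert_array_equal(a.data, b.data)

    def test_conflicting_pair_targets_rejected(self):
        spec = OscillatorSpec(n_regions=3, duration=2.0,
                              pair_plv={(0, 1): 0.5, (1, 0): 0.7})
        with pytest.raises(DataError, match="conflicting"):
            simulate_region_phases(spec)

    def test_cyclic_targets_rejected(self):
        spec = OscillatorSpec(n_regions=3, duration=2.0,
                              pair_plv={(0, 1): 0.5, (1, 2): 0.5, (0, 2): 0.5})
        with pytest.raises(DataError):
            simulate_region_phases(spec)

    def test_phase_hold_preserves_marginal_plv(self):
        spec = OscillatorSpec(n_regions=2, fs=256.0, duration=600.0, seed=3,
                              pair_plv={(0, 1): 0.7}, phase_hold=0.5)
        ph = simulate_region_phases(spec)
        # 1200 independent blocks -> sampling error well inside 0.05
        assert plv(ph[0], ph[1]) == pytest.approx(0.7, abs=0.05)

    def test_signal_is_band_centred_oscillation(self):
        spec = OscillatorSpec(n_regions=1, fs=256.0, duration=60.0, seed=1,
                              band="alpha", base_plv=0.9, noise_sd=0.0,
                              phase_hold=0.5)
        rec = simulate_region_signals(spec)
        f, p = sps.periodogram(rec.data[0], fs=256.0)
        assert 8.0 <= f[np.argmax(p)] <= 14.0


class TestInjectArtifacts:
    def _clean(self, seconds=10.0):
        return simulate_region_signals(
            OscillatorSpec(n_regions=3, fs=256.0, duration=seconds,
                           amplitude=10.0, noise_sd=0.5, seed=2))

    def test_zero_rates_identity(self):
        rec = self._clean()
        out, log = inject_artifacts(rec, ArtifactSpec(), seed=0)
        np.testing.assert_array_equal(out.data, rec.data)
        assert len(log) == 0

    def test_spikes_exceed_rejection_threshold(self):
        rec = self._clean()
        out, log = inject_artifacts(rec, ArtifactSpec(spike_rate=6.0), seed=1)
        assert np.abs(out.data).max() > 70.0
        assert (log["kind"] == "spike").any()

    def test_line_noise_peaks_at_line_frequency(self):
        rec = self._clean(seconds=20.0)
        out, _ = inject_artifacts(rec, ArtifactSpec(line_amp=10.0,
                                                    line_freq=50.0), seed=0)
        f, p_out = sps.periodogram(out.data[1], fs=256.0)
        band = (f > 45) & (f < 55)
        assert f[band][np.argmax(p_out[band])] == pytest.approx(50.0, abs=0.5)

    def test_blinks_land_on_frontal_rows(self):
        rec = self._clean()
        out, log = inject_artifacts(rec, ArtifactSpec(blink_rate=30.0), seed=3,
                                    frontal_labels=["R01"])
        assert (log["kind"] == "blink").any()
        moved = np.abs(out.data - rec.data).max(axis=1)
        assert moved[0] > 50.0 and moved[1] < 1e-9


class TestSimulateCohort:
    def test_behavior_recovers_printed_group_contrast(self, toy_parcellation):
        """PANAS cells drawn from the baseline group means/SDs reproduce the
        published group t-statistic (≈ −22) on average."""
        ts = []
        for rep in range(5):
            spec = CohortSpec(
                parcellation=toy_parcellation,
                groups={"ScD": 50, "HC": 48}, conditions=("pre",),
                behavior_means={("PA", "ScD", "pre"): (19.260, 2.813),
                                ("PA", "HC", "pre"): (30.083, 1.867)},
                seed=100 + rep)
            from plvnet.simulate import simulate_behavior_only
            behav = simulate_behavior_only(spec)
            a = behav.loc[behav.group == "ScD", "score"].to_numpy()
            b = behav.loc[behav.group == "HC", "score"].to_numpy()
            ts.append(ttest_ind(a, b).t)
        assert np.mean(ts) == pytest.approx(-22.35, abs=2.5)

    def test_zero_effect_map_groups_equivalent(self, toy_parcellation):
        spec = CohortSpec(parcellation=toy_parcellation,
                          groups={"ScD": 2, "HC": 2}, conditions=("pre",),
                          duration=30.0, seed=4)
        cohort = simulate_cohort(spec)
        cells = cohort.manifest["cells"]
        assert cells["ScD/pre"]["inter"] == cells["HC/pre"]["inter"]
        assert cells["ScD/pre"]["intra"] == cells["HC/pre"]["intra"]

    def test_network_offset_recovered_from_phases(self, parcellation20):
        """A +0.2 SMN–DMN offset for one cell appears in the generated
        phase coupling as a mean PLV difference close to +0.2."""
        spec = CohortSpec(parcellation=parcellation20,
                          groups={"ScD": 6, "HC": 6}, conditions=("VR-EI",),
                          duration=120.0, seed=21,
                          effect_map={("ScD", "VR-EI", "SMN-DMN"): 0.2},
                          phase_hold=0.0, noise_sd=0.0)
        from plvnet.simulate import _cell_targets, _simulate_cell_phases
        idx_a = parcellation20.indices("SMN")
        idx_b = parcellation20.indices("DMN")

        def mean_plv(group, seed):
            intra, inter, _ = _cell_targets(spec, group, "VR-EI")
            rng = np.random.default_rng(seed)
            G = plv_matrix(_simulate_cell_phases(spec, intra, inter, rng))
            return G[np.ix_(idx_a, idx_b)].mean()

        diff = np.mean([mean_plv("ScD", 300 + r) - mean_plv("HC", 400 + r)
                        for r in range(6)])
        assert diff == pytest.approx(0.2, abs=0.05)

    def test_cohort_determinism(self, toy_parcellation):
        spec = CohortSpec(parcellation=toy_parcellation,
                          groups={"ScD": 2, "HC": 2}, conditions=("pre",),
                          duration=10.0, seed=8,
                          behavior_means={("PA", "ScD", "pre"): (20, 2),
                                          ("PA", "HC", "pre"): (30, 2)})
        c1, c2 = simulate_cohort(spec), simulate_cohort(spec)
        for sid in c1.recordings:
            np.testing.assert_array_equal(c1.recordings[sid].data,
                                          c2.recordings[sid].data)
        assert c1.behavior.equals(c2.behavior)
        assert c1.manifest == c2.manifest

    def test_scores_truncated_to_panas_range(self, toy_parcellation):
        spec = CohortSpec(parcellation=toy_parcellation,
                          groups={"ScD": 30, "HC": 30}, conditions=("pre",),
                          duration=10.0, seed=2,
                          behavior_means={("NA", "ScD", "pre"): (48.0, 6.0),
                                          ("NA", "HC", "pre"): (11.0, 4.0)})
        from plvnet.simulate import simulate_behavior_only
        behav = simulate_behavior_only(spec)
        assert behav["score"].between(10, 50).all()

    def test_out_of_range_target_clipped_with_warning(self, toy_parcellation):
        spec = CohortSpec(parcellation=toy_parcellation,
                          groups={"ScD": 1, "HC": 1}, conditions=("pre",),
                          duration=10.0, seed=1,
                          effect_map={("ScD", "pre", "SMN-DMN"): 0.9})
        with pytest.warns(UserWarning, match="clipped"):
            cohort = simulate_cohort(spec)
        assert cohort.manifest["warnings"]


class TestSimulateEdgeCohort:
    def test_shapes_and_range(self):
        X, pairs = simulate_edge_cohort(10, 6, base=0.3, noise_sd=0.1, seed=0)
        assert X.shape == (10, 15) and len(pairs) == 15
        assert X.min() >= 0.0 and X.max() <= 1.0

    def test_offsets_shift_named_edges_only(self):
        off = {(0, 1): 0.4}
        X0, pairs = simulate_edge_cohort(2000, 4, noise_sd=0.05, seed=1)
        X1, _ = simulate_edge_cohort(2000, 4, noise_sd=0.05,
                                     edge_offsets=off, seed=1)
        k = pairs.index((0, 1))
        assert X1[:, k].mean() - X0[:, k].mean() == pytest.approx(0.4, abs=0.01)
        other = [i for i in range(len(pairs)) if i != k]
        np.testing.assert_allclose(X1[:, other], X0[:, other])
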