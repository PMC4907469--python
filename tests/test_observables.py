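"""Virial stress, rupture detection, crack clustering and decay fitting."""

import numpy as np
import pytest

import hexfrac as hf
from hexfrac.errors import InvalidArgumentError, InvalidStateError

from conftest import brute_force_virial


class TestVirialStress:
    def test_relaxed_lattice_is_stress_free(self, table, small_lattice):
        sigma = hf.virial_stress(small_lattice, table)
        assert np.abs(sigma).max() < 1e-8

    def test_matches_brute_force_oracle_under_strain(self, table, small_lattice):
        strained = hf.apply_affine_strain(small_lattice, hf.StrainProtocol(magnitude=0.03))
        sigma = hf.virial_stress(strained, table)
        oracle = brute_force_virial(strained, table)
        assert np.allclose(sigma, oracle, rtol=1e-10, atol=1e-10)
        assert sigma[0, 0] < 0  # tension is negative in this convention

    def test_matches_oracle_with_velocities_and_mixed_species(self, table):
        system = hf.apply_affine_strain(
            hf.build_hexagonal_lattice(6, 6), hf.StrainProtocol(magnitude=0.04)
        )
        rng = np.random.default_rng(0)
        system.velocities[:] = rng.normal(0, 0.01, system.velocities.shape)
        system.species[::3] = int(hf.Species.DAMAGED)
        assert np.allclose(
            hf.virial_stress(system, table), brute_force_virial(system, table)
        )

    def test_shear_component_is_a_vanishing_boundary_effect(self, table):
        """Axial strain produces no bulk shear stress: the residual sigma_xy
        comes from the staggered free surfaces and decays with lattice size."""
        ratios = []
        for n in (10, 20, 40):
            strained = hf.apply_affine_strain(
                hf.build_hexagonal_lattice(n, n), hf.StrainProtocol(magnitude=0.04)
            )
            sigma = hf.virial_stress(strained, table)
            ratios.append(abs(sigma[0, 1] / sigma[0, 0]))
        assert ratios[0] < 2e-3
        assert ratios[2] < ratios[1] < ratios[0]

    def test_degenerate_area_rejected(self, table):
        system = hf.build_hexagonal_lattice(3, 1)  # zero height
        with pytest.raises(InvalidStateError):
            hf.virial_stress(system, table)

    def test_tensor_is_symmetric(self, table, notched_run):
        final, _, _, _ = notched_run
        sigma = hf.virial_stress(final, table)
        assert sigma[0, 1] == sigma[1, 0]


class TestBrokenBondDetection:
    def _pair_at(self, r):
        system = hf.build_hexagonal_lattice(2, 1, spacing=9.17)
        system.positions[1, 0] = r
        return system

    def test_below_cutoff_intact(self, table):
        assert hf.detect_broken_bonds(self._pair_at(9.64), table) == []

    def test_at_and_beyond_cutoff_broken(self, table):
        broken = hf.detect_broken_bonds(self._pair_at(9.66), table)
        assert len(broken) == 1
        assert broken[0].pair == (0, 1)
        assert broken[0].length == pytest.approx(9.66)

    def test_relaxed_lattice_has_no_broken_bonds(self, table, small_lattice):
        assert hf.detect_broken_bonds(small_lattice, table) == []

    def test_flag_is_monotone(self, table):
        """A bond seen beyond the cutoff stays flagged after it re-enters."""
        system = self._pair_at(9.90)
        system.step = 7
        broken = hf.detect_broken_bonds(system, table)
        assert broken[0].first_step == 7
        system.positions[1, 0] = 9.35  # healed geometrically, still flagged
        broken_again = hf.detect_broken_bonds(system, table)
        assert len(broken_again) == 1
        assert broken_again[0].first_step == 7


class TestCrackClustering:
    def test_empty_report(self, table, small_lattice):
        report = hf.cluster_cracks([], small_lattice)
        assert report.n_broken == 0
        assert report.n_clusters == 0
        assert report.percolates is False

    def test_two_bonds_sharing_a_block_form_one_cluster(self, table, small_lattice):
        bb = [
            hf.BrokenBond(0, (0, 1), 9.7, 1),
            hf.BrokenBond(1, (1, 2), 9.7, 2),
        ]
        report = hf.cluster_cracks(bb, small_lattice)
        assert report.n_clusters == 1
        assert report.clusters[0] == {0, 1}

    def test_distant_bonds_stay_separate(self, table, small_lattice):
        bb = [
            hf.BrokenBond(0, (0, 1), 9.7, 1),
            hf.BrokenBond(1, (88, 89), 9.7, 1),
        ]
        report = hf.cluster_cracks(bb, small_lattice)
        assert report.n_clusters == 2

    def test_vertical_column_of_broken_bonds_percolates(self, table):
        """Hand-built 6x6 lattice with ruptures from bottom to top spans the
        free height; exhaustive check of the expected single cluster."""
        system = hf.build_hexagonal_lattice(6, 6)
        col = 3
        broken = []
        for b, (i, j) in enumerate(system.bonds):
            ri, rj = system.rows[i], system.rows[j]
            ci, cj = system.cols[i], system.cols[j]
            if ri != rj and col in (ci, cj):  # inter-row bonds touching column 3
                broken.append(
                    hf.BrokenBond(int(b), (int(i), int(j)), 9.9, 1)
                )
        report = hf.cluster_cracks(broken, system)
        assert report.percolates is True
        spanning = [
            c for c, s in zip(report.clusters, report.spans_transverse) if s
        ]
        assert len(spanning) >= 1
        # the spanning cluster contains every selected bond (they chain up)
        assert max(len(c) for c in spanning) == len(broken)

    def test_clustering_is_order_independent(self, table, notched_run):
        final, _, _, _ = notched_run
        broken = hf.detect_broken_bonds(final, table)
        assert len(broken) > 0
        rng = np.random.default_rng(5)
        shuffled = [broken[i] for i in rng.permutation(len(broken))]
        a = hf.cluster_cracks(broken, final)
        b = hf.cluster_cracks(shuffled, final)
        assert sorted(map(sorted, a.clusters)) == sorted(map(sorted, b.clusters))
        assert a.percolates == b.percolates

    def test_broken_bonds_have_damaged_endpoint(self, table, notched_run):
        """Rupture implies switching: every broken bond touches damaged blocks."""
        final, _, _, _ = notched_run
        for bb in hf.detect_broken_bonds(final, table):
            i, j = bb.pair
            assert (
                final.species[i] == int(hf.Species.DAMAGED)
                or final.species[j] == int(hf.Species.DAMAGED)
            )


class TestExponentialFit:
    def _series(self, y, t=None):
        t = np.arange(len(y), dtype=float) if t is None else t
        z = np.zeros_like(t)
        return hf.StressSeries(
            steps=np.arange(len(y)), times=t, sigma_xx=np.asarray(y, float),
            sigma_yy=z, sigma_xy=z,
        )

    def test_noiseless_recovery(self):
        t = np.linspace(0, 30, 50)
        fit = hf.fit_exponential_decay(self._series(2 + 8 * np.exp(-t / 5), t))
        assert fit.amplitude == pytest.approx(8.0, abs=1e-6)
        assert fit.tau == pytest.approx(5.0, abs=1e-6)
        assert fit.offset == pytest.approx(2.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_noisy_recovery_monte_carlo(self):
        """tau recovered within 10% on average over 100 noise realisations."""
        t = np.linspace(0, 30, 50)
        clean = 2 + 8 * np.exp(-t / 5)
        errs = []
        for seed in range(100):
            noisy = clean + np.random.default_rng(seed).normal(0, 0.1, t.size)
            fit = hf.fit_exponential_decay(self._series(noisy, t))
            errs.append(abs(fit.tau - 5.0) / 5.0)
        assert np.mean(errs) < 0.10

    def test_constant_series_flagged_degenerate(self):
        fit = hf.fit_exponential_decay(self._series(np.full(20, 3.0)))
        assert fit.degenerate
        assert fit.amplitude == 0.0
        assert fit.offset == pytest.approx(3.0)

    def test_too_few_samples_rejected(self):
        with pytest.raises(InvalidArgumentError):
            hf.fit_exponential_decay(self._series(np.arange(5.0)))

    def test_unknown_component_rejected(self):
        with pytest.raises(InvalidArgumentError):
            hf.fit_exponential_decay(self._series(np.arange(20.0)), component="sigma_zz")
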