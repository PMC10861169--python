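"""EDR generator: geometry, sampling law, calibration, nulls, noise."""

import numpy as np
import pytest
from scipy import stats

import tracelink as tl
from tracelink.errors import BadT, RewireStall


class TestGeometry:
    def test_fixed_seed_identical(self):
        a = tl.generate_geometry(20, 3, seed=4)
        b = tl.generate_geometry(20, 3, seed=4)
        np.testing.assert_array_equal(a.dist, b.dist)
        assert a.atlas == b.atlas

    def test_target_dmax_hit_exactly(self):
        g = tl.generate_geometry(91, 3, seed=0, target_dmax=58.2)
        assert g.dist.max() == pytest.approx(58.2, rel=1e-12)

    def test_symmetric_with_regions(self):
        g = tl.generate_geometry(15, 2, seed=1, n_regions=4)
        np.testing.assert_allclose(g.dist, g.dist.T)
        assert len(set(g.atlas.region_of.values())) == 4

    def test_collinear_equidistant_points(self):
        # three points on a line with spacing s give distances (s, s, 2s)
        pos = np.array([[0.0], [3.0], [6.0]])
        from scipy.spatial.distance import pdist

        assert sorted(pdist(pos)) == [3.0, 3.0, 6.0]


class TestEDRSampling:
    def test_lambda_zero_is_uniform_over_pairs(self):
        from tracelink.synthetic import edr_pair_probabilities

        g = tl.generate_geometry(10, 2, seed=0)
        p, _, _ = edr_pair_probabilities(g.dist, 0.0)
        assert np.allclose(p, p[0])
        # sampled counts pass a chi-square uniformity test
        rng = np.random.default_rng(1)
        c = rng.multinomial(90_000, p)
        assert stats.chisquare(c).pvalue > 0.01

    def test_rows_sum_to_one(self):
        g = tl.generate_geometry(12, 2, seed=2)
        fln = tl.generate_edr_network(
            tl.EDRParams(lam=0.3, n_projections=5000, dist=g.dist, seed=3)
        )
        sums = fln.sum(axis=1)
        active = sums > 0
        np.testing.assert_allclose(sums[active], 1.0, rtol=1e-12)
        assert np.all(np.diag(fln) == 0)

    def test_density_decreases_with_lambda(self):
        g = tl.generate_geometry(20, 2, seed=0, target_dmax=50.0)
        dens = []
        for lam in (0.0, 0.1, 0.4):
            fln = tl.generate_edr_network(
                tl.EDRParams(lam=lam, n_projections=800, dist=g.dist, seed=5)
            )
            dens.append((fln > 0).sum())
        assert dens[0] > dens[1] > dens[2]

    def test_calibration_hits_target_density(self):
        g = tl.generate_geometry(30, 3, seed=1, target_dmax=40.0)
        n = tl.calibrate_projection_count(g.dist, 0.19, 0.7)
        assert abs(tl.expected_density(g.dist, 0.19, n) - 0.7) < 0.02
        fln = tl.generate_edr_network(tl.EDRParams(lam=0.19, n_projections=n, dist=g.dist, seed=2))
        realized = (fln > 0).sum() / (30 * 29)
        assert abs(realized - 0.7) < 0.05

    def test_lambda_recovered_by_mle(self):
        g = tl.generate_geometry(91, 3, seed=1, target_dmax=58.2)
        params = tl.EDRParams(lam=0.19, n_projections=10**6, dist=g.dist, seed=7)
        lam_hat = tl.fit_edr_lambda(tl.sampled_projection_lengths(params), g.dist)
        assert abs(lam_hat - 0.19) / 0.19 < 0.05


class TestPartialDataset:
    def test_full_injection_is_identity(self):
        g = tl.generate_geometry(10, 2, seed=0)
        fln = tl.generate_edr_network(tl.EDRParams(lam=0.2, n_projections=500, dist=g.dist, seed=1))
        ds = tl.make_partial_dataset(fln, g.dist, g.atlas, T=10, seed=0)
        np.testing.assert_array_equal(ds.fln, fln)

    def test_macaque_shapes(self, macaque_like):
        assert macaque_like.fln.shape == (29, 91)
        assert macaque_like.dist.shape == (91, 91)

    def test_bad_t(self):
        g = tl.generate_geometry(10, 2, seed=0)
        with pytest.raises(BadT):
            tl.make_partial_dataset(np.zeros((10, 10)), g.dist, g.atlas, T=11)


class TestRewiring:
    def test_degree_sequences_preserved(self, small_ds):
        wm = tl.transform_weights(small_ds)
        rw = tl.rewire_configuration(wm, seed=1)
        np.testing.assert_array_equal((rw.w > 0).sum(0), (wm.w > 0).sum(0))
        np.testing.assert_array_equal((rw.w > 0).sum(1), (wm.w > 0).sum(1))
        # weights travel with links: same multiset of weights
        np.testing.assert_allclose(np.sort(rw.w[rw.w > 0]), np.sort(wm.w[wm.w > 0]))

    def test_no_self_links_introduced(self, small_ds):
        wm = tl.transform_weights(small_ds)
        rw = tl.rewire_configuration(wm, seed=2)
        inj = small_ds.atlas.injected_indices
        assert np.all(rw.w[np.arange(len(inj)), inj] == 0)

    def test_seed_reproducible(self, small_ds):
        wm = tl.transform_weights(small_ds)
        a = tl.rewire_configuration(wm, seed=3)
        b = tl.rewire_configuration(wm, seed=3)
        np.testing.assert_array_equal(a.w, b.w)

    def test_stall_on_saturated_network(self, toy_atlas):
        w = np.zeros((2, 4))
        w[0, 3] = 1.0
        w[1, 2] = 1.0
        wm = tl.WeightMatrix(w=w, atlas=toy_atlas)
        with pytest.raises(RewireStall):
            tl.rewire_configuration(wm, seed=0, n_swaps=5, max_tries_factor=2)


class TestWeightNoise:
    def test_zero_noise_is_identity(self, small_ds):
        out = tl.synthetic_weight_noise(small_ds.fln, 0.0, seed=0)
        np.testing.assert_array_equal(out, small_ds.fln)

    def test_nonlinks_untouched_and_reproducible(self, small_ds):
        a = tl.synthetic_weight_noise(small_ds.fln, 0.5, seed=4)
        b = tl.synthetic_weight_noise(small_ds.fln, 0.5, seed=4)
        np.testing.assert_array_equal(a, b)
        assert np.array_equal(a == 0, small_ds.fln == 0)

    def test_oracle_rmae_tracks_noise_floor(self, small_ds):
        """An oracle predicting the noiseless weights sees RMAE grow with the
        injected noise, from zero at zero noise."""
        wm_clean = tl.transform_weights(small_ds)
        rmaes = []
        for sd in (0.0, 0.3, 0.8):
            noisy = tl.synthetic_weight_noise(small_ds.fln, sd, seed=6)
            wm_noisy = tl.transform_weights(
                tl.TracingDataset(fln=noisy, dist=small_ds.dist, atlas=small_ds.atlas)
            )
            links = (wm_clean.w > 0) & (wm_noisy.w > 0)
            tab = tl.mae_rmae_table(wm_noisy.w[links], wm_clean.w[links])
            rmaes.append(tab.loc["all_links", "RMAE"])
        assert rmaes[0] == 0.0
        assert rmaes[0] < rmaes[1] < rmaes[2]
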