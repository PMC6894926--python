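"""Searchlight construction, neural RDM normalizations, and RSA maps."""

import numpy as np
import pytest

from actionrsa.models import ModelSet
from actionrsa.patterns import plant_brain_patterns
from actionrsa.rdm import RDM, euclidean_rdm, rdm_correlation
from actionrsa.searchlight import (BetaDataset, Searchlight,
                                   build_searchlights, glm_betas, neural_rdm,
                                   regression_rsa_map, standard_rsa_map)
from actionrsa.surface import make_toy_surface


def brute_force_searchlight(mesh, center, n_features):
    """Geodesic ring expansion: hop rings, last ring by (distance, index)."""
    import collections
    dist = {center: 0}
    q = collections.deque([center])
    while q:
        v = q.popleft()
        for nb in mesh.neighbors[v]:
            if nb not in dist:
                dist[int(nb)] = dist[v] + 1
                q.append(int(nb))
    by_hop = collections.defaultdict(list)
    for v, h in dist.items():
        by_hop[h].append(v)
    members = []
    for h in sorted(by_hop):
        ring = by_hop[h]
        if len(members) + len(ring) <= n_features:
            members.extend(sorted(ring))
        else:
            d = {v: round(float(np.linalg.norm(mesh.vertices[v]
                                               - mesh.vertices[center])), 9)
                 for v in ring}
            ring = sorted(ring, key=lambda v: (d[v], v))
            members.extend(ring[: n_features - len(members)])
            break
    return members


class TestBuildSearchlights:
    def test_single_feature_is_center_only(self, icosphere42):
        sls = build_searchlights(icosphere42, n_features=1)
        assert all(s.members == (s.center,) for s in sls)

    def test_100_members_everywhere_on_icosphere3(self):
        mesh = make_toy_surface(3)
        sls = build_searchlights(mesh, 100)
        assert len(sls) == 642
        assert all(len(s.members) == 100 for s in sls)

    @pytest.mark.parametrize("n_features", [7, 12, 20])
    def test_matches_ring_expansion_oracle(self, icosphere42, n_features):
        sls = build_searchlights(icosphere42, n_features)
        for sl in sls:
            expected = brute_force_searchlight(icosphere42, sl.center,
                                               n_features)
            assert sorted(sl.members) == sorted(expected)

    def test_oversized_request_rejected(self, icosphere42):
        with pytest.raises(ValueError):
            build_searchlights(icosphere42, 43)


@pytest.fixture(scope="module")
def planted():
    """One subject with a single planted semantic region, zero noise."""
    from actionrsa import make_ground_truth
    gt = make_ground_truth(seed=7)
    ms = ModelSet({"semantic": gt.true_rdm.copy(model="semantic")})
    mesh = make_toy_surface(2, n_regions=1, region_size=30, seed=0)
    ds = plant_brain_patterns(mesh, ms, {1: {"semantic": 1.0}}, n_subjects=1,
                              n_runs=2, noise_sd=0.0, seed=0)[0]
    region = mesh.region_vertices(1)
    roi = Searchlight(int(region[0]), tuple(int(v) for v in region))
    return ms, mesh, ds, roi


class TestNeuralRDM:
    def test_planted_region_standard_mode_correlates_one(self, planted):
        ms, mesh, ds, roi = planted
        nr = neural_rdm(ds, roi, mode="standard")
        assert rdm_correlation(nr, ms["semantic"]) == pytest.approx(1.0)

    def test_identical_conditions_flagged_degenerate(self, planted):
        ms, mesh, ds, roi = planted
        flat = BetaDataset("s", np.ones((2, len(ms.items), mesh.n_vertices)),
                           ms.items, mesh)
        nr = neural_rdm(flat, roi, mode="standard")
        assert nr.meta.get("degenerate")
        assert np.all(nr.values == 0)

    def test_condition_permutation_equivariance(self, planted):
        ms, mesh, ds, roi = planted
        perm = np.random.default_rng(0).permutation(len(ms.items))
        permuted = BetaDataset(ds.subject, ds.betas[:, perm, :],
                               tuple(ms.items[i] for i in perm), mesh)
        a = neural_rdm(ds, roi, mode="standard").values
        b = neural_rdm(permuted, roi, mode="standard").values
        assert np.allclose(b, a[np.ix_(perm, perm)], atol=1e-12)

    def test_regression_mode_z_scores_both_ways(self, planted):
        ms, mesh, ds, roi = planted
        rng = np.random.default_rng(1)
        noisy = BetaDataset(
            ds.subject, ds.betas + rng.normal(0, .1, ds.betas.shape),
            ms.items, mesh)
        nr = neural_rdm(noisy, roi, mode="regression")
        # after z-scoring across features every pattern has unit variance,
        # so squared distances are bounded by 4 * n_features
        assert nr.values.max() <= 4 * len(roi.members)


class TestStandardMap:
    def test_planted_region_map_high_inside_zero_noise(self, planted):
        """Full-region coverage is exact (r = 1, asserted elsewhere); partial
        searchlights inside the region still correlate strongly because the
        planted energy is spread over the whole region."""
        ms, mesh, ds, roi = planted
        region = set(mesh.region_vertices(1).tolist())
        sls = [s for s in build_searchlights(mesh, 10)
               if set(s.members) <= region]
        m = standard_rsa_map(ds, ms["semantic"], sls)
        inside = [m.values[s.center] for s in sls]
        assert len(inside) > 0 and min(inside) > 0.6

    def test_map_equals_looped_correlations(self, planted):
        ms, mesh, ds, roi = planted
        sls = build_searchlights(mesh, 10)[:25]
        m = standard_rsa_map(ds, ms["semantic"], sls)
        for sl in sls[:10]:
            nr = neural_rdm(ds, sl, mode="standard")
            if nr.meta.get("degenerate"):
                assert np.isnan(m.values[sl.center])
            else:
                assert m.values[sl.center] == pytest.approx(
                    rdm_correlation(nr, ms["semantic"]))

    def test_pure_noise_map_mean_near_zero(self, planted):
        ms, mesh, _, _ = planted
        rng = np.random.default_rng(2)
        noise = BetaDataset("n", rng.normal(size=(2, 28, mesh.n_vertices)),
                            ms.items, mesh)
        m = standard_rsa_map(noise, ms["semantic"],
                             build_searchlights(mesh, 10))
        assert abs(np.nanmean(m.values)) < 0.03


class TestRegressionMap:
    def test_recovers_planted_mixture_weights(self, two_model_set):
        mesh = make_toy_surface(3, n_regions=1, region_size=80, seed=1)
        ds = plant_brain_patterns(mesh, two_model_set,
                                  {1: {"semantic": 2.0, "body": 3.0}},
                                  n_subjects=1, n_runs=2, noise_sd=0.0,
                                  seed=0)[0]
        region = mesh.region_vertices(1)
        roi = Searchlight(int(region[0]), tuple(int(v) for v in region))
        maps = regression_rsa_map(ds, two_model_set, [roi], mode="raw")
        got = np.array([maps["semantic"].values[roi.center],
                        maps["body"].values[roi.center]])
        assert np.allclose(got, [2.0, 3.0], rtol=1e-6)

    def test_irrelevant_orthogonal_model_leaves_weights(self, two_model_set,
                                                        gt28):
        mesh = make_toy_surface(3, n_regions=1, region_size=80, seed=1)
        ds = plant_brain_patterns(mesh, two_model_set,
                                  {1: {"semantic": 2.0, "body": 3.0}},
                                  n_subjects=1, n_runs=2, noise_sd=0.0,
                                  seed=0)[0]
        region = mesh.region_vertices(1)
        roi = Searchlight(int(region[0]), tuple(int(v) for v in region))
        base = regression_rsa_map(ds, two_model_set, [roi], mode="raw")
        # residualize a third model against the first two: orthogonal addition
        x = two_model_set.matrix().T
        rng = np.random.default_rng(3)
        v = rng.normal(size=x.shape[0])
        design = np.column_stack([np.ones(len(v)), x])
        resid = v - design @ np.linalg.lstsq(design, v, rcond=None)[0]
        resid = resid - resid.min() + 0.05
        extra = RDM.from_vector(resid, two_model_set.items)
        ms3 = ModelSet({"semantic": two_model_set["semantic"],
                        "body": two_model_set["body"], "extra": extra})
        # the residualized vector got shifted/rescaled on ingest; only its
        # span matters: coefficients on the original two models must hold
        wide = regression_rsa_map(ds, ms3, [roi], mode="raw")
        for name in ("semantic", "body"):
            assert wide[name].values[roi.center] == pytest.approx(
                base[name].values[roi.center], abs=1e-6)

    def test_collinear_model_set_rejected_before_loop(self, gt28,
                                                      small_region_mesh):
        ms = ModelSet({"semantic": gt28.true_rdm.copy(),
                       "extra": gt28.true_rdm.copy()})
        ds = BetaDataset("s", np.zeros((2, 28, small_region_mesh.n_vertices)),
                         ms.items, small_region_mesh)
        with pytest.raises(ValueError, match="collinear"):
            regression_rsa_map(ds, ms)

    def test_single_model_agrees_with_standard_up_to_monotone(self, planted):
        ms, mesh, ds, roi = planted
        sls = build_searchlights(mesh, 10)
        std = standard_rsa_map(ds, ms["semantic"], sls)
        reg = regression_rsa_map(ds, ms, sls, mode="raw")["semantic"]
        ok = ~(np.isnan(std.values) | np.isnan(reg.values))
        from scipy.stats import spearmanr
        rho = spearmanr(std.values[ok], reg.values[ok]).statistic
        assert rho > 0.9

    def test_single_model_identity_gives_unit_coefficient(self, planted):
        ms, mesh, ds, roi = planted
        m1 = ModelSet({"semantic": neural_rdm(ds, roi, mode="raw")})
        reg = regression_rsa_map(ds, m1, [roi], mode="raw")["semantic"]
        assert reg.values[roi.center] == pytest.approx(1.0, abs=1e-9)


class TestGLM:
    def test_rank_deficient_design_names_columns(self, small_design_events):
        cfg, events = small_design_events
        series = [np.zeros((cfg.volumes_per_run, 2))] * 2
        dup = [np.ones((cfg.volumes_per_run, 1))] * 2  # duplicates constant
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            glm_betas(series, events, cfg, nuisance_regressors=dup)

    def test_all_zero_series_all_zero_betas(self, small_design_events):
        cfg, events = small_design_events
        series = [np.zeros((cfg.volumes_per_run, 3))] * 2
        est = glm_betas(series, events, cfg)
        assert np.allclose(est, 0)

    def test_constant_offset_absorbed_by_intercept(self, small_design_events):
        cfg, events = small_design_events
        rng = np.random.default_rng(0)
        betas = rng.normal(size=(2, cfg.n_actions, 3))
        from actionrsa.timeseries import simulate_timeseries
        series = simulate_timeseries(betas, events, cfg, noise_sd=0.0)
        shifted = [s + 11.0 for s in series]
        a = glm_betas(series, events, cfg)
        b = glm_betas(shifted, events, cfg)
        assert np.allclose(a, b, atol=1e-8)


@pytest.fixture(scope="module")
def small_design_events():
    from actionrsa.design import DesignConfig, generate_trial_sequence
    cfg = DesignConfig()
    return cfg, generate_trial_sequence(cfg, seed=21)[:2]


class TestBetaDatasetIO:
    def test_hdf5_round_trip(self, tmp_path, planted):
        ms, mesh, ds, roi = planted
        path = tmp_path / "betas.h5"
        ds.to_hdf5(path)
        back = BetaDataset.from_hdf5(path, mesh)
        assert back.subject == ds.subject
        assert back.condition_labels == ds.condition_labels
        assert np.allclose(back.betas, ds.betas)
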