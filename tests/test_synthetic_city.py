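import numpy as np
import pytest

from bymap.rate_allocation import build_service_zones
from bymap.spatial_lattice import (
    build_adjacency,
    morans_i,
    square_grid_lattice,
    write_areas_geojson,
)
from bymap.synthetic_city import (
    generate_city,
    generate_lattice,
    make_truth,
    sample_covariates,
    sample_icar,
    sample_icar_anchored,
    sample_populations,
    scatter_cases_to_services,
    simulate_counts,
    simulate_services,
)
from shapely.geometry import box


class TestGenerateLattice:
    def test_partitions_bbox(self):
        lat = generate_lattice(4, bbox=(0, 0, 1, 1), seed=1)
        assert sum(p.area for p in lat.polygons) == pytest.approx(1.0,
                                                                  abs=1e-9)

    def test_deterministic_geojson(self, tmp_path):
        paths = []
        for k in range(2):
            lat = generate_lattice(25, seed=9)
            p = tmp_path / f"areas{k}.geojson"
            write_areas_geojson(p, lat.area_ids, lat.polygons)
            paths.append(p.read_bytes())
        assert paths[0] == paths[1]

    def test_460_areas_no_islands(self):
        lat = generate_lattice(460, seed=7)
        assert lat.n == 460
        assert lat.islands() == []

    def test_too_few_areas(self):
        with pytest.raises(ValueError, match="at least 4"):
            generate_lattice(3)

    def test_degenerate_bbox(self):
        with pytest.raises(ValueError, match="bbox"):
            generate_lattice(10, bbox=(0, 0, 0, 1))


class TestSampleICAR:
    def test_sum_to_zero(self, grid5_rook):
        st = sample_icar(grid5_rook, tau_st=2.0, seed=0)
        assert abs(st.sum()) < 1e-10

    def test_two_area_antisymmetry(self):
        lat = build_adjacency(["a", "b"], [box(0, 0, 1, 1), box(1, 0, 2, 1)])
        st = sample_icar(lat, tau_st=1.0, seed=4)
        assert st[0] == pytest.approx(-st[1], abs=1e-12)

    def test_variance_scales_inversely_with_tau(self, grid5_rook):
        lo = sample_icar(grid5_rook, tau_st=1.0, seed=1, size=1000)
        hi = sample_icar(grid5_rook, tau_st=2.0, seed=1, size=1000)
        ratio = (lo**2).mean() / (hi**2).mean()
        assert ratio == pytest.approx(2.0, rel=0.10)

    def test_disconnected_rejected(self):
        polys = [box(0, 0, 1, 1), box(1, 0, 2, 1),
                 box(50, 0, 51, 1), box(51, 0, 52, 1)]
        lat = build_adjacency(list("abcd"), polys)
        with pytest.raises(ValueError, match="disconnected"):
            sample_icar(lat, 1.0)

    def test_anchored_conditional_law_smoke(self):
        # full conditional of a non-anchor area: mean = neighbor average,
        # var = 1/(tau * n_neighbors); checked by regression on 4000 draws
        lat = square_grid_lattice(4, 4, "queen")
        tau = 2.0
        draws = sample_icar_anchored(lat, tau, seed=3, size=4000)
        i = lat.index("r1c1")  # 8 neighbors, not adjacent to nothing
        others = [j for j in range(lat.n) if j != i and j != 0]
        A = np.column_stack([draws[:, others], np.ones(len(draws))])
        coef, res_ss, *_ = np.linalg.lstsq(A, draws[:, i], rcond=None)
        resid_var = res_ss[0] / (len(draws) - A.shape[1])
        nbrs = set(lat.neighbors(i).tolist())
        d = len(nbrs)
        for j, c in zip(others, coef):
            expect = 1.0 / d if j in nbrs else 0.0
            assert c == pytest.approx(expect, abs=0.05)
        assert resid_var == pytest.approx(1.0 / (tau * d), rel=0.15)


class TestPopulationsAndCovariates:
    def test_populations_floor_and_scale(self):
        pops = sample_populations(500, seed=0)
        assert pops.min() >= 50
        assert 1000 < np.median(pops) < 2200

    def test_covariates_nonzero_variance_and_ranges(self, grid5_rook):
        covs = sample_covariates(grid5_rook, seed=0)
        assert (covs.std() > 0).all()
        assert covs["imp"].min() >= 0 and covs["imp"].max() <= 86

    def test_covariates_positively_autocorrelated(self):
        stats = []
        for seed in range(20):
            lat = generate_lattice(60, seed=seed)
            covs = sample_covariates(lat, seed=seed)
            stats.append(morans_i(covs["imp"].to_numpy(), lat, 99,
                                  seed=seed).statistic)
        assert np.median(stats) > 0.2


class TestSimulateCounts:
    def test_poisson_mean_at_baseline(self):
        lat = generate_lattice(460, seed=0)
        covs = sample_covariates(lat, seed=0)
        pops = sample_populations(460, seed=0)
        truth = make_truth(lat, covs, seed=0,
                           exp_beta={c: 1.0 for c in covs.columns},
                           include_random_effects=False)
        counts = simulate_counts(truth, pops, covs.to_numpy(), seed=0)
        rate = counts.sum() / pops.sum()
        se = np.sqrt(counts.sum()) / pops.sum()
        assert abs(rate - 0.25) < 3 * max(se, 1e-6) + 1e-3

    def test_offset_linearity(self):
        lat = generate_lattice(100, seed=1)
        covs = sample_covariates(lat, seed=1)
        pops = sample_populations(100, seed=1)
        truth = make_truth(lat, covs, seed=1, include_random_effects=False)
        c1 = simulate_counts(truth, pops, covs.to_numpy(), seed=2)
        c2 = simulate_counts(truth, 2 * pops, covs.to_numpy(), seed=2)
        assert c2.sum() / c1.sum() == pytest.approx(2.0, rel=0.05)

    def test_monotone_in_effect_covariates(self):
        # Table-2-like scenario: risk increases in each nonnull covariate
        lat = generate_lattice(460, seed=3)
        covs = sample_covariates(lat, seed=3)
        pops = sample_populations(460, seed=3)
        truth = make_truth(lat, covs, seed=3, include_random_effects=False)
        counts = simulate_counts(truth, pops, covs.to_numpy(), seed=3)
        rates = counts / pops
        for name in ("migrant_rate", "pop_under15", "imp"):
            x = covs[name].to_numpy()
            order = np.argsort(x)
            bins = np.array_split(order, 4)
            means = [rates[b].mean() for b in bins]
            assert means[0] < means[-1]

    def test_nonfinite_predictor_rejected(self, grid5_rook):
        covs = sample_covariates(grid5_rook, seed=0)
        truth = make_truth(grid5_rook, covs, seed=0)
        bad = covs.to_numpy().copy()
        bad[0, 0] = np.inf
        with pytest.raises(ValueError, match="non-finite"):
            simulate_counts(truth, np.ones(25), bad, seed=0)


class TestServices:
    def _zones(self, n=40, seed=5, **kw):
        lat = generate_lattice(n, seed=seed)
        pops = sample_populations(n, seed=seed)
        services = simulate_services(lat, pops, seed=seed, **kw)
        return lat, pops, services, build_service_zones(services, lat, pops)

    def test_single_service_gets_everything(self):
        lat = generate_lattice(10, seed=0)
        pops = sample_populations(10, seed=0)
        services = simulate_services(lat, pops, n_primary=0,
                                     n_intermediate=0, n_high=1, seed=0)
        zones = build_service_zones(services, lat, pops)
        counts = np.arange(10) * 3
        out = scatter_cases_to_services(counts, zones, seed=1)
        assert out[services[0].service_id] == counts.sum()

    def test_symmetric_split(self):
        lat = generate_lattice(10, seed=0)
        pops = sample_populations(10, seed=0)
        twins = simulate_services(lat, pops, n_primary=0, n_intermediate=0,
                                  n_high=2, seed=0)
        zones = build_service_zones(twins, lat, pops)
        counts = np.full(10, 2000)
        out = scatter_cases_to_services(counts, zones, seed=2)
        total = sum(out.values())
        assert total == counts.sum()
        assert abs(out[twins[0].service_id] - total / 2) < 4 * np.sqrt(total)

    def test_conservation_mixed_tiers(self):
        lat, pops, services, zones = self._zones(60, seed=3)
        rng = np.random.default_rng(0)
        counts = rng.poisson(200, size=60)
        out = scatter_cases_to_services(counts, zones, seed=3)
        assert sum(out.values()) == counts.sum()

    def test_requires_high_complexity(self, grid5_rook):
        with pytest.raises(ValueError, match="high-complexity"):
            simulate_services(grid5_rook, np.ones(25), n_high=0)


class TestGenerateCity:
    def test_bitwise_reproducible(self):
        a = generate_city(n_areas=30, seed=12)
        b = generate_city(n_areas=30, seed=12)
        assert np.array_equal(a.cases, b.cases)
        assert a.service_consultations == b.service_consultations
        assert a.covariates.equals(b.covariates)
        assert a.truth.alpha == b.truth.alpha

    def test_consultations_conserve_cases(self, small_city):
        assert sum(small_city.service_consultations.values()) == \
            small_city.cases.sum()

    def test_truth_invariants(self, small_city):
        t = small_city.truth
        assert abs(t.st.sum()) < 1e-9
        assert (t.expected_rate > 0).all()
        assert (small_city.populations >= 1).all()
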