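"""Exposure kernels, release filtering, cumulative impact, urban shares."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from toxscape.containers import ConfigurationError, DecaySpec
from toxscape.exposure import (
    cumulative_impact,
    impact_buffer,
    impact_containment,
    impact_cutter,
    impact_exponential,
    impact_power,
    select_releases,
    transform_volumes,
    urban_source_share,
)

from conftest import make_lattice_regions, make_site


class TestKernels:
    def test_containment(self):
        spec = DecaySpec("containment", alpha=1.0)
        assert impact_containment(10000.0, True, spec) == 10000.0
        assert impact_containment(10000.0, False, spec) == 0.0
        assert impact_containment(100.0, True, DecaySpec("containment", alpha=2.0)) == 10000.0

    @pytest.mark.parametrize(
        "d, expected", [(50.0, 10000.0), (150.0, 0.0), (100.0, 10000.0)]
    )
    def test_buffer_boundary_included(self, d, expected):
        spec = DecaySpec("buffer", alpha=1.0, threshold=100.0)
        assert impact_buffer(10000.0, d, spec) == expected

    def test_power(self):
        assert impact_power(10000.0, 10.0, DecaySpec("power", alpha=1.0, theta=2.0)) == pytest.approx(100.0)
        assert impact_power(10000.0, 1.0, DecaySpec("power", alpha=1.0, theta=1.0)) == pytest.approx(10000.0)
        spec = DecaySpec("power", alpha=1.0, theta=2.0)
        assert impact_power(10000.0, 0.0, spec) == impact_power(10000.0, 1.0, spec)

    def test_exponential(self):
        spec = DecaySpec("exponential", alpha=1.0, theta=2.0)
        assert impact_exponential(10000.0, 0.0, spec) == pytest.approx(10000.0)
        # 10000 * e^-2, evaluated independently
        assert impact_exponential(10000.0, 1.0, spec) == pytest.approx(
            10000.0 * math.exp(-2.0), rel=1e-12
        )
        r = impact_exponential(10000.0, 2.0, spec) / impact_exponential(10000.0, 1.0, spec)
        assert r == pytest.approx(math.exp(-2.0), rel=1e-12)

    def test_cutter(self):
        spec = DecaySpec("cutter", alpha=1.0, theta=1.0, threshold=100.0)
        assert impact_cutter(10000.0, 0.0, spec) == pytest.approx(10000.0)
        assert impact_cutter(10000.0, 101.0, spec) == 0.0
        # 10000 * (1 - 0.25)^1 at half the threshold
        assert impact_cutter(10000.0, 50.0, spec) == pytest.approx(7500.0)

    def test_missing_threshold_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            DecaySpec("buffer", alpha=1.0)
        with pytest.raises(ConfigurationError):
            DecaySpec("cutter", alpha=1.0, theta=1.0)

    @settings(max_examples=80, deadline=None, derandomize=True)
    @given(
        t=st.floats(1.0, 1e6),
        d1=st.floats(0.0, 400.0),
        d2=st.floats(0.0, 400.0),
        theta=st.floats(0.1, 5.0),
        alpha=st.floats(0.5, 3.0),
    )
    def test_monotone_in_distance_and_volume(self, t, d1, d2, theta, alpha):
        lo, hi = min(d1, d2), max(d1, d2)
        specs = [
            DecaySpec("exponential", alpha=alpha, theta=theta),
            DecaySpec("cutter", alpha=alpha, theta=theta, threshold=200.0),
            DecaySpec("buffer", alpha=alpha, threshold=200.0),
        ]
        fns = [impact_exponential, impact_cutter, impact_buffer]
        for spec, fn in zip(specs, fns):
            assert fn(t, lo, spec) >= fn(t, hi, spec) >= 0.0
            assert fn(2.0 * t, lo, spec) >= fn(t, lo, spec)
        pspec = DecaySpec("power", alpha=alpha, theta=theta)
        if lo >= 1.0:  # beyond the distance floor
            assert impact_power(t, lo, pspec) >= impact_power(t, hi, pspec) >= 0.0

    def test_cutter_theta_to_zero_approaches_buffer(self):
        t = 10000.0
        spec_c = DecaySpec("cutter", alpha=1.0, theta=1e-6, threshold=100.0)
        spec_b = DecaySpec("buffer", alpha=1.0, threshold=100.0)
        for d in np.linspace(0.0, 99.9, 50):
            rel = abs(impact_cutter(t, d, spec_c) - impact_buffer(t, d, spec_b)) / t
            assert rel < 1e-4


class TestVolumeTransform:
    def test_log10_and_identity(self):
        assert transform_volumes(np.array([10000.0]), True)[0] == pytest.approx(4.0)
        assert transform_volumes(np.array([10000.0]), False)[0] == 10000.0

    def test_small_volume_floored_with_warning(self):
        with pytest.warns(UserWarning, match="floored"):
            out = transform_volumes(np.array([5.0]), True)
        assert out[0] == pytest.approx(1.0)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            transform_volumes(np.array([0.0]), True)


class TestSelectReleases:
    def make(self):
        return [
            make_site(0, 0, 0, 0, chem="all_carcinogen"),
            make_site(1, 1, 1, 0, chem="lung_carcinogen"),
            make_site(2, 2, 2, 0, chem="lung_compound"),
        ]

    def test_set_semantics_and_nesting(self):
        sites = self.make()
        s1 = select_releases(sites, "all_carcinogen")
        s2 = select_releases(sites, "lung_carcinogen")
        s3 = select_releases(sites, "lung_compound")
        assert {s.id for s in s1} == {"s0", "s1", "s2"}
        assert {s.id for s in s2} == {"s1"}
        assert {s.id for s in s3} == {"s1", "s2"}
        assert {s.id for s in s2} <= {s.id for s in s3} <= {s.id for s in s1}

    def test_all_lung_carcinogen_kept_by_set2(self):
        sites = [make_site(i, i, 0, 0, chem="lung_carcinogen") for i in range(4)]
        assert len(select_releases(sites, "lung_carcinogen")) == 4

    def test_empty_subset_warns(self):
        sites = [make_site(0, 0, 0, 0, chem="all_carcinogen")]
        with pytest.warns(UserWarning, match="no sites"):
            assert select_releases(sites, "lung_carcinogen") == []

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="unknown release set"):
            select_releases(self.make(), "everything")


class TestCumulativeImpact:
    def test_additivity_within_buffer(self, grid3):
        sites = [make_site(0, 1.5, 1.5, 4, volume=100.0), make_site(1, 1.4, 1.5, 4, volume=200.0)]
        spec = DecaySpec("buffer", alpha=1.0, threshold=10.0)
        imp = cumulative_impact(sites, grid3, spec)
        assert np.allclose(imp.K, 300.0)
        assert np.allclose(imp.per_site.sum(axis=0), imp.K)

    def test_zero_sites_gives_zero_vector(self, grid3):
        imp = cumulative_impact([], grid3, DecaySpec("buffer", threshold=1.0))
        assert imp.K.shape == (9,) and (imp.K == 0).all()

    def test_disjoint_union_linearity(self, grid3, rng):
        spec = DecaySpec("exponential", alpha=1.0, theta=0.5)
        a = [make_site(i, *rng.uniform(0, 3, 2), region_id=4) for i in range(5)]
        b = [make_site(i + 10, *rng.uniform(0, 3, 2), region_id=4) for i in range(4)]
        Ka = cumulative_impact(a, grid3, spec).K
        Kb = cumulative_impact(b, grid3, spec).K
        Kab = cumulative_impact(a + b, grid3, spec).K
        assert np.allclose(Ka + Kb, Kab, rtol=1e-12)

    def test_overflow_names_site(self, grid3):
        sites = [make_site(0, 0.5, 0.5, 0, volume=1e300)]
        with pytest.raises(FloatingPointError, match="s0"):
            cumulative_impact(sites, grid3, DecaySpec("containment", alpha=2.0))

    def test_external_passthrough(self, grid3):
        regions = [r.with_external_risk(float(j)) for j, r in enumerate(grid3)]
        imp = cumulative_impact([], regions, DecaySpec("external"))
        assert np.allclose(imp.K, np.arange(9.0))
        with pytest.raises(ConfigurationError, match="external_risk"):
            cumulative_impact([], grid3, DecaySpec("external"))


class TestUrbanShare:
    def make_scene(self):
        codes = [1] + [5] * 8  # region 0 metropolitan
        regions = make_lattice_regions(3, codes=codes)
        sites = [
            make_site(0, 0.5, 0.5, 0, volume=75.0),   # urban source
            make_site(1, 2.5, 2.5, 8, volume=25.0),   # rural source
        ]
        return regions, sites

    def test_urban_and_rural_split(self):
        regions, sites = self.make_scene()
        spec = DecaySpec("buffer", alpha=1.0, threshold=10.0)
        imp = cumulative_impact(sites, regions, spec)
        share = urban_source_share(imp, sites, regions)
        assert np.allclose(share, 75.0)

    def test_all_urban_sources_give_100(self):
        regions, sites = self.make_scene()
        sites = [sites[0]]
        imp = cumulative_impact(sites, regions, DecaySpec("buffer", threshold=10.0))
        assert np.allclose(urban_source_share(imp, sites, regions), 100.0)

    def test_zero_impact_region_is_missing_not_zero(self):
        regions, sites = self.make_scene()
        spec = DecaySpec("buffer", alpha=1.0, threshold=0.5)  # covers only home cells
        imp = cumulative_impact(sites, regions, spec)
        share = urban_source_share(imp, sites, regions)
        assert np.isnan(share[imp.K == 0]).all()
        assert not np.isnan(share[imp.K > 0]).any()

    def test_conservation(self, rng):
        codes = rng.integers(0, 10, 25).tolist()
        regions = make_lattice_regions(5, codes=codes)
        sites = [
            make_site(i, *rng.uniform(0, 5, 2), region_id=int(rng.integers(0, 25)),
                      volume=float(10 ** rng.uniform(1, 4)))
            for i in range(12)
        ]
        spec = DecaySpec("exponential", alpha=1.0, theta=0.3)
        imp = cumulative_impact(sites, regions, spec)
        share = urban_source_share(imp, sites, regions)
        assert ((share >= 0) & (share <= 100) | np.isnan(share)).all()
        urban_ids = {r.id for r in regions if r.is_metro}
        total_urban = sum(
            imp.per_site[i].sum() for i, s in enumerate(sites) if s.region_id in urban_ids
        )
        assert np.nansum(share / 100.0 * imp.K) == pytest.approx(total_urban, rel=1e-10)

    def test_requires_per_site_matrix(self):
        regions, sites = self.make_scene()
        imp = cumulative_impact(sites, regions, DecaySpec("buffer", threshold=10.0), per_site_cap=1)
        assert imp.per_site is None
        with pytest.raises(ValueError, match="per-site"):
            urban_source_share(imp, sites, regions)
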