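"""Tests for thermal indices, grouping, pools, coverage and filtering."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoce import (
    assign_thermal_groups,
    build_species_pool,
    compute_cti,
    remove_singletons,
    sample_coverage,
)
from thermoce.thermal import (
    THERMAL_GROUPS,
    assign_zone,
    cti_by_site_year,
    species_ranges,
    summarise_site,
    summarise_sites,
)


class TestCTI:
    def test_single_species_identity(self):
        assert compute_cti(pd.Series({"a": 5}), pd.Series({"a": 7.2})) == 7.2

    def test_weighted_mean(self):
        cti = compute_cti(pd.Series({"a": 1, "b": 3}), pd.Series({"a": 4.0, "b": 8.0}))
        assert cti == pytest.approx(7.0)

    def test_equal_abundances_give_unweighted_mean(self):
        sti = pd.Series({"a": 3.0, "b": 9.0, "c": 6.0})
        assert compute_cti(pd.Series(1, index=sti.index), sti) == pytest.approx(6.0)

    def test_species_without_sti_excluded(self):
        cti = compute_cti(pd.Series({"a": 1, "x": 100}), pd.Series({"a": 4.0}))
        assert cti == 4.0

    def test_no_coverage_is_nan_with_warning(self):
        with pytest.warns(UserWarning, match="undefined"):
            assert np.isnan(compute_cti(pd.Series({"x": 3}), pd.Series({"a": 4.0})))

    def test_cti_bounded_by_member_stis(self, rng):
        for _ in range(20):
            n = rng.integers(2, 10)
            sti = pd.Series(rng.normal(8, 3, n), index=[f"s{i}" for i in range(n)])
            ab = pd.Series(rng.integers(1, 50, n), index=sti.index)
            cti = compute_cti(ab, sti)
            assert sti.min() <= cti <= sti.max()

    def test_site_year_table(self):
        obs = pd.DataFrame(
            {
                "site_id": ["A", "A", "A"],
                "year": [2000, 2000, 2001],
                "species": ["a", "b", "a"],
                "count": [1, 3, 2],
            }
        )
        sti = pd.Series({"a": 4.0, "b": 8.0})
        out = cti_by_site_year(obs, sti).set_index("year")["cti"]
        assert out[2000] == pytest.approx(7.0)
        assert out[2001] == pytest.approx(4.0)


class TestThermalGroups:
    def test_even_split(self):
        sti = pd.Series(np.arange(1.0, 9.0), index=[f"s{i}" for i in range(8)])
        groups, _ = assign_thermal_groups(sti)
        assert groups.value_counts().tolist() == [2, 2, 2, 2]

    def test_tie_goes_to_colder_group(self):
        # cuts of (1,2,2,2,3,4,5,6) are (2, 2.5, 4.25): the three STI=2
        # species sit exactly on the first cut and stay cold-adapted
        sti = pd.Series([1, 2, 2, 2, 3, 4, 5, 6], dtype=float,
                        index=[f"s{i}" for i in range(8)])
        groups, cuts = assign_thermal_groups(sti)
        assert cuts == pytest.approx([2.0, 2.5, 4.25])
        expected = ["cold-adapted"] * 4 + ["warm-tolerant"] * 2 + ["warm-adapted"] * 2
        assert list(groups) == expected

    def test_partition_property(self, rng):
        sti = pd.Series(rng.normal(8, 2, 57), index=[f"s{i}" for i in range(57)])
        groups, _ = assign_thermal_groups(sti)
        assert groups.notna().all()
        assert groups.value_counts().sum() == 57

    def test_too_few_species_rejected(self):
        with pytest.raises(ValueError):
            assign_thermal_groups(pd.Series({"a": 1.0, "b": 2.0, "c": 3.0}))


class TestSpeciesPool:
    ranges = pd.DataFrame(
        {"species": ["a", "b"], "min_latitude": [60.0, 62.0], "max_latitude": [65.0, 70.0]}
    )

    @pytest.mark.parametrize(
        "lat,expected",
        [(63.0, {"a", "b"}), (66.0, {"b"}), (65.0, {"a", "b"}), (59.0, set()),
         (60.0, {"a"})],
    )
    def test_inclusive_overlap(self, lat, expected):
        assert set(build_species_pool(lat, self.ranges)) == expected

    def test_group_filter(self):
        groups = pd.Series({"a": "cold-adapted", "b": "warm-adapted"})
        pool = build_species_pool(63.0, self.ranges, groups, "warm-adapted")
        assert set(pool) == {"b"}

    def test_ranges_from_observations(self):
        obs = pd.DataFrame(
            {
                "site_id": ["A", "B", "A"],
                "year": [2000, 2000, 2001],
                "species": ["a", "a", "b"],
                "count": [1, 1, 1],
            }
        )
        sites = pd.DataFrame({"site_id": ["A", "B"], "latitude": [60.0, 65.0]})
        out = species_ranges(obs, sites).set_index("species")
        assert out.loc["a", "min_latitude"] == 60.0
        assert out.loc["a", "max_latitude"] == 65.0
        assert out.loc["b", "max_latitude"] == 60.0


class TestSiteSummaries:
    def test_yearly_means(self):
        obs = pd.DataFrame(
            {
                "site_id": ["A"] * 3,
                "year": [2000, 2000, 2001],
                "species": ["a", "b", "a"],
                "count": [60, 40, 200],
            }
        )
        ranges = pd.DataFrame(
            {"species": ["a", "b"], "min_latitude": [59.0, 59.0],
             "max_latitude": [70.0, 70.0]}
        )
        row = pd.Series({"site_id": "A", "latitude": 62.0})
        out = summarise_site(obs, row, ranges)
        assert out["mean_abundance"] == pytest.approx(150.0)
        assert out["mean_richness"] == pytest.approx(1.5)
        assert out["pool_size"] == 2

    def test_group_richness_sums_to_total(self, fixture_dataset):
        from thermoce.io import sti_series

        ds = fixture_dataset
        sti = sti_series(ds.sti)
        groups, _ = assign_thermal_groups(sti)
        ranges = species_ranges(ds.observations, ds.sites)
        summ = summarise_sites(ds.observations, ds.sites, ranges, groups)
        total = sum(summ[f"S_{g}"] for g in THERMAL_GROUPS)
        assert np.allclose(total, summ["mean_richness"])
        for g in THERMAL_GROUPS:  # observed richness never exceeds group pool
            assert (summ[f"S_{g}"] <= summ[f"Sp_{g}"] + 1e-9).all()

    def test_zone_breakpoints(self):
        assert list(assign_zone(np.array([60.0, 63.0, 65.9, 66.0, 69.0]))) == [
            "South", "Middle", "Middle", "North", "North",
        ]


class TestSampleCoverage:
    def test_no_singletons_is_complete(self):
        assert sample_coverage([5, 3, 2]) == 1.0

    def test_worked_example(self):
        # n=100, f1=5, f2=3
        counts = [1] * 5 + [2] * 3 + [89]
        assert sample_coverage(counts) == pytest.approx(0.95060, abs=1e-5)

    def test_all_singletons_degenerate(self):
        assert sample_coverage([1, 1]) == pytest.approx(0.0)

    def test_empty_vector_rejected(self):
        with pytest.raises(ValueError):
            sample_coverage([])

    @given(st.lists(st.integers(1, 20), min_size=2, max_size=30))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_incrementing_a_singleton_never_decreases_coverage(self, counts):
        counts = np.array(counts)
        before = sample_coverage(counts)
        if (counts == 1).any():
            bumped = counts.copy()
            bumped[np.argmax(counts == 1)] += 1
            assert sample_coverage(bumped) >= before - 1e-12


class TestRemoveSingletons:
    obs = pd.DataFrame(
        {
            "site_id": ["A", "A", "A", "B"],
            "year": [2000, 2000, 2001, 2000],
            "species": ["solo", "pair", "pair", "solo"],
            "count": [1, 1, 1, 2],
        }
    )

    def test_per_site_definition(self):
        out = remove_singletons(self.obs)
        # 'solo' at A totals 1 -> removed there; at B totals 2 -> kept;
        # 'pair' at A has counts (1,1) summing to 2 -> kept
        assert set(zip(out["site_id"], out["species"])) == {
            ("A", "pair"), ("B", "solo"),
        }

    def test_global_mode(self):
        out = remove_singletons(self.obs, mode="global")
        assert set(out["species"]) == {"solo", "pair"}  # both total >= 2 globally

    def test_idempotent(self):
        once = remove_singletons(self.obs)
        twice = remove_singletons(once)
        pd.testing.assert_frame_equal(once, twice)
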