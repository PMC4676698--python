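"""Colocalization distance criterion and spatial association analysis."""

import numpy as np
import pytest
from scipy import stats

from miisr import (CdcSpec, LocalizationTable, RegionOfInterest,
                   compute_cdc, histogram_mode, make_pair_field,
                   nearest_neighbour_distances, randomize_positions,
                   saa_three_colour, saa_two_colour)
from miisr.saa import THREE_COLOUR_CLASSES


def bin_index(value, width=2.0):
    return int(np.floor(value / width))


class TestCdc:
    def test_two_colour_typical_value(self):
        # 10 nm per-channel precision -> 1.65*sqrt(200) = 23.33 nm,
        # inside the typical 23-28 nm two-colour range
        spec = CdcSpec(sigma_c=(10.0, 10.0), i_reg=0.0,
                       cutoff_multiplier=1.65)
        assert compute_cdc(spec) == pytest.approx(23.33, abs=0.01)
        assert 23.0 <= compute_cdc(spec) <= 28.0

    def test_registration_error_only(self):
        spec = CdcSpec(sigma_c=(0.0, 0.0), i_reg=5.0)
        assert compute_cdc(spec) == 5.0

    def test_three_colour_cdc_larger(self):
        two = CdcSpec(sigma_c=(10.0, 10.0))
        three = CdcSpec(sigma_c=(10.0, 10.0, 10.0))
        assert compute_cdc(three) > compute_cdc(two)
        assert 28.0 <= compute_cdc(three) <= 35.0

    @pytest.mark.parametrize("m", [1.0, 1.5, 3.0])
    def test_multiplier_restricted(self, m):
        with pytest.raises(ValueError):
            CdcSpec(sigma_c=(10, 10), cutoff_multiplier=m)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            CdcSpec(sigma_c=(-1.0, 10.0))
        with pytest.raises(ValueError):
            CdcSpec(sigma_c=(10.0, 10.0), i_reg=-1.0)

    def test_literal_sum_compatibility_form(self):
        spec = CdcSpec(sigma_c=(10.0, 10.0), literal_sum=True)
        assert spec.sigma_rms == pytest.approx(np.sqrt(20.0))

    def test_sigma_from_tables(self, small_table):
        spec = CdcSpec.from_tables([small_table, small_table])
        assert spec.sigma_c == (11.2, 11.2)


class TestNearestNeighbour:
    def test_coincident_molecule_distance_zero(self):
        a = LocalizationTable(x=[1.0], y=[1.0])
        b = LocalizationTable(x=[1.0, 5.0], y=[1.0, 5.0])
        assert nearest_neighbour_distances(a, b)[0] == 0.0

    def test_matches_brute_force_oracle(self, small_table, rng):
        b = LocalizationTable(x=rng.uniform(0, 1000, 7),
                              y=rng.uniform(0, 1000, 7))
        nn = nearest_neighbour_distances(small_table, b)
        pairwise = np.sqrt(
            (small_table.x[:, None] - b.x[None]) ** 2
            + (small_table.y[:, None] - b.y[None]) ** 2)
        np.testing.assert_allclose(nn, pairwise.min(axis=1))

    def test_one_distance_per_source_molecule(self, small_table):
        b = LocalizationTable(x=[0.0], y=[0.0])
        assert nearest_neighbour_distances(small_table, b).size == 5

    def test_empty_target_rejected(self, small_table):
        with pytest.raises(ValueError):
            nearest_neighbour_distances(small_table,
                                        LocalizationTable(x=[], y=[]))

    def test_homotypic_warns(self, uniform_table):
        with pytest.warns(UserWarning, match="homotypic"):
            nearest_neighbour_distances(uniform_table, uniform_table)


class TestRandomize:
    def test_all_points_inside_region(self, uniform_table):
        roi = RegionOfInterest.rectangle(0, 0, 2000, 2000)
        out = randomize_positions(uniform_table, roi, 7)
        assert roi.contains(out.xy).all()
        assert out.n == uniform_table.n

    def test_polygon_region_containment(self, uniform_table):
        roi = RegionOfInterest.polygon(
            [(0, 0), (2000, 0), (1000, 2000)])
        out = randomize_positions(uniform_table, roi, 7)
        assert roi.contains(out.xy).all()

    def test_metadata_carried_over(self, small_table):
        roi = RegionOfInterest.rectangle(0, 0, 1000, 1000)
        out = randomize_positions(small_table, roi, 3)
        np.testing.assert_array_equal(out.photons, small_table.photons)
        np.testing.assert_array_equal(out.precision, small_table.precision)

    def test_uniformity_chi_square(self, rng):
        # 10x10 occupancy grid over n=10^4 vs analytic expectation
        t = LocalizationTable(x=np.zeros(10_000), y=np.zeros(10_000))
        roi = RegionOfInterest.rectangle(0, 0, 1000, 1000)
        out = randomize_positions(t, roi, 99)
        counts, _, _ = np.histogram2d(out.x, out.y,
                                      bins=[np.linspace(0, 1000, 11)] * 2)
        chi2 = ((counts - 100.0) ** 2 / 100.0).sum()
        assert chi2 < stats.chi2.ppf(0.99, df=99)


class TestTwoColour:
    def test_noninteracting_fields_match_random_prediction(self, rng):
        n, L = 5000, 8500
        a = LocalizationTable(x=rng.uniform(0, L, n),
                              y=rng.uniform(0, L, n), channel_id="A")
        b = LocalizationTable(x=rng.uniform(0, L, n),
                              y=rng.uniform(0, L, n), channel_id="B")
        spec = CdcSpec(sigma_c=(10.0, 10.0))
        roi = RegionOfInterest.rectangle(0, 0, L, L)
        r_ab, _ = saa_two_colour(a, b, spec, region=roi,
                                 n_randomizations=20, seed=5)
        assert r_ab.enrichment == pytest.approx(1.0, abs=0.15)

    def test_directionality_with_unpaired_excess(self):
        # excess unpaired B lowers B->A association, A->B is unchanged
        spec = CdcSpec(sigma_c=(10.0, 10.0))
        paired = make_pair_field(n_pairs=3000, separation=10.2,
                                 unpaired_b_fraction=0.0, precision=20.0,
                                 seed=11)
        excess = make_pair_field(n_pairs=3000, separation=10.2,
                                 unpaired_b_fraction=1.0, precision=20.0,
                                 seed=11)
        kw = dict(spec=spec, n_randomizations=5, seed=4)
        ab0, ba0 = saa_two_colour(paired.channel("A"), paired.channel("B"),
                                  region=paired.region, **kw)
        ab1, ba1 = saa_two_colour(excess.channel("A"), excess.channel("B"),
                                  region=excess.region, **kw)
        assert ab1.fraction_below_cdc == pytest.approx(
            ab0.fraction_below_cdc, abs=0.05)
        assert ba1.fraction_below_cdc < 0.75 * ba0.fraction_below_cdc

    def test_separation_beyond_cdc_gives_zero_fraction(self):
        spec = CdcSpec(sigma_c=(10.0, 10.0))
        cdc = compute_cdc(spec)
        x = np.arange(20) * 1000.0
        a = LocalizationTable(x=x, y=np.zeros(20), channel_id="A")
        b = LocalizationTable(x=x + 2 * cdc, y=np.zeros(20),
                              channel_id="B")
        roi = RegionOfInterest.rectangle(-100, -100, 25000, 100)
        r_ab, _ = saa_two_colour(a, b, spec, region=roi,
                                 n_randomizations=2, seed=0)
        assert r_ab.fraction_below_cdc == 0.0

    def test_subset_size_validated(self, uniform_table):
        spec = CdcSpec(sigma_c=(10.0, 10.0))
        with pytest.raises(ValueError):
            saa_two_colour(uniform_table, uniform_table.subset([0, 1]),
                           spec, subset_size=10, seed=0)

    def test_translation_and_rotation_invariance(self, rng):
        spec = CdcSpec(sigma_c=(10.0, 10.0))
        scene = make_pair_field(n_pairs=800, separation=10.2,
                                precision=20.0, seed=21)
        a, b = scene.channel("A"), scene.channel("B")
        r0, _ = saa_two_colour(a, b, spec, region=scene.region,
                               n_randomizations=1, seed=3)
        # rotate both channels by 30 deg and translate
        th = np.pi / 6
        rot = np.array([[np.cos(th), -np.sin(th)],
                        [np.sin(th), np.cos(th)]])
        a2 = a.with_coords(a.xy @ rot.T + 500.0)
        b2 = b.with_coords(b.xy @ rot.T + 500.0)
        nn0 = nearest_neighbour_distances(a, b)
        nn2 = nearest_neighbour_distances(a2, b2)
        np.testing.assert_allclose(nn0, nn2, rtol=1e-9)
        assert np.mean(nn2 < r0.cdc) == r0.fraction_below_cdc

    def test_pair_field_mode_recovers_separation(self):
        # 50-mer-scale duplex: 17.0 nm separation at 20 nm precision
        scene = make_pair_field(n_pairs=4000, separation=17.0,
                                precision=20.0, seed=8)
        nn = nearest_neighbour_distances(scene.channel("A"),
                                         scene.channel("B"))
        mode = histogram_mode(nn)
        assert abs(bin_index(mode) - bin_index(17.0)) <= 1


class TestThreeColour:
    @staticmethod
    def _tables(rng, n=50):
        L = 2000.0
        mk = lambda cid: LocalizationTable(
            x=rng.uniform(0, L, n), y=rng.uniform(0, L, n), channel_id=cid)
        return mk("A"), mk("B"), mk("C")

    def test_classification_matches_exhaustive_oracle(self, rng):
        a, b, c = self._tables(rng)
        spec = CdcSpec(sigma_c=(10.0, 10.0, 10.0))
        res = saa_three_colour(a, b, c, spec, n_randomizations=1, seed=1)
        ref = res[0]
        cdc = spec.cdc
        for i in range(a.n):
            d1 = np.sqrt((b.x - a.x[i]) ** 2 + (b.y - a.y[i]) ** 2).min()
            d2 = np.sqrt((c.x - a.x[i]) ** 2 + (c.y - a.y[i]) ** 2).min()
            expected = ("both" if d1 < cdc and d2 < cdc else
                        "first_only" if d1 < cdc else
                        "second_only" if d2 < cdc else "neither")
            assert ref.classes[i] == expected

    def test_fractions_partition_to_one(self, rng):
        a, b, c = self._tables(rng)
        spec = CdcSpec(sigma_c=(10.0, 10.0, 10.0))
        for res in saa_three_colour(a, b, c, spec, n_randomizations=2,
                                    seed=2):
            assert sum(res.fractions.values()) == pytest.approx(1.0)
            assert sum(res.srp_fractions.values()) == pytest.approx(1.0)
            assert set(res.fractions) == set(THREE_COLOUR_CLASSES)

    def test_all_reference_channels_reported(self, rng):
        a, b, c = self._tables(rng, n=20)
        spec = CdcSpec(sigma_c=(10.0, 10.0, 10.0))
        res = saa_three_colour(a, b, c, spec, n_randomizations=1, seed=0)
        assert [r.reference for r in res] == ["A", "B", "C"]

    def test_both_class_for_tight_triple(self):
        a = LocalizationTable(x=[0.0], y=[0.0], channel_id="A")
        b = LocalizationTable(x=[5.0], y=[0.0], channel_id="B")
        c = LocalizationTable(x=[0.0], y=[5.0], channel_id="C")
        spec = CdcSpec(sigma_c=(10.0, 10.0, 10.0))
        res = saa_three_colour(a, b, c, spec, n_randomizations=1, seed=0,
                               region=RegionOfInterest.rectangle(
                                   0, 0, 100, 100))
        assert res[0].classes[0] == "both"

    def test_requires_three_channel_spec(self, rng):
        a, b, c = self._tables(rng, n=10)
        with pytest.raises(ValueError):
            saa_three_colour(a, b, c, CdcSpec(sigma_c=(10.0, 10.0)),
                             seed=0)


class TestHistogramMode:
    def test_mode_is_highest_bin_centre(self):
        d = np.concatenate([np.full(10, 5.0), np.full(3, 40.0)])
        assert histogram_mode(d) == 5.0

    def test_tie_broken_toward_smaller_r(self):
        d = np.concatenate([np.full(5, 5.0), np.full(5, 41.0)])
        assert histogram_mode(d) == 5.0
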