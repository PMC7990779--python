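"""EHH / iHH / iHS unit and property tests against independent oracles."""

import numpy as np
import pytest

from sweepcline.core import MISSING, SnpRecord
from sweepcline.ehh import (
    BinTable,
    EhhCurve,
    IhsResult,
    IhsScan,
    compute_ehh,
    integrate_ihh,
    screen_candidates,
    standardize_ihs,
    unstandardized_ihs,
    _side_area,
)

from conftest import brute_force_ehh, make_matrix


def _curve(positions, values, core_pos=None, allele="derived", side="right", n=4):
    core_pos = core_pos if core_pos is not None else positions[0]
    snp = SnpRecord("core", "1", core_pos, "A", "G")
    return EhhCurve(snp, allele, side, np.asarray(positions), np.asarray(values, float), n)


class TestComputeEhh:
    def test_identical_carriers_give_ehh_one_everywhere(self):
        # 4 derived carriers sharing one extended haplotype across the window
        m = make_matrix([[1, 1, 1, 0, 1]] * 4 + [[0, 0, 0, 1, 0]] * 4)
        for side in ("left", "right"):
            c = compute_ehh(m, 2, "derived", side)
            assert np.allclose(c.ehh_values, 1.0)

    def test_progressive_refinement_to_all_distinct(self):
        # biallelic markers split 4 carriers into 2+2, then into singletons
        m = make_matrix([
            [0, 0, 1, 0, 0],
            [0, 0, 1, 1, 0],
            [0, 1, 1, 0, 1],
            [0, 1, 1, 1, 1],
        ])
        c = compute_ehh(m, 2, "derived", "right")
        # groups {0,2},{1,3} at marker 3 -> EHH=1/3; all distinct at marker 4
        assert c.ehh_values[1] == pytest.approx(2 / 6)
        assert c.ehh_values[-1] == 0.0

    def test_two_groups_of_two(self):
        # 4 carriers splitting 2+2 at the flanking marker: EHH = (1+1)/C(4,2)
        m = make_matrix([
            [0, 0, 1, 0, 0],
            [0, 0, 1, 0, 0],
            [0, 0, 1, 1, 0],
            [0, 0, 1, 1, 0],
            [1, 1, 0, 1, 1],
        ])
        c = compute_ehh(m, 2, "derived", "right")
        assert c.ehh_values[1] == pytest.approx(1 / 3)

    def test_fewer_than_two_carriers_flagged(self):
        m = make_matrix([[0, 0, 1], [0, 0, 0], [0, 0, 0]])
        c = compute_ehh(m, 2, "derived", "left")
        assert "insufficient_carriers" in c.flags
        assert c.ehh_values.size == 0

    def test_missing_carrier_dropped_from_both_sides_of_ratio(self):
        # third carrier missing at marker 3: EHH there computed over 2 carriers
        m = make_matrix([
            [0, 0, 1, 0, 0],
            [0, 0, 1, 0, 1],
            [0, 0, 1, MISSING, 0],
        ])
        c = compute_ehh(m, 2, "derived", "right")
        assert c.ehh_values[1] == pytest.approx(1.0)  # remaining pair identical
        # at marker 4 the two survivors differ
        assert c.ehh_values[2] == 0.0


class TestEhhOracle:
    """Exact agreement with a pairwise-enumeration oracle on random data."""

    @pytest.mark.parametrize("with_missing", [False, True])
    def test_matches_brute_force(self, with_missing):
        rng = np.random.default_rng(7 if with_missing else 8)
        for _ in range(40):
            n_h = rng.integers(4, 20)
            n_s = rng.integers(3, 25)
            alleles = rng.integers(0, 2, size=(n_h, n_s)).astype(np.int8)
            if with_missing:
                mask = rng.random((n_h, n_s)) < 0.07
                alleles[mask] = MISSING
            m = make_matrix(alleles)
            core_j = int(rng.integers(0, n_s))
            positions = [s.pos for s in m.snps]
            for allele_class in ("ancestral", "derived"):
                for side in ("left", "right"):
                    expected = brute_force_ehh(alleles, positions, core_j,
                                               allele_class, side)
                    got = compute_ehh(m, core_j, allele_class, side)
                    if expected is None:
                        assert "insufficient_carriers" in got.flags
                        continue
                    exp_pos, exp_ehh = expected
                    np.testing.assert_array_equal(got.marker_positions, exp_pos)
                    np.testing.assert_allclose(got.ehh_values, exp_ehh, rtol=0, atol=1e-12)

    def test_monotone_and_bounded_without_missing(self):
        rng = np.random.default_rng(11)
        for _ in range(60):
            alleles = rng.integers(0, 2, size=(rng.integers(4, 24), rng.integers(3, 30)))
            m = make_matrix(alleles.astype(np.int8))
            j = int(rng.integers(0, m.n_snps))
            for side in ("left", "right"):
                c = compute_ehh(m, j, "derived", side)
                if c.ehh_values.size == 0:
                    continue
                assert np.all(np.diff(c.ehh_values) <= 1e-12)
                assert np.all((c.ehh_values >= 0) & (c.ehh_values <= 1))

    def test_allele_relabeling_swaps_areas_and_negates_score(self):
        rng = np.random.default_rng(13)
        alleles = rng.integers(0, 2, size=(20, 15)).astype(np.int8)
        m = make_matrix(alleles)
        flipped = make_matrix(1 - alleles)
        j = 7
        def areas(matrix):
            out = {}
            for ac in ("ancestral", "derived"):
                l = compute_ehh(matrix, j, ac, "left")
                r = compute_ehh(matrix, j, ac, "right")
                out[ac], _ = integrate_ihh(l, r)
            return out
        a1, a2 = areas(m), areas(flipped)
        assert a1["ancestral"] == pytest.approx(a2["derived"])
        assert a1["derived"] == pytest.approx(a2["ancestral"])
        lr1 = unstandardized_ihs(a1["ancestral"], a1["derived"])
        lr2 = unstandardized_ihs(a2["ancestral"], a2["derived"])
        assert lr1 == pytest.approx(-lr2)


class TestIntegrateIhh:
    def test_constant_curve_truncates_at_region_edge(self):
        right = _curve([1000, 4000, 8000, 11000], [1, 1, 1, 1])
        area, flags = _side_area(right, 0.05, None)
        assert area == pytest.approx(10_000.0)
        assert "edge_truncated" in flags

    def test_linear_decay_to_exact_cutoff(self):
        right = _curve([1000, 6000, 11000], [1.0, 0.525, 0.05])
        area, flags = _side_area(right, 0.05, None)
        assert area == pytest.approx((1 + 0.05) / 2 * 10_000)  # = 5250
        assert not flags

    def test_interpolated_crossing(self):
        right = _curve([1000, 2000], [1.0, 0.04])
        area, flags = _side_area(right, 0.05, None)
        t = 1000 * (1 - 0.05) / (1 - 0.04)
        assert area == pytest.approx((1 + 0.05) / 2 * t)
        assert not flags

    def test_two_sided_sum_and_flag_union(self):
        left = _curve([1000, 500], [1.0, 0.04], core_pos=1000, side="left")
        right = _curve([1000, 2000], [1.0, 1.0], core_pos=1000)
        area, flags = integrate_ihh(left, right)
        t = 500 * 0.95 / 0.96
        assert area == pytest.approx(0.525 * t + 1000.0)
        assert flags == {"edge_truncated"}

    def test_mismatched_curves_rejected(self):
        l = _curve([1000, 500], [1.0, 0.5], core_pos=1000, side="left", allele="ancestral")
        r = _curve([1000, 2000], [1.0, 0.5], core_pos=1000)
        with pytest.raises(ValueError):
            integrate_ihh(l, r)

    def test_empty_curves_rejected(self):
        l = _curve([1000], [], core_pos=1000, side="left")
        r = _curve([1000], [], core_pos=1000)
        with pytest.raises(ValueError):
            integrate_ihh(l, r)


class TestUnstandardizedIhs:
    @pytest.mark.parametrize("a, d, expected", [
        (3.5, 3.5, 0.0),
        (2.0, 1.0, np.log(2)),
        (1.0, 4.0, np.log(0.25)),
    ])
    def test_closed_form(self, a, d, expected):
        assert unstandardized_ihs(a, d) == pytest.approx(expected)

    def test_zero_area_undefined(self):
        assert np.isnan(unstandardized_ihs(1.0, 0.0))
        assert np.isnan(unstandardized_ihs(0.0, 1.0))


def _results(dafs, ln_ratios, flags=None):
    return [IhsResult(snp=SnpRecord(f"s{i}", "1", 1000 * (i + 1), "A", "G"),
                      population="pop1", daf=d, ihh_a=1.0, ihh_d=1.0, ln_ratio=lr,
                      flags=set(flags[i]) if flags else set())
            for i, (d, lr) in enumerate(zip(dafs, ln_ratios))]


class TestStandardize:
    def test_bins_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(5)
        res = _results(rng.uniform(0.05, 0.95, 400), rng.normal(-0.5, 0.8, 400))
        std = standardize_ihs(res, n_bins=10, min_bin_size=5)
        scored = [r for r in std if np.isfinite(r.ihs)]
        assert len(scored) == 400
        for b in {r.bin_index for r in scored}:
            vals = np.array([r.ihs for r in scored if r.bin_index == b])
            assert vals.mean() == pytest.approx(0.0, abs=1e-10)
            assert vals.std(ddof=1) == pytest.approx(1.0, rel=1e-10)

    def test_small_bin_flagged_without_external_table(self):
        res = _results([0.5], [0.3])
        std = standardize_ihs(res, min_bin_size=5)
        assert "small_bin" in std[0].flags
        assert np.isnan(std[0].ihs)

    def test_external_table_hand_arithmetic(self):
        table = BinTable(np.array([0.0, 1.0]), np.array([0.1]), np.array([0.5]))
        std = standardize_ihs(_results([0.5], [0.6]), external_bin_table=table)
        assert std[0].ihs == pytest.approx(1.0)

    def test_edge_truncated_excluded_by_default(self):
        res = _results([0.3, 0.5], [0.2, 0.4], flags=[["edge_truncated"], []])
        table = BinTable(np.array([0.0, 1.0]), np.array([0.0]), np.array([1.0]))
        std = standardize_ihs(res, external_bin_table=table)
        assert np.isnan(std[0].ihs)
        assert std[1].ihs == pytest.approx(0.4)

    def test_bin_table_round_trip(self, tmp_path):
        rng = np.random.default_rng(3)
        table = BinTable.from_scores(rng.uniform(0.05, 0.95, 300),
                                     rng.normal(0, 1, 300))
        table.to_tsv(tmp_path / "bins.tsv")
        back = BinTable.from_tsv(tmp_path / "bins.tsv")
        np.testing.assert_allclose(back.edges, table.edges)
        np.testing.assert_allclose(back.means, table.means)
        np.testing.assert_allclose(back.sds, table.sds)


class TestScreen:
    def test_threshold_is_strict(self):
        res = _results([0.5, 0.5, 0.5, 0.5], [0] * 4)
        for r, v in zip(res, [2.1, -2.5, 1.9, 2.0]):
            r.ihs = v
        hits = screen_candidates(res, threshold=2.0)
        assert [h[2] for h in hits] == [2.1, -2.5]

    def test_all_zero_scores_give_empty_screen(self):
        res = _results([0.5, 0.6], [0, 0])
        for r in res:
            r.ihs = 0.0
        assert screen_candidates(res) == []


class TestIhsScan:
    def test_low_daf_snps_not_scored(self):
        rng = np.random.default_rng(2)
        alleles = rng.integers(0, 2, size=(40, 10)).astype(np.int8)
        alleles[:, 0] = 0
        alleles[0, 0] = 1  # daf 1/40 < 0.05
        res = IhsScan(make_matrix(alleles)).fit()
        assert "rs0" not in set(res.frame["snp_id"])

    def test_scan_is_deterministic_and_summarises(self):
        rng = np.random.default_rng(21)
        alleles = rng.integers(0, 2, size=(30, 12)).astype(np.int8)
        m = make_matrix(alleles)
        f1 = IhsScan(m).fit().frame
        f2 = IhsScan(m).fit().frame
        assert f1.equals(f2)
        assert "population" in IhsScan(m).fit().summary()
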