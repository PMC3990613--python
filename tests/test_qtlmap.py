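"""Kosambi transforms, map estimation, CIM scan, thresholds, aggregation."""

import math

import numpy as np
import pandas as pd
import pytest

from hetqtl import qtlmap as qm
from hetqtl import simulate as sim


class TestKosambi:
    def test_zero_fixed_point(self):
        assert qm.kosambi_r_to_cm(0.0) == 0.0
        assert qm.kosambi_cm_to_r(0.0) == 0.0

    def test_quarter_recombination_closed_form(self):
        # d = (1/4) ln 3 Morgans = 27.47 cM
        assert qm.kosambi_r_to_cm(0.25) == pytest.approx(25.0 * math.log(3.0), abs=1e-9)
        assert qm.kosambi_r_to_cm(0.25) == pytest.approx(27.47, abs=0.005)

    def test_round_trip_identity(self):
        for r in np.arange(0.01, 0.50, 0.01):
            assert qm.kosambi_cm_to_r(qm.kosambi_r_to_cm(r)) == pytest.approx(r, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            qm.kosambi_r_to_cm(0.5)
        with pytest.raises(ValueError):
            qm.kosambi_cm_to_r(-1.0)

    def test_ril_recomb_haldane_waddington(self):
        assert qm.ril_recomb(0.25) == pytest.approx(1.0 / 3.0)
        assert qm.ril_recomb(0.0) == 0.0


class TestRounding:
    @pytest.mark.parametrize(
        "value,expected",
        [(7.5717, 7.6), (24.983, 25.0), (5.15, 5.2), (5.75, 5.8), (-3.65, -3.7), (5.0, 5.0)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert qm.round_half_away(value, 1) == pytest.approx(expected)


class TestMapEstimation:
    def test_identical_columns_are_zero_distance(self):
        geno = pd.DataFrame({"a": [1, -1, 1, -1], "b": [1, -1, 1, -1]})
        mm = pd.DataFrame({"marker": ["a", "b"], "chrom": ["c", "c"]})
        est = qm.estimate_map_distances(geno, mm)
        assert est["cm"].to_list() == [0.0, 0.0]

    def test_consistency_at_20_cm(self):
        mm = pd.DataFrame(
            {"marker": ["a", "b"], "chrom": ["c", "c"], "cm": [0.0, 20.0], "bp": [1, 2]}
        )
        geno = sim.simulate_ril_genotypes(mm, n_lines=10_000, seed=6)
        est = qm.estimate_map_distances(geno, mm[["marker", "chrom"]])
        assert est["cm"].iloc[1] == pytest.approx(20.0, abs=1.0)

    def test_total_map_length_within_5_pct(self, default_marker_map):
        geno = sim.simulate_ril_genotypes(default_marker_map, n_lines=2000, seed=13)
        est = qm.estimate_map_distances(geno, default_marker_map[["marker", "chrom"]])
        true_total = sum(
            grp["cm"].max() - grp["cm"].min() for _, grp in default_marker_map.groupby("chrom")
        )
        est_total = sum(grp["cm"].max() for _, grp in est.groupby("chrom"))
        assert abs(est_total - true_total) / true_total <= 0.05

    def test_unlinked_markers_capped_and_warned(self, rng):
        geno = pd.DataFrame(
            {"a": rng.choice([1.0, -1.0], 400), "b": rng.choice([1.0, -1.0], 400)}
        )
        geno["b"] = -geno["a"] * np.sign(rng.random(400) - 0.2)  # mostly discordant
        mm = pd.DataFrame({"marker": ["a", "b"], "chrom": ["c", "c"]})
        with pytest.warns(UserWarning, match="unlinked"):
            est = qm.estimate_map_distances(geno, mm)
        assert est["cm"].iloc[1] == 50.0


class TestCofactorSelection:
    def test_null_phenotype_model_stays_weak(self, ril_population):
        rng = np.random.default_rng(17)
        y = pd.Series(rng.normal(size=len(ril_population)), index=ril_population.index)
        cof = qm.select_cofactors(ril_population, y)
        if cof:
            X = np.column_stack(
                [np.ones(len(y))] + [ril_population[m].to_numpy() for m in cof]
            )
            beta, *_ = np.linalg.lstsq(X, y.to_numpy(), rcond=None)
            resid = y.to_numpy() - X @ beta
            r2 = 1 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))
            assert r2 < 0.10

    def test_planted_marker_selected_first(self, ril_population, default_marker_map):
        marker = default_marker_map["marker"].iloc[40]
        x = ril_population[marker].to_numpy()
        sd = sim.residual_sd_for_fraction(1.0, 0.3)
        rng = np.random.default_rng(19)
        first = 0
        for rep in range(200):
            y = pd.Series(x + rng.normal(0, sd, size=len(x)), index=ril_population.index)
            sel = qm.select_cofactors(ril_population, y, max_cofactors=1)
            first += bool(sel) and sel[0] == marker
        assert first >= 0.95 * 200

    def test_zero_budget_gives_empty_set(self, ril_population):
        y = pd.Series(np.arange(len(ril_population)), index=ril_population.index, dtype=float)
        assert qm.select_cofactors(ril_population, y, max_cofactors=0) == []

    def test_constant_phenotype_gives_empty_set(self, ril_population):
        y = pd.Series(1.0, index=ril_population.index)
        assert qm.select_cofactors(ril_population, y) == []


class TestScan:
    def test_constant_phenotype_gives_zero_lod(self, ril_population, default_marker_map):
        y = pd.Series(3.14, index=ril_population.index)
        profile = qm.scan(ril_population, y, default_marker_map)
        assert (profile.positions["lod"] == 0).all()

    def test_lod_at_marker_equals_single_marker_regression(self, marked_map):
        """At a cofactor-free marker position LOD = -(n/2) log10(1 - R^2)."""
        geno = sim.simulate_ril_genotypes(marked_map, n_lines=266, seed=23)
        rng = np.random.default_rng(23)
        marker = marked_map[(marked_map.chrom == "chr03") & (marked_map.cm == 44.0)]["marker"].iloc[0]
        x = geno[marker].to_numpy()
        y_arr = 0.8 * x + rng.normal(0, 1.5, size=len(x))
        y = pd.Series(y_arr, index=geno.index)
        profile = qm.scan(geno, y, marked_map)
        pos = profile.positions
        at_marker = pos[(pos["chrom"] == "chr03") & (np.isclose(pos["cm"], 44.0))]
        r2 = np.corrcoef(x, y_arr)[0, 1] ** 2
        expected = -(len(y) / 2.0) * math.log10(1 - r2)
        assert at_marker["lod"].iloc[0] == pytest.approx(expected, rel=1e-9)

    def test_grid_covers_marker_span(self, ril_population, default_marker_map):
        y = pd.Series(
            np.random.default_rng(5).normal(size=len(ril_population)),
            index=ril_population.index,
        )
        profile = qm.scan(ril_population, y, default_marker_map, step=2.0)
        for chrom, grp in default_marker_map.groupby("chrom"):
            sub = profile.positions[profile.positions["chrom"] == chrom]
            assert sub["cm"].min() == pytest.approx(grp["cm"].min())
            assert sub["cm"].max() == pytest.approx(grp["cm"].max())
        assert (profile.positions["lod"] >= 0).all()

    def test_expected_code_interpolates_between_flanks(self, default_marker_map):
        geno = sim.simulate_ril_genotypes(default_marker_map, n_lines=100, seed=29)
        grp = default_marker_map[default_marker_map["chrom"] == "chr01"]
        mid = (grp["cm"].iloc[0] + grp["cm"].iloc[1]) / 2
        codes = qm.expected_qtl_code(geno, default_marker_map, "chr01", mid)
        same = geno[grp["marker"].iloc[0]] == geno[grp["marker"].iloc[1]]
        assert (np.abs(codes) <= 1).all()
        assert np.all(np.sign(codes[same.to_numpy()]) == geno.loc[same, grp["marker"].iloc[0]])

    def test_missing_genotypes_fall_back_to_nearest_flank(self, default_marker_map):
        geno = sim.simulate_ril_genotypes(default_marker_map, n_lines=30, seed=31)
        grp = default_marker_map[default_marker_map["chrom"] == "chr01"]
        m0, m1, m2 = grp["marker"].iloc[:3]
        geno_missing = geno.copy()
        geno_missing.loc[geno.index[0], m1] = np.nan
        pos = (grp["cm"].iloc[1] + grp["cm"].iloc[2]) / 2
        codes = qm.expected_qtl_code(geno_missing, default_marker_map, "chr01", pos)
        assert np.isfinite(codes).all()


class TestPermutationThreshold:
    def test_monotone_in_alpha_and_reproducible(self, ril_population, default_marker_map):
        rng = np.random.default_rng(37)
        y = pd.Series(rng.normal(size=len(ril_population)), index=ril_population.index)
        thrs = [
            qm.permutation_threshold(
                ril_population, y, default_marker_map, n_perm=100, alpha=a, seed=1
            )
            for a in (0.01, 0.1, 0.5, 1.0)
        ]
        assert thrs == sorted(thrs, reverse=True)
        again = qm.permutation_threshold(
            ril_population, y, default_marker_map, n_perm=100, alpha=0.01, seed=1
        )
        assert again == thrs[0]

    def test_alpha_one_is_minimum_of_null_maxima(self, ril_population, default_marker_map):
        rng = np.random.default_rng(38)
        y = pd.Series(rng.normal(size=len(ril_population)), index=ril_population.index)
        thr = qm.permutation_threshold(
            ril_population, y, default_marker_map, n_perm=50, alpha=1.0, seed=2
        )
        gen = np.random.default_rng(2)
        Y = np.column_stack([gen.permutation(y.to_numpy()) for _ in range(50)])
        maxima = qm.max_scan_lods(ril_population, Y, default_marker_map)
        assert thr == pytest.approx(maxima.min())

    def test_constant_phenotype_rejected(self, ril_population, default_marker_map):
        y = pd.Series(1.0, index=ril_population.index)
        with pytest.raises(ValueError):
            qm.permutation_threshold(ril_population, y, default_marker_map, n_perm=10, seed=0)


class TestCallAndAggregate:
    def test_profile_below_threshold_yields_no_qtls(self, ril_population, default_marker_map):
        rng = np.random.default_rng(41)
        y = pd.Series(rng.normal(size=len(ril_population)), index=ril_population.index)
        profile = qm.scan(ril_population, y, default_marker_map, trait="T", environment="e")
        assert qm.call_qtls(profile, 1e6, default_marker_map, ril_population, y) == []

    def test_noise_free_marker_effect_recovered_exactly(self, marked_map):
        geno = sim.simulate_ril_genotypes(marked_map, n_lines=120, seed=43)
        marker = marked_map[(marked_map.chrom == "chr03") & (marked_map.cm == 44.0)]["marker"].iloc[0]
        y = pd.Series(geno[marker].to_numpy(), index=geno.index)
        profile = qm.scan(geno, y, marked_map, trait="T", environment="e")
        records = qm.call_qtls(profile, 3.0, marked_map, geno, y)
        best = max(records, key=lambda r: r.lod)
        assert best.chrom == "chr03"
        assert best.peak_cm == pytest.approx(44.0)
        assert best.additive_effect == pytest.approx(1.0)
        assert best.r2_pct == pytest.approx(100.0, abs=1e-6)

    def test_flanking_markers_bracket_the_peak(self, marked_map):
        geno = sim.simulate_ril_genotypes(marked_map, n_lines=200, seed=47)
        marker = marked_map[(marked_map.chrom == "chr03") & (marked_map.cm == 44.0)]["marker"].iloc[0]
        rng = np.random.default_rng(48)
        y = pd.Series(geno[marker] + rng.normal(0, 1.0, len(geno)), index=geno.index)
        profile = qm.scan(geno, y, marked_map, trait="T", environment="e")
        for rec in qm.call_qtls(profile, 3.0, marked_map, geno, y):
            assert rec.cm_lo <= rec.peak_cm <= rec.cm_hi

    @staticmethod
    def _record(trait, env, chrom, lo, hi, lod, marker_lo="mL", marker_hi="mH"):
        return qm.QTLRecord(
            trait=trait, environment=env, chrom=chrom, peak_cm=(lo + hi) / 2,
            marker_lo=marker_lo, marker_hi=marker_hi, cm_lo=lo, cm_hi=hi,
            r2_pct=10.0, additive_effect=1.0, lod=lod, threshold=3.0,
        )

    def test_single_environment_mean_is_its_own_lod(self):
        merged = qm.aggregate_environments([self._record("DTH", "e1", "c1", 0, 10, 6.24)])
        assert len(merged) == 1
        assert merged[0].mean_lod == 6.2
        assert merged[0].name == "qdth-1"

    def test_overlapping_intervals_merge_disjoint_stay(self):
        records = [
            self._record("DTH", "e1", "c1", 0, 10, 4.0),
            self._record("DTH", "e2", "c1", 10, 20, 6.0),   # shares the 10 cM endpoint
            self._record("DTH", "e3", "c1", 50, 60, 8.0),   # disjoint
            self._record("PHT", "e1", "c1", 0, 10, 5.0),    # other trait
        ]
        merged = qm.aggregate_environments(records)
        by_name = {m.name: m for m in merged}
        assert set(by_name) == {"qdth-1", "qdth-2", "qpht-1"}
        assert by_name["qdth-1"].mean_lod == 5.0
        assert by_name["qdth-1"].cm_lo == 0 and by_name["qdth-1"].cm_hi == 20
        assert by_name["qdth-2"].mean_lod == 8.0

    def test_aggregation_idempotence(self):
        records = [
            self._record("DTH", "e1", "c1", 0, 10, 4.0),
            self._record("DTH", "e2", "c1", 5, 20, 6.0),
        ]
        merged = qm.aggregate_environments(records)
        again = qm.aggregate_environments(
            [r for m in merged for r in m.records]
        )
        assert len(again) == len(merged) == 1
        assert again[0].mean_lod == merged[0].mean_lod
        assert (again[0].cm_lo, again[0].cm_hi) == (merged[0].cm_lo, merged[0].cm_hi)

    def test_mean_lod_selection_boundary(self):
        merged = qm.aggregate_environments(
            [
                self._record("DTH", "e1", "c1", 0, 10, 5.0),
                self._record("PHT", "e1", "c2", 0, 10, 4.9),
                self._record("TGW", "e1", "c3", 0, 10, 4.95),  # rounds to 5.0: retained
            ]
        )
        kept = qm.select_by_mean_lod(merged, 5.0)
        brute = [m for m in merged if m.mean_lod >= 5.0]
        assert kept == brute
        assert {m.trait for m in kept} == {"DTH", "TGW"}
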