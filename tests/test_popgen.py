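import numpy as np
import pandas as pd
import pytest

from ldanchor import (
    GenotypeMatrix,
    PanelMetadata,
    allele_freq_trajectory,
    annual_allele_change,
    call_introgression_carriers,
    fst_outlier_scan,
    group_by_decade,
    nei_fst_pair,
    nei_fst_pairwise,
    per_locus_fst,
    phase_to_reference,
)
from ldanchor.popgen import DECADE_LABELS, DecadeGroups, FreqTrajectory

from conftest import make_gm, make_map


def meta_from_years(years: dict[str, float | None]) -> PanelMetadata:
    return PanelMetadata(
        pd.DataFrame(
            {
                "individual_id": list(years),
                "cultivar_name": list(years),
                "registration_year": [np.nan if y is None else y for y in years.values()],
                "origin": "x",
            }
        )
    )


def two_group_matrix(freq_a, freq_b, n_per=10, n_loci=1):
    """Inbred dosage matrix realizing exact per-group allele frequencies."""
    cols = []
    for _ in range(n_loci):
        a = np.zeros(n_per)
        a[: int(round(freq_a * n_per))] = 2.0
        b = np.zeros(n_per)
        b[: int(round(freq_b * n_per))] = 2.0
        cols.append(np.concatenate([a, b]))
    ids = [f"a{k}" for k in range(n_per)] + [f"b{k}" for k in range(n_per)]
    gm = GenotypeMatrix(ids, [f"L{j}" for j in range(n_loci)], np.column_stack(cols))
    return gm, [f"a{k}" for k in range(n_per)], [f"b{k}" for k in range(n_per)]


class TestDecadeGroups:
    @pytest.mark.parametrize(
        "year, label",
        [(1998, "1990s"), (1966, "1960s"), (2010, "2010-2020"), (2020, "2010-2020"),
         (1969, "1960s"), (2009, "2000s")],
    )
    def test_floor_rule(self, year, label):
        groups = group_by_decade(meta_from_years({"g": year}))
        assert groups.assignment["g"] == label

    def test_out_of_range_and_missing_excluded(self):
        groups = group_by_decade(
            meta_from_years({"old": 1950, "future": 2025, "unknown": None, "ok": 1980})
        )
        assert set(groups.excluded) == {"old", "future", "unknown"}
        assert list(groups.assignment) == ["ok"]


class TestTrajectory:
    def _groups(self, gm_ids_by_label):
        assignment = {}
        for label, ids in gm_ids_by_label.items():
            for g in ids:
                assignment[g] = label
        return DecadeGroups(assignment)

    def test_absent_and_fixed_alleles(self):
        # 1960s: allele absent; 1970s: fixed
        gm = GenotypeMatrix(
            ["a1", "a2", "b1", "b2"], ["L"], np.array([[0.0], [0.0], [2.0], [2.0]])
        )
        groups = self._groups({"1960s": ["a1", "a2"], "1970s": ["b1", "b2"]})
        traj = allele_freq_trajectory(gm, groups, allele_rule="alt")[("L")]
        assert traj.frequency[0] == 0.0
        assert traj.frequency[1] == 1.0
        assert np.isnan(traj.frequency[2])  # empty cohort

    def test_minor_allele_fixed_panel_wide(self):
        gm = GenotypeMatrix(
            ["a", "b", "c", "d"], ["L"], np.array([[2.0], [2.0], [2.0], [0.0]])
        )
        groups = self._groups({"1960s": ["a", "b"], "1970s": ["c", "d"]})
        traj = allele_freq_trajectory(gm, groups)["L"]
        # panel-wide minor allele is the reference (freq 0.25): per-group ref freqs
        assert traj.frequency[0] == pytest.approx(0.0)
        assert traj.frequency[1] == pytest.approx(0.5)


class TestAnnualChange:
    def _traj(self, freqs, n=None):
        freqs = np.asarray(freqs, dtype=float)
        n = np.full(len(freqs), 10) if n is None else np.asarray(n)
        return FreqTrajectory("m", DECADE_LABELS, freqs, n)

    def test_constant_trajectory_zero_slope(self):
        assert annual_allele_change(self._traj([0.3] * 6)) == pytest.approx(0.0)

    def test_matches_hand_ols_on_six_points(self):
        freqs = np.array([0, 0, 0, 25, 50, 75]) / 100.0
        traj = self._traj(freqs)
        years = np.array([1965, 1975, 1985, 1995, 2005, 2015], dtype=float)
        y = freqs * 100
        slope_oracle = np.polyfit(years, y, 1)[0]
        assert annual_allele_change(traj) == pytest.approx(slope_oracle, abs=1e-10)

    def test_two_point_slope(self):
        freqs = np.array([0.0, 0.10, np.nan, np.nan, np.nan, np.nan])
        assert annual_allele_change(self._traj(freqs)) == pytest.approx(1.0)

    def test_single_point_returns_none(self):
        freqs = np.array([0.2, np.nan, np.nan, np.nan, np.nan, np.nan])
        assert annual_allele_change(self._traj(freqs)) is None

    def test_weighting_by_group_size(self):
        # heavily weighting the flat early cohorts drags the slope down
        freqs = np.array([0.0, 0.0, 0.0, 0.0, 0.0, 0.5])
        equal = annual_allele_change(self._traj(freqs))
        skewed = annual_allele_change(self._traj(freqs, n=[100, 100, 100, 100, 100, 5]))
        assert skewed < equal


class TestNeiFst:
    def test_hand_arithmetic_case(self):
        gm, a, b = two_group_matrix(0.2, 0.8)
        res = nei_fst_pair(gm, a, b)
        assert res.ht == pytest.approx(0.5, abs=1e-12)
        assert res.hs == pytest.approx(0.32, abs=1e-12)
        assert res.fst == pytest.approx(0.36, abs=1e-12)

    def test_fixed_difference_gives_one(self):
        gm, a, b = two_group_matrix(1.0, 0.0, n_loci=5)
        assert nei_fst_pair(gm, a, b).fst == pytest.approx(1.0)

    def test_identical_frequencies_give_zero(self):
        gm, a, b = two_group_matrix(0.3, 0.3, n_loci=4)
        assert nei_fst_pair(gm, a, b).fst == pytest.approx(0.0, abs=1e-12)

    def test_all_monomorphic_undefined(self):
        gm, a, b = two_group_matrix(0.0, 0.0)
        assert nei_fst_pair(gm, a, b).fst is None

    def test_allele_flip_invariance(self):
        gm, a, b = two_group_matrix(0.2, 0.7, n_loci=3)
        flipped = gm.dosage.copy()
        flipped[:, 1] = 2.0 - flipped[:, 1]
        gm2 = GenotypeMatrix(gm.individual_ids, gm.marker_ids, flipped)
        assert nei_fst_pair(gm2, a, b).fst == pytest.approx(
            nei_fst_pair(gm, a, b).fst, abs=1e-12
        )

    def test_pairwise_matrix_symmetric(self, sim_panel):
        _, (gm, _mm, _hits, meta, _qc, _truth) = sim_panel
        groups = group_by_decade(meta)
        mat = nei_fst_pairwise(gm, groups)
        np.testing.assert_allclose(mat.to_numpy(), mat.to_numpy().T, atol=1e-12)
        assert np.allclose(np.diag(mat.to_numpy()), 0.0)


class TestPerLocusFst:
    def _six_group_panel(self, seed=0):
        rng = np.random.default_rng(seed)
        ids, assignment = [], {}
        for label in DECADE_LABELS:
            for k in range(8):
                g = f"{label}_{k}"
                ids.append(g)
                assignment[g] = label
        dosage = rng.choice([0.0, 2.0], size=(len(ids), 30))
        return GenotypeMatrix(ids, [f"L{j}" for j in range(30)], dosage), DecadeGroups(
            assignment
        )

    def test_matches_brute_force_oracle(self):
        gm, groups = self._six_group_panel()
        fst = per_locus_fst(gm, groups)
        for j, marker in enumerate(gm.marker_ids):
            ps, ns = [], []
            for label in DECADE_LABELS:
                rows = [gm.individual_ids.index(g) for g in groups.members(label)]
                col = gm.dosage[rows, j]
                vals = col[~np.isnan(col)]
                ps.append(vals.mean() / 2.0)
                ns.append(len(vals))
            ps, ns = np.array(ps), np.array(ns, dtype=float)
            w = ns / ns.sum()
            pbar = (w * ps).sum()
            ht = 2 * pbar * (1 - pbar)
            hs = (w * 2 * ps * (1 - ps)).sum()
            if ht == 0:
                assert np.isnan(fst[marker])
            else:
                assert fst[marker] == pytest.approx((ht - hs) / ht, abs=1e-12)

    def test_differentiated_locus_exceeds_homogeneous(self):
        ids, assignment = [], {}
        for label in DECADE_LABELS:
            for k in range(6):
                g = f"{label}_{k}"
                ids.append(g)
                assignment[g] = label
        # locus 0: two cohorts fixed for opposite alleles, rest intermediate
        col0, col1 = [], []
        for li, label in enumerate(DECADE_LABELS):
            for k in range(6):
                if li == 0:
                    col0.append(0.0)
                elif li == 1:
                    col0.append(2.0)
                else:
                    col0.append(2.0 if k % 2 else 0.0)
                col1.append(2.0 if k % 2 else 0.0)  # identical freqs everywhere
        gm = GenotypeMatrix(ids, ["diff", "homog"], np.column_stack([col0, col1]))
        fst = per_locus_fst(gm, DecadeGroups(assignment))
        assert fst["diff"] > fst["homog"]
        assert fst["homog"] == pytest.approx(0.0, abs=1e-12)

    def test_in_unit_interval_where_defined(self, sim_panel):
        _, (gm, _mm, _hits, meta, _qc, _truth) = sim_panel
        fst = per_locus_fst(gm, group_by_decade(meta))
        vals = fst.dropna()
        assert ((vals >= 0) & (vals <= 1)).all()


class TestOutlierScan:
    def test_monomorphic_locus_absent(self):
        ids, assignment = [], {}
        for label in DECADE_LABELS[:2]:
            for k in range(12):
                g = f"{label}_{k}"
                ids.append(g)
                assignment[g] = label
        rng = np.random.default_rng(1)
        dosage = rng.choice([0.0, 2.0], size=(24, 5))
        dosage[:, 0] = 0.0
        gm = GenotypeMatrix(ids, [f"L{j}" for j in range(5)], dosage)
        table = fst_outlier_scan(gm, DecadeGroups(assignment), n_perm=100, seed=0)
        assert "L0" not in set(table["marker_id"])

    def test_low_nperm_warns(self):
        gm, groups = TestPerLocusFst()._six_group_panel(seed=2)
        with pytest.warns(UserWarning, match="n_perm"):
            fst_outlier_scan(gm, groups, n_perm=50, seed=0)

    def test_sweep_block_flagged(self, sim_panel):
        _, (gm, _mm, _hits, meta, _qc, truth) = sim_panel
        groups = group_by_decade(meta)
        table = fst_outlier_scan(gm, groups, n_perm=500, seed=3)
        intro = table[table["marker_id"].isin(truth.introgression_markers)]
        rest = table[~table["marker_id"].isin(truth.introgression_markers)]
        # sweep loci have the smallest attainable permutation p-values
        assert (intro["p_value"] == intro["p_value"].min()).all()
        assert intro["fst"].min() > rest["fst"].quantile(0.99)


class TestGraphicalGenotypes:
    def _region_panel(self):
        rng = np.random.default_rng(4)
        n = 10
        ref = rng.choice([0.0, 2.0], size=6)
        rows = [ref, 2.0 - ref]  # reference and its complement
        for _ in range(n - 2):
            rows.append(rng.choice([0.0, 2.0], size=6))
        ids = ["ref", "anti"] + [f"g{k}" for k in range(n - 2)]
        gm = GenotypeMatrix(ids, [f"m{j}" for j in range(6)], np.array(rows))
        mm = make_map([(f"m{j}", "2A", 1_000_000 * (j + 1)) for j in range(6)])
        return gm, mm

    def test_reference_matches_itself(self):
        gm, mm = self._region_panel()
        gg = phase_to_reference(gm, mm, ("2A", 1, 10_000_000), "ref")
        assert gg.match_fraction["ref"] == pytest.approx(1.0)
        assert (gg.codes.loc["ref"] == "match").all()

    def test_complementary_individual_scores_zero(self):
        gm, mm = self._region_panel()
        gg = phase_to_reference(gm, mm, ("2A", 1, 10_000_000), "ref")
        assert gg.match_fraction["anti"] == pytest.approx(0.0)

    def test_het_and_missing_codes(self):
        gm, mm = self._region_panel()
        gm.dosage[2, 0] = 1.0
        gm.dosage[2, 1] = np.nan
        gg = phase_to_reference(gm, mm, ("2A", 1, 10_000_000), "ref")
        assert gg.codes.iloc[2, 0] == "het"
        assert gg.codes.iloc[2, 1] == "missing"

    def test_region_marker_count(self):
        # a 54-marker region fixture: all markers inside 0-24.5 Mbp appear
        rng = np.random.default_rng(5)
        n_mark = 54
        gm = GenotypeMatrix(
            ["r", "s"],
            [f"m{j}" for j in range(n_mark)],
            rng.choice([0.0, 2.0], size=(2, n_mark)),
        )
        mm = make_map(
            [(f"m{j}", "2A", 1 + j * 450_000) for j in range(n_mark)]
        )
        gg = phase_to_reference(gm, mm, ("2A", 1, 24_500_000), "r")
        assert gg.codes.shape[1] == n_mark

    def test_empty_region_errors(self):
        gm, mm = self._region_panel()
        with pytest.raises(ValueError, match="no markers"):
            phase_to_reference(gm, mm, ("7D", 1, 2), "ref")


class TestCarriers:
    def test_reference_is_carrier_and_strict_threshold(self):
        gm, mm = TestGraphicalGenotypes()._region_panel()
        # individual g0 differs from ref at exactly one marker
        g0_row = gm.individual_ids.index("g0")
        ref_row = gm.individual_ids.index("ref")
        gm.dosage[g0_row] = gm.dosage[ref_row]
        gm.dosage[g0_row, 0] = 2.0 - gm.dosage[ref_row, 0]
        gg = phase_to_reference(gm, mm, ("2A", 1, 10_000_000), "ref")
        meta = meta_from_years({g: 1990 + i for i, g in enumerate(gm.individual_ids)})
        carriers = call_introgression_carriers(gg, meta, match_threshold=1.0)
        assert "ref" in set(carriers["individual_id"])
        assert "g0" not in set(carriers["individual_id"])

    def test_first_carrier_year_on_synthetic_sweep(self, sim_panel):
        cfg, (gm, _mm, _hits, meta, _qc, truth) = sim_panel
        first = truth.carriers.sort_values("registration_year").iloc[0]
        region = (
            cfg.introgression.chromosome,
            cfg.introgression.start_bp,
            cfg.introgression.end_bp,
        )
        gg = phase_to_reference(gm, truth.true_map, region, first["individual_id"])
        carriers = call_introgression_carriers(gg, meta)
        first_years = carriers.loc[carriers["first_carrier"], "registration_year"]
        assert (first_years == cfg.introgression.start_year).all()

    def test_carrier_count_nondecreasing_over_decades(self, sim_panel):
        cfg, (gm, _mm, _hits, meta, _qc, truth) = sim_panel
        groups = group_by_decade(meta)
        carriers = set(truth.carriers["individual_id"])
        sizes = [
            sum(g in carriers for g in groups.members(label)) for label in DECADE_LABELS
        ]
        assert all(b >= a for a, b in zip(sizes, sizes[1:]))
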