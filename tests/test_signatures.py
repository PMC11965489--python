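"""Carcinogen signature, mitotic clock, and PRBS score construction."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import fieldsig as fs
from fieldsig.signatures import CpGSetScoreDefinition, read_bed3
from fieldsig.sim import simulate_annotation_resources, simulate_fetal_betas


def _tissue_block(n_cpgs=8, per_group=3, seed=0):
    rng = np.random.default_rng(seed)
    cols = [f"e{i}" for i in range(per_group)] + [f"u{i}" for i in range(per_group)]
    exposed = pd.Series([True] * per_group + [False] * per_group, index=cols)
    beta = pd.DataFrame(
        rng.uniform(0.2, 0.8, size=(n_cpgs, len(cols))),
        index=[f"cg{i}" for i in range(n_cpgs)], columns=cols,
    )
    return beta, exposed


class TestTissueRanking:
    def test_strong_hyper_cpg_ranked_first(self):
        beta, exposed = _tissue_block()
        beta.loc["cg0"] = 0.2
        beta.loc["cg0", exposed[exposed].index] = 0.7
        r = fs.rank_tissue_cpgs(beta, exposed)
        assert r.hyper_rank["cg0"] == 1.0
        assert r.hypo_rank["cg0"] == len(beta)

    def test_all_equal_differences_get_average_rank(self):
        beta, exposed = _tissue_block()
        beta.loc[:, :] = 0.5
        r = fs.rank_tissue_cpgs(beta, exposed)
        assert (r.hyper_rank == (len(beta) + 1) / 2).all()

    def test_ranks_match_sort_oracle(self):
        beta, exposed = _tissue_block(seed=3)
        r = fs.rank_tissue_cpgs(beta, exposed)
        diff = {
            c: beta.loc[c, exposed[exposed].index].mean()
            - beta.loc[c, exposed[~exposed].index].mean()
            for c in beta.index
        }
        order = sorted(diff, key=diff.get, reverse=True)
        for pos, c in enumerate(order, start=1):
            assert r.hyper_rank[c] == pos

    def test_single_group_rejected(self):
        beta, exposed = _tissue_block()
        with pytest.raises(ValueError, match="2 samples per exposure group"):
            fs.rank_tissue_cpgs(beta, pd.Series(True, index=beta.columns))


class TestCombineRankings:
    def test_identical_rankings_unchanged(self):
        r = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        out = fs.combine_rankings_geometric([r, r, r])
        pd.testing.assert_series_equal(out["rank"], r.rename("rank"))

    def test_hand_geometric_means(self):
        # CpG ranks (1,4), (2,2), (3,1) -> geo means 2.0, 2.0, sqrt(3)
        t1 = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        t2 = pd.Series([4.0, 2.0, 1.0], index=["a", "b", "c"])
        out = fs.combine_rankings_geometric([t1, t2])
        assert out.loc["a", "geo_mean"] == pytest.approx(2.0)
        assert out.loc["b", "geo_mean"] == pytest.approx(2.0)
        assert out.loc["c", "geo_mean"] == pytest.approx(math.sqrt(3))
        assert out.loc["c", "rank"] == 1.0
        assert out.loc["a", "rank"] == out.loc["b", "rank"] == 2.5

    def test_single_tissue_identity(self):
        r = pd.Series([2.0, 1.0, 3.0], index=["a", "b", "c"])
        out = fs.combine_rankings_geometric([r])
        pd.testing.assert_series_equal(out["rank"], r.rename("rank"))

    def test_mismatched_universe_rejected(self):
        r1 = pd.Series([1.0, 2.0], index=["a", "b"])
        r2 = pd.Series([1.0, 2.0], index=["a", "c"])
        with pytest.raises(ValueError, match="universe"):
            fs.combine_rankings_geometric([r1, r2])


class TestDefineSignature:
    def test_sets_have_size_k_and_are_disjoint(self, small_cohort):
        beta, sheet, _ = small_cohort
        sig = fs.define_carcinogen_signature(beta, sheet, k=150)
        assert len(sig.hyper_cpgs) == len(sig.hypo_cpgs) == 150
        assert not set(sig.hyper_cpgs) & set(sig.hypo_cpgs)

    def test_planted_cpgs_dominate_selection(self, small_cohort):
        beta, sheet, truth = small_cohort
        sig = fs.define_carcinogen_signature(beta, sheet, k=150)
        assert len(set(sig.hyper_cpgs) & set(truth["hyper_cpgs"])) / 150 >= 0.95
        assert len(set(sig.hypo_cpgs) & set(truth["hypo_cpgs"])) / 150 >= 0.95

    def test_scaling_normalizes_healthy_mammary(self, small_cohort):
        beta, sheet, _ = small_cohort
        sig = fs.define_carcinogen_signature(beta, sheet, k=100)
        healthy = sheet.index[
            (sheet.tissue == "mammary_gland") & (sheet.exposure == "P/D-")
        ]
        s = fs.score_carcinogen(beta[healthy], sig, scaled=True)
        assert s.mean() == pytest.approx(0.0, abs=1e-12)
        assert s.std(ddof=1) == pytest.approx(1.0, abs=1e-12)

    def test_invariant_to_sample_order(self, small_cohort):
        beta, sheet, _ = small_cohort
        sig1 = fs.define_carcinogen_signature(beta, sheet, k=50)
        perm = list(beta.columns[::-1])
        sig2 = fs.define_carcinogen_signature(beta[perm], sheet.loc[perm], k=50)
        assert sig1.hyper_cpgs == sig2.hyper_cpgs
        assert sig1.hypo_cpgs == sig2.hypo_cpgs
        assert sig1.scale_location == pytest.approx(sig2.scale_location)

    def test_too_few_cpgs_rejected(self, small_cohort):
        beta, sheet, _ = small_cohort
        with pytest.raises(ValueError, match="CpGs"):
            fs.define_carcinogen_signature(beta.iloc[:100], sheet, k=100)

    def test_missing_healthy_mammary_rejected(self, small_cohort):
        beta, sheet, _ = small_cohort
        keep = sheet.index[sheet.tissue != "mammary_gland"]
        with pytest.raises(ValueError, match="mammary"):
            fs.define_carcinogen_signature(beta[keep], sheet.loc[keep], k=50)

    def test_round_trip_json(self, small_cohort, tmp_path):
        beta, sheet, _ = small_cohort
        sig = fs.define_carcinogen_signature(beta, sheet, k=50)
        sig.to_json(tmp_path / "sig.json")
        back = fs.CarcinogenSignature.from_json(tmp_path / "sig.json")
        assert back == sig


class TestScoreCarcinogen:
    def _sig(self):
        return fs.CarcinogenSignature(
            hyper_cpgs=["h1", "h2"], hypo_cpgs=["l1", "l2"],
            scale_location=0.0, scale_spread=1.0, k=2,
        )

    def test_extreme_scores(self):
        beta = pd.DataFrame(
            {"s": [1.0, 1.0, 0.0, 0.0]}, index=["h1", "h2", "l1", "l2"]
        )
        assert fs.score_carcinogen(beta, self._sig(), scaled=False)["s"] == pytest.approx(1.0)

    def test_balanced_betas_score_zero(self):
        beta = pd.DataFrame({"s": [0.4, 0.6, 0.5, 0.5]}, index=["h1", "h2", "l1", "l2"])
        assert fs.score_carcinogen(beta, self._sig(), scaled=False)["s"] == pytest.approx(0.0)

    def test_coverage_floor_enforced(self):
        beta = pd.DataFrame({"s": [1.0, 0.0]}, index=["h1", "l1"])
        with pytest.raises(ValueError, match="floor"):
            fs.score_carcinogen(beta, self._sig())

    @settings(max_examples=40, derandomize=True, deadline=None)
    @given(
        st.lists(st.floats(0.0, 1.0), min_size=4, max_size=4),
        st.integers(0, 1),
        st.floats(0.01, 0.2),
    )
    def test_monotone_in_hyper_and_hypo_betas(self, vals, which, bump):
        """Raising a hyper-set beta raises the score; a hypo-set beta lowers it."""
        beta = pd.DataFrame({"s": vals}, index=["h1", "h2", "l1", "l2"])
        base = fs.score_carcinogen(beta, self._sig(), scaled=False)["s"]
        target = ["h1", "l1"][which]
        beta2 = beta.copy()
        beta2.loc[target, "s"] = min(1.0, beta2.loc[target, "s"] + bump)
        new = fs.score_carcinogen(beta2, self._sig(), scaled=False)["s"]
        moved = beta2.loc[target, "s"] - beta.loc[target, "s"]
        if which == 0:
            assert new >= base - 1e-12 and (moved == 0 or new > base - 1e-12)
        else:
            assert new <= base + 1e-12


class TestScoreCpgSet:
    def test_arithmetic_mean(self):
        d = CpGSetScoreDefinition(cpg_ids=("a", "b", "c"), label="mitotic_clock")
        beta = pd.DataFrame({"s": [0.2, 0.4, 0.9]}, index=["a", "b", "c"])
        assert fs.score_cpg_set(beta, d)["s"] == pytest.approx(0.5)

    @pytest.mark.parametrize("fill,expect", [(0.0, 0.0), (1.0, 1.0)])
    def test_extremes(self, fill, expect):
        d = CpGSetScoreDefinition(cpg_ids=("a", "b"), label="prbs")
        beta = pd.DataFrame({"s": [fill, fill]}, index=["a", "b"])
        assert fs.score_cpg_set(beta, d)["s"] == expect

    def test_scores_bounded_by_unit_interval(self, small_cohort):
        beta, _, truth = small_cohort
        d = CpGSetScoreDefinition(cpg_ids=tuple(truth["hyper_cpgs"][:50]), label="mitotic_clock")
        s = fs.score_cpg_set(beta, d)
        assert ((s >= 0) & (s <= 1)).all()

    def test_planted_drift_recovered(self):
        """Exposure shifts clock CpGs by +0.2; scored difference matches."""
        cfg = fs.ScenarioConfig(
            seed=33, n_cpgs=1000, tissues=("mammary_gland", "liver"), n_per_group=8,
            effect_size_hyper=0.2, effect_size_hypo=0.2,
            n_affected_hyper=150, n_affected_hypo=150, noise_sd=0.01,
        )
        beta, sheet, truth = fs.simulate_discovery_cohort(cfg)
        d = CpGSetScoreDefinition(cpg_ids=tuple(truth["hyper_cpgs"]), label="mitotic_clock")
        s = fs.score_cpg_set(beta, d)
        exposed = sheet.exposure == "P/D+"
        gap = s[exposed.to_numpy()].mean() - s[(~exposed).to_numpy()].mean()
        assert gap == pytest.approx(0.2, abs=0.02)


class TestMitoticClockSelection:
    def _inputs(self):
        cpg_ann = pd.DataFrame(
            {
                "chrom": ["chr1"] * 6,
                "pos": [100, 350, 450, 700, 1000, 1200],
            },
            index=[f"cg{i}" for i in range(6)],
        )
        tss = pd.DataFrame({"gene": ["GeneA", "GeneB"], "chrom": ["chr1", "chr1"], "tss": [300, 1150]})
        hom = pd.DataFrame({"human_gene": ["GENEA", "GENEB"], "mouse_gene": ["GeneA", "GeneB"]})
        fetal = pd.DataFrame(
            0.05, index=cpg_ann.index,
            columns=["brain_1", "intestine_1", "limb_1", "liver_1"],
        )
        tissues = pd.Series(
            ["brain", "intestine", "limb", "liver"], index=fetal.columns
        )
        return cpg_ann, tss, hom, fetal, tissues

    def test_window_and_fetal_rules(self):
        cpg_ann, tss, hom, fetal, tissues = self._inputs()
        fetal.loc["cg2"] = [0.12, 0.05, 0.05, 0.05]  # fails one fetal tissue
        d = fs.select_mitotic_clock_cpgs(
            ["GENEA", "GENEB"], hom, tss, cpg_ann, fetal, tissues, window=200
        )
        # cg1 (|350-300|=50), cg3 (|700-300|=400 no; |700-1150| no) ...
        # within 200 of TSS 300: cg1 (50), cg2 (150) but fetal-filtered,
        # cg0 (200 exactly, inclusive); TSS 1150: cg4 (150), cg5 (50)
        assert set(d.cpg_ids) == {"cg0", "cg1", "cg4", "cg5"}

    def test_matches_brute_force_interval_scan(self):
        res = simulate_annotation_resources(
            300, seed=9, n_genes=10, n_pcgt=6, chrom_length=20_000
        )
        fetal, tissues = simulate_fetal_betas(res["cpg_annotation"].index, seed=9)
        d = fs.select_mitotic_clock_cpgs(
            res["pcgt_genes"], res["homolog_map"], res["tss_annotation"],
            res["cpg_annotation"], fetal, tissues,
        )
        mouse = set(
            res["homolog_map"].set_index("human_gene").loc[res["pcgt_genes"], "mouse_gene"]
        )
        expected = []
        for c, row in res["cpg_annotation"].iterrows():
            near = any(
                row["chrom"] == g.chrom and abs(row["pos"] - g.tss) <= 200
                for g in res["tss_annotation"].itertuples()
                if g.gene in mouse
            )
            if not near:
                continue
            means = fetal.loc[c].groupby(tissues).mean()
            if (means < 0.10).all():
                expected.append(c)
        assert list(d.cpg_ids) == expected

    def test_uncovered_pcgt_list_rejected(self):
        cpg_ann, tss, hom, fetal, tissues = self._inputs()
        with pytest.raises(ValueError, match="homolog"):
            fs.select_mitotic_clock_cpgs(["NOTAGENE"], hom, tss, cpg_ann, fetal, tissues)


class TestPrbsSelection:
    def test_boundary_conventions(self):
        cpg_ann = pd.DataFrame(
            {"chrom": ["chr1", "chr1", "chr1"], "pos": [100, 111, 91]},
            index=["in_peak", "past_end", "at_start"],
        )
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [90], "end": [110]})
        d = fs.select_prbs_cpgs(peaks, cpg_ann)
        # 1-based 91 = 0-based 90 = first base of the half-open interval
        assert set(d.cpg_ids) == {"in_peak", "at_start"}

    def test_matches_nested_loop_oracle(self):
        res = simulate_annotation_resources(200, seed=17, n_peaks=5, chrom_length=20_000)
        d = fs.select_prbs_cpgs(res["peaks"], res["cpg_annotation"])
        expected = [
            c
            for c, row in res["cpg_annotation"].iterrows()
            if any(
                p.chrom == row["chrom"] and p.start < row["pos"] <= p.end
                for p in res["peaks"].itertuples()
            )
        ]
        assert list(d.cpg_ids) == expected

    def test_malformed_bed_reports_line_numbers(self, tmp_path):
        bed = tmp_path / "bad.bed"
        bed.write_text("chr1\t10\t20\nchr1\tx\t30\nchr2\t5\n")
        with pytest.raises(ValueError, match=r"\[2, 3\]"):
            read_bed3(bed)

    def test_bed_round_trip(self, tmp_path):
        bed = tmp_path / "peaks.bed"
        bed.write_text("# comment\nchr1\t10\t20\nchr2\t5\t9\n")
        peaks = read_bed3(bed)
        assert peaks.shape == (2, 3)
        assert peaks.loc[1, "end"] == 9
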