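"""Preprocessing, imputation, per-protein linear models, FDR estimation,
candidate selection and the bait-corrected proteoform filter."""

import numpy as np
import pandas as pd
import pytest

from pfp import interactome as im
from pfp import simulate as sim
from pfp.io import QuantMatrix


def _quant(values: np.ndarray, groups: dict[str, str], flags=None) -> QuantMatrix:
    cols = list(groups)
    df = pd.DataFrame(values, columns=cols,
                      index=[f"P{i}" for i in range(values.shape[0])])
    flag_df = pd.DataFrame(False, index=df.index,
                           columns=["reverse", "contaminant", "only_identified_by_site"])
    if flags:
        for prot, col in flags:
            flag_df.loc[prot, col] = True
    genes = pd.Series({p: p for p in df.index})
    return QuantMatrix(df, genes, flag_df, pd.Series(groups))


GROUPS_2x3 = {"c1": "CTRL", "c2": "CTRL", "c3": "CTRL",
              "b1": "BAIT", "b2": "BAIT", "b3": "BAIT"}


class TestPreprocess:
    def test_three_valid_in_one_group_retained(self):
        vals = np.array([[20, 21, 22, np.nan, np.nan, np.nan]])
        out = im.preprocess(_quant(vals, GROUPS_2x3), log2_transform=False)
        assert list(out.values.index) == ["P0"]

    def test_two_valid_everywhere_removed(self):
        vals = np.array([[20, 21, np.nan, 22, 23, np.nan]])
        out = im.preprocess(_quant(vals, GROUPS_2x3), log2_transform=False)
        assert out.values.empty

    def test_flagged_rows_removed(self):
        vals = np.tile([20, 21, 22, 23, 24, 25.0], (2, 1))
        qm = _quant(vals, GROUPS_2x3, flags=[("P0", "contaminant")])
        out = im.preprocess(qm, log2_transform=False)
        assert list(out.values.index) == ["P1"]

    def test_log2_transform(self):
        vals = np.full((1, 6), 1024.0)
        out = im.preprocess(_quant(vals, GROUPS_2x3), log2_transform=True)
        assert np.allclose(out.values, 10.0)

    def test_constructed_fixture_reproduces_filter_counts(self):
        qm = sim.simulate_filter_fixture(
            n_identified=500, n_flagged=40, n_pass=210, seed=7
        )
        out = im.preprocess(qm, log2_transform=False)
        assert out.values.shape[0] == 210


class TestImpute:
    def test_complete_matrix_unchanged(self, rng):
        df = pd.DataFrame(rng.normal(25, 2, (20, 4)))
        pd.testing.assert_frame_equal(im.impute(df), df)

    def test_reproducible_per_seed(self, rng):
        df = pd.DataFrame(rng.normal(25, 2, (50, 4)))
        df.iloc[:10, 0] = np.nan
        a = im.impute(df, seed=3)
        b = im.impute(df, seed=3)
        c = im.impute(df, seed=4)
        pd.testing.assert_frame_equal(a, b)
        assert not a.equals(c)

    def test_shifted_normal_monte_carlo_oracle(self, rng):
        """Imputed mean matches (sample mean - 1.8 sd) over many draws."""
        n = 20_000
        obs = rng.normal(25.0, 2.0, n)
        col = np.concatenate([obs, np.full(n, np.nan)])
        df = pd.DataFrame({"s": col})
        out = im.impute(df, method="shifted_normal", seed=11)
        imputed = out["s"].to_numpy()[n:]
        mean, sd = obs.mean(), obs.std(ddof=1)
        se = 0.3 * sd / np.sqrt(n)
        assert abs(imputed.mean() - (mean - 1.8 * sd)) <= 4 * se
        assert imputed.std(ddof=1) == pytest.approx(0.3 * sd, rel=0.05)

    def test_qrilc_like_imputes_into_left_tail(self, rng):
        """Left-censoring property: imputed values sit below the median."""
        full = rng.normal(25.0, 2.0, 3000)
        censored = full.copy()
        limit = np.quantile(full, 0.25)
        censored[full < limit] = np.nan
        df = pd.DataFrame({"s": censored})
        out = im.impute(df, method="qrilc_like", seed=5)
        imputed = out["s"].to_numpy()[np.isnan(censored)]
        median = np.nanmedian(censored)
        assert (imputed < median).mean() >= 0.95

    def test_sparse_column_falls_back(self, rng):
        df = pd.DataFrame({"a": [20.0, np.nan, np.nan, np.nan, np.nan, np.nan],
                           "b": rng.normal(25, 1, 6)})
        out = im.impute(df, method="qrilc_like", seed=1)
        assert np.isfinite(out.to_numpy()).all()

    def test_unknown_method(self):
        with pytest.raises(ValueError):
            im.impute(pd.DataFrame({"a": [1.0]}), method="magic")


class TestFitAndContrast:
    def test_two_groups_t_squared_equals_f(self, rng):
        df = pd.DataFrame(rng.normal(25, 1, (30, 6)),
                          columns=list(GROUPS_2x3))
        anova, table = im.fit_and_contrast(df, pd.Series(GROUPS_2x3),
                                           [("BAIT", "CTRL")])
        assert np.allclose(table["t"] ** 2, anova["F"], rtol=1e-10)

    def test_balanced_3v3_matches_textbook_pooled_t(self):
        a = np.array([10.0, 11.0, 12.0])
        b = np.array([14.0, 15.0, 19.0])
        df = pd.DataFrame([np.concatenate([b, a])], columns=list(GROUPS_2x3))
        _, table = im.fit_and_contrast(df, pd.Series(GROUPS_2x3),
                                       [("CTRL", "BAIT")])
        sp2 = (a.var(ddof=1) + b.var(ddof=1)) / 2
        t_hand = (b.mean() - a.mean()) / np.sqrt(sp2 * (2 / 3))
        assert table["t"].iloc[0] == pytest.approx(t_hand, rel=1e-12)
        assert table["estimate"].iloc[0] == pytest.approx(b.mean() - a.mean())

    def test_sample_permutation_invariance(self, rng):
        df = pd.DataFrame(rng.normal(25, 1, (10, 6)), columns=list(GROUPS_2x3))
        anova1, t1 = im.fit_and_contrast(df, pd.Series(GROUPS_2x3), [("BAIT", "CTRL")])
        perm = ["b2", "c3", "b1", "c1", "b3", "c2"]
        anova2, t2 = im.fit_and_contrast(df[perm], pd.Series(GROUPS_2x3),
                                         [("BAIT", "CTRL")])
        pd.testing.assert_frame_equal(anova1, anova2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_matches_statsmodels_ols_on_random_designs(self, rng):
        """Five-group designs equal the per-protein OLS oracle."""
        import statsmodels.formula.api as smf

        groups = {}
        for g in "ABCDE":
            for r in range(3):
                groups[f"{g}{r}"] = g
        df = pd.DataFrame(rng.normal(20, 2, (5, 15)), columns=list(groups))
        anova, table = im.fit_and_contrast(df, pd.Series(groups),
                                           [("A", "B"), ("D", "E")])
        for i, prot in enumerate(df.index):
            long = pd.DataFrame({"y": df.loc[prot].to_numpy(),
                                 "g": list(groups.values())})
            fit = smf.ols("y ~ C(g)", data=long).fit()
            assert anova["F"].iloc[i] == pytest.approx(fit.fvalue, rel=1e-10)

    def test_absent_bait_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(2, 6)), columns=list(GROUPS_2x3))
        with pytest.raises(ValueError, match="absent bait"):
            im.fit_and_contrast(df, pd.Series(GROUPS_2x3), [("NOPE", "CTRL")])


class TestEstimateFdr:
    def test_all_ones(self):
        assert (im.estimate_fdr([1.0, 1.0, 1.0]) == 1.0).all()

    def test_bh_step_up_closed_form(self):
        q = im.estimate_fdr([0.01, 0.02, 0.03, 0.04], "bh")
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            im.estimate_fdr([])

    def test_mixture_recovers_pi0(self, rng):
        """90% null / 10% Beta(0.1, 1) mixture: pi0 estimated within 0.05."""
        n = 5000
        p = np.concatenate([
            rng.uniform(size=int(0.9 * n)),
            rng.beta(0.1, 1.0, size=int(0.1 * n)),
        ])
        q = im.estimate_fdr(p, "mixture")
        # implied pi0 from q at p=1 region
        top = q[np.argsort(p)][-10:]
        assert abs(top.mean() - 0.9) < 0.05

    def test_mixture_monotone_and_close_to_bh_under_null(self, rng):
        p = rng.uniform(size=2000)
        qm = im.estimate_fdr(p, "mixture")
        order = np.argsort(p)
        assert (np.diff(qm[order]) >= -1e-12).all()
        qb = im.estimate_fdr(p, "bh")
        # under a pure null both are near 1 for large p
        assert abs(qm[order][-50:].mean() - qb[order][-50:].mean()) < 0.05


class TestSelectCandidates:
    #: one control plus three FL/PR pairs per set, as in real multi-bait runs;
    #: the extra baits contribute residual degrees of freedom to the pooled fit
    SET_BAITS = ["eDHFR", "B_FL", "B_PR", "C_FL", "C_PR", "D_FL", "D_PR"]

    @classmethod
    def _pipeline(cls, seed, edges, **kwargs):
        qm, truth = sim.simulate_interactome_matrix(
            cls.SET_BAITS, truth_edges=edges, seed=seed, **kwargs
        )
        filt = im.preprocess(qm, log2_transform=False)
        imputed = im.impute(filt.values, seed=seed)
        _, table = im.fit_and_contrast(imputed, qm.groups, [("B_FL", "eDHFR")])
        return im.select_candidates("B_FL", "eDHFR", table,
                                    bait_protein="BAIT_B_FL")

    def test_spiked_preys_recovered(self):
        edges = [("B_FL", f"PREY{i}", 3.0) for i in range(10)]
        cand = self._pipeline(1, edges)
        hits = set(cand.loc[cand["candidate"], "protein"])
        assert len(hits & {f"PREY{i}" for i in range(10)}) >= 9
        false = hits - {f"PREY{i}" for i in range(10)}
        assert len(false) <= 3

    def test_control_enriched_protein_not_candidate(self, rng):
        table = pd.DataFrame([{
            "protein": "P1", "contrast": "B vs C", "group_a": "B", "group_b": "C",
            "estimate": -3.0, "t": -30.0, "p_value": 1e-9,
        }])
        out = im.select_candidates("B", "C", table)
        assert not out["candidate"].any()
        assert out["direction"].iloc[0] == "C"

    def test_bait_row_excluded_but_reported(self):
        edges = [("B_FL", "PREY0", 4.0)]
        cand = self._pipeline(2, edges)
        bait_rows = cand[cand["is_bait_row"]]
        assert len(bait_rows) == 1
        assert not bait_rows["candidate"].iloc[0]

    def test_null_matrix_false_candidate_rate(self):
        rates, totals = [], 0
        for seed in range(5):
            cand = self._pipeline(seed, edges=[])
            rates.append(cand["candidate"].sum())
            totals += len(cand)
        rate = np.sum(rates) / totals
        assert rate <= 0.01 + 3 * np.sqrt(0.01 * 0.99 / totals)


class TestProteoformDifferential:
    @staticmethod
    def _table(est, p=1e-6):
        return pd.DataFrame([{
            "protein": "PREY", "contrast": "FL vs PR", "group_a": "FL",
            "group_b": "PR", "estimate": est, "t": 10.0, "p_value": p,
        }])

    def test_rejected_by_bait_level_correction(self):
        """Prey at +1.5 toward FL with bait delta +2.0 toward FL fails."""
        out = im.proteoform_differential(
            "FL", "PR", self._table(1.5), {"PREY"}, set(), set(),
            bait_level_fl=30.0, bait_level_pr=28.0,
        )
        assert not out["retained"].iloc[0]
        assert not out["pass_bait_correction"].iloc[0]

    def test_weak_side_enrichment_exempt_from_correction(self):
        """Prey toward PR while the FL bait is stronger is retained."""
        out = im.proteoform_differential(
            "FL", "PR", self._table(-1.5), set(), {"PREY"}, set(),
            bait_level_fl=30.0, bait_level_pr=28.0,
        )
        assert out["retained"].iloc[0]
        assert out["direction"].iloc[0] == "PR-specific"

    def test_fold_change_filter_removes_small_estimates(self):
        """Significant but |log2| <= 1 (GAG-like artifact) is excluded."""
        out = im.proteoform_differential(
            "FL", "PR", self._table(0.8), {"PREY"}, set(), set(),
            bait_level_fl=30.0, bait_level_pr=30.0,
        )
        assert not out["retained"].iloc[0]
        assert not out["pass_fold_change"].iloc[0]

    def test_known_interactor_rescue(self):
        out = im.proteoform_differential(
            "FL", "PR", self._table(2.5), set(), set(), {"PREY"},
            bait_level_fl=30.0, bait_level_pr=30.0,
        )
        assert out["retained"].iloc[0]

    def test_not_candidate_not_known_rejected(self):
        out = im.proteoform_differential(
            "FL", "PR", self._table(2.5), set(), set(), set(),
            bait_level_fl=30.0, bait_level_pr=30.0,
        )
        assert not out["retained"].iloc[0]

    def test_bait_correction_shrinks_with_growing_offset(self):
        """Increasing the FL bait offset can only shrink the FL-side list."""
        retained_counts = []
        for offset in (0.0, 1.0, 2.0, 4.0):
            table = pd.concat([
                self._table(e).assign(protein=f"PREY{j}")
                for j, e in enumerate([1.2, 1.8, 2.5, 3.5])
            ], ignore_index=True)
            out = im.proteoform_differential(
                "FL", "PR", table, {f"PREY{j}" for j in range(4)}, set(), set(),
                bait_level_fl=30.0 + offset, bait_level_pr=30.0,
            )
            retained_counts.append(int(out["retained"].sum()))
        assert retained_counts == sorted(retained_counts, reverse=True)


def test_frequency_table_counting_oracle(rng):
    candidate_lists = {
        f"bait{i}": {f"PREY{j}" for j in rng.choice(30, 10, replace=False)}
        for i in range(17)
    }
    diff_tables = {
        f"cmp{i}": {f"PREY{j}" for j in rng.choice(30, 5, replace=False)}
        for i in range(6)
    }
    table = im.frequency_table(candidate_lists, diff_tables)
    for _, row in table.iterrows():
        assert row["n_baits_candidate"] == sum(
            row["prey"] in s for s in candidate_lists.values()
        )
        assert row["n_comparisons_differential"] == sum(
            row["prey"] in s for s in diff_tables.values()
        )
    counts = table["n_baits_candidate"].to_numpy()
    assert (counts[:-1] >= counts[1:] - 1e-9).any() or len(counts) < 2
    # prey in every list has frequency 17
    everywhere = {"EVERY"}
    table2 = im.frequency_table({f"b{i}": everywhere for i in range(17)}, {})
    assert table2.iloc[0]["n_baits_candidate"] == 17


def test_overlap_stats_identity_and_random_oracle(rng):
    s = {"A", "B", "C"}
    ov = im.overlap_stats(s, s)
    assert ov.pct_shared_of_a == 100.0 and ov.unique_a == set()
    for _ in range(20):
        a = {f"G{int(x)}" for x in rng.choice(50, 20, replace=False)}
        b = {f"G{int(x)}" for x in rng.choice(50, 20, replace=False)}
        ov = im.overlap_stats(a, b)
        assert ov.n_shared == len(a & b)
        assert ov.unique_a == a - b and ov.unique_b == b - a
        assert ov.pct_shared_of_a == round(100 * len(a & b) / len(a), 1)
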