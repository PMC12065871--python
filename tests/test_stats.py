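"""Statistical engine: normalization, moderated t, BH, scoring, enrichment,
covalent-candidate flagging and ThT kinetics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

import lipmap as lm
from lipmap.io import ExperimentDesign
from lipmap.stats import NO_MODERATION, ModerationParams


# ---------------------------------------------------------------------------
# oracles (kept independent of the implementations they check)


def bh_bruteforce(p):
    """Step-up BH straight from the definition: q_(i) = min_{j>=i} p_(j)*n/j."""
    p = np.asarray(p, float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    for rank_pos, idx in enumerate(order):
        candidates = [
            p[order[j]] * n / (j + 1) for j in range(rank_pos, n)
        ]
        q[idx] = min(1.0, min(candidates))
    return q


def residue_mean_bruteforce(placed_scores, length):
    """placed_scores: list of (start, end, score); per-residue plain mean."""
    out = np.full(length, np.nan)
    for i in range(1, length + 1):
        covering = [s for (a, b, s) in placed_scores if a <= i <= b]
        if covering:
            out[i - 1] = sum(covering) / len(covering)
    return out


# ---------------------------------------------------------------------------
# normalization


class TestMedianNormalize:
    def test_single_sample_unchanged(self, small_quant_table):
        one = small_quant_table[small_quant_table.sample_id == "treated_1"]
        out = lm.log2_and_median_normalize(one)
        np.testing.assert_allclose(
            out["intensity"], np.log2(one["intensity"]), atol=1e-12
        )

    def test_two_samples_meet_at_common_median(self):
        rows = []
        for s, scale in (("a", 2.0**20), ("b", 2.0**22)):
            for i, pep in enumerate(["MDVFMK", "GLSKAK", "EGVVHG"]):
                rows.append(
                    dict(sample_id=s, condition=s, replicate=1, protein_id="P",
                         peptide_sequence=pep, assay_type="LIP",
                         intensity=scale * (1 + i))
                )
        out = lm.log2_and_median_normalize(pd.DataFrame(rows))
        med = out.groupby("sample_id")["intensity"].median()
        assert med["a"] == pytest.approx(21.0 + math.log2(2), abs=1e-9)
        assert med["a"] == pytest.approx(med["b"], abs=1e-9)

    def test_random_table_all_medians_equal(self):
        rng = np.random.default_rng(42)
        rows = []
        for s in range(6):
            for p in range(50):
                rows.append(
                    dict(sample_id=f"s{s}", condition=f"c{s % 2}",
                         replicate=s // 2 + 1, protein_id="P",
                         peptide_sequence="PEPTIDE"[: 6] + "AK",
                         assay_type="LIP", intensity=0.0)
                )
                rows[-1]["peptide_sequence"] = f"AA{p:03d}".replace(
                    "0", "G").replace("1", "A").replace("2", "L").replace(
                    "3", "S").replace("4", "V").replace("5", "T").replace(
                    "6", "N").replace("7", "Q").replace("8", "D").replace(
                    "9", "E")
                rows[-1]["intensity"] = float(rng.lognormal(14, 2))
        out = lm.log2_and_median_normalize(pd.DataFrame(rows))
        med = out.groupby("sample_id")["intensity"].median()
        assert med.max() - med.min() < 1e-9

    def test_empty_sample_rejected(self, small_quant_table):
        t = small_quant_table.copy()
        t.loc[t.sample_id == "treated_1", "intensity"] = np.nan
        t["intensity"] = t["intensity"].astype(float)
        # NaN intensities are "missing": sample has zero quantified peptides
        t2 = t.dropna().copy()
        extra = small_quant_table.iloc[[0]].copy()
        extra["intensity"] = np.nan
        with pytest.raises(ValueError, match="treated_1"):
            lm.log2_and_median_normalize(pd.concat([t2, extra]))


def _log2_table(rows):
    return pd.DataFrame(
        rows,
        columns=["sample_id", "condition", "replicate", "protein_id",
                 "peptide_sequence", "assay_type", "intensity"],
    )


class TestTrypticControlNormalize:
    samples = [("t_1", "treated"), ("t_2", "treated"), ("c_1", "control")]

    def _channel(self, assay, values):
        return _log2_table(
            [
                (sid, cond, int(sid[-1]), "P", "MDVFMK", assay, v)
                for (sid, cond), v in zip(self.samples, values)
            ]
        )

    def test_constant_tc_cancels(self):
        lip = self._channel("LIP", [10.0, 11.0, 12.0])
        tc = self._channel("TC", [20.0, 20.0, 20.0])
        out = lm.tryptic_control_normalize(lip, tc)
        np.testing.assert_allclose(out["intensity"], [10.0, 11.0, 12.0])

    def test_lip_equal_tc_gives_flat_median(self):
        vals = [10.0, 12.0, 13.0]
        out = lm.tryptic_control_normalize(
            self._channel("LIP", vals), self._channel("TC", vals)
        )
        assert set(out["intensity"]) == {12.0}  # per-peptide TC median

    def test_signal_class_separation(self):
        """Covalent (both channels) cancels; conformational (LiP only) stays."""
        base = 15.0
        # covalent: both channels down 2 in treated
        lip_cov = self._channel("LIP", [base - 2, base - 2, base])
        tc_cov = self._channel("TC", [base - 2, base - 2, base])
        out = lm.tryptic_control_normalize(lip_cov, tc_cov)
        treated = out[out.condition == "treated"]["intensity"]
        control = out[out.condition == "control"]["intensity"]
        assert treated.mean() - control.mean() == pytest.approx(0.0, abs=1e-12)

        # conformational: LiP only down 2
        lip_conf = self._channel("LIP", [base - 2, base - 2, base])
        tc_flat = self._channel("TC", [base, base, base])
        out = lm.tryptic_control_normalize(lip_conf, tc_flat)
        treated = out[out.condition == "treated"]["intensity"]
        control = out[out.condition == "control"]["intensity"]
        assert treated.mean() - control.mean() == pytest.approx(-2.0, abs=1e-12)

    def test_unpartnered_rows_dropped_with_count(self, caplog):
        lip = self._channel("LIP", [10.0, 11.0, 12.0])
        tc = self._channel("TC", [20.0, 20.0, 20.0]).iloc[:2]
        with caplog.at_level("INFO"):
            out = lm.tryptic_control_normalize(lip, tc)
        assert len(out) == 2
        assert "dropped 1" in caplog.text


# ---------------------------------------------------------------------------
# moderated t-test


class TestModeratedTTest:
    def test_identical_groups_null(self):
        fc, t, df, p = lm.moderated_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert fc == 0.0 and t == 0.0 and p == 1.0

    def test_d0_zero_equals_pooled_ttest_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            nt, nr = rng.integers(2, 6, 2)
            x = rng.normal(0, 1, nt)
            y = rng.normal(0.5, 1, nr)
            fc, t, df, p = lm.moderated_ttest(x, y, NO_MODERATION)
            t_ref, p_ref = sps.ttest_ind(x, y, equal_var=True)
            assert t == pytest.approx(t_ref, abs=1e-10)
            assert p == pytest.approx(p_ref, abs=1e-10)
            assert df == nt + nr - 2

    def test_large_d0_approaches_z_on_prior_variance(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([4.0, 5.0, 6.0])
        s0 = 0.5
        _, t_large, _, _ = lm.moderated_ttest(
            x, y, ModerationParams(prior_df=1e9, prior_var=s0**2)
        )
        expected = (x.mean() - y.mean()) / (s0 * math.sqrt(2 / 3))
        assert t_large == pytest.approx(expected, rel=1e-4)
        _, t_inf, df_inf, p_inf = lm.moderated_ttest(
            x, y, ModerationParams(prior_df=math.inf, prior_var=s0**2)
        )
        assert t_inf == pytest.approx(expected, rel=1e-12)
        assert math.isinf(df_inf)
        assert p_inf == pytest.approx(2 * sps.norm.sf(abs(expected)), rel=1e-12)

    def test_insufficient_replicates_rejected(self):
        with pytest.raises(ValueError, match="insufficient"):
            lm.moderated_ttest([1.0], [1.0, 2.0])

    def test_t_monotone_in_effect_size(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 4)
        y = rng.normal(0, 1, 4)
        mod = ModerationParams(prior_df=4.0, prior_var=1.0)
        shifts = np.linspace(0, 5, 11)
        tvals = []
        for delta in shifts:
            # same spread, growing mean difference
            _, t, _, _ = lm.moderated_ttest(x + delta, y, mod)
            tvals.append(t)
        base_fc = x.mean() - y.mean()
        order = np.argsort(np.abs(base_fc + shifts))
        assert np.all(np.diff(np.abs(np.array(tvals)[order])) > 0)


class TestEstimateModeration:
    def test_recovers_prior_df_within_25pct(self):
        rng = np.random.default_rng(3)
        d0_true, s0sq, d = 8.0, 0.02, 6
        sigma2 = s0sq * d0_true / rng.chisquare(d0_true, 5000)
        s2 = sigma2 * rng.chisquare(d, 5000) / d
        mod = lm.estimate_moderation(s2, d)
        assert mod.prior_df == pytest.approx(d0_true, rel=0.25)
        assert mod.prior_var == pytest.approx(s0sq, rel=0.25)

    def test_constant_variances_give_infinite_prior(self):
        mod = lm.estimate_moderation(np.full(50, 0.04), 6)
        assert math.isinf(mod.prior_df)
        assert mod.prior_var == pytest.approx(0.04, rel=0.3)

    def test_wildly_spread_variances_give_small_prior_df(self):
        s2 = np.logspace(-2, 2, 10)
        mod = lm.estimate_moderation(s2, 6)
        assert math.isfinite(mod.prior_df)
        assert mod.prior_df < 5

    def test_degenerate_zero_variances_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            lm.estimate_moderation(np.zeros(20), 6)


# ---------------------------------------------------------------------------
# BH and scoring


class TestAdjustBH:
    def test_worked_example(self):
        q = lm.adjust_bh(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04], atol=1e-12)

    def test_single_p_is_its_own_q(self):
        assert lm.adjust_bh(np.array([0.37]))[0] == pytest.approx(0.37)

    def test_oracle_equivalence_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(1000):
            n = int(rng.integers(1, 201))
            p = rng.uniform(1e-12, 1.0, n)
            if rng.random() < 0.3:  # inject ties
                p[: n // 2] = p[0]
            np.testing.assert_array_equal(lm.adjust_bh(p), bh_bruteforce(p))

    def test_matches_statsmodels(self):
        statsmodels = pytest.importorskip("statsmodels.stats.multitest")
        rng = np.random.default_rng(5)
        p = rng.uniform(0.0001, 1, 300)
        np.testing.assert_allclose(
            lm.adjust_bh(p),
            statsmodels.multipletests(p, method="fdr_bh")[1],
            atol=1e-12,
        )

    def test_permutation_invariance(self):
        rng = np.random.default_rng(13)
        p = rng.uniform(0.001, 1, 50)
        q = lm.adjust_bh(p)
        perm = rng.permutation(50)
        np.testing.assert_allclose(lm.adjust_bh(p[perm]), q[perm], atol=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lm.adjust_bh(np.array([0.5, 0.0]))
        with pytest.raises(ValueError):
            lm.adjust_bh(np.array([0.5, 1.2]))


class TestPeptideScore:
    @pytest.mark.parametrize(
        "q,log2fc,expected",
        [
            (0.05, 1.0, 1.3010299956639813),
            (1.0, 7.3, 0.0),
            (0.01, -2.0, 4.0),
        ],
    )
    def test_worked_examples(self, q, log2fc, expected):
        assert lm.peptide_score(log2fc, q) == pytest.approx(expected, abs=1e-10)

    def test_default_threshold_value(self):
        assert lm.DEFAULT_TAU == pytest.approx(1.30103, abs=5e-6)

    @given(
        q1=st.floats(1e-10, 1.0, exclude_max=True),
        q2=st.floats(1e-10, 1.0, exclude_max=True),
        fc=st.floats(0.01, 10),
    )
    @settings(max_examples=200, deadline=None)
    def test_score_increases_as_q_decreases(self, q1, q2, fc):
        lo, hi = sorted((q1, q2))
        if lo < hi:
            assert lm.peptide_score(fc, lo) > lm.peptide_score(fc, hi)


# ---------------------------------------------------------------------------
# differential analysis


def _make_table(rng, n_pep, n_rep, effect_idx=(), effect=0.0, cv=0.10):
    sd = math.log2(1 + cv)
    alphabet = "ACDEFGHILMNQSTVWY"
    rows = []
    for k in range(n_pep):
        pep = "".join(
            alphabet[int(c, 17)] for c in np.base_repr(k + 17**3, 17).zfill(7)
        )
        base = rng.normal(18, 1.5)
        for cond in ("treated", "control"):
            for r in range(1, n_rep + 1):
                x = base + rng.normal(0, sd)
                if cond == "treated" and k in effect_idx:
                    x += effect
                rows.append(
                    dict(sample_id=f"{cond}_{r}", condition=cond, replicate=r,
                         protein_id="P", peptide_sequence=pep,
                         assay_type="LIP", intensity=x)
                )
    return pd.DataFrame(rows)


class TestDifferentialAnalysis:
    def test_null_table_controls_fdr(self):
        fracs = []
        for seed in range(20):
            rng = np.random.default_rng(200 + seed)
            table = _make_table(rng, n_pep=1000, n_rep=4)
            design = ExperimentDesign.from_table(table, ("treated", "control"))
            rec = lm.differential_analysis(table, design)
            fracs.append((rec["q_value"] < 0.05).mean())
        assert np.mean(fracs) <= 0.01

    def test_power_on_planted_fourfold_effect(self):
        rng = np.random.default_rng(77)
        planted = set(range(50))
        table = _make_table(rng, 1000, 4, effect_idx=planted, effect=2.0)
        design = ExperimentDesign.from_table(table, ("treated", "control"))
        rec = lm.differential_analysis(table, design)
        peps = sorted(rec["peptide_sequence"].unique())
        # recover planted identity through deterministic peptide naming
        planted_peps = set(
            _make_table(np.random.default_rng(77), 50, 2)["peptide_sequence"]
        )
        hit = rec[(rec["q_value"] < 0.05) & (rec["log2FC"].abs() > 1)]
        found = planted_peps & set(hit["peptide_sequence"])
        assert len(found) >= 0.9 * len(planted_peps)

    def test_one_sided_peptide_skipped(self, caplog):
        rng = np.random.default_rng(1)
        table = _make_table(rng, 5, 3)
        lonely = table["peptide_sequence"].unique()[0]
        table = table[
            ~((table.peptide_sequence == lonely) & (table.condition == "control"))
        ]
        design = ExperimentDesign.from_table(table, ("treated", "control"))
        with caplog.at_level("INFO"):
            rec = lm.differential_analysis(table, design)
        assert lonely not in set(rec["peptide_sequence"])
        assert "skipped 1" in caplog.text

    def test_absent_contrast_condition_rejected(self, small_quant_table):
        design = ExperimentDesign(
            conditions=("treated", "dmso"), contrast=("treated", "dmso")
        )
        table = small_quant_table.copy()
        table["intensity"] = np.log2(table["intensity"])
        with pytest.raises(ValueError, match="dmso"):
            lm.differential_analysis(table, design)


class TestCovalentCandidates:
    def _records(self, rows):
        return pd.DataFrame(
            rows, columns=["protein_id", "peptide_sequence", "log2FC", "q_value"]
        )

    def test_decrease_flagged_increase_not(self):
        rec = lm.detect_covalent_candidates(
            self._records(
                [("P", "AAAK", -2.0, 0.01), ("P", "CCCK", 2.0, 0.01)]
            )
        )
        flagged = dict(zip(rec["peptide_sequence"], rec["covalent_candidate"]))
        assert flagged == {"AAAK": True, "CCCK": False}

    def test_summary_report_counts(self, default_experiment):
        """Planted TC decreases on 3 of 6 tryptic peptides read '3 of 6'."""
        truth0, _, _, _ = default_experiment
        # plant covalent sites hitting exactly 3 of the 6 shortest tryptic
        # peptides of a toy protein
        seq = "AAADDFK" + "CCEEGGR" + "HHIILLK" + "MMNNQQR" + "SSTTVVK" + "WWYYAAR"
        truth = lm.default_truth(
            seed=5,
            sequence=seq,
            protein_id="TOY6",
            accessibility_regions=(),
            covalent_sites=((3, -2.0), (10, -2.0), (17, -2.0)),
            background_proteins=truth0.background_proteins[:2],
        )
        rules = lm.DigestionRules(max_missed_cleavages=0, background_rate=0.0,
                                  half_tryptic_fraction=0.0)
        lip, tc, record = lm.simulate_lip_experiment(truth, rules)
        tc_log = lm.log2_and_median_normalize(tc)
        design = ExperimentDesign.from_table(tc_log, ("treated", "control"))
        rec = lm.differential_analysis(tc_log, design, assay="TC")
        flagged = lm.detect_covalent_candidates(rec)
        summary = flagged.attrs["summary"]
        row = summary[summary.protein_id == "TOY6"].iloc[0]
        assert row["report"] == "3 of 6 flagged"


# ---------------------------------------------------------------------------
# Fisher enrichment


class TestFisherEnrichment:
    def test_hits_equal_background_p_one(self):
        bg = {f"g{i}" for i in range(20)}
        res = lm.fisher_enrichment(bg, bg, {"T": {f"g{i}" for i in range(5)}})
        assert res["p_value"].iloc[0] == pytest.approx(1.0)

    def test_worked_contingency_example(self):
        hits = {f"h{i}" for i in range(20)}
        bg = hits | {f"b{i}" for i in range(980)}
        term = {f"h{i}" for i in range(10)} | {f"b{i}" for i in range(90)}
        res = lm.fisher_enrichment(hits, bg, {"T": term})
        row = res.iloc[0]
        assert (row["a"], row["b"], row["c"], row["d"]) == (10, 10, 90, 890)
        assert row["odds_ratio"] == pytest.approx(9.888888888, rel=1e-9)
        # brute-force two-sided hypergeometric summation
        rv = sps.hypergeom(1000, 100, 20)
        probs = rv.pmf(np.arange(0, 21))
        p_expected = probs[probs <= rv.pmf(10) * (1 + 1e-12)].sum()
        assert row["p_value"] == pytest.approx(p_expected, abs=1e-10)

    def test_term_disjoint_from_hits(self):
        hits = {"h1", "h2", "h3"}
        bg = hits | {f"b{i}" for i in range(97)}
        res = lm.fisher_enrichment(hits, bg, {"T": {"b1", "b2"}})
        row = res.iloc[0]
        assert row["odds_ratio"] == 0.0
        assert row["p_value"] >= 0.05

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            lm.fisher_enrichment(set(), {"a"}, {})
        with pytest.raises(ValueError):
            lm.fisher_enrichment({"x"}, {"a"}, {})  # not a subset


# ---------------------------------------------------------------------------
# ThT kinetics


def _logistic(t, f0, fmax, k, th):
    return f0 + (fmax - f0) / (1 + np.exp(-k * (t - th)))


class TestThTFit:
    times = np.arange(0.0, 18.0)

    def test_noiseless_recovery(self):
        f = _logistic(self.times, 0.0, 100.0, 1.0, 8.0)
        fit = lm.fit_tht_curve(self.times, f)
        assert fit.t_half == pytest.approx(8.0, abs=1e-6)
        assert fit.fmax == pytest.approx(100.0, abs=1e-4)
        assert not fit.flat

    def test_noisy_recovery_median_error(self):
        errors = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            f = _logistic(self.times, 5.0, 100.0, 1.0, 8.0)
            f = f * (1 + rng.normal(0, 0.05, f.size))
            fit = lm.fit_tht_curve(self.times, f)
            errors.append(abs(fit.t_half - 8.0))
        assert np.median(errors) < 0.4

    def test_flat_curve_reports_infinite_half_time(self):
        rng = np.random.default_rng(2)
        f = 50.0 + rng.normal(0, 0.5, self.times.size)
        fit = lm.fit_tht_curve(self.times, f)
        assert fit.flat
        assert math.isinf(fit.t_half)

    def test_t_end_is_mean_of_last_three(self):
        f = _logistic(self.times, 0.0, 100.0, 1.0, 8.0)
        fit = lm.fit_tht_curve(self.times, f)
        assert fit.t_end == pytest.approx(np.mean(f[-3:]))

    def test_non_monotone_times_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            lm.fit_tht_curve([0, 1, 1, 2, 3, 4], np.zeros(6))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 6"):
            lm.fit_tht_curve([0, 1, 2, 3, 4], np.zeros(5))
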