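import numpy as np
import pandas as pd
import pytest
from scipy import stats
from statsmodels.stats.multitest import multipletests

from metadrug import nomination, scoring, synth
from metadrug.scoring import GeneSetCollection, ScoreTable


def _score_table(values, signature="glycolysis"):
    idx = [f"s{i}" for i in range(len(values))]
    return ScoreTable(pd.DataFrame({signature: values}, index=idx))


def _imputed(columns, n):
    idx = [f"s{i}" for i in range(n)]
    return pd.DataFrame(columns, index=idx)


class TestAssociation:
    def test_exact_linear_relation(self):
        rng = np.random.default_rng(0)
        response = rng.normal(size=30)
        scores = _score_table(10.0 - 2.0 * response)
        imputed = _imputed({"d1": response}, 30)
        out = nomination.score_response_association(
            scores, imputed, None, "glycolysis"
        )
        row = out.iloc[0]
        assert row["beta1"] == pytest.approx(-2.0, abs=1e-10)
        assert row["beta0"] == pytest.approx(10.0, abs=1e-10)
        assert row["p_value"] < 1e-20

    def test_null_pvalues_uniform(self):
        rng = np.random.default_rng(1)
        n, n_drugs = 150, 200
        scores = _score_table(rng.normal(size=n))
        imputed = _imputed({f"d{k}": rng.normal(size=n) for k in range(n_drugs)}, n)
        out = nomination.score_response_association(scores, imputed, None, "glycolysis")
        ks = stats.kstest(out["p_value"], "uniform").statistic
        assert ks < 0.1

    def test_age_covariate_when_irrelevant(self):
        rng = np.random.default_rng(2)
        n = 120
        response = rng.normal(size=n)
        noise = rng.normal(0, 0.5, size=n)
        scores = _score_table(5.0 - 1.5 * response + noise, "oxphos")
        age = rng.uniform(45, 85, size=n)
        clinical = pd.DataFrame(
            {"sample_id": [f"s{i}" for i in range(n)], "age_at_procurement": age}
        )
        imputed = _imputed({"d": response}, n)
        with_age = nomination.score_response_association(
            scores, imputed, clinical, "oxphos"
        ).iloc[0]
        without = nomination.score_response_association(
            scores, imputed, None, "oxphos"
        ).iloc[0]
        assert not np.isnan(with_age["beta2"])
        se = 0.5 / np.sqrt(n)  # rough slope SE scale
        assert abs(with_age["beta1"] - without["beta1"]) < 3 * se

    def test_constant_response_p_one(self):
        scores = _score_table(np.arange(10.0))
        imputed = _imputed({"d": np.ones(10)}, 10)
        with pytest.warns(UserWarning, match="constant"):
            out = nomination.score_response_association(scores, imputed, None, "glycolysis")
        assert out.iloc[0]["p_value"] == 1.0

    def test_too_few_samples(self):
        scores = _score_table([1.0, 2.0])
        imputed = _imputed({"d": [0.1, 0.2]}, 2)
        with pytest.raises(ValueError, match="3 shared"):
            nomination.score_response_association(scores, imputed, None, "glycolysis")


class TestBhAdjust:
    def test_hand_computed_step_up(self):
        # p*m/rank = [.04, .04, .04, .04]; cummin from the top keeps .04
        out = nomination.bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_second_hand_example(self):
        # [.01,.04,.03]: sorted [.01,.03,.04] -> [.03,.045,.04] -> cummin [.03,.04,.04]
        out = nomination.bh_adjust([0.01, 0.04, 0.03])
        assert np.allclose(out, [0.03, 0.04, 0.04])

    def test_single_p_unchanged(self):
        assert nomination.bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert np.allclose(nomination.bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_error(self):
        with pytest.raises(ValueError):
            nomination.bh_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            nomination.bh_adjust([-0.1])

    def test_matches_statsmodels(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=50)
        ours = nomination.bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref)

    def test_monotone_in_raw_order(self):
        rng = np.random.default_rng(4)
        p = np.sort(rng.uniform(size=30))
        adj = nomination.bh_adjust(p)
        assert (np.diff(adj) >= -1e-12).all()


def _assoc_frame(rows):
    return pd.DataFrame(rows, columns=nomination.ASSOC_COLUMNS)


def _row(drug, score_type, cohort, beta1, p, source="src"):
    return (drug, score_type, cohort, source, 0.0, beta1, np.nan, p, np.nan, 50)


class TestNominateSets:
    def test_cross_cohort_intersection_rule(self):
        assoc = _assoc_frame([
            _row("dA", "glycolysis", "EC", -1.0, 0.001),
            _row("dA", "glycolysis", "WC", -1.0, 0.9),
            _row("dB", "glycolysis", "EC", -1.0, 0.001),
            _row("dB", "glycolysis", "WC", -1.0, 0.001),
            _row("dA", "oxphos", "EC", -1.0, 0.5),
            _row("dA", "oxphos", "WC", -1.0, 0.5),
            _row("dB", "oxphos", "EC", -1.0, 0.5),
            _row("dB", "oxphos", "WC", -1.0, 0.5),
        ])
        sets, adjusted = nomination.nominate_drug_sets(assoc, alpha=0.05)
        assert sets.cross_cohort_hg["src"] == {"dB"}
        assert "dA" in sets.drug_hg[("EC", "src")]

    def test_positive_slope_excluded(self):
        assoc = _assoc_frame([
            _row("dA", "glycolysis", "EC", +1.0, 0.0001),
            _row("dA", "oxphos", "EC", -1.0, 0.5),
        ])
        sets, _ = nomination.nominate_drug_sets(assoc)
        assert sets.drug_hg[("EC", "src")] == set()

    def test_de_is_intersection_of_hg_and_ox(self):
        assoc = _assoc_frame([
            _row("dA", "glycolysis", "EC", -1.0, 0.001),
            _row("dA", "oxphos", "EC", -1.0, 0.001),
            _row("dB", "glycolysis", "EC", -1.0, 0.001),
            _row("dB", "oxphos", "EC", -1.0, 0.9),
        ])
        sets, _ = nomination.nominate_drug_sets(assoc)
        assert sets.drug_de[("EC", "src")] == {"dA"}
        assert sets.drug_de[("EC", "src")] == (
            sets.drug_hg[("EC", "src")] & sets.drug_ox[("EC", "src")]
        )

    def test_alpha_extremes(self):
        rng = np.random.default_rng(5)
        assoc = _assoc_frame([
            _row(f"d{k}", "glycolysis", "EC", -1.0, rng.uniform())
            for k in range(20)
        ])
        all_neg, _ = nomination.nominate_drug_sets(assoc, alpha=1.0)
        assert all_neg.drug_hg[("EC", "src")] == {f"d{k}" for k in range(20)}
        none, _ = nomination.nominate_drug_sets(assoc, alpha=1e-300)
        assert none.drug_hg[("EC", "src")] == set()

    def test_null_calibration_cross_cohort(self):
        # under a global null the cross-cohort set should almost always be empty
        rng = np.random.default_rng(6)
        n_drugs, n = 200, 60
        empties = 0
        reps = 10
        for _ in range(reps):
            rows = []
            for cohort in ("EC", "WC"):
                score = rng.normal(size=n)
                for k in range(n_drugs):
                    x = rng.normal(size=n)
                    slope, _, _, p, _ = stats.linregress(x, score)
                    rows.append(_row(f"d{k}", "glycolysis", cohort, slope, p))
            sets, _ = nomination.nominate_drug_sets(_assoc_frame(rows))
            if not sets.cross_cohort_hg["src"]:
                empties += 1
        assert empties >= reps - 1


class TestPrimaryMoa:
    def _assoc(self):
        return _assoc_frame([
            _row("d1", "glycolysis", "EC", -1, 0.001),
            _row("d2", "glycolysis", "EC", -1, 0.002),
            _row("d3", "glycolysis", "EC", -1, 0.003),
            _row("d4", "glycolysis", "EC", -1, 0.004),
            _row("d1", "glycolysis", "WC", -1, 0.001),
            _row("d2", "glycolysis", "WC", -1, 0.002),
            _row("d3", "glycolysis", "WC", -1, 0.003),
            _row("d4", "glycolysis", "WC", -1, 0.004),
        ])

    def test_shared_moa_flagged_primary(self):
        meta = pd.DataFrame({
            "drug_id": ["d1", "d2", "d3", "d4"],
            "moa": ["CDK inhibitor", "CDK inhibitor", "x", "y"],
            "status": ["approved"] * 4,
        })
        out = nomination.primary_moa_summary({"d1", "d2", "d3", "d4"}, meta, self._assoc())
        cdk = out[out["moa"] == "CDK inhibitor"].iloc[0]
        assert cdk["count"] == 2 and bool(cdk["primary"])

    def test_unique_moas_not_primary(self):
        meta = pd.DataFrame({
            "drug_id": ["d1", "d2", "d3", "d4"],
            "moa": ["a", "b", "c", "d"],
            "status": ["approved"] * 4,
        })
        out = nomination.primary_moa_summary({"d1", "d2", "d3", "d4"}, meta, self._assoc())
        assert not out["primary"].any()

    def test_top_half_overlap_rule(self):
        # d2 is top-half in EC only -> excluded from the overlap
        assoc = _assoc_frame([
            _row("d1", "glycolysis", "EC", -1, 0.001),
            _row("d2", "glycolysis", "EC", -1, 0.002),
            _row("d3", "glycolysis", "EC", -1, 0.003),
            _row("d4", "glycolysis", "EC", -1, 0.004),
            _row("d1", "glycolysis", "WC", -1, 0.001),
            _row("d2", "glycolysis", "WC", -1, 0.04),
            _row("d3", "glycolysis", "WC", -1, 0.002),
            _row("d4", "glycolysis", "WC", -1, 0.03),
        ])
        meta = pd.DataFrame({
            "drug_id": ["d1", "d2", "d3", "d4"],
            "moa": ["m1", "m1", "m2", "m2"],
            "status": ["approved"] * 4,
        })
        out = nomination.primary_moa_summary({"d1", "d2", "d3", "d4"}, meta, assoc)
        m1 = out[out["moa"] == "m1"].iloc[0]
        assert m1["count"] == 1  # only d1 overlaps both halves

    def test_missing_moa_counts_unknown(self):
        meta = pd.DataFrame({
            "drug_id": ["d1", "d2"],
            "moa": [np.nan, np.nan],
            "status": ["approved"] * 2,
        })
        out = nomination.primary_moa_summary({"d1", "d2"}, meta, self._assoc())
        assert set(out["moa"]) == {"unknown"}


class TestFilterCascade:
    @pytest.fixture()
    def universe(self, small_config, small_panel):
        expr, measured, metadata, truth = small_panel
        sets = synth.generate_gene_sets(small_config)
        drugs = sorted(truth.planted_hg_drugs | truth.planted_de_drugs)
        rows = []
        for drug in drugs:
            for cohort in ("EC", "WC"):
                for st in ("glycolysis", "oxphos"):
                    rows.append(_row(drug, st, cohort, -1.0, 0.001))
        assoc = _assoc_frame(rows)
        assoc["fdr"] = assoc["p_value"]
        return expr, measured, metadata, truth, sets, assoc, set(drugs)

    def test_status_filter(self, universe):
        expr, measured, metadata, truth, sets, assoc, drugs = universe
        metadata = metadata.copy()
        victim = sorted(drugs)[0]
        metadata.loc[metadata["drug_id"] == victim, "status"] = "preclinical"
        trail = nomination.run_filter_cascade(
            drugs, metadata, assoc, expr, measured, None, sets,
            enabled=(True, False, False, False),
        )
        assert victim not in trail.final
        rec = [r for r in trail.records if r["drug_id"] == victim][0]
        assert rec["reason"] == "status=preclinical"

    def test_opposing_association_filter(self, universe):
        expr, measured, metadata, truth, sets, assoc, drugs = universe
        victim = sorted(drugs)[1]
        extra = _assoc_frame([_row(victim, "oxphos", "other-cohort", +2.0, 0.0001)])
        extra["fdr"] = extra["p_value"]
        assoc2 = pd.concat([assoc, extra], ignore_index=True)
        trail = nomination.run_filter_cascade(
            drugs, metadata, assoc2, expr, measured, None, sets,
            enabled=(False, True, False, False),
        )
        assert victim not in trail.final
        assert drugs - {victim} == trail.final

    def test_measured_sign_filter_keeps_planted(self, universe):
        expr, measured, metadata, truth, sets, assoc, drugs = universe
        de = sorted(truth.planted_de_drugs)[0]
        trail = nomination.run_filter_cascade(
            {de}, metadata, assoc, expr, measured, None, sets,
            enabled=(False, False, True, False),
        )
        assert de in trail.final

    def test_missing_measured_data_fails(self, universe):
        expr, measured, metadata, truth, sets, assoc, drugs = universe
        victim = sorted(drugs)[0]
        trail = nomination.run_filter_cascade(
            {victim}, metadata, assoc, expr, measured.drop(columns=[victim]),
            None, sets, enabled=(False, False, True, False),
        )
        assert victim not in trail.final
        rec = [r for r in trail.records if r["drug_id"] == victim][0]
        assert rec["reason"] == "no measured data"

    def test_perturbation_activation_removed(self, small_config, universe):
        expr, measured, metadata, truth, sets, assoc, drugs = universe
        activated = sorted(drugs)[0]
        quiet = sorted(drugs)[1]
        perturb = synth.generate_perturbation_profiles(
            small_config, truth,
            {activated: {"glycolysis": 1.0}, quiet: {"glycolysis": 0.0}},
            n_replicates=5,
        )
        trail = nomination.run_filter_cascade(
            drugs, metadata, assoc, expr, measured, perturb, sets,
            enabled=(False, False, False, True),
        )
        assert activated not in trail.final
        assert quiet in trail.final

    def test_no_perturbation_data_passes_with_reason(self, universe):
        expr, measured, metadata, truth, sets, assoc, drugs = universe
        trail = nomination.run_filter_cascade(
            drugs, metadata, assoc, expr, measured, None, sets,
            enabled=(False, False, False, True),
        )
        assert trail.final == drugs
        assert all(r["reason"] == "no data" for r in trail.records)

    def test_survivors_nested_and_idempotent(self, universe):
        expr, measured, metadata, truth, sets, assoc, drugs = universe
        trail = nomination.run_filter_cascade(
            drugs, metadata, assoc, expr, measured, None, sets
        )
        sofar = drugs
        for surv in trail.survivors:
            assert surv <= sofar
            sofar = surv
        if trail.final:
            again = nomination.run_filter_cascade(
                trail.final, metadata, assoc, expr, measured, None, sets
            )
            assert again.final == trail.final

    def test_empty_candidates_error(self, universe):
        expr, measured, metadata, truth, sets, assoc, _ = universe
        with pytest.raises(ValueError, match="empty"):
            nomination.run_filter_cascade(
                set(), metadata, assoc, expr, measured, None, sets
            )
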