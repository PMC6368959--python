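"""Genetic-model encoding, plateau routing, scanning, validity, adjustment."""

import numpy as np
import pytest

from curescan.cohort_io import MISSING
from curescan.design import categorical_design, clinical_frame
from curescan.exceptions import UndefinedInputError
from curescan.scan import (
    GENETIC_MODELS,
    bonferroni_threshold,
    encode,
    model_validity,
    multivariable_refit,
    route,
    scan_results_frame,
    univariable_scan,
)
from curescan.simulate import (
    CohortSpec,
    SnpEffect,
    routing_fixtures,
    simulate_cohort,
)


class TestEncode:
    def test_recessive(self):
        design, obs, labels, counts = encode([0, 1, 2], "recessive")
        assert np.array_equal(design[:, 0], [0, 0, 1])
        assert counts.tolist() == [2, 1]

    def test_codominant_two_indicators(self):
        design, obs, labels, counts = encode([0, 1, 2], "codominant")
        assert np.array_equal(design, [[0, 0], [1, 0], [0, 1]])

    def test_dominant_and_additive(self):
        d_dom, *_ = encode([0, 1, 2, 2], "dominant")
        assert np.array_equal(d_dom[:, 0], [0, 1, 1, 1])
        d_add, *_ = encode([0, 1, 2, 2], "additive")
        assert np.array_equal(d_add[:, 0], [0, 1, 2, 2])

    def test_missing_excluded_and_empty_category_counted(self):
        design, obs, labels, counts = encode([0, 1, MISSING, 1], "recessive")
        assert obs.sum() == 3
        assert counts.tolist() == [3, 0]  # no minor homozygote -> skip downstream

    def test_codominant_nests_dominant(self):
        rng = np.random.default_rng(0)
        codes = rng.integers(0, 3, 50)
        d_dom, *_ = encode(codes, "dominant")
        d_co, *_ = encode(codes, "codominant")
        # dominant column is the sum of the two co-dominant indicators
        assert np.array_equal(d_dom[:, 0], d_co.sum(axis=1))


class TestRoute:
    @pytest.mark.parametrize("fixture_idx,expected", [(0, "mixture-cure"), (1, "cox"), (2, "log-rank"), (3, "skipped")])
    def test_constructed_fixtures_route_to_expected_branch(self, fixture_idx, expected):
        fx = routing_fixtures(seed=0)[fixture_idx]
        dec = route(
            fx.cohort.genotypes.codes[fx.snp_index],
            fx.model,
            fx.cohort.times,
            fx.cohort.events,
        )
        assert dec.method == expected == fx.expected_method

    def test_routing_deterministic(self):
        for fx in routing_fixtures(seed=3):
            d1 = route(fx.cohort.genotypes.codes[0], fx.model, fx.cohort.times, fx.cohort.events)
            d2 = route(fx.cohort.genotypes.codes[0], fx.model, fx.cohort.times, fx.cohort.events)
            assert d1.method == d2.method == fx.expected_method
            assert np.array_equal(d1.plateaus, d2.plateaus, equal_nan=True)

    def test_log_rank_precedence_over_cox(self):
        # one genotype category event-free AND another with plateau zero
        codes = np.array([2] * 5 + [0] * 5 + [1] * 10, np.int8)
        times = np.r_[np.full(5, 8.0), np.linspace(0.5, 2, 5), np.linspace(1, 9, 10)]
        events = np.r_[np.zeros(5, int), np.ones(5, int), np.ones(10, int) * 0]
        events[10:15] = 1
        dec = route(codes, "codominant", times, events)
        assert dec.plateaus[0] == 0.0 and dec.plateaus[2] == 1.0
        assert dec.method == "log-rank"

    def test_every_pair_yields_exactly_one_method(self, default_cohort):
        c = default_cohort
        for model in GENETIC_MODELS:
            dec = route(c.genotypes.codes[0], model, c.times, c.events)
            assert dec.method in ("mixture-cure", "cox", "log-rank", "skipped")


class TestBonferroni:
    def test_reference_snp_count_gives_printed_threshold(self):
        thr = bonferroni_threshold(0.05, 810_622)
        assert f"{thr:.1e}" == "6.2e-08"

    @pytest.mark.parametrize("alpha,n,expected", [(0.05, 1, 0.05), (0.05, 1000, 5e-5)])
    def test_simple_cases(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected)

    def test_zero_tests_error(self):
        with pytest.raises(UndefinedInputError):
            bonferroni_threshold(0.05, 0)


@pytest.fixture(scope="module")
def planted_scan():
    spec = CohortSpec(
        n=379,
        maf_list=(0.38, 0.3, 0.02),
        seed=99,
        snp_effects=(SnpEffect(0, "recessive", 0.3, np.log(8.0)),),
    )
    c = simulate_cohort(spec)
    results = univariable_scan(c.genotypes, c.times, c.events, n_tests=3)
    return c, results


class TestUnivariableScan:
    def test_one_row_per_snp_model(self, planted_scan):
        _, results = planted_scan
        assert len(results) == 12
        keys = {(r.snp_id, r.model) for r in results}
        assert len(keys) == 12

    def test_rare_snp_skipped_for_recessive_and_codominant(self, planted_scan):
        _, results = planted_scan
        rare = [r for r in results if r.snp_id == "snp00002"]
        by_model = {r.model: r.method for r in rare}
        # MAF 0.02 at n=379: expect < 2 minor homozygotes
        assert by_model["recessive"] == "skipped"
        assert by_model["codominant"] == "skipped"

    def test_planted_large_latency_effect_detected(self):
        detected = 0
        for s in range(12):
            spec = CohortSpec(
                n=379,
                maf_list=(0.38,),
                seed=500 + s,
                snp_effects=(SnpEffect(0, "recessive", 0.0, np.log(8.0)),),
            )
            c = simulate_cohort(spec)
            res = univariable_scan(
                c.genotypes, c.times, c.events, models=("recessive",), n_tests=1
            )[0]
            detected += (not res.error) and res.p_value < 0.05
        assert detected >= 7  # majority of replicates

    def test_additive_dominant_never_cox(self, planted_scan):
        _, results = planted_scan
        for r in results:
            if r.model in ("additive", "dominant"):
                assert r.method != "cox"

    def test_deterministic_result_table(self, planted_scan):
        c, results = planted_scan
        again = univariable_scan(c.genotypes, c.times, c.events, n_tests=3)
        f1 = scan_results_frame(results)
        f2 = scan_results_frame(again)
        assert f1.equals(f2)

    def test_fit_failures_captured_not_raised(self):
        # two patients only: KM plateau rules still fire, fits may fail
        spec = CohortSpec(n=12, maf_list=(0.5,), seed=1)
        c = simulate_cohort(spec)
        results = univariable_scan(c.genotypes, c.times, c.events, n_tests=1)
        assert len(results) == 4  # no exception escaped


class TestModelValidity:
    def test_no_minor_homozygotes_dominant_coincides(self):
        spec = CohortSpec(n=200, maf_list=(0.05,), seed=13)
        c = simulate_cohort(spec)
        codes = c.genotypes.codes[0].copy()
        codes[codes == 2] = 1  # remove minor homozygotes entirely
        res = univariable_scan(
            type(c.genotypes)(c.genotypes.snps, c.genotypes.patients, codes[None, :]),
            c.times,
            c.events,
            models=("dominant",),
            n_tests=1,
        )[0]
        checked = model_validity(res, codes, c.times, c.events)
        assert checked.validity == "plausible"
        assert checked.validity_p == 1.0

    def test_truly_dominant_rarely_rejected(self):
        rejected = 0
        n_rep = 30
        for s in range(n_rep):
            spec = CohortSpec(
                n=1000,
                maf_list=(0.3,),
                seed=700 + s,
                snp_effects=(SnpEffect(0, "dominant", np.log(2.0), np.log(2.5)),),
            )
            c = simulate_cohort(spec)
            res = univariable_scan(
                c.genotypes, c.times, c.events, models=("dominant",), n_tests=1
            )[0]
            checked = model_validity(res, c.genotypes.codes[0], c.times, c.events)
            rejected += checked.validity == "rejected"
            # identified-vs-codominant coefficient comparison is reported
            assert "identified_hr" in checked.coef_comparison
            assert len(checked.coef_comparison["codominant_hr"]) >= len(
                checked.coef_comparison["identified_hr"]
            )
        # type-I at alpha = 0.05: expect ~1.5 of 30
        assert rejected <= 6

    def test_heterozygote_only_effect_rejects_recessive(self):
        rejected = 0
        n_rep = 15
        for s in range(n_rep):
            spec = CohortSpec(n=1000, maf_list=(0.45,), seed=800 + s)
            c = simulate_cohort(spec)
            codes = c.genotypes.codes[0]
            het = (codes == 1).astype(float)
            # heterozygote advantage on latency only
            rng = np.random.default_rng(900 + s)
            t = np.where(
                (het == 1) & (c.events == 1), c.times * 0.25, c.times
            )
            res = univariable_scan(
                type(c.genotypes)(c.genotypes.snps, c.genotypes.patients, codes[None, :]),
                t,
                c.events,
                models=("recessive",),
                n_tests=1,
            )[0]
            if res.method in ("mixture-cure", "cox"):
                checked = model_validity(res, codes, t, c.events)
                rejected += checked.validity == "rejected"
        assert rejected > n_rep / 2


class TestMultivariableRefit:
    @staticmethod
    def scan_one(c, model="dominant"):
        return univariable_scan(
            c.genotypes, c.times, c.events, models=(model,), n_tests=1
        )[0]

    def test_neutral_covariates_leave_estimate(self):
        spec = CohortSpec(
            n=600,
            maf_list=(0.3,),
            seed=21,
            snp_effects=(SnpEffect(0, "dominant", 0.0, np.log(3.0)),),
        )
        c = simulate_cohort(spec)
        res = self.scan_one(c)
        frame = clinical_frame(c.clinical)
        D, names, mask = categorical_design(frame, ["sex", "location"])
        adj = multivariable_refit(res, c.genotypes.codes[0], c.times, c.events, D, mask)
        assert adj.adjusted
        # outcome-neutral covariates: adjusted HR close to univariable HR
        assert abs(np.log(adj.adj_hr[0]) - np.log(res.hr_est[0])) < 0.35

    def test_planted_confounder_correction(self):
        """A covariate driving both genotype frequency and outcome biases the
        univariable estimate; adjustment moves it toward the truth (zero)."""
        deltas = []
        for s in range(10):
            rng = np.random.default_rng(40 + s)
            n = 600
            sex = rng.random(n) < 0.5
            # genotype exposure depends on the confounder
            codes = np.where(
                rng.random(n) < np.where(sex, 0.65, 0.2), 1, 0
            ).astype(np.int8)
            spec = CohortSpec(
                n=n,
                maf_list=(0.3,),
                seed=60 + s,
                incidence_cov_effects={"sex": {"male": 1.2}},
                latency_cov_effects={"sex": {"male": 0.8}},
            )
            c = simulate_cohort(spec)
            c.covariates["sex"] = np.where(sex, "male", "female")
            for j, rec in enumerate(c.clinical):
                rec.sex = c.covariates.at[j, "sex"]
            # regenerate outcomes so the confounder acts through the spec
            from curescan.simulate import simulate_outcomes

            gm = type(c.genotypes)(c.genotypes.snps, c.genotypes.patients, codes[None, :])
            c2 = simulate_outcomes(gm, c.covariates, spec, seed=60 + s)
            res = self.scan_one(c2)
            if res.method != "mixture-cure" or res.error:
                continue
            frame = clinical_frame(c2.clinical)
            D, names, mask = categorical_design(frame, ["sex"])
            adj = multivariable_refit(res, codes, c2.times, c2.events, D, mask)
            if adj.adjusted:
                deltas.append(abs(np.log(adj.adj_hr[0])) - abs(np.log(res.hr_est[0])))
        assert len(deltas) >= 6
        assert np.median(deltas) < 0  # adjusted closer to the true null

    def test_complete_case_n_drop(self, default_cohort):
        c = default_cohort
        res = self.scan_one(c)
        frame = clinical_frame(c.clinical)
        # treatment and BRAF carry explicit unknown levels in the generator
        D, names, mask = categorical_design(frame, ["treatment_5fu", "braf_v600e"])
        n_unknown = int((~mask).sum())
        assert n_unknown > 0
        adj = multivariable_refit(res, c.genotypes.codes[0], c.times, c.events, D, mask)
        assert adj.adj_n == 379 - n_unknown
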