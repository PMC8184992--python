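import json
import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import aseqcc as aq
from aseqcc.counts import GENE_COL, ReplicateSet
from aseqcc.inference import (
    BIASED_MATERNAL,
    BIASED_PATERNAL,
    UNBIASED,
    concordance,
    corrected_proportion_test,
    two_sample_proportion_test,
)

from conftest import make_table


class TestCorrectedProportionTest:
    def test_qcc2_halving_identity(self):
        # dividing both counts by QCC^2 = 4 must reproduce the uncorrected
        # test on the quartered counts exactly
        p_a, lo_a, hi_a = corrected_proportion_test(100, 200, qcc=2.0)
        p_b, lo_b, hi_b = corrected_proportion_test(25, 50, qcc=1.0)
        assert (p_a, lo_a, hi_a) == (p_b, lo_b, hi_b)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            corrected_proportion_test(0, 0, qcc=1.0)

    def test_subunit_qcc_warns(self):
        with pytest.warns(UserWarning):
            corrected_proportion_test(30, 100, qcc=0.8)

    def test_bad_confidence_level(self):
        with pytest.raises(ValueError):
            corrected_proportion_test(30, 100, qcc=1.0, conf=1.5)

    @settings(max_examples=60, derandomize=True)
    @given(st.integers(1, 500), st.integers(1, 500))
    def test_monotone_in_qcc(self, m, extra):
        total = m + extra
        grid = [1.0, 1.5, 2.0, 3.0]
        results = [corrected_proportion_test(m, total, qcc=q) for q in grid]
        pvals = [r[0] for r in results]
        widths = [r[2] - r[1] for r in results]
        assert all(b >= a - 1e-12 for a, b in zip(pvals, pvals[1:]))
        assert all(b >= a - 1e-12 for a, b in zip(widths, widths[1:]))


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
class TestAgainstRPropTest:
    """Independent oracle: R stats::prop.test on integer counts."""

    CASES_1S = [(30, 100, 0.5), (55, 100, 0.5), (3, 10, 0.3), (999, 1000, 0.5),
                (50, 100, 0.5), (1, 2, 0.5)]
    CASES_2S = [(30, 100, 50, 120), (10, 40, 30, 45), (500, 1000, 520, 1000)]

    @classmethod
    def _run_r(cls):
        script = """
        out <- list()
        cases1 <- list(%s)
        for (i in seq_along(cases1)) {
          cc <- cases1[[i]]
          r <- prop.test(cc[1], cc[2], p = cc[3])
          out[[length(out)+1]] <- c(r$p.value, r$conf.int[1], r$conf.int[2])
        }
        cases2 <- list(%s)
        for (i in seq_along(cases2)) {
          cc <- cases2[[i]]
          r <- prop.test(c(cc[1], cc[3]), c(cc[2], cc[4]))
          out[[length(out)+1]] <- r$p.value
        }
        cat(jsonlite::toJSON(out, digits = 12))
        """ % (
            ", ".join(f"c({m}, {n}, {p})" for m, n, p in cls.CASES_1S),
            ", ".join(f"c({a}, {b}, {c}, {d})" for a, b, c, d in cls.CASES_2S),
        )
        res = subprocess.run(["Rscript", "-e", script], capture_output=True,
                             text=True, check=True)
        return json.loads(res.stdout)

    def test_one_and_two_sample_agree_with_r(self):
        r_out = self._run_r()
        for (m, n, p0), expected in zip(self.CASES_1S, r_out):
            p, lo, hi = corrected_proportion_test(m, n, qcc=1.0, null_ai=p0)
            assert p == pytest.approx(expected[0], rel=1e-6, abs=1e-12)
            assert lo == pytest.approx(expected[1], rel=1e-6)
            assert hi == pytest.approx(expected[2], rel=1e-6)
        for (x1, n1, x2, n2), expected in zip(self.CASES_2S, r_out[len(self.CASES_1S):]):
            p = two_sample_proportion_test(x1, n1, x2, n2)
            assert p == pytest.approx(expected[0], rel=1e-6, abs=1e-12)


class TestPointAITest:
    def _reps(self, maternal, paternal):
        return ReplicateSet([make_table(maternal, paternal)])

    def test_extreme_ai_significant_at_qcc_one(self):
        reps = self._reps([1000, 500], [0, 500])
        res = aq.test_point_ai(reps, qcc=1.0)
        assert bool(res.set_index("gene_id").loc["g0", "significant"])
        assert not bool(res.set_index("gene_id").loc["g1", "significant"])

    def test_huge_qcc_kills_significance(self):
        reps = self._reps([1000], [0])
        res = aq.test_point_ai(reps, qcc=100.0)
        assert not res["significant"].any()

    def test_per_gene_null_ai(self):
        reps = self._reps([800, 800], [200, 200])
        null = {"g0": 0.8, "g1": 0.5}
        res = aq.test_point_ai(reps, qcc=1.0, null_ai=null).set_index("gene_id")
        assert not bool(res.loc["g0", "significant"])  # matches its own null
        assert bool(res.loc["g1", "significant"])

    def test_coverage_filter_applied(self):
        reps = self._reps([4, 400], [4, 400])
        res = aq.test_point_ai(reps, qcc=1.0, min_total=10)
        assert res["gene_id"].tolist() == ["g1"]

    @pytest.mark.filterwarnings("ignore:QCC < 1")
    def test_type_one_error_controlled_with_estimated_qcc(self):
        # balanced binomial data; QCC estimated from the same replicates;
        # Bonferroni should keep the family-wise error at or below alpha
        n_runs, fails = 120, 0
        for run in range(n_runs):
            params = aq.SimulationParams(n_genes=400, coverage=100.0,
                                         rho_signal=0.0, seed=10_000 + run)
            reps, _ = aq.simulate_experiment(params)
            qcc = aq.estimate_qcc_pair(reps[0], reps[1],
                                       aq.QCCConfig(seed=run)).qcc
            res = aq.test_point_ai(reps, qcc=qcc)
            fails += int(res["significant"].any())
        assert fails / n_runs <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / n_runs)


class TestDifferentialAI:
    def test_identical_samples_yield_nothing(self, binomial_pair):
        r1, r2 = binomial_pair
        s = ReplicateSet([r1, r2])
        res = aq.test_differential_ai(s, s, 1.0, 1.0)
        assert res["significant"].sum() == 0

    def test_symmetric_under_sample_swap(self, binomial_pair):
        r1, r2 = binomial_pair
        s1 = ReplicateSet([r1])
        s2 = ReplicateSet([r2])
        a = aq.test_differential_ai(s1, s2, 1.2, 1.4)
        b = aq.test_differential_ai(s2, s1, 1.4, 1.2)
        np.testing.assert_allclose(a["p_value"], b["p_value"])

    def test_large_true_difference_detected(self):
        rng = np.random.default_rng(3)
        cov = 500
        s1 = ReplicateSet([make_table([rng.binomial(cov, 0.5)], [0], ["g0"])])
        s2 = ReplicateSet([make_table([rng.binomial(cov, 0.9)], [0], ["g0"])])
        for s in (s1, s2):
            t = s[0]
            t["paternal_count"] = cov - t["maternal_count"]
        res = aq.test_differential_ai(s1, s2, 1.0, 1.0)
        assert bool(res["significant"][0])

    def test_min_effect_filter(self, binomial_pair):
        r1, r2 = binomial_pair
        s1, s2 = ReplicateSet([r1]), ReplicateSet([r2])
        res = aq.test_differential_ai(s1, s2, 1.0, 1.0, min_effect=2.0)
        assert res["significant"].sum() == 0  # |dAI| can never reach 2

    def test_missing_qcc_rejected(self, binomial_pair):
        r1, r2 = binomial_pair
        with pytest.raises(ValueError):
            aq.test_differential_ai(ReplicateSet([r1]), ReplicateSet([r2]), None, 1.0)


class TestBiasLabels:
    def _result(self, ai, significant):
        return pd.DataFrame({"gene_id": [f"g{i}" for i in range(len(ai))],
                             "ai": ai, "null_ai": 0.5, "significant": significant})

    def test_direction_labels(self):
        labels = aq.classify_bias(self._result([0.9, 0.1, 0.9], [True, True, False]))
        assert labels.tolist() == [BIASED_MATERNAL, BIASED_PATERNAL, UNBIASED]

    def test_identical_labels_full_concordance(self):
        a = pd.Series([BIASED_MATERNAL, UNBIASED], index=["g0", "g1"])
        s = concordance(a, a.copy())
        assert s.concordance == 1.0 and s.n_biased_both == 1

    def test_disjoint_biased_sets(self):
        a = pd.Series([BIASED_MATERNAL, UNBIASED], index=["g0", "g1"])
        b = pd.Series([UNBIASED, BIASED_MATERNAL], index=["g0", "g1"])
        s = concordance(a, b)
        assert s.concordance == 0.0
        assert s.n_biased_only_1 == 1 and s.n_biased_only_2 == 1

    def test_opposite_directions_counted(self):
        a = pd.Series([BIASED_MATERNAL, BIASED_MATERNAL], index=["g0", "g1"])
        b = pd.Series([BIASED_MATERNAL, BIASED_PATERNAL], index=["g0", "g1"])
        s = concordance(a, b)
        assert s.n_biased_both == 1 and s.n_opposite_direction == 1
        assert s.concordance == 0.5
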