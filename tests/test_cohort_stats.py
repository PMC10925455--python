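import numpy as np
import pandas as pd
import pytest

from zonescore import (
    classify_zones, paired_test, scores_to_frame, spearman_correlation,
    stratified_analysis, zone_scores,
)

import oracles


def _frame(zs_pos, zs_neg, marker="cd8", compartment="peritumoral"):
    zs_pos = np.asarray(zs_pos, dtype=float)
    zs_neg = np.asarray(zs_neg, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = zs_neg / zs_pos
    return pd.DataFrame({
        "case_id": [f"c{i}" for i in range(len(zs_pos))],
        "marker": marker, "compartment": compartment,
        "zs_pos": zs_pos, "zs_neg": zs_neg, "ratio_neg_over_pos": ratio,
    })


class TestPairedTest:
    def test_toy_differences(self):
        # diffs [1, 2, 3]: t = 2 / (1 / sqrt(3)), df = 2
        res = paired_test(_frame([0.0, 0.0, 0.0], [1.0, 2.0, 3.0]))
        assert res.mean_diff == pytest.approx(2.0)
        assert res.t_statistic == pytest.approx(3.46410, abs=1e-4)
        assert res.df == 2
        assert res.p_value == pytest.approx(0.07418, abs=1e-4)

    def test_no_effect_identity(self):
        res = paired_test(_frame([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]))
        assert res.t_statistic == 0.0
        assert res.p_value == 1.0

    def test_too_few_usable_cases(self):
        df = _frame([1.0, 2.0, np.nan], [2.0, 3.0, 1.0])
        with pytest.raises(ValueError, match="2"):
            paired_test(df)

    def test_mixed_groups_rejected(self):
        df = pd.concat([_frame([1, 2, 3], [2, 3, 4], marker="cd8"),
                        _frame([1, 2, 3], [2, 3, 4], marker="cd4")])
        with pytest.raises(ValueError, match="marker"):
            paired_test(df)

    def test_fraction_uses_defined_ratios_only(self):
        df = _frame([1.0, 1.0, 0.0, 2.0], [2.0, 0.5, 1.0, 4.0])
        res = paired_test(df)
        assert res.n_ratio_defined == 3     # the 0-denominator case drops out
        assert res.fraction_neg_dominant == pytest.approx(2 / 3)

    def test_swap_negates_t_and_flips_fraction(self, rng):
        zs_pos = rng.gamma(2.0, 1.0, size=12)
        zs_neg = rng.gamma(2.0, 1.2, size=12)
        a = paired_test(_frame(zs_pos, zs_neg))
        b = paired_test(_frame(zs_neg, zs_pos))
        assert b.t_statistic == -a.t_statistic
        assert b.p_value == a.p_value
        assert b.fraction_neg_dominant == pytest.approx(
            1.0 - a.fraction_neg_dominant
        )

    def test_matches_integration_oracle(self, rng):
        """t-test p-values agree with numerical integration of the t density."""
        for _ in range(100):
            n = int(rng.integers(3, 15))
            df = _frame(rng.normal(1, 0.5, n), rng.normal(1.2, 0.5, n))
            res = paired_test(df)
            assert res.p_value == pytest.approx(
                oracles.t_two_sided_p(res.t_statistic, res.df), abs=1e-10
            )


class TestSpearman:
    def test_monotone_limits(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        assert spearman_correlation(
            x, [2.0, 4.0, 5.0, 7.0, 11.0]
        )[0] == pytest.approx(1.0, abs=1e-12)
        assert spearman_correlation(
            x, [5.0, 4.0, 3.0, 2.0, 1.0]
        )[0] == pytest.approx(-1.0, abs=1e-12)

    def test_hand_ranked_example(self):
        # ranks of y are [2, 1, 4, 3, 5]: sum d^2 = 4, rho = 1 - 24/120
        rho, _ = spearman_correlation([1, 2, 3, 4, 5], [2, 1, 4, 3, 5])
        assert rho == pytest.approx(0.8, abs=1e-12)
        assert rho == pytest.approx(
            oracles.spearman_rho(np.array([1, 2, 3, 4, 5.0]),
                                 np.array([2, 1, 4, 3, 5.0]))
        )

    def test_constant_vector_sentinel(self):
        rho, p = spearman_correlation([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert np.isnan(rho) and np.isnan(p)

    def test_matches_rank_oracle_with_ties(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 30))
            x = rng.integers(0, 8, n).astype(float)   # ties guaranteed
            y = rng.integers(0, 8, n).astype(float)
            if np.all(x == x[0]) or np.all(y == y[0]):
                continue
            rho, p = spearman_correlation(x, y)
            assert rho == pytest.approx(oracles.spearman_rho(x, y), abs=1e-10)
            if abs(rho) < 1.0:
                assert p == pytest.approx(
                    oracles.spearman_p(rho, n), abs=1e-10
                )


class TestStratified:
    @staticmethod
    def _cohort(rng, n=12):
        scores = _frame(rng.gamma(2, 1, n), rng.gamma(2, 1.3, n))
        meta = pd.DataFrame({
            "case_id": scores["case_id"],
            "all_same": "x",
            "split": ["a" if i < n // 2 else "b" for i in range(n)],
            "tiny": ["z" if i < 2 else "w" for i in range(n)],
        })
        return scores, meta

    def test_single_stratum_equals_plain_test(self, rng):
        scores, meta = self._cohort(rng)
        [res] = stratified_analysis(scores, meta, "all_same")
        plain = paired_test(scores)
        assert res.t_statistic == plain.t_statistic
        assert res.p_value == plain.p_value
        assert res.stratum == "x"

    def test_small_stratum_reported_as_skipped(self, rng):
        scores, meta = self._cohort(rng)
        results = stratified_analysis(scores, meta, "tiny")
        by_stratum = {r.stratum: r for r in results}
        assert by_stratum["z"].skipped_reason is not None
        assert by_stratum["w"].skipped_reason is None

    def test_unknown_column_raises(self, rng):
        scores, meta = self._cohort(rng)
        with pytest.raises(KeyError, match="nope"):
            stratified_analysis(scores, meta, "nope")

    def test_results_flag_missing_adjustment(self, rng):
        scores, meta = self._cohort(rng)
        for r in stratified_analysis(scores, meta, "split"):
            assert r.multiplicity_adjusted is False

    def test_planted_effect_recovered_in_both_strata(self):
        """Same 2x CD8 effect planted in two strata of a synthetic cohort."""
        from zonescore import generate_cohort
        from conftest import small_spec

        spec = small_spec(effect_ratio={"cd8": 2.0})
        masks, meta = generate_cohort(spec, 24)
        rows = []
        for m in masks:
            p = classify_zones(m, band_depth_um=25.0)
            rows.extend(zone_scores(m, p))
        df = scores_to_frame(rows)
        sl = df[(df.marker == "cd8") & (df.compartment == "peritumoral")]
        meta = meta.assign(half=["a" if i < 12 else "b"
                                 for i in range(len(meta))])
        results = stratified_analysis(sl, meta, "half")
        assert len(results) == 2
        for r in results:
            assert r.skipped_reason is None
            assert r.p_value <= 0.05
            assert r.t_statistic > 0
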