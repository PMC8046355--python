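import math

import numpy as np
import pandas as pd
import pytest

from y2hscreen import scores
from y2hscreen.scores import ScoreParams

import oracles


def enrich_frame(p, f, bait="b1"):
    return pd.DataFrame(
        {
            "bait": bait,
            "prey": [f"p{i}" for i in range(len(p))],
            "pvalue": p,
            "log2fc": f,
        }
    )


def random_enrich_instance(rng, n_preys, n_baits):
    rows = []
    for b in range(n_baits):
        p = rng.random(n_preys) ** rng.uniform(0.5, 3)
        f = rng.normal(0, 3, n_preys)
        p[rng.random(n_preys) < 0.05] = np.nan
        f[rng.random(n_preys) < 0.05] = np.nan
        rows.append(
            pd.DataFrame(
                {
                    "bait": f"b{b}",
                    "prey": [f"p{i}" for i in range(n_preys)],
                    "pvalue": p,
                    "log2fc": f,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def random_pairwise_instance(rng, n_preys, n_baits):
    rows = []
    for i in range(n_baits):
        for j in range(n_baits):
            if i == j:
                continue
            rows.append(
                pd.DataFrame(
                    {
                        "bait": f"b{i}",
                        "bait_other": f"b{j}",
                        "prey": [f"p{k}" for k in range(n_preys)],
                        "pvalue": rng.random(n_preys),
                        "log2fc": rng.normal(0, 2, n_preys),
                    }
                )
            )
    return pd.concat(rows, ignore_index=True)


class TestScoreParams:
    def test_alpha_bounds(self):
        with pytest.raises(ValueError):
            ScoreParams(enrich_p_val=0.0)
        with pytest.raises(ValueError):
            ScoreParams(spec_p_val=1.5)

    def test_window_width_is_adjusted_to_divide_alpha(self):
        params = ScoreParams(window_width=0.3)
        assert params.n_windows == 4
        assert params.width(1.0) <= 0.3


class TestEnrichmentScore:
    def test_all_pairs_above_alpha_score_zero(self):
        res = enrich_frame([0.5, 0.9], [2.0, 1.0])
        out = scores.enrichment_score(res, ScoreParams(enrich_p_val=0.1))
        assert (out.enrichment == 0).all()

    def test_worked_chain_with_two_windows(self):
        # alpha = 1, two windows of width 0.5; the depleted prey (f = -1)
        # is zeroed by the fold-change rule, all others follow the
        # rank-within-rank chain
        res = enrich_frame([0.001, 0.2, 0.6, 0.9], [3.0, 2.0, -1.0, 4.0])
        params = ScoreParams(window_width=0.5)
        out = scores.enrichment_score(res, params).enrichment.to_numpy()
        records = [
            ("b1", f"p{i}", p, f)
            for i, (p, f) in enumerate(
                zip([0.001, 0.2, 0.6, 0.9], [3.0, 2.0, -1.0, 4.0])
            )
        ]
        expected = oracles.enrichment_oracle(records, alpha=1.0, b=2)
        np.testing.assert_allclose(
            out, [expected[("b1", f"p{i}")] for i in range(4)]
        )
        # hand evaluation: E(p) = [0.75, 0.5, 0 (zeroed), 0]; window 1 holds
        # preys 1-2 (spread (0.75-0.5)/2, E(f) = [0.5, 0]), window 2 holds
        # preys 3-4 whose post-zero p-scores are both 0, so its spread (and
        # fold-change increment) is 0; combined [0.8125, 0.5, 0, 0],
        # rescaled by 0.8125
        np.testing.assert_allclose(out, [1.0, 0.5 / 0.8125, 0.0, 0.0])
        assert out[0] > out[1] > out[2] == out[3]

    def test_missing_values_are_conservative(self):
        res = enrich_frame([np.nan, 0.01], [5.0, np.nan])
        out = scores.enrichment_score(res).enrichment.to_numpy()
        # missing p counts as 1 (last rank), missing f as 0
        assert out[1] > out[0]

    def test_duplicated_bait_leaves_scores_unchanged(self, rng):
        p = rng.random(12)
        f = rng.normal(1, 2, 12)
        single = scores.enrichment_score(enrich_frame(p, f))
        doubled = scores.enrichment_score(
            pd.concat(
                [enrich_frame(p, f, "b1"), enrich_frame(p, f, "b2")],
                ignore_index=True,
            )
        )
        merged = single.merge(doubled[doubled.bait == "b1"], on="prey")
        # duplication doubles every competition rank and window size,
        # shifting each score by O(1/N) — values stay close and the overall
        # ranking is essentially preserved
        np.testing.assert_allclose(
            merged.enrichment_x, merged.enrichment_y, atol=0.1
        )
        from scipy import stats as sps

        rho = sps.spearmanr(merged.enrichment_x, merged.enrichment_y).statistic
        assert rho > 0.95

    def test_monotone_p_transform_preserving_windows_is_invariant(self, rng):
        # transform p -> p**2 within each window maps the window onto
        # itself monotonically when windows are [0, 1] with b = 1
        p = rng.random(30)
        f = rng.normal(0, 1, 30)
        params = ScoreParams(n_windows=1)
        a = scores.enrichment_score(enrich_frame(p, f), params)
        b = scores.enrichment_score(enrich_frame(p**2, f), params)
        np.testing.assert_allclose(a.enrichment, b.enrichment)

    def test_matches_loops_oracle_on_random_instances(self, rng):
        for _ in range(25):
            inst = random_enrich_instance(
                rng, int(rng.integers(3, 50)), int(rng.integers(1, 4))
            )
            got = scores.enrichment_score(inst)
            records = [
                (r.bait, r.prey, r.pvalue, r.log2fc) for r in inst.itertuples()
            ]
            expected = oracles.enrichment_oracle(records)
            for r, g in zip(records, got.enrichment):
                assert g == pytest.approx(expected[(r[0], r[1])], abs=1e-12)


class TestSpecificityScore:
    def _pairwise(self, rows):
        return pd.DataFrame(
            rows, columns=["bait", "bait_other", "prey", "pvalue", "log2fc"]
        )

    def test_non_specific_prey_scores_zero(self):
        # a prey equally abundant with every bait: f ~ 0, p above alpha
        rows = []
        for i, j in [("A", "B"), ("B", "A")]:
            rows.append((i, j, "p0", 0.95, 0.0))
            rows.append((i, j, "p1", 0.001, 2.0 if i == "A" else -2.0))
        out = scores.specificity_score(
            self._pairwise(rows), ScoreParams(spec_p_val=0.5)
        )
        assert out[out.prey == "p0"].specificity.max() == pytest.approx(0.0)

    def test_negative_fold_change_rule_forces_zero(self):
        rows = [
            ("A", "B", "p0", 0.001, -1.0),
            ("B", "A", "p0", 0.001, 1.0),
            ("A", "B", "p1", 0.01, 0.5),
            ("B", "A", "p1", 0.01, -0.5),
        ]
        out = scores.specificity_score(self._pairwise(rows))
        a = out[(out.bait == "A") & (out.prey == "p0")].specificity.item()
        assert a == 0.0

    def test_strongly_specific_prey_reaches_one(self):
        rows = []
        baits = ["A", "B", "C"]
        for i in baits:
            for j in baits:
                if i == j:
                    continue
                if i == "A":
                    rows.append((i, j, "pT", 1e-6, 4.0))
                elif j == "A":
                    rows.append((i, j, "pT", 1e-6, -4.0))
                else:
                    rows.append((i, j, "pT", 0.99, 0.0))
                for k in range(3):
                    rows.append((i, j, f"null{k}", 0.8, 0.01))
        out = scores.specificity_score(self._pairwise(rows))
        top = out[(out.bait == "A") & (out.prey == "pT")].specificity.item()
        assert top == pytest.approx(1.0)
        assert (out.specificity <= 1.0).all()

    def test_fewer_than_two_baits_is_an_error(self):
        rows = [("A", "A", "p0", 0.5, 1.0)]
        with pytest.raises(ValueError, match="2 baits"):
            scores.specificity_score(self._pairwise(rows))

    def test_matches_loops_oracle_on_random_instances(self, rng):
        for _ in range(15):
            n_b = int(rng.integers(2, 5))
            inst = random_pairwise_instance(rng, int(rng.integers(3, 30)), n_b)
            got = scores.specificity_score(inst)
            records = [
                (r.bait, r.bait_other, r.prey, r.pvalue, r.log2fc)
                for r in inst.itertuples()
            ]
            expected = oracles.specificity_oracle(records, n_baits=n_b)
            lookup = dict(
                zip(zip(got.bait, got.prey), got.specificity)
            )
            for key, val in expected.items():
                assert lookup[key] == pytest.approx(val, abs=1e-12)


class TestInframeScore:
    def _stats(self, rho):
        return pd.DataFrame(
            {
                "bait": "b1",
                "prey": [f"p{i}" for i in range(len(rho))],
                "rho": rho,
            }
        )

    def test_missing_rho_scores_zero(self):
        out = scores.inframe_score(self._stats([np.nan, 1.0]))
        assert out.inframe.tolist() == [0.0, 1.0]

    def test_single_defined_rho_scores_one(self):
        out = scores.inframe_score(self._stats([np.nan, -3.0]))
        assert out.inframe.tolist() == [0.0, 1.0]

    def test_rank_arithmetic(self):
        out = scores.inframe_score(self._stats([-2.0, 0.0, 3.0]))
        np.testing.assert_allclose(out.inframe, [1 / 3, 2 / 3, 1.0])

    def test_invariant_under_increasing_transform(self, rng):
        rho = rng.normal(0, 2, 40)
        a = scores.inframe_score(self._stats(rho))
        b = scores.inframe_score(self._stats(np.tanh(rho)))
        np.testing.assert_allclose(a.inframe, b.inframe)

    def test_matches_loops_oracle(self, rng):
        rho = rng.normal(0, 1, 25)
        rho[rng.random(25) < 0.2] = np.nan
        got = scores.inframe_score(self._stats(rho))
        expected = oracles.inframe_oracle(
            [("b1", f"p{i}", r) for i, r in enumerate(rho)]
        )
        for i, g in enumerate(got.inframe):
            assert g == pytest.approx(expected[("b1", f"p{i}")])


class TestBorda:
    def _table(self, e, s, i, bait="b1"):
        return pd.DataFrame(
            {
                "bait": bait,
                "prey": [f"p{k}" for k in range(len(e))],
                "enrichment": e,
                "specificity": s,
                "inframe": i,
            }
        )

    def test_concordant_orderings_are_preserved(self):
        t = self._table([0.9, 0.5, 0.1], [0.8, 0.4, 0.2], [1.0, 0.6, 0.0])
        borda = scores.borda_ensemble(t)
        assert borda[0] > borda[1] > borda[2]
        assert borda[0] == pytest.approx(1.0)

    def test_constant_component_does_not_change_ordering(self, rng):
        e = rng.random(10)
        s = rng.random(10)
        with_const = scores.borda_ensemble(
            self._table(e, s, np.full(10, 0.5))
        )
        without = scores.borda_ensemble(
            self._table(e, s, np.zeros(10)), which=("enrichment", "specificity")
        )
        np.testing.assert_array_equal(
            np.argsort(-with_const.to_numpy()), np.argsort(-without.to_numpy())
        )

    def test_symmetric_components_tie(self):
        t = self._table([1.0, 0.0], [0.0, 1.0], [0.5, 0.5])
        borda = scores.borda_ensemble(t)
        assert borda[0] == pytest.approx(borda[1])

    def test_matches_loops_oracle(self, rng):
        t = pd.concat(
            [
                self._table(
                    rng.random(8), rng.random(8), rng.random(8), bait=f"b{b}"
                )
                for b in range(3)
            ],
            ignore_index=True,
        )
        got = scores.borda_ensemble(t)
        expected = oracles.borda_oracle(
            t.to_dict("records"), ("enrichment", "specificity", "inframe")
        )
        for idx, row in t.iterrows():
            assert got[idx] == pytest.approx(expected[(row.bait, row.prey)])


class TestScoreTable:
    def test_all_scores_are_in_unit_interval(self, rng):
        enrich = random_enrich_instance(rng, 20, 3)
        pairwise = random_pairwise_instance(rng, 20, 3)
        rho = pd.DataFrame(
            {
                "bait": np.repeat([f"b{i}" for i in range(3)], 20),
                "prey": np.tile([f"p{k}" for k in range(20)], 3),
                "rho": rng.normal(0, 1, 60),
            }
        )
        table = scores.compute_score_table(enrich, pairwise, rho)
        for col in ("enrichment", "specificity", "inframe", "borda"):
            assert table[col].between(0, 1).all()
            assert table[col].max() == pytest.approx(1.0)

    def test_missing_components_default_to_zero(self, rng):
        enrich = random_enrich_instance(rng, 10, 1)
        table = scores.compute_score_table(enrich, None, None)
        assert (table.specificity == 0).all()
        assert (table.inframe == 0).all()
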