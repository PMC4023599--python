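"""Co-expression classification, ddCt quantification, clustering."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bzipkit.expression import (
    classify_responders,
    cluster_expression,
    compare_qpcr_vs_atlas,
    ddct_relative_expression,
    pairwise_pcc,
    pcc_pvalue,
)
from bzipkit.records import ExpressionMatrix, RecordError
from bzipkit.simulate import gen_expression_matrix, gen_qpcr


def _matrix(values, prefix="g"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(
        [f"{prefix}{i}" for i in range(values.shape[0])],
        [f"s{j}" for j in range(values.shape[1])],
        values,
    )


class TestPairwisePcc:
    def test_affine_copy_strong_positive(self):
        x = np.arange(10.0)
        m = _matrix([x, 2.0 * x + 5.0])
        (pair,) = pairwise_pcc(m)
        assert pair.pcc == pytest.approx(1.0)
        assert pair.klass == "strong-positive"

    def test_negation_significant_negative(self):
        x = np.arange(10.0)
        m = _matrix([x, -x])
        (pair,) = pairwise_pcc(m)
        assert pair.pcc == pytest.approx(-1.0)
        assert pair.klass == "significant-negative"

    def test_too_few_samples_errors(self):
        with pytest.raises(ValueError):
            pairwise_pcc(_matrix([[1.0, 2.0], [2.0, 1.0]]))

    def test_zero_variance_row_excluded_with_warning(self):
        m = _matrix([[1, 2, 3, 4], [4, 3, 2, 1], [5, 5, 5, 5]])
        with pytest.warns(UserWarning):
            pairs = pairwise_pcc(m)
        assert len(pairs) == 1

    def test_oracle_agreement_1e12(self):
        """Classes and r values against a direct covariance-formula oracle."""
        rng = np.random.default_rng(8)
        m = _matrix(rng.normal(size=(10, 54)))
        pairs = {(p.gene_a, p.gene_b): p for p in pairwise_pcc(m)}
        n = 54
        for i in range(10):
            for j in range(i + 1, 10):
                x, y = m.values[i], m.values[j]
                r = float(
                    np.sum((x - x.mean()) * (y - y.mean()))
                    / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2))
                )
                p = pairs[(f"g{i}", f"g{j}")]
                assert p.pcc == pytest.approx(r, abs=1e-12)
                t = abs(r) * np.sqrt((n - 2) / (1 - r * r))
                assert p.p_value == pytest.approx(2 * stats.t.sf(t, n - 2), abs=1e-12)
                # independent class decision
                if p.p_value < 0.01 and r >= 0.35:
                    expected = "strong-positive" if r > 0.9 else "significant-positive"
                elif p.p_value < 0.01 and r <= -0.35:
                    expected = "significant-negative"
                else:
                    expected = "not-significant"
                assert p.klass == expected

    def test_boundary_r_inclusive(self):
        """r exactly at the 0.35 threshold with p < alpha is positive."""
        # construct y with sample correlation exactly 0.35 via Gram-Schmidt
        rng = np.random.default_rng(2)
        n = 54
        x = rng.normal(size=n)
        z = rng.normal(size=n)
        xc = (x - x.mean()) / np.std(x)
        zc = z - z.mean()
        zc -= (zc @ xc) / (xc @ xc) * xc  # orthogonal to x
        zc /= np.std(zc)
        r0 = 0.35
        y = r0 * xc + np.sqrt(1 - r0**2) * zc
        # pin the threshold to the achieved r so the comparison sits exactly
        # on the boundary: inclusive >= must classify it positive
        r_exact = float(np.corrcoef(x, y)[0, 1])
        (pair,) = pairwise_pcc(_matrix([x, y]), pos=r_exact)
        assert pair.pcc == pytest.approx(0.35, abs=1e-12)
        assert pair.klass == "significant-positive"

    def test_symmetric_matrix_properties(self):
        m, _ = gen_expression_matrix(6, 20, seed=5)
        pairs = pairwise_pcc(m)
        assert len(pairs) == 15
        assert all(-1.0 <= p.pcc <= 1.0 for p in pairs)


class TestDdct:
    def test_equal_cts_give_fold_one(self):
        rows = []
        for cond in ("0d", "4d"):
            rows.append({"gene_id": "g", "condition": cond, "ct_target": 24.0, "ct_reference": 15.0})
        folds = ddct_relative_expression(pd.DataFrame(rows), "0d")
        assert set(folds["fold"]) == {1.0}

    def test_one_cycle_shift_doubles(self):
        rows = [
            {"gene_id": "g", "condition": "0d", "ct_target": 20.0, "ct_reference": 15.0},
            {"gene_id": "g", "condition": "4d", "ct_target": 19.0, "ct_reference": 15.0},
        ]
        folds = ddct_relative_expression(pd.DataFrame(rows), "0d")
        assert folds.set_index("condition")["fold"]["4d"] == pytest.approx(2.0)

    def test_zero_noise_generator_round_trip(self):
        genes = [f"g{i}" for i in range(5)]
        conditions = ["0d", "4d", "8d"]
        planted = {(g, c): 2.0 ** (i - 2) for i, g in enumerate(genes) for c in conditions[1:]}
        table, truth = gen_qpcr(genes, conditions, planted, "0d", seed=7)
        folds = ddct_relative_expression(table, "0d").set_index(["gene_id", "condition"])["fold"]
        for (g, c), f in truth.folds.items():
            assert folds[(g, c)] == pytest.approx(f, abs=1e-9)

    def test_control_exactly_one_with_noise(self):
        table, _ = gen_qpcr(["g"], ["0d", "4d"], {("g", "4d"): 3.0}, "0d", ct_noise_sd=0.3, seed=8)
        folds = ddct_relative_expression(table, "0d").set_index(["gene_id", "condition"])["fold"]
        assert folds[("g", "0d")] == pytest.approx(1.0)

    def test_additive_ct_shift_invariance(self):
        """Shifting target and reference Cts of a condition equally changes nothing."""
        table, _ = gen_qpcr(["g"], ["0d", "4d"], {("g", "4d"): 2.5}, "0d", seed=9)
        shifted = table.copy()
        mask = shifted["condition"] == "4d"
        shifted.loc[mask, ["ct_target", "ct_reference"]] += 1.7
        a = ddct_relative_expression(table, "0d")["fold"]
        b = ddct_relative_expression(shifted, "0d")["fold"]
        np.testing.assert_allclose(a, b, atol=1e-12)

    def test_missing_control_errors(self):
        df = pd.DataFrame(
            [{"gene_id": "g", "condition": "4d", "ct_target": 20.0, "ct_reference": 15.0}]
        )
        with pytest.raises(RecordError):
            ddct_relative_expression(df, "0d")

    def test_missing_reference_ct_errors(self):
        df = pd.DataFrame(
            [
                {"gene_id": "g", "condition": "0d", "ct_target": 20.0, "ct_reference": np.nan},
            ]
        )
        with pytest.raises(RecordError, match="g"):
            ddct_relative_expression(df, "0d")


class TestResponders:
    def test_flat_profile_is_none(self):
        folds = pd.DataFrame(
            {"gene_id": ["g"] * 3, "condition": list("abc"), "fold": [1.0, 1.0, 1.0]}
        )
        (call,) = classify_responders(folds)
        assert call.direction == "none"

    def test_boundary_two_fold_inclusive(self):
        folds = pd.DataFrame(
            {"gene_id": ["g"] * 2, "condition": ["a", "b"], "fold": [1.1, 2.0]}
        )
        (call,) = classify_responders(folds)
        assert call.direction == "up" and call.max_fold == 2.0

    def test_both_directions_possible(self):
        folds = pd.DataFrame(
            {"gene_id": ["g"] * 2, "condition": ["a", "b"], "fold": [4.0, 0.2]}
        )
        directions = {c.direction for c in classify_responders(folds)}
        assert directions == {"up", "down"}

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(6)
        folds = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(30) for _ in range(4)],
                "condition": ["a", "b", "c", "d"] * 30,
                "fold": 2.0 ** rng.normal(0, 1.5, size=120),
            }
        )
        prev = None
        for thr in (1.5, 2.0, 3.0, 5.0):
            responders = {
                c.gene_id for c in classify_responders(folds, thr) if c.direction != "none"
            }
            if prev is not None:
                assert responders <= prev
            prev = responders

    def test_vs_bruteforce_threshold_scan(self):
        rng = np.random.default_rng(16)
        folds = pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(20) for _ in range(3)],
                "condition": ["a", "b", "c"] * 20,
                "fold": 2.0 ** rng.normal(0, 2, size=60),
            }
        )
        calls = classify_responders(folds, 2.0)
        got = {(c.gene_id, c.direction) for c in calls}
        expected = set()
        for g in folds["gene_id"].unique():
            fs = folds[folds["gene_id"] == g]["fold"]
            ds = []
            if fs.max() >= 2.0:
                ds.append("up")
            if fs.min() <= 0.5:
                ds.append("down")
            for d in ds or ["none"]:
                expected.add((g, d))
        assert got == expected


class TestClustering:
    def test_planted_blocks_recovered(self):
        m, truth = gen_expression_matrix(
            12, 30, blocks=[[0, 1, 2, 3], [6, 7, 8, 9]], r_target=0.99, seed=10
        )
        sub = ExpressionMatrix(
            truth.blocks[0] + truth.blocks[1],
            m.sample_ids,
            np.vstack([m.row(g) for g in truth.blocks[0] + truth.blocks[1]]),
        )
        labels = cluster_expression(sub, k=2)
        first = {labels[g] for g in truth.blocks[0]}
        second = {labels[g] for g in truth.blocks[1]}
        assert len(first) == 1 and len(second) == 1 and first != second

    def test_k_equals_n_singletons(self):
        m, _ = gen_expression_matrix(5, 10, seed=11)
        labels = cluster_expression(m, k=5)
        assert len(set(labels.values())) == 5

    def test_gene_order_invariant_up_to_renaming(self):
        m, _ = gen_expression_matrix(10, 20, blocks=[[0, 1, 2]], r_target=0.95, seed=12)
        perm = list(reversed(range(10)))
        mp = ExpressionMatrix(
            [m.gene_ids[i] for i in perm], m.sample_ids, m.values[perm]
        )
        a = cluster_expression(m, k=3)
        b = cluster_expression(mp, k=3)
        # same partition structure
        part_a = {}
        part_b = {}
        for g in m.gene_ids:
            part_a.setdefault(a[g], set()).add(g)
            part_b.setdefault(b[g], set()).add(g)
        assert {frozenset(s) for s in part_a.values()} == {
            frozenset(s) for s in part_b.values()
        }

    def test_k_too_large_errors(self):
        m, _ = gen_expression_matrix(3, 10, seed=13)
        with pytest.raises(ValueError):
            cluster_expression(m, k=4)


class TestQpcrVsAtlas:
    def _atlas(self, profiles):
        genes = list(profiles)
        vals = np.array([profiles[g] for g in genes], dtype=float)
        return ExpressionMatrix(genes, [f"t{j}" for j in range(vals.shape[1])], vals)

    def test_identical_profiles_flagged(self):
        atlas = self._atlas({"g": [1, 2, 3, 4, 5, 6]})
        qpcr = pd.DataFrame(
            {"gene_id": "g", "condition": [f"c{j}" for j in range(6)], "fold": [1, 2, 3, 4, 5, 6]}
        )
        pairs = [(f"c{j}", f"t{j}") for j in range(6)]
        df = compare_qpcr_vs_atlas(qpcr, atlas, pairs)
        assert df.iloc[0]["agreement"] and df.iloc[0]["pcc"] == pytest.approx(1.0)

    def test_orthogonal_four_points_not_flagged(self):
        atlas = self._atlas({"g": [1, -1, 1, -1]})
        qpcr = pd.DataFrame(
            {"gene_id": "g", "condition": [f"c{j}" for j in range(4)], "fold": [1, 1.0001, 1, 1.0002]}
        )
        pairs = [(f"c{j}", f"t{j}") for j in range(4)]
        df = compare_qpcr_vs_atlas(qpcr, atlas, pairs)
        assert not df.iloc[0]["agreement"]

    def test_fewer_than_three_matches_skipped(self):
        atlas = self._atlas({"g": [1, 2]})
        qpcr = pd.DataFrame({"gene_id": "g", "condition": ["c0", "c1"], "fold": [1, 2]})
        with pytest.warns(UserWarning):
            df = compare_qpcr_vs_atlas(qpcr, atlas, [("c0", "t0"), ("c1", "t1")])
        assert df.empty

    def test_flag_matches_exact_t_test_oracle(self):
        rng = np.random.default_rng(14)
        for _ in range(10):
            x = rng.normal(size=4)
            y = 0.99 * (x - x.mean()) / x.std() + 0.01 * rng.normal(size=4)
            atlas = self._atlas({"g": y})
            qpcr = pd.DataFrame(
                {"gene_id": "g", "condition": [f"c{j}" for j in range(4)], "fold": x}
            )
            df = compare_qpcr_vs_atlas(qpcr, atlas, [(f"c{j}", f"t{j}") for j in range(4)])
            r, p = stats.pearsonr(x, y)
            assert df.iloc[0]["pcc"] == pytest.approx(r, abs=1e-9)
            assert df.iloc[0]["agreement"] == (p < 0.01)
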