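import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from binet.io import ExpressionMatrix, GeneSet
from binet.scoring import (CompositeScore, circadian_normalize, cluster_score,
                           composite_score, evaluate_auc, gene_zscore,
                           stratify_survival)
from binet.synthetic import GeneratorBlueprint, generate_polarized_matrix


def brute_force_auc(scores, labels):
    """Pair-counting Mann-Whitney AUC with 0.5 credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l]
    neg = [s for s, l in zip(scores, labels) if not l]
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p, n in itertools.product(pos, neg))
    return wins / (len(pos) * len(neg))


class TestGeneZscore:
    def test_centering_at_threshold(self):
        assert gene_zscore(np.array([3.0]), 3.0, stddev=1.0)[0] == 0.0

    def test_unit_at_three_sigma(self):
        assert gene_zscore(np.array([6.0]), 3.0, stddev=1.0)[0] == pytest.approx(1.0)

    def test_constant_gene_yields_zeros(self):
        z = gene_zscore(np.full(5, 2.0), 1.0)
        assert (z == 0).all()


class TestClusterScore:
    def _em(self, rows, genes):
        return ExpressionMatrix(pd.DataFrame(
            np.asarray(rows, float), index=genes,
            columns=[f"s{i}" for i in range(len(rows[0]))]))

    def test_single_gene_cluster_equals_z_row(self, rng):
        row = np.r_[rng.normal(2, 0.3, 10), rng.normal(8, 0.3, 10)]
        em = self._em([row], ["GA"])
        from binet.stepminer import fit_step
        expected = gene_zscore(row, fit_step(row).threshold, row.std())
        np.testing.assert_allclose(cluster_score(em, GeneSet("c", {"GA"})),
                                   expected)

    def test_duplicated_gene_idempotent(self, rng):
        row = np.r_[rng.normal(2, 0.3, 10), rng.normal(8, 0.3, 10)]
        em1 = self._em([row], ["GA"])
        em2 = self._em([row, row], ["GA", "GB"])
        np.testing.assert_allclose(
            cluster_score(em1, GeneSet("c", {"GA"})),
            cluster_score(em2, GeneSet("c", {"GA", "GB"})), atol=1e-12)

    def test_recovers_planted_latent_activity(self, dataset):
        genes = GeneSet("c13", set(dataset.gene_clusters[13]))
        score = cluster_score(dataset.matrix, genes)
        latent = dataset.latent.loc[13].to_numpy()
        r = np.corrcoef(score, latent)[0, 1]
        assert r >= 0.95

    def test_empty_intersection_is_error(self, rng):
        em = self._em([rng.normal(size=10)], ["GA"])
        with pytest.raises(ValueError, match="missing"):
            cluster_score(em, GeneSet("missing", {"ZZ"}))


class TestCompositeScore:
    def test_linearity_in_weights(self, dataset):
        sigs = [(GeneSet("c13", set(dataset.gene_clusters[13])), -1.0),
                (GeneSet("c3", set(dataset.gene_clusters[3])), 2.0)]
        doubled = [(g, 2 * w) for g, w in sigs]
        s1 = composite_score(dataset.matrix, sigs).score
        s2 = composite_score(dataset.matrix, doubled).score
        np.testing.assert_allclose(s2, 2 * s1, rtol=1e-9)

    def test_sign_convention_reactive_low(self):
        for seed in (0, 1, 2):
            ds = generate_polarized_matrix(GeneratorBlueprint(seed=seed))
            sigs = [(GeneSet("c13", set(ds.gene_clusters[13])), -1.0),
                    (GeneSet("c14", set(ds.gene_clusters[14])), 1.0),
                    (GeneSet("c3", set(ds.gene_clusters[3])), 2.0)]
            cs = composite_score(ds.matrix, sigs)
            s = cs.as_series()
            m1 = s[ds.annotation[ds.annotation == "M1"].index].mean()
            m2 = s[ds.annotation[ds.annotation == "M2"].index].mean()
            assert m1 < m2

    def test_perfect_separation_at_zero_noise(self, dataset_clean):
        ds = dataset_clean
        sigs = [(GeneSet("c13", set(ds.gene_clusters[13])), -1.0),
                (GeneSet("c14", set(ds.gene_clusters[14])), 1.0),
                (GeneSet("c3", set(ds.gene_clusters[3])), 2.0)]
        cs = composite_score(ds.matrix, sigs)
        s = cs.as_series()
        lab = s.index.isin(ds.annotation.index)
        auc_m1 = evaluate_auc(s[lab].to_numpy(),
                              (ds.annotation.reindex(s.index[lab]) == "M1"))
        assert 1.0 - auc_m1 == pytest.approx(1.0)  # M1 at the low end

    def test_calls_follow_threshold_and_margin(self):
        cs = CompositeScore(sample_ids=list("abcd"),
                            score=np.array([-2.0, 0.1, 0.4, 2.0]),
                            threshold=0.25, margin=0.5)
        assert cs.calls == ["REACTIVE", "INTERMEDIATE", "INTERMEDIATE",
                            "TOLERANT"]

    def test_ordering_recovers_monotone_gradient(self, rng):
        # samples move linearly from reactive to tolerant latent state
        t = np.linspace(0, 1, 60)
        genes, rows = [], []
        for i in range(10):
            rows.append(4 + 4 * (1 - t) + rng.normal(0, 0.25, 60))
            genes.append(f"R{i}")
        for i in range(10):
            rows.append(4 + 4 * t + rng.normal(0, 0.25, 60))
            genes.append(f"T{i}")
        em = ExpressionMatrix(pd.DataFrame(
            np.vstack(rows), index=genes,
            columns=[f"s{i}" for i in range(60)]))
        sigs = [(GeneSet("r", {f"R{i}" for i in range(10)}), -1.0),
                (GeneSet("t", {f"T{i}" for i in range(10)}), 1.0)]
        cs = composite_score(em, sigs)
        rho = sps.spearmanr(cs.score, t).statistic
        assert rho >= 0.9


class TestEvaluateAuc:
    def test_perfect_separation(self):
        assert evaluate_auc([1, 2, 3, 10, 11], [0, 0, 0, 1, 1]) == 1.0

    def test_null_labels_near_half(self, rng):
        s = rng.normal(size=4000)
        y = rng.integers(0, 2, 4000)
        assert abs(evaluate_auc(s, y) - 0.5) < 0.05

    def test_matches_pair_counting_small_n(self, rng):
        for _ in range(100):
            n = int(rng.integers(4, 13))
            scores = rng.integers(0, 5, n).astype(float)  # force ties
            labels = np.zeros(n, dtype=bool)
            labels[rng.choice(n, int(rng.integers(1, n)), replace=False)] = True
            if labels.all() or not labels.any():
                continue
            assert evaluate_auc(scores, labels) == pytest.approx(
                brute_force_auc(scores, labels))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate_auc([1, 2], [1, 1])


def hand_logrank(times, events, groups):
    """Textbook observed-minus-expected log-rank statistic."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    groups = np.asarray(groups, int)
    o_minus_e, var = 0.0, 0.0
    for t in sorted(set(times[events == 1])):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (groups == 1)).sum()
        d = ((times == t) & (events == 1)).sum()
        d1 = ((times == t) & (events == 1) & (groups == 1)).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    return o_minus_e ** 2 / var


class TestStratifySurvival:
    def _cs(self, scores, threshold, margin=0.0):
        return CompositeScore(sample_ids=[f"s{i}" for i in range(len(scores))],
                              score=np.asarray(scores, float),
                              threshold=threshold, margin=margin)

    def _cohort(self, times, events):
        return pd.DataFrame({"sample": [f"s{i}" for i in range(len(times))],
                             "time": times, "event": events})

    def test_identical_survival_groups(self, rng):
        times = np.tile(rng.exponential(5, 30), 2)
        events = np.ones(60, int)
        scores = np.r_[np.zeros(30), np.ones(30)]
        res = stratify_survival(self._cs(scores, 0.5), self._cohort(times, events))
        assert res.p_value > 0.9
        assert res.statistic == pytest.approx(0.0, abs=1e-6)

    def test_doubled_hazard_detected(self, rng):
        n = 200
        scores = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        rates = np.where(scores > 0.5, 0.2, 0.1)
        times = rng.exponential(1 / rates)
        res = stratify_survival(self._cs(scores, 0.5),
                                self._cohort(times, np.ones(n, int)))
        assert res.p_value < 0.01

    def test_matches_hand_logrank_on_toy(self):
        times = [1.0, 2.0, 3.0, 4.0]
        events = [1, 1, 1, 1]
        scores = [0.0, 1.0, 0.0, 1.0]
        res = stratify_survival(self._cs(scores, 0.5),
                                self._cohort(times, events))
        expected = hand_logrank(times, events, [0, 1, 0, 1])
        assert res.statistic == pytest.approx(expected, rel=1e-6)

    def test_three_candidates_reported(self, rng):
        scores = rng.normal(size=40)
        cs = self._cs(scores, 0.0, margin=0.3)
        res = stratify_survival(cs, self._cohort(rng.exponential(5, 40),
                                                 np.ones(40, int)))
        assert set(res.candidate_p) == {"threshold", "threshold-margin",
                                        "threshold+margin"}

    def test_all_candidates_empty_is_error(self):
        cs = self._cs([1.0, 1.0, 1.0, 1.0], 5.0)
        with pytest.raises(ValueError):
            stratify_survival(cs, self._cohort([1, 2, 3, 4], [1, 1, 1, 1]))


class TestCircadianNormalize:
    def test_perfect_trend_removed(self):
        clock = np.linspace(0, 4, 20)
        score = 2.0 * clock + 1.0
        out = circadian_normalize(score, clock, np.zeros(20))
        assert np.ptp(out) == pytest.approx(0.0, abs=1e-9)

    def test_uncorrelated_clock_preserves_order(self, rng):
        score = rng.normal(0, 1, 100)
        clock = rng.normal(5, 1, 100)
        groups = np.r_[np.zeros(50), np.ones(50)]
        out = circadian_normalize(score, clock, groups)
        rho = sps.spearmanr(out, score).statistic
        assert rho >= 0.95

    def test_zero_range_group_skipped(self, caplog):
        score = np.array([1.0, 1.0, 0.0, 2.0])
        clock = np.array([3.0, 4.0, 1.0, 5.0])
        out = circadian_normalize(score, clock, np.array([0, 0, 1, 1]))
        assert np.isfinite(out).all()

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            circadian_normalize([1.0], [1.0, 2.0], [0, 0])
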