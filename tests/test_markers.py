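import numpy as np
import pytest

from nephroscope import markers, preprocess, simulate
from nephroscope.clustering import ClusterAssignment
from nephroscope.io import ExpressionMatrix
from nephroscope.markers import (
    ParameterError,
    gene_auroc,
    l1_sparsity_path,
    predict_id_scores,
    proliferation_score,
    select_markers,
    train_id_classifier,
)


def sweep_auroc(pos, neg):
    """Independent oracle: explicit threshold sweep, trapezoidal ROC area."""
    vals = np.concatenate([pos, neg])
    thresholds = np.concatenate([[-np.inf], np.sort(np.unique(vals)), [np.inf]])
    tpr, fpr = [], []
    for t in thresholds[::-1]:
        tpr.append((pos > t).mean())
        fpr.append((neg > t).mean())
    return float(np.trapezoid(tpr, fpr))


def ft_expr(vals):
    vals = np.asarray(vals, dtype=float)
    return ExpressionMatrix([f"g{i}" for i in range(vals.shape[0])],
                            [f"c{j}" for j in range(vals.shape[1])], vals, "freeman_tukey")


class TestGeneAuroc:
    def test_perfect_separation(self):
        x = ft_expr([[5.0, 6.0, 7.0, 1.0, 1.0, 1.0]])
        asg = ClusterAssignment([f"c{j}" for j in range(6)], np.array([0, 0, 0, 1, 1, 1]))
        coi, auc = gene_auroc(x, asg, "g0")
        assert coi == 0
        assert auc == pytest.approx(1.0)

    def test_constant_gene_is_half(self):
        x = ft_expr([[2.0] * 6])
        asg = ClusterAssignment([f"c{j}" for j in range(6)], np.array([0, 0, 0, 1, 1, 1]))
        _, auc = gene_auroc(x, asg, "g0")
        assert auc == pytest.approx(0.5)

    def test_toy_matches_threshold_sweep(self):
        pos = np.array([3.0, 5.0, 4.0])
        neg = np.array([1.0, 2.0, 3.0])
        x = ft_expr([np.concatenate([pos, neg])])
        asg = ClusterAssignment([f"c{j}" for j in range(6)], np.array([0, 0, 0, 1, 1, 1]))
        _, auc = gene_auroc(x, asg, "g0")
        assert auc == pytest.approx(sweep_auroc(pos, neg), abs=1e-12)

    def test_rank_formula_equals_sweep_on_random_instances(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n1 = rng.integers(2, 16)
            n0 = rng.integers(2, 16)
            pos = rng.integers(0, 6, n1).astype(float)
            neg = rng.integers(0, 6, n0).astype(float)
            got = markers._rank_auroc(pos, neg)
            assert got == pytest.approx(sweep_auroc(pos, neg), abs=1e-12)

    def test_single_cluster_raises(self):
        x = ft_expr([[1.0, 2.0]])
        asg = ClusterAssignment(["c0", "c1"], np.array([0, 0]))
        with pytest.raises(ParameterError):
            gene_auroc(x, asg, "g0")


class TestSelectMarkers:
    def _fixture(self):
        """3 clusters x 30 cells; g0 perfect marker of cluster 0, g1 borderline."""
        rng = np.random.default_rng(1)
        n = 90
        labels = np.repeat([0, 1, 2], 30)
        vals = rng.uniform(1.0, 1.4, (6, n))  # FT-scale baseline, "detected" > 1
        vals[0, labels == 0] = rng.uniform(3.0, 5.0, 30)  # exclusive marker
        x = ft_expr(vals)
        return x, ClusterAssignment(list(x.cells), labels)

    def test_planted_exclusive_marker_selected(self):
        x, asg = self._fixture()
        recs = select_markers(x, asg)
        rec = next(r for r in recs if r.gene == "g0")
        assert rec.coi == 0 and rec.selected and all(rec.passes)

    def test_auroc_exactly_at_threshold_not_candidate(self):
        x, asg = self._fixture()
        recs = select_markers(x, asg, auroc_min=1.0)  # even AUROC 1.0 must fail ">"
        rec = next(r for r in recs if r.gene == "g0")
        assert rec.auroc == pytest.approx(1.0)
        assert not rec.passes[0] and not rec.selected

    def test_top_k_cap(self):
        """A cluster with 6 qualifying genes keeps only the 4 best by AUROC."""
        rng = np.random.default_rng(2)
        labels = np.repeat([0, 1], 40)
        vals = rng.uniform(1.0, 1.2, (8, 80))
        # genes 0..5 all mark cluster 0, with decreasing separation
        for g in range(6):
            vals[g, labels == 0] = rng.uniform(3.0 - 0.2 * g, 4.0 - 0.2 * g, 40)
        x = ft_expr(vals)
        asg = ClusterAssignment(list(x.cells), labels)
        recs = select_markers(x, asg)
        sel0 = [r for r in recs if r.selected and r.coi == 0]
        cand0 = [r for r in recs if all(r.passes) and r.coi == 0]
        assert len(cand0) == 6
        assert len(sel0) == 4
        worst_sel = min(r.auroc for r in sel0)
        best_unsel = max(r.auroc for r in cand0 if not r.selected)
        assert worst_sel >= best_unsel

    def test_selected_flags_audited(self):
        spec = simulate.CountSimSpec(n_clusters=10, cells_per_cluster=100,
                                     n_genes=1000, marker_fold=8.0,
                                     n_program_factors=0, seed=23)
        cm, gt = simulate.generate_counts(spec)
        sm = preprocess.knn_smooth(cm, k=10, seed=0)
        ft = preprocess.freeman_tukey(
            preprocess.normalize(sm, preprocess.library_size_factors(sm)))
        asg = ClusterAssignment(list(cm.cells), gt.cluster)
        recs = select_markers(ft, asg)
        per_cluster: dict = {}
        for r in recs:
            if r.selected:
                assert all(r.passes) and r.rank_in_coi <= 4
                per_cluster[r.coi] = per_cluster.get(r.coi, 0) + 1
        assert all(v <= 4 for v in per_cluster.values())
        # planted markers that meet the criteria are recovered
        planted = {g for gs in gt.marker_genes.values() for g in gs}
        qualifying = {r.gene for r in recs if r.gene in planted and all(r.passes)}
        selected = {r.gene for r in recs if r.selected}
        assert len(qualifying & selected) / max(len(qualifying), 1) >= 0.95


class TestProliferationScore:
    def test_constant_gene_contributes_zero(self):
        x = ft_expr(np.ones((1, 6)) * 2.0)
        x.genes = ["PROLIF1"]
        asg = ClusterAssignment(list(x.cells), np.array([0, 0, 1, 1, 2, 2]))
        s = proliferation_score(x, asg, ["PROLIF1"])
        np.testing.assert_allclose(s.to_numpy(), 0.0)

    def test_planted_proliferative_cluster_scores_highest(self):
        spec = simulate.CountSimSpec(n_clusters=4, cells_per_cluster=80, n_genes=600,
                                     proliferative_cluster=2, proliferation_fold=4.0,
                                     seed=19)
        cm, gt = simulate.generate_counts(spec)
        ft = preprocess.freeman_tukey(
            preprocess.normalize(cm, preprocess.library_size_factors(cm)))
        asg = ClusterAssignment(list(cm.cells), gt.cluster)
        s = proliferation_score(ft, asg, [f"PROLIF{i+1}" for i in range(10)])
        assert s.idxmax() == 2

    def test_scores_average_to_zero(self):
        rng = np.random.default_rng(3)
        x = ft_expr(rng.uniform(1, 3, (5, 30)))
        x.genes = [f"PROLIF{i+1}" for i in range(5)]
        asg = ClusterAssignment(list(x.cells), np.repeat([0, 1, 2], 10))
        s = proliferation_score(x, asg, x.genes)
        assert s.mean() == pytest.approx(0.0, abs=1e-12)

    def test_all_missing_raises(self):
        x = ft_expr(np.ones((2, 4)))
        asg = ClusterAssignment(list(x.cells), np.array([0, 0, 1, 1]))
        with pytest.raises(ParameterError):
            proliferation_score(x, asg, ["NOPE"])


def two_blob_expression(rng, n_per=60, n_genes=40, sep=3.0):
    labels = np.repeat([0, 1], n_per)
    vals = rng.normal(0, 1, (n_genes, 2 * n_per))
    vals[:10, labels == 1] += sep
    return ft_expr(np.abs(vals) + 1.0), labels


class TestIdClassifier:
    def test_separable_blobs_perfect_heldout_accuracy(self):
        rng = np.random.default_rng(4)
        x, labels = two_blob_expression(rng)
        train = np.arange(0, 120, 2)
        test = np.arange(1, 120, 2)
        xt = ExpressionMatrix(x.genes, [x.cells[i] for i in train],
                              x.values[:, train], "freeman_tukey")
        xs = ExpressionMatrix(x.genes, [x.cells[i] for i in test],
                              x.values[:, test], "freeman_tukey")
        model = train_id_classifier(xt, labels[train], n_hvg=40, folds=5, seed=0)
        res = predict_id_scores(model, xs)
        assert (res.assigned == labels[test]).mean() == 1.0
        np.testing.assert_allclose(res.probabilities.sum(axis=1), 1.0)

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(5)
        x, labels = two_blob_expression(rng, sep=3.0)
        perm = rng.permutation(labels)
        train = np.arange(0, 120, 2)
        test = np.arange(1, 120, 2)
        xt = ExpressionMatrix(x.genes, [x.cells[i] for i in train],
                              x.values[:, train], "freeman_tukey")
        xs = ExpressionMatrix(x.genes, [x.cells[i] for i in test],
                              x.values[:, test], "freeman_tukey")
        model = train_id_classifier(xt, perm[train], n_hvg=40, folds=5, seed=0)
        res = predict_id_scores(model, xs)
        acc = (res.assigned == perm[test]).mean()
        assert abs(acc - 0.5) < 0.2  # binomial noise around chance

    def test_l1_path_sparsity_monotone(self):
        rng = np.random.default_rng(6)
        x, labels = two_blob_expression(rng)
        counts = l1_sparsity_path(x, labels, Cs=[0.005, 0.1, 10.0], seed=0)
        assert counts == sorted(counts)

    def test_id_score_is_max_probability(self):
        rng = np.random.default_rng(7)
        x, labels = two_blob_expression(rng)
        model = train_id_classifier(x, labels, n_hvg=40, folds=4, seed=0)
        res = predict_id_scores(model, x)
        np.testing.assert_allclose(res.id_score,
                                   res.probabilities.max(axis=1))
        assert (res.id_score >= 0.5).all()  # two classes: max prob >= 1/2
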