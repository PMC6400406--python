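"""AUROC-based marker-gene selection, proliferation scoring, and the
multinomial "id score" classifier.

For each gene, the *cluster of interest* (COI) is the cluster with the
highest mean expression.  A single-gene threshold classifier for COI
membership traces an ROC as the threshold sweeps the expression range; its
area (AUROC) is computed by the rank (Mann-Whitney) formula with midranks
for ties, which is identical to the threshold sweep.  A gene is a marker
candidate when all four criteria hold:

1. AUROC strictly exceeding ``auroc_min`` (default 0.8);
2. detected (nonzero) in at least ``detect_min`` (80%) of COI cells;
3. mean expression in the COI at least ``mean_min`` (1.5, on the
   variance-stabilized scale);
4. significantly expressed — above the COI's 25th expression percentile —
   in at most ``outside_max`` (25%) of the cells outside the COI.

Per cluster the top ``top_k`` (4) candidates by AUROC form the marker set.

The id-score classifier is an L1-penalized multinomial logistic regression
on the top highly variable genes, its penalty chosen by cross-validated
deviance; a cell's id score is its maximum predicted class probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression, LogisticRegressionCV
from sklearn.preprocessing import StandardScaler

from .clustering import ClusterAssignment, cluster_profile
from .io import ExpressionMatrix

_FT_ZERO = 1.0  # Freeman-Tukey image of a zero count


class ParameterError(ValueError):
    pass


@dataclass
class MarkerRecord:
    gene: str
    coi: object
    auroc: float
    detect_frac_coi: float
    mean_coi: float
    sig_frac_outside: float
    passes: tuple[bool, bool, bool, bool]
    selected: bool
    rank_in_coi: int

    def as_dict(self) -> dict:
        d = self.__dict__.copy()
        d["pass_auroc"], d["pass_detect"], d["pass_mean"], d["pass_outside"] = d.pop("passes")
        return d


@dataclass
class ClassifierModel:
    classes: list
    genes: list[str]            # feature genes, in training order
    coefficients: np.ndarray    # (n_classes, n_genes)
    intercepts: np.ndarray
    scaler_mean: np.ndarray
    scaler_scale: np.ndarray
    shrinkage: float            # selected inverse regularization C
    cv_folds: int

    @property
    def classifier_genes(self) -> list[str]:
        nz = np.any(self.coefficients != 0, axis=0)
        return [g for g, m in zip(self.genes, nz) if m]


@dataclass
class IdScoreResult:
    cells: list[str]
    classes: list
    probabilities: np.ndarray  # (n_cells, n_classes)

    @property
    def assigned(self) -> np.ndarray:
        return np.asarray(self.classes, dtype=object)[self.probabilities.argmax(axis=1)]

    @property
    def id_score(self) -> np.ndarray:
        return self.probabilities.max(axis=1)


def _rank_auroc(pos: np.ndarray, neg: np.ndarray) -> float:
    """Mann-Whitney AUROC with midranks; equals the threshold-sweep ROC area."""
    n1, n0 = pos.size, neg.size
    if n1 == 0 or n0 == 0:
        raise ParameterError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    r1 = ranks[:n1].sum()
    return float((r1 - n1 * (n1 + 1) / 2) / (n1 * n0))


def gene_auroc(x: ExpressionMatrix, assign: ClusterAssignment, gene: str) -> tuple[object, float]:
    """COI and AUROC of the single-gene COI-membership classifier."""
    uniq = np.unique(assign.labels)
    if uniq.size < 2:
        raise ParameterError("need at least 2 clusters")
    gi = x.gene_index([gene])
    if gi.size == 0:
        raise ParameterError(f"gene {gene!r} not in matrix")
    v = x.values[gi[0]]
    means = np.array([v[assign.labels == lab].mean() for lab in uniq])
    coi = uniq[int(means.argmax())]
    in_coi = assign.labels == coi
    return coi, _rank_auroc(v[in_coi], v[~in_coi])


def select_markers(
    x: ExpressionMatrix,
    assign: ClusterAssignment,
    auroc_min: float = 0.8,
    detect_min: float = 0.80,
    mean_min: float = 1.5,
    outside_max: float = 0.25,
    top_k: int = 4,
) -> list[MarkerRecord]:
    """Four-criterion AUROC marker selection with per-cluster top-k ranking.

    Expects variance-stabilized (Freeman-Tukey) expression: detection is
    "value above the transform's image of zero".  Candidates are ranked per
    COI by AUROC descending (ties by detection fraction, then COI mean,
    then gene name) and the top ``top_k`` per cluster are selected.
    """
    if list(assign.cells) != list(x.cells):
        raise ParameterError("assignment does not match the matrix cells")
    labels = assign.labels
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ParameterError("need at least 2 clusters")
    detect_thr = _FT_ZERO if x.transform_tag == "freeman_tukey" else 0.0

    masks = {lab: labels == lab for lab in uniq}
    mean_by_cluster = np.stack([x.values[:, m].mean(axis=1) for m in masks.values()])
    coi_idx = mean_by_cluster.argmax(axis=0)

    records: list[MarkerRecord] = []
    # rank all cells once per gene: vectorized midranks along the cell axis
    ranks = rankdata(x.values, axis=1)
    for g in range(x.n_genes):
        coi = uniq[coi_idx[g]]
        m = masks[coi]
        n1, n0 = int(m.sum()), int((~m).sum())
        v = x.values[g]
        auroc = float((ranks[g][m].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))
        detect = float((v[m] > detect_thr).mean())
        mean_coi = float(v[m].mean())
        q25 = float(np.percentile(v[m], 25))
        outside = float((v[~m] > q25).mean())
        passes = (auroc > auroc_min, detect >= detect_min,
                  mean_coi >= mean_min, outside <= outside_max)
        records.append(MarkerRecord(x.genes[g], coi, auroc, detect, mean_coi,
                                    outside, passes, False, 0))

    for lab in uniq:
        cands = [r for r in records if r.coi == lab and all(r.passes)]
        cands.sort(key=lambda r: (-r.auroc, -r.detect_frac_coi, -r.mean_coi, r.gene))
        for i, r in enumerate(cands):
            r.rank_in_coi = i + 1
            r.selected = i < top_k
    return records


def markers_table(records: list[MarkerRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.as_dict() for r in records]).set_index("gene")


def proliferation_score(
    x: ExpressionMatrix,
    assign: ClusterAssignment,
    proliferation_markers: list[str],
) -> pd.Series:
    """Mean Z-scored proliferation-marker expression per cluster.

    Each marker's cluster means are standardized across clusters; the score
    is the mean Z over the marker list.  Constant genes contribute 0; marker
    genes missing from the matrix are skipped with a warning.
    """
    present = [g for g in proliferation_markers if g.upper() in {s.upper() for s in x.genes}]
    missing = set(proliferation_markers) - set(present)
    if not present:
        raise ParameterError("none of the proliferation markers are in the matrix")
    if missing:
        warnings.warn(f"proliferation markers not in matrix: {sorted(missing)}")
    prof = cluster_profile(x, assign, genes=present)
    score = prof.zscores.mean(axis=1)
    return pd.Series(score, index=pd.Index(prof.clusters, name="cluster"), name="proliferation_score")


def train_id_classifier(
    x_train: ExpressionMatrix,
    labels: np.ndarray,
    n_hvg: int = 500,
    folds: int = 20,
    seed: int = 0,
    Cs: int | list[float] = 10,
) -> ClassifierModel:
    """L1-penalized multinomial logistic regression with CV-chosen penalty.

    Features are the ``n_hvg`` most variable genes of the training matrix
    (by CV² excess over the a + b/mu trend), standardized.  ``folds`` is
    reduced with a warning when the smallest class has fewer members.
    """
    from .preprocess import select_hvg

    labels = np.asarray(labels)
    classes, counts = np.unique(labels, return_counts=True)
    if classes.size < 2:
        raise ParameterError("need at least 2 classes")
    min_class = int(counts.min())
    if min_class < folds:
        warnings.warn(f"smallest class has {min_class} members; reducing folds from {folds}")
        folds = max(2, min_class)

    n_hvg = min(n_hvg, x_train.n_genes)
    hvg = select_hvg(x_train, fraction=n_hvg / max(1, int(x_train.n_genes)))
    genes = hvg.selected[:n_hvg] if len(hvg.selected) >= n_hvg else hvg.selected
    if not genes:
        genes = list(x_train.genes)
    gi = x_train.gene_index(genes)
    feats = x_train.values[gi].T  # cells x genes

    scaler = StandardScaler().fit(feats)
    z = scaler.transform(feats)
    clf = LogisticRegressionCV(
        Cs=Cs, cv=folds, penalty="l1", solver="saga", max_iter=5000,
        scoring="neg_log_loss", random_state=seed, tol=1e-4,
    ).fit(z, labels)
    return ClassifierModel(
        classes=clf.classes_.tolist(),
        genes=[x_train.genes[i] for i in gi],
        coefficients=np.atleast_2d(clf.coef_),
        intercepts=np.atleast_1d(clf.intercept_),
        scaler_mean=scaler.mean_,
        scaler_scale=scaler.scale_,
        shrinkage=float(np.atleast_1d(clf.C_)[0]),
        cv_folds=folds,
    )


def predict_id_scores(model: ClassifierModel, x_test: ExpressionMatrix) -> IdScoreResult:
    """Class probabilities, assignment, and id score per test cell.

    Model genes missing from the test matrix are imputed as zero expression
    (with a warning).
    """
    lookup = {g.upper(): i for i, g in enumerate(x_test.genes)}
    feats = np.zeros((x_test.n_cells, len(model.genes)))
    missing = []
    for j, g in enumerate(model.genes):
        i = lookup.get(g.upper())
        if i is None:
            missing.append(g)
        else:
            feats[:, j] = x_test.values[i]
    if missing:
        warnings.warn(f"{len(missing)} model genes missing from test matrix; imputed as 0")
    z = (feats - model.scaler_mean) / model.scaler_scale
    logits = z @ model.coefficients.T + model.intercepts
    if len(model.classes) == 2 and model.coefficients.shape[0] == 1:
        p1 = 1.0 / (1.0 + np.exp(-logits[:, 0]))
        probs = np.column_stack([1 - p1, p1])
    else:
        logits -= logits.max(axis=1, keepdims=True)
        e = np.exp(logits)
        probs = e / e.sum(axis=1, keepdims=True)
    return IdScoreResult(list(x_test.cells), model.classes, probs)


def l1_sparsity_path(
    x: ExpressionMatrix,
    labels: np.ndarray,
    Cs: list[float],
    seed: int = 0,
) -> list[int]:
    """Number of genes with any nonzero weight along an L1 penalty path."""
    feats = StandardScaler().fit_transform(x.values.T)
    out = []
    for c in Cs:
        clf = LogisticRegression(penalty="l1", solver="saga", C=c, max_iter=5000,
                                 random_state=seed, tol=1e-5).fit(feats, labels)
        out.append(int(np.any(np.atleast_2d(clf.coef_) != 0, axis=0).sum()))
    return out
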