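"""Admixture-style ancestry estimation and discriminant analysis of principal components.

Ancestry proportions are estimated with a masked, simplex-constrained
nonnegative matrix factorization — an analogue of the sNMF approach, not
a port of it. Genotypes are one-hot encoded into per-locus 3-state
frequencies X (n x 3m); the model X ~ Q G factorizes them into per-sample
ancestry proportions Q (rows on the simplex) and per-cluster ancestral
genotype frequencies G (each cluster's 3-state block per locus on the
simplex). Missing calls are masked out of the loss. Optimisation is block
projected-gradient descent with Lipschitz step sizes and backtracking, so
the penalised loss is non-increasing across iterations. The number of
clusters K is chosen by masked-prediction cross-entropy: a fraction of
observed calls is hidden, the model fit without them, and K scored by how
well it predicts the hidden genotypes.

DAPC (discriminant analysis of principal components) first reduces
mean-imputed, centred genotypes to ``n_pcs`` principal components, then
runs linear discriminant analysis on the population labels. The number
of PCs to retain is chosen by stratified cross-validation of the
reassignment rate.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin, TransformerMixin
from sklearn.decomposition import PCA
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.utils.validation import check_is_fitted

from .genotype_io import MISSING, GenotypeMatrix, PopulationMap

logger = logging.getLogger(__name__)

__all__ = [
    "AncestryNMF",
    "AncestryResult",
    "DAPC",
    "DapcResult",
    "estimate_ancestry",
    "select_k",
    "dapc",
    "crossvalidate_pcs",
]


# ---------------------------------------------------------------------------
# ancestry (masked NMF)
# ---------------------------------------------------------------------------


@dataclass
class AncestryResult:
    Q: np.ndarray               # (n, K) ancestry proportions
    G_freq: np.ndarray          # (K, 3m) ancestral genotype frequencies
    K: int
    cross_entropy: float        # masked-prediction loss (training entries)
    seed: int


def _codes_of(data: GenotypeMatrix | np.ndarray) -> np.ndarray:
    if isinstance(data, GenotypeMatrix):
        return data.calls
    return np.asarray(data)


def _one_hot(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """One-hot encode codes into (n, 3m) X with observation mask W."""
    n, m = codes.shape
    X = np.zeros((n, 3 * m))
    W = np.zeros((n, 3 * m))
    obs = codes != MISSING
    rows, cols = np.nonzero(obs)
    X[rows, 3 * cols + codes[rows, cols]] = 1.0
    for k in range(3):
        W[rows, 3 * cols + k] = 1.0
    return X, W


def _project_rows_simplex(v: np.ndarray) -> np.ndarray:
    """Euclidean projection of each row onto the probability simplex."""
    n, k = v.shape
    u = np.sort(v, axis=1)[:, ::-1]
    css = np.cumsum(u, axis=1) - 1.0
    ind = np.arange(1, k + 1)
    cond = u - css / ind > 0
    rho = k - np.argmax(cond[:, ::-1], axis=1) - 1
    # rows where cond is all False cannot occur for finite input
    lam = css[np.arange(n), rho] / (rho + 1.0)
    return np.maximum(v - lam[:, None], 0.0)


def _project_freq_blocks(G: np.ndarray) -> np.ndarray:
    """Project each per-locus 3-state block of each cluster onto the simplex."""
    k, threem = G.shape
    blocks = G.reshape(k, threem // 3, 3).reshape(-1, 3)
    return _project_rows_simplex(blocks).reshape(k, threem // 3, 3).reshape(k, threem)


class AncestryNMF(BaseEstimator, TransformerMixin):
    """Masked nonnegative matrix factorization of one-hot genotypes.

    Parameters
    ----------
    n_components : int
        Number of ancestral clusters K.
    alpha : float, default 10.0
        Ridge penalty on Q, regularising ancestry proportions toward
        balanced membership when the data are uninformative.
    max_iter : int, default 500
    tol : float, default 1e-6
        Relative penalised-loss change below which iteration stops.
    random_state : int, default 0

    Attributes
    ----------
    Q_ : ndarray (n, K)
        Ancestry proportions, rows summing to 1.
    components_ : ndarray (K, 3m)
        Ancestral genotype frequencies, each 3-state block summing to 1.
    loss_curve_ : list of float
        Penalised loss after each iteration; non-increasing.
    cross_entropy_ : float
        Mean negative log-probability of the observed genotypes.
    """

    def __init__(
        self,
        n_components: int = 2,
        alpha: float = 10.0,
        max_iter: int = 500,
        tol: float = 1e-6,
        random_state: int = 0,
    ) -> None:
        self.n_components = n_components
        self.alpha = alpha
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    # -- internal ----------------------------------------------------------

    def _loss(self, X: np.ndarray, W: np.ndarray, Q: np.ndarray, G: np.ndarray) -> float:
        R = W * (Q @ G - X)
        return float((R**2).sum() + self.alpha * (Q**2).sum())

    def fit(self, X: GenotypeMatrix | np.ndarray, y: object = None) -> "AncestryNMF":
        codes = _codes_of(X)
        n, m = codes.shape
        K = self.n_components
        if K < 1:
            raise ValueError("n_components must be >= 1")
        if K > n:
            raise ValueError(f"n_components={K} exceeds n_samples={n}")
        Xoh, W = _one_hot(codes)
        rng = np.random.default_rng(self.random_state)

        # uniform start keeps the fit equivariant under sample reordering;
        # the symmetric start is broken by the randomised G init below
        Q = np.full((n, K), 1.0 / K)
        # start clusters at perturbed empirical genotype frequencies
        with np.errstate(invalid="ignore"):
            emp = np.where(W.sum(axis=0) > 0, Xoh.sum(axis=0) / np.maximum(W.sum(axis=0), 1), 1 / 3)
        G = np.clip(emp[None, :] + 0.05 * rng.standard_normal((K, 3 * m)), 1e-3, None)
        G = _project_freq_blocks(G)

        loss = self._loss(Xoh, W, Q, G)
        self.loss_curve_ = [loss]
        for it in range(self.max_iter):
            # Q block: projected gradient, Lipschitz step with backtracking
            GGt = G @ G.T
            L_q = 2.0 * (np.linalg.eigvalsh(GGt)[-1] + self.alpha) + 1e-12
            grad_q = 2.0 * ((W * (Q @ G - Xoh)) @ G.T) + 2.0 * self.alpha * Q
            step = 1.0 / L_q
            for _ in range(20):
                Q_new = _project_rows_simplex(Q - step * grad_q)
                new_loss = self._loss(Xoh, W, Q_new, G)
                if new_loss <= loss + 1e-10:
                    break
                step *= 0.5
            Q, loss = Q_new, min(new_loss, loss)

            # G block
            QtQ = Q.T @ Q
            L_g = 2.0 * np.linalg.eigvalsh(QtQ)[-1] + 1e-12
            grad_g = 2.0 * (Q.T @ (W * (Q @ G - Xoh)))
            step = 1.0 / L_g
            for _ in range(20):
                G_new = _project_freq_blocks(G - step * grad_g)
                new_loss = self._loss(Xoh, W, Q, G_new)
                if new_loss <= loss + 1e-10:
                    break
                step *= 0.5
            G, prev = G_new, loss
            loss = min(new_loss, loss)
            self.loss_curve_.append(loss)
            if prev > 0 and (prev - loss) / prev < self.tol:
                break

        order = self._cluster_order(Q)
        self.Q_ = Q[:, order]
        self.components_ = G[order]
        self.n_iter_ = len(self.loss_curve_) - 1
        self.cross_entropy_ = masked_cross_entropy(
            self.Q_, self.components_, codes, codes != MISSING
        )
        return self

    @staticmethod
    def _cluster_order(Q: np.ndarray) -> np.ndarray:
        """Order clusters by the first sample index at which they are modal."""
        modal = Q.argmax(axis=1)
        first = np.full(Q.shape[1], Q.shape[0] + 1)
        for i, k in enumerate(modal):
            if first[k] > Q.shape[0]:
                first[k] = i
        return np.argsort(first, kind="stable")

    def transform(self, X: GenotypeMatrix | np.ndarray) -> np.ndarray:
        check_is_fitted(self, "Q_")
        return self.Q_

    def result(self) -> AncestryResult:
        check_is_fitted(self, "Q_")
        return AncestryResult(
            Q=self.Q_,
            G_freq=self.components_,
            K=self.n_components,
            cross_entropy=self.cross_entropy_,
            seed=self.random_state,
        )


def masked_cross_entropy(
    Q: np.ndarray, G: np.ndarray, codes: np.ndarray, entry_mask: np.ndarray
) -> float:
    """Mean -log P(observed genotype) over masked-in entries.

    Predicted per-locus 3-state probabilities come from Q G, clipped and
    renormalised per locus.
    """
    n, m = codes.shape
    P = Q @ G
    P = P.reshape(n, m, 3)
    P = np.clip(P, 1e-9, None)
    P = P / P.sum(axis=2, keepdims=True)
    rows, cols = np.nonzero(entry_mask & (codes != MISSING))
    if rows.size == 0:
        raise ValueError("no entries to score")
    probs = P[rows, cols, codes[rows, cols]]
    return float(-np.log(probs).mean())


def estimate_ancestry(
    gm: GenotypeMatrix | np.ndarray,
    K: int,
    seed: int = 0,
    alpha: float = 10.0,
    **kwargs,
) -> AncestryResult:
    """Fit ancestry proportions for K clusters (thin estimator wrapper)."""
    est = AncestryNMF(n_components=K, alpha=alpha, random_state=seed, **kwargs)
    est.fit(gm)
    return est.result()


def select_k(
    gm: GenotypeMatrix | np.ndarray,
    K_range: list[int] | range,
    seed: int = 0,
    holdout_fraction: float = 0.05,
    n_reps: int = 5,
    alpha: float = 10.0,
    max_iter: int = 200,
) -> tuple[int, dict[int, float]]:
    """Choose K by masked-prediction cross-entropy.

    For each of ``n_reps`` replicates a ``holdout_fraction`` of the
    observed calls is hidden, each K is fit on the remainder and scored
    on the hidden entries; curves are averaged and the smallest K
    attaining the minimum is returned.
    """
    codes = _codes_of(gm)
    K_list = sorted(set(int(k) for k in K_range))
    if not K_list:
        raise ValueError("K_range is empty")
    rng = np.random.default_rng(seed)
    curves = np.zeros((n_reps, len(K_list)))
    for rep in range(n_reps):
        mask = _draw_holdout(codes, holdout_fraction, rng)
        train = codes.copy()
        train[mask] = MISSING
        for ki, K in enumerate(K_list):
            est = AncestryNMF(
                n_components=K,
                alpha=alpha,
                max_iter=max_iter,
                random_state=int(rng.integers(2**31 - 1)),
            ).fit(train)
            curves[rep, ki] = masked_cross_entropy(est.Q_, est.components_, codes, mask)
    mean_curve = dict(zip(K_list, curves.mean(axis=0)))
    best = min(mean_curve, key=lambda k: (round(mean_curve[k], 12), k))
    return best, mean_curve


def _draw_holdout(
    codes: np.ndarray, fraction: float, rng: np.random.Generator, max_tries: int = 10
) -> np.ndarray:
    obs = codes != MISSING
    for _ in range(max_tries):
        mask = obs & (rng.random(codes.shape) < fraction)
        remaining = obs & ~mask
        if remaining.sum(axis=0).min() >= 1 and mask.any():
            return mask
    raise RuntimeError("could not draw a holdout mask leaving every locus observed")


# ---------------------------------------------------------------------------
# DAPC
# ---------------------------------------------------------------------------


@dataclass
class DapcResult:
    n_pcs: int
    discriminants: np.ndarray       # (n, n_axes) sample scores
    axis_variance: np.ndarray       # per-axis share of discriminable variance
    group_centroids: dict[str, np.ndarray]
    populations: list[str]


class DAPC(BaseEstimator, ClassifierMixin):
    """Discriminant analysis of principal components.

    Mean-imputes missing genotype codes per locus, centres, projects to
    ``n_pcs`` principal components, then fits linear discriminant
    analysis on the population labels. ``n_axes`` defaults to
    min(n_groups - 1, n_pcs).
    """

    def __init__(self, n_pcs: int = 20, n_axes: int | None = None) -> None:
        self.n_pcs = n_pcs
        self.n_axes = n_axes

    def fit(self, X: GenotypeMatrix | np.ndarray, y) -> "DAPC":
        codes = _codes_of(X).astype(float)
        y = np.asarray(y)
        n = codes.shape[0]
        if self.n_pcs >= n:
            raise ValueError(f"n_pcs={self.n_pcs} must be < n_samples={n}")
        labels, counts = np.unique(y, return_counts=True)
        if counts.min() < 2:
            small = labels[counts < 2]
            raise ValueError(
                f"populations with a single sample: {', '.join(map(str, small))}"
            )
        Z = self._impute(codes, fit=True)
        self.pca_ = PCA(n_components=self.n_pcs, svd_solver="full")
        scores = self.pca_.fit_transform(Z)
        n_axes = self.n_axes or min(len(labels) - 1, self.n_pcs)
        self.lda_ = LinearDiscriminantAnalysis(n_components=n_axes)
        self.lda_.fit(scores, y)
        self.classes_ = self.lda_.classes_
        self.discriminants_ = self.lda_.transform(scores)
        ratio = self.lda_.explained_variance_ratio_[:n_axes]
        self.axis_variance_ = ratio
        self.group_centroids_ = {
            str(lab): self.discriminants_[y == lab].mean(axis=0) for lab in labels
        }
        self._train_labels = y
        return self

    def _impute(self, codes: np.ndarray, fit: bool) -> np.ndarray:
        miss = codes == MISSING
        if fit:
            with np.errstate(invalid="ignore"):
                col_mean = np.where(
                    (~miss).sum(axis=0) > 0,
                    np.where(miss, 0, codes).sum(axis=0) / np.maximum((~miss).sum(axis=0), 1),
                    0.0,
                )
            self.col_mean_ = col_mean
        Z = np.where(miss, self.col_mean_[None, :], codes)
        return Z

    def transform(self, X: GenotypeMatrix | np.ndarray) -> np.ndarray:
        check_is_fitted(self, "lda_")
        Z = self._impute(_codes_of(X).astype(float), fit=False)
        return self.lda_.transform(self.pca_.transform(Z))

    def predict(self, X: GenotypeMatrix | np.ndarray) -> np.ndarray:
        check_is_fitted(self, "lda_")
        Z = self._impute(_codes_of(X).astype(float), fit=False)
        return self.lda_.predict(self.pca_.transform(Z))

    def result(self) -> DapcResult:
        check_is_fitted(self, "lda_")
        return DapcResult(
            n_pcs=self.n_pcs,
            discriminants=self.discriminants_,
            axis_variance=self.axis_variance_,
            group_centroids=self.group_centroids_,
            populations=[str(c) for c in self.classes_],
        )


def dapc(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    n_pcs: int = 20,
    n_axes: int | None = None,
) -> DapcResult:
    """Fit DAPC on a genotype matrix and population map."""
    popmap.validate(gm)
    y = popmap.labels_for(gm.sample_ids)
    return DAPC(n_pcs=n_pcs, n_axes=n_axes).fit(gm, y).result()


def crossvalidate_pcs(
    gm: GenotypeMatrix,
    popmap: PopulationMap,
    candidate_n_pcs: list[int],
    n_reps: int = 30,
    seed: int = 0,
    test_fraction: float = 0.1,
) -> tuple[int, dict[int, float]]:
    """Choose the number of PCs by stratified holdout reassignment.

    Each replicate holds out ~``test_fraction`` of every population
    (at least one sample, while keeping at least two in training;
    populations too small to stratify stay whole in training, logged).
    The candidate maximising mean correct reassignment wins; ties go to
    the smallest candidate.
    """
    popmap.validate(gm)
    y = popmap.labels_for(gm.sample_ids)
    codes = gm.calls
    n = codes.shape[0]
    cands = sorted(set(int(c) for c in candidate_n_pcs))
    if any(c >= n for c in cands):
        raise ValueError("candidate n_pcs must be below the sample count")
    rng = np.random.default_rng(seed)
    scores = {c: [] for c in cands}
    for _ in range(n_reps):
        test_idx: list[int] = []
        for pop in np.unique(y):
            members = np.nonzero(y == pop)[0]
            k = max(1, int(round(test_fraction * members.size)))
            if members.size - k < 2:
                logger.info("population %s too small to stratify; kept in training", pop)
                continue
            test_idx.extend(rng.choice(members, size=k, replace=False))
        if not test_idx:
            raise ValueError("no population large enough to hold out samples")
        test = np.array(sorted(test_idx))
        train = np.setdiff1d(np.arange(n), test)
        for c in cands:
            est = DAPC(n_pcs=c).fit(codes[train], y[train])
            pred = est.predict(codes[test])
            scores[c].append(float((pred == y[test]).mean()))
    mean_scores = {c: float(np.mean(s)) for c, s in scores.items()}
    best = max(cands, key=lambda c: (round(mean_scores[c], 12), -c))
    return best, mean_scores
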