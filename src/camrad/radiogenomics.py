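"""Radiogenomic mapping between imaging features and gene expression.

Pipeline: variance-based gene filtering; weighted co-expression module
detection (|r|^power adjacency, average-linkage clustering with a static
cut, eigengene-based module merging); module eigengenes as first principal
components; Pearson module-feature correlation; elastic-net multigene
signatures for prognostic features with ten-fold cross-validated (alpha,
lambda) selection; signature transfer to new cohorts; and hypergeometric
gene-set enrichment with BH correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_is_fitted

from .survival import bh_adjust

__all__ = [
    "filter_genes",
    "CoexpressionModules",
    "detect_modules",
    "module_eigengene",
    "module_feature_correlation",
    "ElasticNetSignature",
    "elastic_net_signature",
    "apply_signature",
    "hypergeometric_enrichment",
]

GREY = "grey"


def _ols_predict(X_train, y_train, X_test, support):
    """Least-squares refit on a support; intercept-only when it is empty."""
    if support.size == 0:
        return np.full(X_test.shape[0], y_train.mean())
    Xa = np.column_stack([np.ones(X_train.shape[0]), X_train[:, support]])
    sol, *_ = np.linalg.lstsq(Xa, y_train, rcond=None)
    return sol[0] + X_test[:, support] @ sol[1:]


def filter_genes(expr: pd.DataFrame, min_expressed_frac: float = 0.2,
                 top_k: int = 5000) -> pd.DataFrame:
    """Drop rarely expressed genes, then keep the ``top_k`` most variable.

    A gene must be nonzero in at least ``min_expressed_frac`` of samples;
    survivors are ranked by variance across samples (ties broken by gene id)
    and the top ``top_k`` retained, preserving input order.
    """
    expr = expr.astype(float)
    frac = (expr != 0).mean(axis=1)
    kept = expr.loc[frac >= min_expressed_frac]
    if len(kept) > top_k:
        var = kept.var(axis=1)
        order = sorted(kept.index, key=lambda g: (-var[g], g))
        topset = set(order[:top_k])
        kept = kept.loc[[g for g in kept.index if g in topset]]
    return kept


def module_eigengene(expr_module: pd.DataFrame) -> np.ndarray:
    """First principal component of a module's gene-standardised expression.

    Returned as a unit-variance sample-score vector with sign fixed so the
    mean correlation with the member genes is positive.
    """
    X = expr_module.to_numpy(dtype=float)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError("expr_module must be genes x samples")
    sd = X.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    Z = (X - X.mean(axis=1, keepdims=True)) / sd
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    score = vt[0]
    corr = Z @ score
    if corr.mean() < 0:
        score = -score
    return score / score.std()


class CoexpressionModules(BaseEstimator):
    """Weighted co-expression module detection.

    The adjacency between genes is |Pearson r|^``power``; modules come from
    average-linkage hierarchical clustering of the dissimilarity
    1 - adjacency with a static cut chosen to maximise the number of
    clusters of at least ``min_size`` genes (ties -> lower cut height).
    Modules whose eigengenes have correlation dissimilarity 1 - cor below
    ``merge_height`` are merged.  Genes in undersized clusters are labelled
    grey (unassigned).

    Attributes
    ----------
    assignments_ : pd.Series gene -> module label ("module_1", ..., "grey")
    eigengenes_ : pd.DataFrame modules x samples, unit-variance scores
    cut_height_ : the selected static cut height
    """

    def __init__(self, power: int = 5, min_size: int = 60, merge_height: float = 0.25,
                 max_cut_height: float = 0.999):
        self.power = power
        self.min_size = min_size
        self.merge_height = merge_height
        self.max_cut_height = max_cut_height

    def fit(self, expr: pd.DataFrame, y=None):
        expr = expr.astype(float)
        genes = list(expr.index)
        n_genes = len(genes)
        if n_genes < self.min_size:
            warnings.warn("fewer genes than min_size; all genes left unassigned")
            self.assignments_ = pd.Series(GREY, index=genes)
            self.eigengenes_ = pd.DataFrame(columns=expr.columns)
            self.cut_height_ = np.nan
            return self
        corr = np.corrcoef(expr.to_numpy())
        corr = np.nan_to_num(corr, nan=0.0)
        adjacency = np.abs(corr) ** self.power
        dissim = 1.0 - adjacency
        np.fill_diagonal(dissim, 0.0)
        dissim = np.clip((dissim + dissim.T) / 2.0, 0.0, None)
        Z = linkage(squareform(dissim, checks=False), method="average")

        # Static cut maximising the number of modules of size >= min_size.
        # Cut heights are capped at max_cut_height: a merge at dissimilarity
        # ~1 joins clusters with |r|^power ~ 0, i.e. no co-expression, so
        # cutting above it would glue unrelated genes into pseudo-modules.
        heights = np.unique(Z[:, 2])
        cuts = np.concatenate([(heights[:-1] + heights[1:]) / 2.0, [heights[-1] + 1e-6]])
        capped = cuts[cuts <= self.max_cut_height]
        if capped.size:
            cuts = capped
        best_labels, best_count, best_h = None, -1, None
        for h in cuts:
            labels = fcluster(Z, t=h, criterion="distance")
            sizes = np.bincount(labels)
            count = int(np.sum(sizes[1:] >= self.min_size))
            if count > best_count:
                best_labels, best_count, best_h = labels, count, h
        self.cut_height_ = float(best_h)
        labels = best_labels
        sizes = np.bincount(labels)
        module_ids = [c for c in range(1, sizes.size) if sizes[c] >= self.min_size]
        members = {c: [genes[i] for i in np.flatnonzero(labels == c)] for c in module_ids}

        # eigengene-similarity merging
        while len(members) > 1:
            ids = sorted(members)
            eig = np.vstack([module_eigengene(expr.loc[members[c]]) for c in ids])
            ec = np.corrcoef(eig)
            d = 1.0 - ec
            np.fill_diagonal(d, np.inf)
            i, j = np.unravel_index(np.argmin(d), d.shape)
            if d[i, j] >= self.merge_height:
                break
            keep, drop = ids[i], ids[j]
            members[keep] = members[keep] + members.pop(drop)

        assignments = pd.Series(GREY, index=genes, dtype=object)
        eigengenes = {}
        for k, c in enumerate(sorted(members, key=lambda c: -len(members[c])), start=1):
            name = f"module_{k}"
            assignments[members[c]] = name
            eigengenes[name] = module_eigengene(expr.loc[members[c]])
        self.assignments_ = assignments
        self.eigengenes_ = pd.DataFrame(eigengenes, index=expr.columns).T
        return self


def detect_modules(expr: pd.DataFrame, power: int = 5, min_size: int = 60,
                   merge_height: float = 0.25) -> CoexpressionModules:
    """Functional wrapper: fit and return a :class:`CoexpressionModules`."""
    return CoexpressionModules(power=power, min_size=min_size, merge_height=merge_height).fit(expr)


def module_feature_correlation(eigengenes: pd.DataFrame, features: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (with p) between every module eigengene and every feature.

    ``eigengenes`` is modules x samples; ``features`` is samples x features.
    Returns a tidy frame (module, feature, r, p).
    """
    rows = []
    for module, scores in eigengenes.iterrows():
        for feat in features.columns:
            r, p = stats.pearsonr(scores.to_numpy(float), features[feat].to_numpy(float))
            rows.append({"module": module, "feature": feat, "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


class ElasticNetSignature(BaseEstimator, RegressorMixin):
    """Multigene elastic-net signature for one imaging feature.

    Genes are preselected by absolute Pearson correlation with the target
    feature (``top_corr_genes``), then an elastic net

        (1/2n) ||y - X b - b0||^2 + lambda (alpha ||b||_1 + (1-alpha)/2 ||b||^2)

    is fitted with (alpha, lambda) chosen by ``folds``-fold cross-validated
    error over the grids.  The signature is the set of genes with nonzero
    coefficients.

    ``selection_rule`` controls how the cross-validation picks the model:

    * ``"relaxed"`` (default): alpha by CV-minimum, then lambda by CV of the
      debiased (OLS-refit) model along the path with the one-standard-error
      rule, and the reported coefficients are the OLS refit on the selected
      support.  This counteracts the well-known over-selection of
      CV-minimum penalised fits and markedly improves support recovery.
    * ``"1se"``: sparsest penalised model within one SE of the CV minimum.
    * ``"min"``: the CV-minimum penalised model.

    Attributes: ``signature_`` (gene ids), ``coef_`` (nonzero coefficients,
    same order), ``intercept_``, ``l1_ratio_`` (alpha), ``lambda_``,
    ``r2_`` (in-sample R^2).
    """

    def __init__(self, top_corr_genes: int = 100, l1_ratio_grid=None, lambda_grid=None,
                 folds: int = 10, selection_rule: str = "relaxed", random_state: int = 0):
        self.top_corr_genes = top_corr_genes
        self.l1_ratio_grid = l1_ratio_grid
        self.lambda_grid = lambda_grid
        self.folds = folds
        self.selection_rule = selection_rule
        self.random_state = random_state

    def _grids(self):
        l1 = (np.round(np.arange(0.05, 0.951, 0.05), 2) if self.l1_ratio_grid is None
              else np.asarray(self.l1_ratio_grid, float))
        lam = (np.logspace(-4, 0, 50) if self.lambda_grid is None
               else np.asarray(self.lambda_grid, float))
        return l1, lam

    def fit(self, expr: pd.DataFrame, feature):
        """``expr`` is genes x samples; ``feature`` one value per sample."""
        expr = expr.astype(float)
        y = np.asarray(feature, dtype=float)
        if expr.shape[1] != y.size:
            raise ValueError("feature length must match sample count")
        X = expr.to_numpy()
        with np.errstate(invalid="ignore"):
            sd = X.std(axis=1)
            r = np.where(
                sd > 0,
                ((X - X.mean(axis=1, keepdims=True)) @ (y - y.mean()))
                / (np.maximum(sd, 1e-300) * y.std() * y.size),
                0.0,
            )
        k = min(self.top_corr_genes, len(expr))
        order = np.argsort(-np.abs(r), kind="stable")[:k]
        self.preselected_ = list(expr.index[np.sort(order)])
        Xs = expr.loc[self.preselected_].to_numpy().T  # samples x genes

        folds = self.folds
        if folds > y.size:
            warnings.warn(f"reducing folds from {folds} to {y.size}")
            folds = y.size
        l1_grid, lam_grid = self._grids()
        cv = KFold(n_splits=folds, shuffle=True, random_state=self.random_state)
        with warnings.catch_warnings():
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            model = ElasticNetCV(l1_ratio=list(l1_grid), alphas=list(lam_grid), cv=cv,
                                 max_iter=50_000, random_state=self.random_state)
            model.fit(Xs, y)
            if self.selection_rule == "relaxed":
                return self._fit_relaxed(Xs, y, float(model.l1_ratio_), lam_grid, cv, model)
        if self.selection_rule == "min":
            l1_best, lam_best = float(model.l1_ratio_), float(model.alpha_)
            final = model
        elif self.selection_rule == "1se":
            # one-standard-error rule: sparsest (largest lambda) model whose
            # fold-averaged CV error is within one SE of the global minimum
            mse = model.mse_path_  # (n_l1, n_lambda, n_folds)
            mean = mse.mean(axis=2)
            se = mse.std(axis=2, ddof=1) / np.sqrt(mse.shape[2])
            i0, j0 = np.unravel_index(np.argmin(mean), mean.shape)
            admissible = mean <= mean[i0, j0] + se[i0, j0]
            lambdas = np.asarray(model.alphas_[0] if np.ndim(model.alphas_) > 1
                                 else model.alphas_)
            ii, jj = np.nonzero(admissible)
            l1_arr = np.asarray(model.l1_ratio, dtype=float)
            # sparsest admissible model: maximise the effective L1 penalty
            pick = int(np.argmax(l1_arr[ii] * lambdas[jj]))
            l1_best, lam_best = float(l1_arr[ii[pick]]), float(lambdas[jj[pick]])
            final = ElasticNet(alpha=lam_best, l1_ratio=l1_best, max_iter=50_000,
                               random_state=self.random_state).fit(Xs, y)
        else:
            raise ValueError("selection_rule must be 'min' or '1se'")
        self.l1_ratio_ = l1_best
        self.lambda_ = lam_best
        self.intercept_ = float(final.intercept_)
        nz = np.flatnonzero(final.coef_ != 0)
        self.signature_ = [self.preselected_[i] for i in nz]
        self.coef_ = final.coef_[nz].copy()
        self.full_coef_ = pd.Series(final.coef_, index=self.preselected_)
        self.r2_ = float(final.score(Xs, y))
        self.cv_mse_path_ = model.mse_path_
        return self

    def _fit_relaxed(self, Xs, y, l1_best, lam_grid, cv, cv_model):
        """Relaxed selection: CV the OLS refit of each path support at the
        chosen alpha; pick lambda by the one-standard-error rule; report the
        full-data OLS refit on the selected support."""
        from sklearn.linear_model import enet_path

        lambdas = np.sort(np.asarray(lam_grid, dtype=float))[::-1]
        folds = cv.get_n_splits()
        errs = np.zeros((lambdas.size, folds))
        for f, (tr, va) in enumerate(cv.split(Xs)):
            _, coefs, _ = enet_path(Xs[tr], y[tr], l1_ratio=l1_best, alphas=lambdas)
            for li in range(lambdas.size):
                support = np.flatnonzero(coefs[:, li])
                pred = _ols_predict(Xs[tr], y[tr], Xs[va], support)
                errs[li, f] = float(np.mean((y[va] - pred) ** 2))
        mean = errs.mean(axis=1)
        se = errs.std(axis=1, ddof=1) / np.sqrt(folds)
        i0 = int(np.argmin(mean))
        admissible = np.flatnonzero(mean <= mean[i0] + se[i0])
        lam_best = float(lambdas[admissible[np.argmax(lambdas[admissible])]])
        _, coefs, _ = enet_path(Xs, y, l1_ratio=l1_best, alphas=lambdas)
        support = np.flatnonzero(coefs[:, int(np.argwhere(lambdas == lam_best)[0, 0])])
        beta = np.zeros(Xs.shape[1])
        if support.size:
            Xa = np.column_stack([np.ones(len(y)), Xs[:, support]])
            sol, *_ = np.linalg.lstsq(Xa, y, rcond=None)
            self.intercept_ = float(sol[0])
            beta[support] = sol[1:]
        else:
            self.intercept_ = float(y.mean())
        self.l1_ratio_ = l1_best
        self.lambda_ = lam_best
        self.signature_ = [self.preselected_[i] for i in support]
        self.coef_ = beta[support].copy()
        self.full_coef_ = pd.Series(beta, index=self.preselected_)
        fitted = self.intercept_ + Xs @ beta
        ss_res = float(np.sum((y - fitted) ** 2))
        ss_tot = float(np.sum((y - y.mean()) ** 2))
        self.r2_ = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
        self.cv_mse_path_ = cv_model.mse_path_
        return self

    def predict(self, expr_new: pd.DataFrame) -> np.ndarray:
        """Signature scores (intercept + sum coef * expression) per sample."""
        check_is_fitted(self, "signature_")
        missing = [g for g in self.signature_ if g not in expr_new.index]
        if missing:
            raise KeyError(f"expression matrix is missing signature genes: {missing}")
        Xn = expr_new.loc[self.signature_].to_numpy(dtype=float).T
        return self.intercept_ + Xn @ self.coef_


def elastic_net_signature(expr: pd.DataFrame, feature, top_corr_genes: int = 100,
                          l1_ratio_grid=None, lambda_grid=None, folds: int = 10,
                          seed: int = 0) -> ElasticNetSignature:
    """Functional wrapper: fit and return an :class:`ElasticNetSignature`."""
    return ElasticNetSignature(top_corr_genes, l1_ratio_grid, lambda_grid, folds, seed).fit(
        expr, feature
    )


def apply_signature(expr_new: pd.DataFrame, signature: ElasticNetSignature) -> np.ndarray:
    """Predicted feature scores for a new cohort's expression matrix."""
    return signature.predict(expr_new)


def hypergeometric_enrichment(signature_genes, gene_sets: dict, universe) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each gene set.

    p = P(overlap >= observed) under sampling ``len(signature)`` genes from
    the ``universe`` without replacement; BH-adjusted across sets.  Genes
    outside the universe are ignored.  Returns a frame indexed by set name
    with overlap, set_size, p and p_adjusted.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    sig = set(signature_genes) & universe
    rows = {}
    for name, members in gene_sets.items():
        inset = set(members) & universe
        k = len(sig & inset)
        if len(inset) == 0:
            warnings.warn(f"gene set {name!r} has no genes in the universe; skipped")
            continue
        p = float(stats.hypergeom.sf(k - 1, len(universe), len(inset), len(sig)))
        rows[name] = {"overlap": k, "set_size": len(inset), "p": min(p, 1.0)}
    result = pd.DataFrame.from_dict(rows, orient="index")
    if len(result):
        result["p_adjusted"] = bh_adjust(result["p"].to_numpy())
    return result
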