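"""Scikit-learn-style estimators over the GBLUP core.

``GBLUPRegressor`` and ``OneVsAllGBLUPClassifier`` take a plain dosage
matrix as ``X`` so they compose with sklearn pipelines and model selection;
internally they build the VanRaden relationship matrix with training-set
allele frequencies and re-use those frequencies when extending the matrix
to prediction-time genotypes, which is the conditional-expectation route to
BLUPs for unobserved individuals.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin, RegressorMixin
from sklearn.utils.validation import check_array, check_is_fitted, check_X_y

from .categorical import MCMCSettings, one_vs_all_classify
from .genotypes import GenotypeMatrix, compute_grm
from .gblup import ModelSpec, VarianceComponents, fit_gblup

__all__ = ["GBLUPRegressor", "OneVsAllGBLUPClassifier"]


def _joint_kinship(X_train, X_new, freqs):
    n_tr, n_new = X_train.shape[0], X_new.shape[0]
    ids = [f"train{i}" for i in range(n_tr)] + [f"new{i}" for i in range(n_new)]
    markers = [f"m{j}" for j in range(X_train.shape[1])]
    geno = GenotypeMatrix(ids, markers, np.vstack([X_train, X_new]))
    return ids, compute_grm(geno, freqs=freqs)


class GBLUPRegressor(RegressorMixin, BaseEstimator):
    """Genomic BLUP regression on allele dosages.

    Parameters
    ----------
    variance_components : (sigma_g2, sigma_e2) tuple, optional
        Fix the variance components instead of estimating them by REML.

    Attributes
    ----------
    sigma_g2_, sigma_e2_, h2_ : fitted variance components and heritability
    g_train_ : genetic-value BLUPs of the training individuals
    intercept_ : fitted grand mean
    """

    def __init__(self, variance_components=None):
        self.variance_components = variance_components

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float)
        if np.min(X) < 0 or np.max(X) > 2:
            raise ValueError("dosages must lie in [0, 2]")
        self.X_train_ = X
        self.freqs_ = X.mean(axis=0) / 2.0
        ids = [f"train{i}" for i in range(X.shape[0])]
        markers = [f"m{j}" for j in range(X.shape[1])]
        kin = compute_grm(GenotypeMatrix(ids, markers, X), freqs=self.freqs_)
        vc = (
            VarianceComponents(*self.variance_components)
            if self.variance_components is not None
            else None
        )
        spec = ModelSpec(response=pd.Series(y, index=ids), kinship=kin)
        fit = fit_gblup(spec, vc=vc, compute_reliability=False)
        vc = fit.variance_components
        self.sigma_g2_ = vc.sigma_g2
        self.sigma_e2_ = vc.sigma_e2
        self.h2_ = vc.h2
        self.intercept_ = float(fit.beta_hat["intercept"])
        self.g_train_ = fit.g_hat.to_numpy()
        self.y_train_ = y
        self.n_features_in_ = X.shape[1]
        return self

    def predict(self, X):
        check_is_fitted(self, "g_train_")
        X = check_array(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count differs from fit time")
        ids, kin = _joint_kinship(self.X_train_, X, self.freqs_)
        n_tr = self.X_train_.shape[0]
        spec = ModelSpec(
            response=pd.Series(self.y_train_, index=ids[:n_tr]), kinship=kin
        )
        vc = VarianceComponents(self.sigma_g2_, self.sigma_e2_)
        fit = fit_gblup(spec, vc=vc, compute_reliability=False)
        return (self.intercept_ + fit.g_hat.loc[ids[n_tr:]]).to_numpy()


class OneVsAllGBLUPClassifier(ClassifierMixin, BaseEstimator):
    """One-versus-all probit GBLUP classifier on allele dosages.

    Each class gets a binary latent-liability GBLUP fitted by Gibbs
    sampling; ``predict`` assigns the class of maximal raw posterior
    membership probability.
    """

    def __init__(self, iterations=1500, burn_in=500, thin=5, random_state=0):
        self.iterations = iterations
        self.burn_in = burn_in
        self.thin = thin
        self.random_state = random_state

    def fit(self, X, y):
        X, y = check_X_y(X, y, dtype=float, ensure_2d=True)
        self.X_train_ = X
        self.y_train_ = np.asarray(y).astype(str)
        self.classes_ = np.unique(self.y_train_)
        if len(self.classes_) < 2:
            raise ValueError("need at least 2 classes")
        self.freqs_ = X.mean(axis=0) / 2.0
        self.n_features_in_ = X.shape[1]
        return self

    def _settings(self):
        return MCMCSettings(
            seed=int(self.random_state),
            iterations=int(self.iterations),
            burn_in=int(self.burn_in),
            thin=int(self.thin),
        )

    def predict_proba(self, X):
        check_is_fitted(self, "classes_")
        X = check_array(X, dtype=float)
        ids, kin = _joint_kinship(self.X_train_, X, self.freqs_)
        n_tr = self.X_train_.shape[0]
        labels = pd.Series(self.y_train_, index=ids[:n_tr])
        assign = one_vs_all_classify(
            labels, kin, self._settings(), unlabeled=ids[n_tr:], min_class_size=2
        )
        P = assign.probabilities[list(self.classes_)].to_numpy()
        return P / P.sum(axis=1, keepdims=True)

    def predict(self, X):
        P = self.predict_proba(X)
        return self.classes_[np.argmax(P, axis=1)]
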