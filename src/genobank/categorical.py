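"""Binary-response GBLUP via a probit liability model, and the
one-versus-all multi-class classifier built on it.

The latent-liability model is ``y* = X beta + g + e`` with ``e ~ N(0, 1)``
(residual variance fixed at 1 for identifiability) and observed class
``1{y* > 0}``; ``g ~ N(0, sigma_g^2 G)`` over labeled *and* unlabeled
accessions jointly.  Fitting is by data-augmentation Gibbs sampling:
truncated-normal draws for the latent liabilities, conjugate normal updates
for beta and g, and a scaled-inverse-chi-square update for sigma_g^2.  The
reported membership probability per accession is the Monte-Carlo posterior
mean of ``Phi(x_i beta + g_i)``.

For K > 2 classes, K one-versus-all binary fits are run and each accession
is assigned the class of maximal raw membership probability (probabilities
are deliberately not renormalized before the argmax; their sum is kept as a
diagnostic).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.stats import norm, truncnorm

from .genotypes import Kinship
from .gblup import _inv_G

__all__ = [
    "MCMCSettings",
    "BinaryFit",
    "CategoricalAssignment",
    "fit_binary_gblup",
    "one_vs_all_classify",
    "classification_rate",
]

logger = logging.getLogger(__name__)


@dataclass
class MCMCSettings:
    """Gibbs chain settings; a seed is required for reproducibility."""

    seed: int
    iterations: int = 6000
    burn_in: int = 1000
    thin: int = 5
    prior_df: float = 5.0
    prior_scale: float = 1.4  # prior mode for sigma_g^2 approx 1

    def __post_init__(self):
        if self.iterations <= self.burn_in:
            raise ValueError("chain length must exceed burn-in")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")

    def spawn(self, key: int) -> "MCMCSettings":
        """Derive deterministic per-class settings for one-versus-all runs."""
        child = np.random.SeedSequence(self.seed, spawn_key=(key,))
        return MCMCSettings(
            seed=int(child.generate_state(1)[0] % (2**31)),
            iterations=self.iterations,
            burn_in=self.burn_in,
            thin=self.thin,
            prior_df=self.prior_df,
            prior_scale=self.prior_scale,
        )


@dataclass
class BinaryFit:
    """Posterior-mean membership probabilities from one binary GBLUP chain."""

    accession_ids: list[str]
    prob: pd.Series  # P(class == 1) per accession, labeled and unlabeled
    sigma_g2_mean: float
    diagnostics: dict = field(default_factory=dict)


@dataclass
class CategoricalAssignment:
    """One-versus-all result: per-class probabilities and argmax label."""

    accession_ids: list[str]
    classes: list[str]
    probabilities: pd.DataFrame  # accession x class, raw (not renormalized)
    assigned: pd.Series
    margin: pd.Series  # top1 - top2 probability


def _truncated_normal(rng, mean, positive):
    """One draw per entry from N(mean, 1) truncated to y*>0 (or y*<0)."""
    a = np.where(positive, -mean, -np.inf)
    b = np.where(positive, np.inf, -mean)
    return truncnorm.rvs(a, b, loc=mean, scale=1.0, random_state=rng)


def fit_binary_gblup(
    labels01: pd.Series,
    kinship: Kinship,
    mcmc: MCMCSettings,
    covariates: pd.DataFrame | None = None,
) -> BinaryFit:
    """Probit GBLUP for a 0/1 response on the labeled subset of a kinship.

    Parameters
    ----------
    labels01 : Series mapping labeled accession ids to {0, 1}; accessions of
        the kinship absent from the index (or NA) are treated as unlabeled
        and receive posterior membership probabilities.
    kinship : Kinship over labeled and unlabeled accessions.
    mcmc : chain settings (seed required).
    covariates : optional fixed-effect columns indexed by accession;
        intercept-only by default.
    """
    labels01 = pd.Series(labels01).dropna()
    labels01.index = labels01.index.astype(str)
    vals = set(labels01.unique())
    if not vals <= {0, 1}:
        raise ValueError("labels must be coded 0/1")
    if vals != {0, 1}:
        raise ValueError("both classes must be present in the labels")
    ids = list(kinship.accession_ids)
    unknown = set(labels01.index) - set(ids)
    if unknown:
        raise ValueError(f"labeled accessions absent from kinship: {sorted(unknown)[:5]}")

    n = len(ids)
    lab_idx = kinship.index_of(labels01.index)
    obs = labels01.to_numpy(dtype=float)
    positive = obs > 0.5

    if covariates is not None:
        cov = covariates.copy()
        cov.index = cov.index.astype(str)
        X = np.column_stack(
            [np.ones(len(lab_idx))]
            + [cov.loc[labels01.index, c].to_numpy(dtype=float) for c in cov.columns]
        )
        X_all = np.column_stack(
            [np.ones(n)] + [cov.loc[ids, c].to_numpy(dtype=float) for c in cov.columns]
        )
    else:
        X = np.ones((len(lab_idx), 1))
        X_all = np.ones((n, 1))
    p = X.shape[1]

    rng = np.random.default_rng(mcmc.seed)
    Ginv = _inv_G(kinship.G)
    XtX = X.T @ X
    XtX_chol = linalg.cho_factor(XtX)

    # state
    beta = np.zeros(p)
    g = np.zeros(n)
    sigma_g2 = 1.0
    ystar = np.where(positive, 0.5, -0.5)

    nz = np.zeros(n)
    np.add.at(nz, lab_idx, 1.0)  # Z'Z diagonal (one record per labeled accession)
    ZtZ = np.diag(nz)

    prob_sum = np.zeros(n)
    sg2_sum = 0.0
    kept = 0
    for it in range(mcmc.iterations):
        eta_lab = X @ beta + g[lab_idx]
        ystar = _truncated_normal(rng, eta_lab, positive)
        # beta | rest  (flat prior, residual variance 1)
        resid = ystar - g[lab_idx]
        mean_b = linalg.cho_solve(XtX_chol, X.T @ resid)
        Lb = linalg.cholesky(linalg.inv(XtX), lower=True)
        beta = mean_b + Lb @ rng.standard_normal(p)
        # g | rest: precision Q = Z'Z + Ginv / sigma_g2
        Q = ZtZ + Ginv / sigma_g2
        rhs = np.zeros(n)
        np.add.at(rhs, lab_idx, ystar - X @ beta)
        Lq = linalg.cholesky(Q, lower=True)
        mean_g = linalg.cho_solve((Lq, True), rhs)
        z = rng.standard_normal(n)
        g = mean_g + linalg.solve_triangular(Lq.T, z, lower=False)
        # sigma_g2 | g: scaled-inverse-chi-square
        ssq = float(g @ (Ginv @ g))
        df = mcmc.prior_df + n
        scale = mcmc.prior_df * mcmc.prior_scale + ssq
        sigma_g2 = scale / rng.chisquare(df)
        if it >= mcmc.burn_in and (it - mcmc.burn_in) % mcmc.thin == 0:
            prob_sum += norm.cdf(X_all @ beta + g)
            sg2_sum += sigma_g2
            kept += 1
    prob = pd.Series(prob_sum / kept, index=ids, name="prob")
    return BinaryFit(
        accession_ids=ids,
        prob=prob,
        sigma_g2_mean=sg2_sum / kept,
        diagnostics={
            "iterations": mcmc.iterations,
            "burn_in": mcmc.burn_in,
            "thin": mcmc.thin,
            "kept_samples": kept,
            "n_labeled": len(lab_idx),
        },
    )


def one_vs_all_classify(
    labels: pd.Series,
    kinship: Kinship,
    mcmc: MCMCSettings,
    unlabeled: list[str] | None = None,
    min_class_size: int = 2,
    covariates: pd.DataFrame | None = None,
) -> CategoricalAssignment:
    """Multi-class assignment by K one-versus-all binary GBLUP fits.

    For K = 2 a single binary fit is run (probabilities of the second class
    and its complement).  For K > 2, one chain per class; the assigned label
    is the argmax of the raw membership probabilities, ties broken by
    alphabetical class order with a logged warning.
    """
    labels = pd.Series(labels).dropna()
    labels.index = labels.index.astype(str)
    counts = labels.value_counts()
    too_small = counts[counts < max(min_class_size, 2)]
    if len(too_small):
        raise ValueError(
            "classes below the minimum labeled-membership threshold: "
            + ", ".join(f"{c} (n={n})" for c, n in too_small.items())
        )
    classes = sorted(counts.index.astype(str))
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    ids = list(kinship.accession_ids)

    probs = {}
    if len(classes) == 2:
        y01 = (labels == classes[1]).astype(int)
        fit = fit_binary_gblup(y01, kinship, mcmc, covariates=covariates)
        probs[classes[1]] = fit.prob
        probs[classes[0]] = 1.0 - fit.prob
    else:
        for j, cls in enumerate(classes):
            y01 = (labels == cls).astype(int)
            fit = fit_binary_gblup(y01, kinship, mcmc.spawn(j), covariates=covariates)
            probs[cls] = fit.prob
    P = pd.DataFrame(probs, index=ids)[classes]
    arr = P.to_numpy()
    top = np.argmax(arr, axis=1)  # argmax takes the first (alphabetical) on ties
    sorted_p = np.sort(arr, axis=1)
    margin = sorted_p[:, -1] - sorted_p[:, -2]
    if np.any(margin == 0):
        logger.warning(
            "%d accessions with tied class probabilities; assigned the "
            "alphabetically first class",
            int(np.sum(margin == 0)),
        )
    assigned = pd.Series([classes[t] for t in top], index=ids, name="assigned")
    result = CategoricalAssignment(
        accession_ids=ids,
        classes=classes,
        probabilities=P,
        assigned=assigned,
        margin=pd.Series(margin, index=ids, name="margin"),
    )
    if unlabeled is not None:
        keep = [str(u) for u in unlabeled]
        result.probabilities = P.loc[keep]
        result.assigned = assigned.loc[keep]
        result.margin = result.margin.loc[keep]
        result.accession_ids = keep
    return result


def classification_rate(assigned: pd.Series, truth: pd.Series) -> float:
    """Proportion of exact label matches over a shared accession set."""
    assigned = pd.Series(assigned)
    truth = pd.Series(truth)
    if len(assigned) == 0:
        raise ValueError("empty input")
    if set(assigned.index) != set(truth.index):
        raise ValueError("assigned and truth must cover the same accessions")
    truth = truth.loc[assigned.index]
    return float((assigned.astype(str) == truth.astype(str)).mean())
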