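"""Gaussian-response GBLUP: variance components, mixed model equations,
BLUPs for phenotyped and unphenotyped accessions, per-individual reliabilities.

Model
-----
``y = X beta + Z g + e`` with ``g ~ N(0, sigma_g^2 G)`` and
``e ~ N(0, sigma_e^2 I)``, where ``G`` is the marker-derived additive genomic
relationship matrix over *all* accessions (phenotyped and unphenotyped) and
``Z`` is the 0/1 incidence matrix mapping the phenotyped records onto
accessions.  Variance components are estimated by exact restricted maximum
likelihood through the spectral decomposition of the phenotyped submatrix of
``G`` (one-dimensional optimization over the variance ratio), so fits are
deterministic.  Genetic values for unphenotyped accessions are obtained
jointly by carrying them in ``G`` (their rows of ``Z`` are simply absent),
which is algebraically the conditional-expectation extension of BLUP and
yields their reliabilities directly from the mixed-model-equation
coefficient matrix.

Reliability of a BLUP is the squared-scale quantity
``r_i = 1 - d_i * sigma_e^2 / sigma_g^2`` where ``d_i`` is the i-th diagonal
element of the ``C^22`` block of a generalized inverse of Henderson's
coefficient matrix; equivalently ``1 - PEV_i / sigma_g^2``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from .genotypes import Kinship

__all__ = [
    "ModelSpec",
    "VarianceComponents",
    "GBLUPFit",
    "estimate_variance_components",
    "fit_gblup",
    "reliabilities",
    "predict_ability",
]

logger = logging.getLogger(__name__)

_COND_LIMIT = 1e12
_JITTER_SCALE = 1e-6


class ConvergenceError(RuntimeError):
    """REML optimization failed; carries the profile-likelihood trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = trace


@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    reml_loglik: float | None = None

    def __post_init__(self):
        if self.sigma_g2 < 0:
            raise ValueError("sigma_g2 must be >= 0")
        if self.sigma_e2 <= 0:
            raise ValueError("sigma_e2 must be > 0")

    @property
    def h2(self) -> float:
        return self.sigma_g2 / (self.sigma_g2 + self.sigma_e2)

    @property
    def ratio(self) -> float:
        """lambda = sigma_e^2 / sigma_g^2 used in the mixed model equations."""
        return self.sigma_e2 / self.sigma_g2


@dataclass
class ModelSpec:
    """Response, fixed-effect design and kinship for one GBLUP fit.

    response maps a (subset of) accessions to phenotype values (e.g. BLUEs);
    covariates is an optional data frame indexed by accession id — an
    intercept column is always prepended.  kinship must cover the union of
    phenotyped and to-be-predicted accessions.
    """

    response: pd.Series
    kinship: Kinship
    covariates: pd.DataFrame | None = None

    def __post_init__(self):
        self.response = pd.Series(self.response, dtype=float)
        self.response.index = self.response.index.astype(str)
        self.response = self.response.dropna()
        if self.response.index.has_duplicates:
            raise ValueError("duplicate accessions in response")
        missing = set(self.response.index) - set(self.kinship.accession_ids)
        if missing:
            raise ValueError(f"response accessions absent from kinship: {sorted(missing)[:5]}")

    @property
    def phenotyped_ids(self) -> list[str]:
        obs = set(self.response.index)
        return [a for a in self.kinship.accession_ids if a in obs]


def _design(spec: ModelSpec, ids: list[str]) -> tuple[np.ndarray, list[str]]:
    """Intercept-plus-covariates design over `ids`, pruned to full column rank."""
    n = len(ids)
    cols = [np.ones(n)]
    names = ["intercept"]
    if spec.covariates is not None:
        cov = spec.covariates.copy()
        cov.index = cov.index.astype(str)
        missing = set(ids) - set(cov.index)
        if missing:
            raise ValueError(f"covariates missing accessions: {sorted(missing)[:5]}")
        cov = cov.loc[ids]
        for c in cov.columns:
            cols.append(cov[c].to_numpy(dtype=float))
            names.append(str(c))
    X = np.column_stack(cols)
    # drop linearly dependent columns (e.g. full dummy sets next to the intercept)
    q, r, piv = linalg.qr(X, mode="economic", pivoting=True)
    tol = np.abs(r[0, 0]) * max(X.shape) * np.finfo(float).eps
    rank = int(np.sum(np.abs(np.diag(r)) > tol))
    if rank < X.shape[1]:
        keep = np.sort(piv[:rank])
        dropped = [names[j] for j in piv[rank:]]
        logger.info("dropping linearly dependent covariate columns: %s", dropped)
        X = X[:, keep]
        names = [names[j] for j in keep]
    return X, names


def _spectral_reml(y: np.ndarray, X: np.ndarray, G: np.ndarray):
    """Exact REML for y = Xb + g + e, g ~ N(0, s_g^2 G), via eigen-rotation.

    Profiles the likelihood over the ratio gamma = sigma_g^2 / sigma_e^2 on a
    log grid refined by bounded scalar minimization.
    """
    n, p = X.shape
    if n - p < 1:
        raise ValueError("need more phenotyped accessions than fixed effects")
    s, U = linalg.eigh(G)
    s = np.clip(s, 0.0, None)
    yt = U.T @ y
    Xt = U.T @ X

    trace = []

    def neg_reml(log_gamma):
        gamma = np.exp(log_gamma)
        w = gamma * s + 1.0  # V / sigma_e^2 eigenvalues
        Xw = Xt / w[:, None]
        XtVX = Xt.T @ Xw
        try:
            cf = linalg.cho_factor(XtVX)
        except linalg.LinAlgError:
            return np.inf
        beta = linalg.cho_solve(cf, Xw.T @ yt)
        r = yt - Xt @ beta
        rss = float(r @ (r / w))
        if rss <= 0:
            return np.inf
        sigma_e2 = rss / (n - p)
        val = (
            (n - p) * np.log(sigma_e2)
            + np.sum(np.log(w))
            + 2.0 * np.sum(np.log(np.diag(cf[0])))
            + (n - p)
        )
        trace.append((gamma, -0.5 * val))
        return val

    grid = np.linspace(-14.0, 14.0, 57)
    vals = np.array([neg_reml(g) for g in grid])
    if not np.any(np.isfinite(vals)):
        raise ConvergenceError("REML profile likelihood is nowhere finite", trace)
    j = int(np.nanargmin(vals))
    lo = grid[max(j - 1, 0)]
    hi = grid[min(j + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(neg_reml, bounds=(lo, hi), method="bounded")
    if not res.success:
        raise ConvergenceError("REML optimization did not converge", trace)
    gamma = float(np.exp(res.x))
    w = gamma * s + 1.0
    Xw = Xt / w[:, None]
    beta = linalg.solve(Xt.T @ Xw, Xw.T @ yt, assume_a="pos")
    r = yt - Xt @ beta
    sigma_e2 = float(r @ (r / w)) / (n - p)
    sigma_g2 = gamma * sigma_e2
    # clamp an essentially-zero genetic ratio at the grid edge
    if res.x <= grid[0] + 1e-9:
        sigma_g2 = 0.0
    return sigma_g2, sigma_e2, -0.5 * float(res.fun)


def estimate_variance_components(spec: ModelSpec) -> VarianceComponents:
    """REML variance components from the phenotyped accessions.

    Deterministic: spectral decomposition of the phenotyped submatrix of G,
    then one-dimensional optimization over the genetic:residual variance
    ratio.
    """
    obs = spec.phenotyped_ids
    if len(obs) < 10:
        raise ValueError("need at least 10 phenotyped accessions")
    y = spec.response.loc[obs].to_numpy()
    if np.var(y) <= 0:
        raise ValueError("phenotypic variance must be positive")
    X, _ = _design(spec, obs)
    G_oo = spec.kinship.submatrix(obs).G
    sg2, se2, ll = _spectral_reml(y, X, G_oo)
    return VarianceComponents(sg2, se2, reml_loglik=ll)


@dataclass
class GBLUPFit:
    """Solution of the mixed model equations for one trait."""

    accession_ids: list[str]
    beta_hat: pd.Series
    g_hat: pd.Series
    variance_components: VarianceComponents
    reliability: pd.Series | None = None
    phenotyped: pd.Index = field(default_factory=lambda: pd.Index([]))

    def predicted_values(self, covariates_row=None) -> pd.Series:
        """Intercept + genetic value; covariate contributions beyond the
        intercept are omitted (they depend on the accession's covariates)."""
        return self.beta_hat.get("intercept", 0.0) + self.g_hat


def _inv_G(G: np.ndarray) -> np.ndarray:
    """Inverse of G with ridge jitter when ill-conditioned (logged)."""
    s = linalg.eigvalsh(G)
    smax = max(s[-1], 0.0)
    smin = s[0]
    if smin <= 0 or (smax > 0 and smax / max(smin, 1e-300) > _COND_LIMIT):
        jit = _JITTER_SCALE * float(np.mean(np.diag(G)))
        logger.warning("G ill-conditioned; adding ridge jitter %.3g", jit)
        G = G + jit * np.eye(G.shape[0])
    return linalg.inv(G)


def _assemble_mme(spec: ModelSpec, vc: VarianceComponents):
    ids = list(spec.kinship.accession_ids)
    obs = spec.phenotyped_ids
    if vc.sigma_g2 <= 0:
        raise ValueError("sigma_g2 must be positive to assemble the MME")
    y = spec.response.loc[obs].to_numpy()
    X, names = _design(spec, obs)
    n_all = len(ids)
    obs_idx = spec.kinship.index_of(obs)
    Z = np.zeros((len(obs), n_all))
    Z[np.arange(len(obs)), obs_idx] = 1.0
    lam = vc.ratio
    Ginv = _inv_G(spec.kinship.G)
    C = np.block(
        [
            [X.T @ X, X.T @ Z],
            [Z.T @ X, Z.T @ Z + lam * Ginv],
        ]
    )
    rhs = np.concatenate([X.T @ y, Z.T @ y])
    return ids, obs, X, names, Z, C, rhs


def fit_gblup(
    spec: ModelSpec,
    vc: VarianceComponents | None = None,
    compute_reliability: bool = True,
) -> GBLUPFit:
    """Solve Henderson's mixed model equations.

    Unphenotyped accessions present in the kinship receive genetic-value
    BLUPs (and reliabilities) through the joint system; ``beta_hat`` is the
    GLS solution for the fixed effects.
    """
    if vc is None:
        vc = estimate_variance_components(spec)
    ids, obs, X, names, Z, C, rhs = _assemble_mme(spec, vc)
    p = X.shape[1]
    try:
        sol = linalg.solve(C, rhs, assume_a="sym")
    except linalg.LinAlgError:
        raise linalg.LinAlgError(
            "singular MME coefficient matrix; re-encode the fixed effects to full rank"
        )
    beta = pd.Series(sol[:p], index=names, name="beta_hat")
    g = pd.Series(sol[p:], index=ids, name="g_hat")
    fit = GBLUPFit(
        accession_ids=ids,
        beta_hat=beta,
        g_hat=g,
        variance_components=vc,
        phenotyped=pd.Index(obs),
    )
    if compute_reliability:
        fit.reliability = reliabilities(fit, spec)
    return fit


def reliabilities(fit: GBLUPFit, spec: ModelSpec) -> pd.Series:
    """Per-accession reliability ``r_i = 1 - d_i sigma_e^2 / sigma_g^2``.

    ``d_i`` is the diagonal of the ``C^22`` block of the Moore-Penrose
    pseudoinverse of the MME coefficient matrix assembled at the fitted
    variance ratio; defined for phenotyped and unphenotyped accessions
    alike, clipped to [0, 1].
    """
    vc = fit.variance_components
    ids, obs, X, names, Z, C, rhs = _assemble_mme(spec, vc)
    p = X.shape[1]
    Cinv = linalg.pinvh(C)
    d = np.diag(Cinv)[p:]
    r = 1.0 - d * vc.sigma_e2 / vc.sigma_g2
    if np.any(r < -1e-8):
        warnings.warn(
            f"reliability below -1e-8 (min {r.min():.3g}); check variance components",
            RuntimeWarning,
        )
    return pd.Series(np.clip(r, 0.0, 1.0), index=ids, name="reliability")


def predict_ability(predicted, observed) -> float:
    """Pearson correlation between predicted and observed values."""
    predicted = np.asarray(predicted, dtype=float)
    observed = np.asarray(observed, dtype=float)
    if predicted.shape != observed.shape or predicted.ndim != 1:
        raise ValueError("predicted and observed must be 1-D of equal length")
    if len(predicted) < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(predicted) == 0 or np.std(observed) == 0:
        raise ValueError("correlation undefined for a constant vector")
    return float(stats.pearsonr(predicted, observed)[0])
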