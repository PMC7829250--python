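"""Shared fixtures: small deterministic simulations reused across test modules."""

import numpy as np
import pandas as pd
import pytest

import genobank as gb


@pytest.fixture(scope="session")
def structured_sim():
    """Two Balding-Nichols subpopulations at Fst 0.3 with a major-gene class."""
    cfg = gb.SimConfig(seed=7, n_per_subpop=(150, 150), m=1000, fst=0.3)
    geno, truth = gb.simulate_genotypes(cfg)
    labels = gb.simulate_categorical(geno, cfg, truth)
    kin = gb.compute_grm(geno)
    return cfg, geno, labels, kin, truth


@pytest.fixture(scope="session")
def quantitative_sim():
    """Single unstructured population, polygenic trait h2 = 0.8, BLUEs."""
    cfg = gb.SimConfig(
        seed=11,
        n_per_subpop=(300,),
        m=600,
        fst=0.0,
        traits=(gb.TraitSpec("yield", h2=0.8, n_qtl=100),),
    )
    geno, truth = gb.simulate_genotypes(cfg)
    records = gb.simulate_quantitative(geno, cfg, truth)
    blues = gb.estimate_blues(records, "yield")
    kin = gb.compute_grm(geno)
    return cfg, geno, records, blues, kin, truth


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_psd_kinship(rng, n, m=None):
    """Random full-rank kinship from a small marker matrix plus a ridge."""
    m = m or 3 * n
    W = rng.normal(size=(n, m))
    G = W @ W.T / m + 0.05 * np.eye(n)
    ids = [f"i{j:03d}" for j in range(n)]
    return gb.Kinship(ids, G)


def gls_blup_oracle(y, X, G, Z, sigma_g2, sigma_e2):
    """Textbook GLS/BLUP closed form: beta = (X'V^-1X)^-1 X'V^-1 y and
    g_hat = sigma_g2 G Z' P y with P the projection-adjusted inverse of
    V = sigma_g2 Z G Z' + sigma_e2 I.  Independent of the MME route."""
    import scipy.linalg as la

    V = sigma_g2 * Z @ G @ Z.T + sigma_e2 * np.eye(Z.shape[0])
    Vi = la.inv(V)
    XtViX = X.T @ Vi @ X
    beta = la.solve(XtViX, X.T @ Vi @ y)
    P = Vi - Vi @ X @ la.inv(XtViX) @ X.T @ Vi
    g_hat = sigma_g2 * G @ Z.T @ P @ y
    pev = sigma_g2 * G - sigma_g2**2 * G @ Z.T @ P @ Z @ G
    return beta, g_hat, np.diag(pev)
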