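"""Multi-year phenotype records, per-accession BLUEs and categorical labels.

Records are long-format tables with columns (accession, trait, year, value):
days for flowering time, cm for plant height, g for thousand grain weight in
the barley application, but the module is unit-agnostic.  BLUEs come from
the linear mixed model

    value = genotype (fixed) + year (random, iid) + residual,

fitted by REML on the year-variance ratio with the genotype effects in
cell-means coding, so the reported BLUE is the adjusted mean of each
accession.  With a single year level the model degrades gracefully to
per-accession means.
"""

from __future__ import annotations

from typing import Callable

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "validate_records",
    "estimate_blues",
    "merge_growth_habit",
    "GROWTH_HABITS",
    "ROW_TYPES",
]

GROWTH_HABITS = ("spring", "winter", "intermediate", "facultative")
ROW_TYPES = ("two-rowed", "six-rowed", "deficiens", "intermedium", "labile")

RECORD_COLUMNS = ["accession", "trait", "year", "value"]


def validate_records(records: pd.DataFrame) -> pd.DataFrame:
    """Check the record schema and aggregate duplicate (accession, trait, year)
    cells by their mean."""
    missing = set(RECORD_COLUMNS) - set(records.columns)
    if missing:
        raise ValueError(f"records missing columns: {sorted(missing)}")
    rec = records[RECORD_COLUMNS].copy()
    rec["accession"] = rec["accession"].astype(str)
    rec["year"] = rec["year"].astype(int)
    rec["value"] = rec["value"].astype(float)
    if not np.all(np.isfinite(rec["value"])):
        raise ValueError("record values must be finite")
    return rec.groupby(["accession", "trait", "year"], as_index=False)["value"].mean()


def _reml_year_ratio(y, acc_codes, yr_codes, n_acc, n_yr):
    """Profile REML over gamma = sigma_year^2 / sigma_e^2.

    V = sigma_e^2 (I + gamma Z Z') with Z the year incidence; Woodbury keeps
    every solve at the size of the year table.
    """
    n = len(y)
    Xg = np.zeros((n, n_acc))
    Xg[np.arange(n), acc_codes] = 1.0
    Z = np.zeros((n, n_yr))
    Z[np.arange(n), yr_codes] = 1.0
    counts = Z.sum(axis=0)

    def fit_at(gamma):
        if gamma == 0.0:
            XtVX = Xg.T @ Xg
            XtVy = Xg.T @ y
            beta = np.linalg.solve(XtVX, XtVy)
            r = y - Xg @ beta
            quad = float(r @ r)
            logdetV0 = 0.0
        else:
            A = np.diag(counts + 1.0 / gamma)
            Ainv = np.diag(1.0 / (counts + 1.0 / gamma))
            ZtX = Z.T @ Xg
            Zty = Z.T @ y
            XtVX = Xg.T @ Xg - ZtX.T @ Ainv @ ZtX
            XtVy = Xg.T @ y - ZtX.T @ (Ainv @ Zty)
            beta = np.linalg.solve(XtVX, XtVy)
            r = y - Xg @ beta
            Ztr = Z.T @ r
            quad = float(r @ r - Ztr @ (Ainv @ Ztr))
            logdetV0 = float(np.sum(np.log(1.0 + gamma * counts)))
        return beta, quad, logdetV0, XtVX

    def neg_reml(log_gamma):
        gamma = np.exp(log_gamma)
        try:
            beta, quad, logdetV0, XtVX = fit_at(gamma)
        except np.linalg.LinAlgError:
            return np.inf
        if quad <= 0:
            return np.inf
        p = n_acc
        sigma_e2 = quad / (n - p)
        sign, logdetX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        return (n - p) * np.log(sigma_e2) + logdetV0 + logdetX

    grid = np.linspace(-12.0, 8.0, 41)
    vals = np.array([neg_reml(g) for g in grid])
    j = int(np.nanargmin(vals))
    res = optimize.minimize_scalar(
        neg_reml,
        bounds=(grid[max(j - 1, 0)], grid[min(j + 1, len(grid) - 1)]),
        method="bounded",
    )
    gamma = float(np.exp(res.x))
    if res.x <= grid[0] + 1e-9:
        gamma = 0.0
    beta, quad, _, _ = fit_at(gamma)
    sigma_e2 = quad / (n - n_acc)
    return beta, gamma, sigma_e2


def estimate_blues(
    records: pd.DataFrame,
    trait: str,
    prefilter: Callable[[pd.DataFrame], pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Best linear unbiased estimates per accession for one trait.

    Parameters
    ----------
    records : DataFrame with columns (accession, trait, year, value)
    trait : trait name to extract
    prefilter : optional callable applied to the trait's record table before
        fitting (hook for outlier handling; identity by default).

    Returns
    -------
    DataFrame indexed by accession with columns ``blue`` and ``n_records``.
    """
    rec = validate_records(records)
    rec = rec[rec["trait"] == trait]
    if rec.empty:
        raise ValueError(f"trait {trait!r} absent from records")
    if prefilter is not None:
        rec = validate_records(prefilter(rec))
    if rec["accession"].nunique() < 2:
        raise ValueError("need records for at least 2 accessions")

    acc = pd.Categorical(rec["accession"])
    yr = pd.Categorical(rec["year"])
    y = rec["value"].to_numpy()
    n_acc, n_yr = len(acc.categories), len(yr.categories)

    if n_yr == 1:
        blues = rec.groupby("accession")["value"].mean()
    else:
        beta, _, _ = _reml_year_ratio(y, acc.codes, yr.codes, n_acc, n_yr)
        blues = pd.Series(beta, index=list(acc.categories))
    out = pd.DataFrame(
        {
            "blue": blues,
            "n_records": rec.groupby("accession").size().reindex(blues.index),
        }
    )
    out.index.name = "accession"
    return out


def merge_growth_habit(labels: pd.Series) -> pd.Series:
    """Collapse growth habit to the two-class {spring, winter} vocabulary.

    Intermediate and facultative accessions are relabeled winter; missing
    labels stay missing.
    """
    mapping = {"intermediate": "winter", "facultative": "winter"}
    out = labels.replace(mapping)
    bad = set(out.dropna().unique()) - {"spring", "winter"}
    if bad:
        raise ValueError(f"unknown growth-habit labels: {sorted(bad)}")
    return out
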