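"""Genotype container, genomic relationship matrix, Rogers' distances and PCoA.

The genotype representation is a dense matrix of reference-allele dosages in
[0, 2]: integers {0, 1, 2} for hard calls, fractional values for imputed
dosages.  All derived matrices (kinship, distances, ordination coordinates)
carry the accession identifiers and are aligned by identifier, never by
position.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

__all__ = [
    "GenotypeMatrix",
    "Kinship",
    "DistanceMatrix",
    "PCoAResult",
    "allele_frequencies",
    "compute_grm",
    "rogers_distance",
    "pcoa",
]


def _check_unique(ids, what):
    ids = [str(i) for i in ids]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{what} must be unique")
    return ids


@dataclass
class GenotypeMatrix:
    """``n`` accessions x ``m`` biallelic markers as allele dosages.

    Parameters
    ----------
    accession_ids : sequence of str
        Unique accession identifiers (rows).
    marker_ids : sequence of str
        Unique marker identifiers (columns).
    dosages : ndarray of shape (n, m)
        Reference-allele dosages, each in [0, 2], no missing entries.
    """

    accession_ids: list[str]
    marker_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self):
        self.accession_ids = _check_unique(self.accession_ids, "accession_ids")
        self.marker_ids = _check_unique(self.marker_ids, "marker_ids")
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be a 2-D matrix")
        n, m = self.dosages.shape
        if n != len(self.accession_ids) or m != len(self.marker_ids):
            raise ValueError("dosage shape does not match id lists")
        if n < 2 or m < 1:
            raise ValueError("need at least 2 accessions and 1 marker")
        if not np.all(np.isfinite(self.dosages)):
            raise ValueError("dosages contain missing/non-finite entries")
        if self.dosages.min() < 0 or self.dosages.max() > 2:
            raise ValueError("dosages must lie in [0, 2]")

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    def index_of(self, ids) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            return np.array([pos[str(i)] for i in ids], dtype=int)
        except KeyError as e:  # pragma: no cover - message path
            raise KeyError(f"unknown accession id {e.args[0]!r}") from None

    def subset(self, ids) -> "GenotypeMatrix":
        """Row-subset by accession id, preserving the requested order."""
        idx = self.index_of(ids)
        return GenotypeMatrix(
            [self.accession_ids[i] for i in idx], list(self.marker_ids), self.dosages[idx]
        )


@dataclass
class Kinship:
    """VanRaden genomic relationship matrix over a set of accessions."""

    accession_ids: list[str]
    G: np.ndarray

    def __post_init__(self):
        self.accession_ids = _check_unique(self.accession_ids, "accession_ids")
        self.G = np.asarray(self.G, dtype=float)
        n = len(self.accession_ids)
        if self.G.shape != (n, n):
            raise ValueError("G shape does not match accession_ids")
        if not np.allclose(self.G, self.G.T, atol=1e-8 * max(1.0, np.abs(self.G).max())):
            raise ValueError("G must be symmetric")
        self.G = (self.G + self.G.T) / 2.0

    def index_of(self, ids) -> np.ndarray:
        pos = {a: i for i, a in enumerate(self.accession_ids)}
        try:
            return np.array([pos[str(i)] for i in ids], dtype=int)
        except KeyError as e:
            raise KeyError(f"unknown accession id {e.args[0]!r}") from None

    def submatrix(self, ids) -> "Kinship":
        idx = self.index_of(ids)
        return Kinship([self.accession_ids[i] for i in idx], self.G[np.ix_(idx, idx)])


@dataclass
class DistanceMatrix:
    """Symmetric pairwise distance matrix with zero diagonal, entries in [0, 1]."""

    accession_ids: list[str]
    D: np.ndarray

    def __post_init__(self):
        self.accession_ids = _check_unique(self.accession_ids, "accession_ids")
        self.D = np.asarray(self.D, dtype=float)
        n = len(self.accession_ids)
        if self.D.shape != (n, n):
            raise ValueError("D shape does not match accession_ids")
        if not np.allclose(self.D, self.D.T, atol=1e-10):
            raise ValueError("D must be symmetric")
        if not np.allclose(np.diag(self.D), 0.0, atol=1e-12):
            raise ValueError("D must have a zero diagonal")
        if self.D.min() < -1e-12 or self.D.max() > 1 + 1e-12:
            raise ValueError("distances must lie in [0, 1]")


@dataclass
class PCoAResult:
    """Principal-coordinate (classical MDS) embedding of a distance matrix."""

    accession_ids: list[str]
    coordinates: np.ndarray  # (n, k), columns ordered by decreasing eigenvalue
    eigenvalues: np.ndarray  # k leading eigenvalues, descending
    explained: np.ndarray  # proportions of the sum of positive eigenvalues
    negative_eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))


def allele_frequencies(geno: GenotypeMatrix) -> np.ndarray:
    """Observed reference-allele frequency per marker, mean(dosage) / 2."""
    return geno.dosages.mean(axis=0) / 2.0


def compute_grm(geno: GenotypeMatrix, freqs: np.ndarray | None = None) -> Kinship:
    """VanRaden genomic relationship matrix.

    ``G = W W' / (2 * sum_k p_k (1 - p_k))`` where ``W`` is the dosage matrix
    centered by twice the allele frequencies.  Monomorphic markers (frequency
    0 or 1) contribute zero to the cross-product and are excluded from the
    denominator sum.

    Parameters
    ----------
    geno : GenotypeMatrix
    freqs : array of shape (m,), optional
        Allele frequencies used for centering; defaults to the observed
        frequencies of `geno`.  Supplying training-set frequencies here
        keeps centering consistent when extending G to new accessions.
    """
    if freqs is None:
        freqs = allele_frequencies(geno)
    freqs = np.asarray(freqs, dtype=float)
    if freqs.shape != (geno.m,):
        raise ValueError("freqs must have one entry per marker")
    poly = (freqs > 0.0) & (freqs < 1.0)
    if not np.any(poly):
        raise ValueError("all markers are monomorphic; GRM denominator is zero")
    W = geno.dosages - 2.0 * freqs
    W[:, ~poly] = 0.0
    denom = 2.0 * np.sum(freqs[poly] * (1.0 - freqs[poly]))
    G = (W @ W.T) / denom
    return Kinship(list(geno.accession_ids), G)


def rogers_distance(geno: GenotypeMatrix) -> DistanceMatrix:
    """Mean per-locus Rogers' distance between all accession pairs.

    For a biallelic locus with dosages ``d_i``, ``d_j`` the per-locus Rogers'
    distance ``sqrt(0.5 * sum_alleles (p_a - q_a)^2)`` reduces to
    ``|d_i - d_j| / 2``; the pairwise distance is the arithmetic mean over
    loci, hence lies in [0, 1].
    """
    # mean_l |d_i - d_j| / 2 == cityblock(d_i, d_j) / (2 m)
    condensed = pdist(geno.dosages, metric="cityblock") / (2.0 * geno.m)
    return DistanceMatrix(list(geno.accession_ids), squareform(condensed))


def pcoa(D: DistanceMatrix, k: int) -> PCoAResult:
    """Classical multidimensional scaling (principal coordinate analysis).

    Double-centers ``-0.5 * D∘D``, eigendecomposes, and returns the top-``k``
    coordinate axes scaled by the square roots of their eigenvalues.
    Negative eigenvalues (non-Euclidean input) are reported but excluded
    both from the coordinates and from the explained-variance denominator.
    """
    n = len(D.accession_ids)
    k = int(k)
    if k < 1 or k >= n:
        raise ValueError(f"k must satisfy 1 <= k < n (got k={k}, n={n})")
    A = -0.5 * D.D**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = 1e-10 * max(1.0, abs(evals[0]) if n else 1.0)
    pos = evals > tol
    neg = evals < -tol
    total_pos = evals[pos].sum() if np.any(pos) else 0.0
    lead = evals[:k].copy()
    coords = np.zeros((n, k))
    scale = np.sqrt(np.clip(lead, 0.0, None))
    coords = evecs[:, :k] * scale
    if total_pos > 0:
        explained = np.clip(lead, 0.0, None) / total_pos
    else:
        explained = np.zeros(k)
    return PCoAResult(
        accession_ids=list(D.accession_ids),
        coordinates=coords,
        eigenvalues=lead,
        explained=explained,
        negative_eigenvalues=evals[neg],
    )
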