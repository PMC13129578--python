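"""Genotype encoding and sample-relatedness PCA.

Genotypes are encoded as alt-allele dosage (0/0 -> 0, 0/1 -> 1, 1/1 -> 2).
The PCA standardizes the samples x sites matrix column-wise (centered,
unit sample variance — the behaviour of R's ``prcomp(center=TRUE,
scale.=TRUE)``) and decomposes it by SVD.  Columns with zero variance
cannot be unit-scaled and are dropped first; their count is reported.
Component signs are arbitrary, as in any SVD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from .model import Cohort

__all__ = ["GenotypeMatrix", "PcaResult", "encode_genotypes", "run_pca"]

_CODE = {"0/0": 0, "0/1": 1, "1/1": 2}


@dataclass
class GenotypeMatrix:
    samples: list[str]
    sites: list[str]  # "chrom-pos-type" keys in (chrom, pos) order
    values: np.ndarray  # shape (n_samples, n_sites), ints in {0,1,2}


@dataclass
class PcaResult:
    scores: np.ndarray  # (n_samples, n_components)
    explained_fraction: np.ndarray
    loadings: np.ndarray  # (n_kept_sites, n_components)
    n_dropped_sites: int
    site_keys: list[str]


def encode_genotypes(cohort: Cohort) -> GenotypeMatrix:
    """Dosage-encode the cohort into a samples x sites integer matrix."""
    if not cohort.sites:
        raise ValueError("cohort has no sites")
    keys = [s.key for s in cohort.sites]
    values = np.array(
        [[_CODE[s.genotypes.get(sample, "0/0")] for s in cohort.sites] for sample in cohort.samples],
        dtype=np.int8,
    )
    return GenotypeMatrix(samples=list(cohort.samples), sites=keys, values=values)


def run_pca(matrix: GenotypeMatrix, center: bool = True, scale: bool = True) -> PcaResult:
    """Centered, unit-variance PCA of the dosage matrix."""
    X = matrix.values.astype(float)
    if X.shape[0] < 2:
        raise ValueError("PCA requires at least two samples")
    variances = X.var(axis=0)
    keep = variances > 0
    n_dropped = int((~keep).sum())
    if not keep.any():
        raise ValueError("all genotype columns are constant; PCA undefined")
    X = X[:, keep]
    site_keys = [k for k, kept in zip(matrix.sites, keep) if kept]
    if center:
        X = X - X.mean(axis=0)
    if scale:
        X = X / X.std(axis=0, ddof=1)
    n_comp = min(X.shape)
    if center:
        pca = PCA(n_components=n_comp, svd_solver="full")
        scores = pca.fit_transform(X)
        explained = pca.explained_variance_ratio_
        loadings = pca.components_.T
    else:
        # sklearn's PCA always re-centers; for an uncentered decomposition
        # take the SVD of the matrix as-is
        U, s, Vt = np.linalg.svd(X, full_matrices=False)
        scores = U * s
        explained = s**2 / np.sum(s**2)
        loadings = Vt.T
        scores, explained, loadings = scores[:, :n_comp], explained[:n_comp], loadings[:, :n_comp]
    return PcaResult(
        scores=scores,
        explained_fraction=explained,
        loadings=loadings,
        n_dropped_sites=n_dropped,
        site_keys=site_keys,
    )
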