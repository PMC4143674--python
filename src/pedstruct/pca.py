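"""Principal components for pedigree samples, three ways.

All three derivations share Eigenstrat-style SNP normalization
(mean-centering by twice the allele frequency, scaling by the binomial
standard deviation at a smoothed frequency estimate) and differ only in who
determines the axes:

* ``all`` — every genotyped individual, uniform weights (diversity of the
  whole sample, but large families can swamp small ones);
* ``weighted`` — individuals weighted by the inverse of their family's
  genotyped size, so each family contributes equal total weight to allele
  frequencies, centering, and the covariance operator;
* ``unrelated`` — fit on a maximal pairwise-unrelated subset (founders and
  marry-ins), with everyone else projected onto the fitted axes.

Scores use the convention s = X v with unit-norm SNP loadings v, so
sum_i w_i s_ik s_il = lambda_k delta_kl: score vectors are orthogonal under
the weight metric and have weighted mean zero.  The sign of each component
is fixed by making its largest-magnitude loading positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix
from .pedigree import Pedigree

__all__ = ["NormalizedMatrix", "PCAResult", "normalize", "pca_all",
           "pca_weighted", "pca_unrelated", "scree_report", "write_evec"]

log = logging.getLogger(__name__)


@dataclass
class NormalizedMatrix:
    """Centered/scaled dosage matrix ready for eigendecomposition."""

    values: np.ndarray          # n x m', float64; missing imputed to 0
    column_freqs: np.ndarray    # smoothed alt-frequency estimate per kept SNP
    column_centers: np.ndarray  # 2 x (unsmoothed weighted frequency)
    kept_snps: np.ndarray       # indices into the source SNP table
    weights: np.ndarray         # per-individual weights used (sum to 1)


@dataclass
class PCAResult:
    approach: str
    eigenvalues: np.ndarray         # descending, non-negative
    variance_fraction: np.ndarray   # lambda_k / total variance
    scores: np.ndarray              # n x k, rows follow `samples`
    loadings: np.ndarray            # m' x k, unit-norm columns
    weights: np.ndarray             # per-individual weight used in the fit
    samples: list[tuple[str, str]]
    projected: np.ndarray = field(default=None)  # bool per individual

    def __post_init__(self) -> None:
        if self.projected is None:
            self.projected = np.zeros(len(self.samples), dtype=bool)

    @property
    def n_components(self) -> int:
        return len(self.eigenvalues)

    def scores_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.scores,
                          columns=[f"PC{i+1}" for i in range(self.n_components)])
        df.insert(0, "fid", [f for f, _ in self.samples])
        df.insert(1, "iid", [i for _, i in self.samples])
        df["projected"] = self.projected
        return df


def normalize(
    g: GenotypeMatrix,
    weights: np.ndarray | None = None,
    smoothing: bool = True,
) -> NormalizedMatrix:
    """Eigenstrat-style normalization under per-individual weights.

    The weighted alt-allele frequency q_j is estimated over non-missing
    entries; each column is centered at 2 q_j (exact weighted mean zero) and
    scaled by sqrt(p_j (1 - p_j)), where p_j is q_j with plus-one posterior
    smoothing at the effective sample size (p = (2 n_eff q + 1) /
    (2 n_eff + 2)) unless ``smoothing`` is off.  Missing dosages become 0
    after centering (mean imputation); columns monomorphic among observed
    entries are dropped.
    """
    n, m = g.dosages.shape
    w = np.full(n, 1.0 / n) if weights is None else np.asarray(weights, float)
    if w.shape != (n,) or np.any(w <= 0):
        raise ValueError("weights must be positive, one per individual")
    w = w / w.sum()

    D = g.dosages.astype(np.float64)
    obs = g.dosages != MISSING
    D[~obs] = 0.0
    w_obs = w @ obs                      # total weight observing each SNP
    with np.errstate(invalid="ignore", divide="ignore"):
        q = (w @ D) / (2.0 * w_obs)
    keep = np.nonzero(obs.any(axis=0) & (q > 0) & (q < 1))[0]
    if keep.size == 0:
        raise ValueError("all columns monomorphic after frequency estimation")
    q = q[keep]
    if smoothing:
        n_eff = 1.0 / float(w @ w)
        p = (2.0 * n_eff * q + 1.0) / (2.0 * n_eff + 2.0)
    else:
        p = q
    X = (D[:, keep] - 2.0 * q) / np.sqrt(p * (1.0 - p))
    X[~obs[:, keep]] = 0.0
    return NormalizedMatrix(values=X, column_freqs=p, column_centers=2.0 * q,
                            kept_snps=keep, weights=w)


def _decompose(norm: NormalizedMatrix, approach: str,
               samples: list[tuple[str, str]],
               n_components: int | None = None) -> PCAResult:
    X, w = norm.values, norm.weights
    n = X.shape[0]
    sw = np.sqrt(w)
    C = (sw[:, None] * X) @ (sw[:, None] * X).T
    total_var = float(np.trace(C))
    evals, evecs = np.linalg.eigh(C)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    evals = np.clip(evals, 0.0, None)
    # centering removes one degree of freedom; discard numerically-null PCs
    rank = min(n - 1, X.shape[1])
    tol = max(evals[0] * 1e-12, 0.0) if evals.size else 0.0
    k = int(np.sum(evals[:rank] > tol))
    if n_components is not None:
        k = min(k, n_components)
    if k < rank:
        log.debug("pca[%s]: %d informative components (of %d possible)",
                  approach, k, rank)
    evals, evecs = evals[:k], evecs[:, :k]

    with np.errstate(divide="ignore", invalid="ignore"):
        loadings = (X.T @ (sw[:, None] * evecs)) / np.sqrt(evals)
        scores = (np.sqrt(evals) / sw[:, None]) * evecs
    # sign convention: largest-magnitude loading positive
    for j in range(k):
        a = np.argmax(np.abs(loadings[:, j]))
        if loadings[a, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    return PCAResult(approach=approach, eigenvalues=evals,
                     variance_fraction=evals / total_var if total_var else evals,
                     scores=scores, loadings=loadings, weights=w,
                     samples=list(samples))


def pca_all(g: GenotypeMatrix, n_components: int | None = None,
            smoothing: bool = True) -> PCAResult:
    """Approach using all genotyped individuals with uniform weights."""
    if g.n_samples < 2:
        raise ValueError("need at least 2 individuals")
    norm = normalize(g, smoothing=smoothing)
    return _decompose(norm, "all", g.samples, n_components)


def family_weights(g: GenotypeMatrix, ped: Pedigree | None = None) -> np.ndarray:
    """Per-individual weights (1 / family size) / (number of families), so
    every family's total weight is equal and the weights sum to 1.  Family
    membership is the fid of each sample; ``ped`` is accepted for interface
    symmetry but fids in the genotype matrix are authoritative."""
    fids = [f for f, _ in g.samples]
    sizes = pd.Series(fids).value_counts()
    n_fam = len(sizes)
    return np.array([1.0 / (sizes[f] * n_fam) for f in fids])


def pca_weighted(g: GenotypeMatrix, ped: Pedigree | None = None,
                 n_components: int | None = None, smoothing: bool = True,
                 weighting: str = "full") -> PCAResult:
    """Inverse-family-size weighted PCA: families contribute equally.

    ``weighting='full'`` (default) applies the weights to frequency
    estimation, centering, and the covariance operator;
    ``'covariance-only'`` keeps uniform-weight normalization and weights
    only the covariance.
    """
    w = family_weights(g, ped)
    if weighting == "full":
        norm = normalize(g, weights=w, smoothing=smoothing)
    elif weighting == "covariance-only":
        norm = normalize(g, smoothing=smoothing)
        norm = NormalizedMatrix(norm.values, norm.column_freqs,
                                norm.kept_snps, w / w.sum())
    else:
        raise ValueError("weighting must be 'full' or 'covariance-only'")
    return _decompose(norm, "weighted", g.samples, n_components)


def pca_unrelated(
    g: GenotypeMatrix,
    unrelated: list[tuple[str, str]],
    project_all: bool = True,
    n_components: int | None = None,
    smoothing: bool = True,
) -> PCAResult:
    """PCA fit on a pairwise-unrelated subset; relatives optionally
    projected onto the fitted loadings using the subset's allele
    frequencies for normalization (``projected`` flags them)."""
    keys = [tuple(k) for k in unrelated]
    keyset = set(keys)
    if not keyset <= set(g.samples):
        raise ValueError("unrelated set contains samples absent from genotypes")
    if len(keys) < 2:
        raise ValueError("need at least 2 unrelated individuals")
    g_fit = g.subset_samples(keys)
    norm = normalize(g_fit, smoothing=smoothing)
    res = _decompose(norm, "unrelated", g_fit.samples, n_components)
    if not project_all:
        return res

    # normalize everyone with the subset's frequency estimates, project
    D = g.dosages[:, norm.kept_snps].astype(np.float64)
    obs = g.dosages[:, norm.kept_snps] != MISSING
    p = norm.column_freqs
    Xall = (D - norm.column_centers) / np.sqrt(p * (1.0 - p))
    Xall[~obs] = 0.0
    scores = Xall @ res.loadings
    projected = np.array([s not in keyset for s in g.samples])
    # fitted individuals keep their fit-time scores (identical by algebra,
    # asserted in tests); weights vector reported for the fit subset
    return PCAResult(approach="unrelated", eigenvalues=res.eigenvalues,
                     variance_fraction=res.variance_fraction, scores=scores,
                     loadings=res.loadings, weights=res.weights,
                     samples=list(g.samples), projected=projected)


def scree_report(res: PCAResult, margin: float = 0.2) -> tuple[pd.DataFrame, int]:
    """Eigenvalue table plus a heuristic elbow suggestion.

    Suggested k is the largest k with lambda_k > (1 + margin) x mean of the
    remaining eigenvalues — a labeled heuristic, not a significance test;
    the retained-PC count stays a user parameter downstream.
    """
    lam = np.asarray(res.eigenvalues, float)
    if lam.size == 0:
        raise ValueError("no eigenvalues")
    cum = np.cumsum(res.variance_fraction)
    table = pd.DataFrame(dict(pc=np.arange(1, lam.size + 1), eigenvalue=lam,
                              variance_fraction=res.variance_fraction,
                              cumulative_fraction=cum))
    suggested = 0
    for k in range(lam.size - 1, 0, -1):
        if lam[k - 1] > (1.0 + margin) * lam[k:].mean():
            suggested = k
            break
    return table, suggested


def write_evec(res: PCAResult, path, ped: Pedigree | None = None) -> None:
    """Eigenstrat .evec-compatible output: a header row of eigenvalues, then
    one row per individual (fid:iid, PC coordinates, family label)."""
    with open(path, "w") as fh:
        fh.write("#eigvals: " + " ".join(f"{v:.6g}" for v in res.eigenvalues)
                 + "\n")
        for (fid, iid), row in zip(res.samples, res.scores):
            fh.write("\t".join([f"{fid}:{iid}",
                                *(f"{v:.6g}" for v in row), fid]) + "\n")
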