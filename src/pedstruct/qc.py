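"""Genotype cleaning chain.

The cleaning order mirrors standard pre-PCA practice for family data:
duplicate/monozygotic-twin removal, call-rate filtering (SNPs before
samples), LD pruning to an approximately independent marker panel, then a
Hardy-Weinberg exact-test sweep summarized as a Q-Q table.  HWE is assessed
on unrelated individuals only by default, since relatives violate the
binomial sampling assumption behind the test.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import MISSING, GenotypeMatrix
from .pedigree import Pedigree

__all__ = ["drop_mz_twins", "call_rate_filter", "ld_prune", "hwe_exact",
           "qq_summary", "HWEResult", "QQSummary"]

log = logging.getLogger(__name__)


def drop_mz_twins(
    g: GenotypeMatrix,
    ped: Pedigree | None = None,
    identity_threshold: float = 0.999,
    seed: int = 0,
) -> tuple[GenotypeMatrix, list[tuple[str, str]]]:
    """Remove all but one member of each monozygotic-twin/duplicate cluster.

    Same-family sample pairs whose genotype concordance over the non-missing
    overlap exceeds ``identity_threshold`` are clustered by transitive
    closure; one member of each cluster is kept, chosen by a seeded RNG, and
    the dropped sample keys are returned.  Concordance-based detection is a
    reproducible surrogate for provider-identified MZ twins.
    """
    if not (0.9 < identity_threshold <= 1.0):
        raise ValueError("identity_threshold must be in (0.9, 1]")
    rng = np.random.default_rng(seed)
    n = g.n_samples
    parent = list(range(n))

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    by_fam: dict[str, list[int]] = {}
    for i, (fid, _) in enumerate(g.samples):
        by_fam.setdefault(fid, []).append(i)

    valid = g.dosages != MISSING
    for idxs in by_fam.values():
        for a_pos, i in enumerate(idxs):
            for j in idxs[a_pos + 1:]:
                both = valid[i] & valid[j]
                nb = int(both.sum())
                if nb == 0:
                    continue
                conc = float((g.dosages[i, both] == g.dosages[j, both]).mean())
                if conc >= identity_threshold:
                    parent[find(i)] = find(j)

    clusters: dict[int, list[int]] = {}
    for i in range(n):
        clusters.setdefault(find(i), []).append(i)
    drop: list[int] = []
    for members in clusters.values():
        if len(members) > 1:
            keep = members[int(rng.integers(len(members)))]
            drop.extend(m for m in members if m != keep)
    if not drop:
        return g, []
    dropped_keys = [g.samples[i] for i in sorted(drop)]
    keep_idx = [i for i in range(n) if i not in set(drop)]
    log.info("drop_mz_twins: removed %d duplicate samples", len(drop))
    return g.take_samples(keep_idx), dropped_keys


def call_rate_filter(
    g: GenotypeMatrix,
    min_snp_rate: float = 0.98,
    min_sample_rate: float = 0.95,
) -> GenotypeMatrix:
    """Drop low-call-rate SNPs, then low-call-rate samples (in that order —
    sample call rates are recomputed on the surviving SNP panel)."""
    if not (0 <= min_snp_rate <= 1 and 0 <= min_sample_rate <= 1):
        raise ValueError("call-rate thresholds must be in [0, 1]")
    keep_snps = np.nonzero(g.snp_call_rate() >= min_snp_rate)[0]
    if keep_snps.size == 0:
        raise ValueError("empty panel: all SNPs fail the call-rate filter")
    g2 = g.take_snps(keep_snps)
    keep_samples = np.nonzero(g2.sample_call_rate() >= min_sample_rate)[0]
    return g2.take_samples(keep_samples)


def _pairwise_complete_r2(X: np.ndarray) -> np.ndarray:
    """r^2 between columns of X over pairwise-complete observations.

    Returns (r2, n_pairs); undefined correlations (zero variance or no
    overlap) come back as 0."""
    M = (X != MISSING).astype(np.float64)
    A = np.where(X == MISSING, 0, X).astype(np.float64)
    A2 = A * A
    n = M.T @ M
    Sx = A.T @ M
    Sy = Sx.T
    Sxx = A2.T @ M
    Syy = Sxx.T
    Sxy = A.T @ A
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * Sxy - Sx * Sy
        var = (n * Sxx - Sx * Sx) * (n * Syy - Sy * Sy)
        r2 = np.where(var > 0, cov * cov / var, 0.0)
    return r2, n


def ld_prune(
    g: GenotypeMatrix,
    r2_max: float = 0.5,
    window: int = 50,
    step: int = 5,
    min_pairs: int = 10,
) -> GenotypeMatrix:
    """Windowed greedy LD pruning on dosage correlation.

    Within each chromosome (SNPs in position order), a window of ``window``
    SNPs advances by ``step``; whenever two retained SNPs in the window have
    squared Pearson dosage correlation above ``r2_max`` the later-position
    SNP is removed.  Pairs with fewer than ``min_pairs`` complete
    observations are left unexamined (and logged).  The survivor panel has
    no within-window pair exceeding the threshold.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    order = np.lexsort((g.snps.pos.to_numpy(), g.snps.chrom.to_numpy()))
    keep_global: list[int] = []
    skipped_pairs = 0
    for chrom in pd.unique(g.snps.chrom.to_numpy()[order]):
        cidx = order[g.snps.chrom.to_numpy()[order] == chrom]
        m = cidx.size
        kept = np.ones(m, dtype=bool)
        start = 0
        while True:
            end = min(start + window, m)
            live = np.nonzero(kept[start:end])[0] + start
            if live.size > 1:
                r2, npairs = _pairwise_complete_r2(
                    g.dosages[:, cidx[live]].astype(np.float64))
                for a in range(live.size):
                    if not kept[live[a]]:
                        continue
                    for b in range(a + 1, live.size):
                        if not kept[live[b]]:
                            continue
                        if npairs[a, b] < min_pairs:
                            skipped_pairs += 1
                            continue
                        if r2[a, b] > r2_max:
                            kept[live[b]] = False  # later position removed
            if end == m:
                break
            start += step
        keep_global.extend(cidx[kept])
    if skipped_pairs:
        log.info("ld_prune: %d pairs with <%d complete observations left "
                 "unexamined", skipped_pairs, min_pairs)
    return g.take_snps(np.sort(keep_global))


@dataclass
class HWEResult:
    """Per-SNP exact-test results: table with snp_id, p, n, obs_het, exp_het."""

    table: pd.DataFrame

    @property
    def pvalues(self) -> np.ndarray:
        return self.table["p"].to_numpy()


def hwe_exact_pvalue(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Exact Hardy-Weinberg test p-value for one biallelic SNP.

    Conditional on the allele count, P(n_het | n, n_alt) is proportional to
    the multinomial weight times 2^n_het; the p-value sums the probabilities
    of all heterozygote counts no more probable than the observed one.
    Monomorphic SNPs return 1 by convention.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = n_het + 2 * n_hom_alt
    if n == 0 or n_alt == 0 or n_alt == 2 * n:
        return 1.0
    rare = min(n_alt, 2 * n - n_alt)
    # heterozygote counts share the parity of the rare-allele count
    h_min = rare % 2
    hs = np.arange(h_min, rare + 1, 2)
    # log-probabilities (unnormalized), stable for large n; counts expressed
    # in the rare allele: rare_hom + common_hom + het = n
    from scipy.special import gammaln
    rare_hom = (rare - hs) // 2
    common_hom = n - hs - rare_hom
    logp = (hs * np.log(2.0)
            - gammaln(hs + 1) - gammaln(rare_hom + 1) - gammaln(common_hom + 1))
    logp -= logp.max()
    p = np.exp(logp)
    p /= p.sum()
    obs = p[(hs == n_het).nonzero()[0][0]]
    return float(min(1.0, p[p <= obs * (1 + 1e-12)].sum()))


def hwe_exact(g: GenotypeMatrix, subset=None) -> HWEResult:
    """Exact HWE test per SNP over ``subset`` (sample keys; default all).

    The recommended subset is a maximal unrelated genotyped set, since
    related individuals do not contribute independent genotypes.
    """
    gm = g.subset_samples(subset) if subset is not None else g
    if gm.n_samples == 0:
        raise ValueError("empty sample subset for HWE")
    rows = []
    for j, snp_id in enumerate(gm.snps.snp_id):
        d = gm.dosages[:, j]
        n0 = int((d == 0).sum())
        n1 = int((d == 1).sum())
        n2 = int((d == 2).sum())
        n = n0 + n1 + n2
        q = (n1 + 2 * n2) / (2 * n) if n else 0.0
        rows.append((snp_id, hwe_exact_pvalue(n0, n1, n2), n, n1,
                     2 * n * q * (1 - q)))
    return HWEResult(pd.DataFrame(
        rows, columns=["snp_id", "p", "n", "obs_het", "exp_het"]))


@dataclass
class QQSummary:
    """Q-Q table of -log10 p-values plus a genomic-inflation-style slope."""

    table: pd.DataFrame        # columns: expected, observed (-log10 scale)
    lambda_gc: float


def qq_summary(pvals) -> QQSummary:
    """Observed vs expected p-value quantiles and the median-based inflation
    factor lambda = median(chi2_1(p)) / 0.4549."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    obs = np.sort(p)
    m = p.size
    expected = (np.arange(1, m + 1) - 0.5) / m
    table = pd.DataFrame(dict(expected=-np.log10(expected),
                              observed=-np.log10(obs)))
    chi = stats.chi2.isf(p, df=1)
    lam = float(np.median(chi) / stats.chi2.isf(0.5, df=1))
    return QQSummary(table=table, lambda_gc=lam)
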