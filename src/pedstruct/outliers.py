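"""Family-level outlier detection in PC space.

The core statistic is the leave-one-family-out standardized centroid
distance: drop each family in turn, recompute the centroid and per-PC
standard deviations of everyone else (the PC scores themselves stay fixed),
and measure how many SDs the dropped family's centroid sits from the rest.
Families are ranked by this distance; a generational-trajectory summary
shows the regression of an outlier family toward the group mean as
marry-ins dilute its founder ancestry.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .pca import PCAResult
from .pedigree import Individual, Pedigree

__all__ = ["OutlierReport", "GenerationalTrajectory", "family_centroids",
           "loo_sd_distance", "generational_trajectory", "rank_and_flag",
           "marryin_flags"]


@dataclass
class OutlierReport:
    """Per-family leave-one-out distances (SD units), ranks, and centroids."""

    table: pd.DataFrame     # fid, n, centroid coords, distance_sd, rank
    k: int
    approach: str

    def ranked(self) -> pd.DataFrame:
        return self.table.sort_values("rank").reset_index(drop=True)


@dataclass
class GenerationalTrajectory:
    """Per-generation summary of one family's drift toward the sample mean."""

    fid: str
    per_generation: pd.DataFrame   # generation, n, mean dist (all/descendants)
    per_individual: pd.DataFrame   # iid, generation, marryin, PCs, dist
    k: int


def _score_block(res: PCAResult, k: int) -> np.ndarray:
    if k > res.n_components:
        raise ValueError(f"k={k} exceeds {res.n_components} available PCs")
    return res.scores[:, :k]


def family_centroids(res: PCAResult, ped: Pedigree | None, k: int
                     ) -> pd.DataFrame:
    """Unweighted per-family mean of member scores over the first k PCs.

    The last row (fid ``__global__``) is the centroid of all individuals.
    """
    S = _score_block(res, k)
    fids = np.array([f for f, _ in res.samples])
    rows = []
    for fid in sorted(set(fids)):
        mask = fids == fid
        if not mask.any():  # pragma: no cover - defensive
            warnings.warn(f"family {fid} has no scored members")
            continue
        rows.append((fid, int(mask.sum()), *S[mask].mean(axis=0)))
    rows.append(("__global__", len(fids), *S.mean(axis=0)))
    return pd.DataFrame(rows,
                        columns=["fid", "n", *[f"PC{i+1}" for i in range(k)]])


def loo_sd_distance(res: PCAResult, ped: Pedigree | None, k: int,
                    mahalanobis: bool = False) -> OutlierReport:
    """Leave-one-family-out standardized centroid distance per family.

    For family f, the centroid of its members is compared with the centroid
    of all remaining individuals, standardized by the remaining
    individuals' per-PC population SD (divide by n); the distance is the
    per-axis standardized Euclidean norm over the first k PCs (full
    covariance Mahalanobis with ``mahalanobis=True``).  PC scores are held
    fixed from the input fit; only centroid and SD are recomputed.
    """
    S = _score_block(res, k)
    fids = np.array([f for f, _ in res.samples])
    unique = sorted(set(fids))
    if len(unique) < 2:
        raise ValueError("need at least 2 families")
    rows = []
    for fid in unique:
        mask = fids == fid
        rest = S[~mask]
        if rest.shape[0] < 2:
            raise ValueError(f"fewer than 2 individuals remain without {fid}")
        c = S[mask].mean(axis=0)
        m = rest.mean(axis=0)
        if mahalanobis:
            cov = np.cov(rest, rowvar=False, ddof=0).reshape(k, k)
            d = float(np.sqrt((c - m) @ np.linalg.solve(cov, c - m)))
        else:
            sd = rest.std(axis=0, ddof=0)
            d = float(np.sqrt(np.sum(((c - m) / sd) ** 2)))
        rows.append((fid, int(mask.sum()), *c, d))
    table = pd.DataFrame(rows, columns=["fid", "n",
                                        *[f"PC{i+1}" for i in range(k)],
                                        "distance_sd"])
    table["rank"] = (table["distance_sd"].rank(ascending=False, method="first")
                     .astype(int))
    return OutlierReport(table=table, k=k, approach=res.approach)


def marryin_flags(ped: Pedigree, fid: str) -> dict[str, bool]:
    """Classify each generation-0 member of a family.

    A marry-in is a generation-0 individual none of whose children has a
    generation-0 co-parent; childless generation-0 members are treated as
    marry-ins.  The remaining generation-0 members form founding couples.
    """
    members = ped.families[fid]
    children: dict[str, list[Individual]] = {}
    for m in members:
        if m.father:
            children.setdefault(m.father, []).append(m)
            children.setdefault(m.mother, []).append(m)
    flags = {}
    for m in members:
        if m.generation != 0:
            continue
        kids = children.get(m.iid, [])
        couple = False
        for kid in kids:
            other = kid.father if kid.mother == m.iid else kid.mother
            if ped[(fid, other)].generation == 0:
                couple = True
        flags[m.iid] = not couple
    return flags


def generational_trajectory(res: PCAResult, ped: Pedigree, fid: str, k: int
                            ) -> GenerationalTrajectory:
    """Group a family's scored members by generation and measure each
    generation's mean distance to the global centroid.

    Marry-ins are flagged and excluded from the descendant-only means:
    being drawn from the general population, they sit near the global
    centroid and would mask the founder lineage's convergence.
    """
    if fid not in ped.families:
        raise KeyError(f"family {fid!r} not in pedigree")
    S = _score_block(res, k)
    global_centroid = S.mean(axis=0)
    pos = {key: i for i, key in enumerate(res.samples)}
    flags = marryin_flags(ped, fid)
    rows = []
    for m in ped.families[fid]:
        if m.key not in pos:
            continue
        s = S[pos[m.key]]
        rows.append(dict(iid=m.iid, generation=m.generation,
                         marryin=flags.get(m.iid, False),
                         **{f"PC{i+1}": s[i] for i in range(k)},
                         dist=float(np.linalg.norm(s - global_centroid))))
    per_ind = pd.DataFrame(rows).sort_values(["generation", "iid"]
                                             ).reset_index(drop=True)
    gen_rows = []
    for gen, grp in per_ind.groupby("generation"):
        desc = grp[~grp.marryin]
        pcs = [f"PC{i+1}" for i in range(k)]
        gen_rows.append(dict(
            generation=int(gen), n=len(grp), n_descendant=len(desc),
            mean_dist=float(grp.dist.mean()),
            mean_dist_descendants=(float(desc.dist.mean()) if len(desc)
                                   else np.nan),
            **{f"mean_{c}": float(grp[c].mean()) for c in pcs}))
    per_gen = pd.DataFrame(gen_rows)
    return GenerationalTrajectory(fid=fid, per_generation=per_gen,
                                  per_individual=per_ind, k=k)


def rank_and_flag(report: OutlierReport, sd_flag: float = 2.0
                  ) -> pd.DataFrame:
    """Order families by distance (descending) and flag those at or above
    ``sd_flag`` SDs.  The default of 2 SD is a tool default chosen to sit
    between typical outlier and non-outlier ranges, not a universal
    constant."""
    if sd_flag < 0:
        raise ValueError("sd_flag must be non-negative")
    out = report.table.sort_values("distance_sd", ascending=False
                                   ).reset_index(drop=True)
    out["flagged"] = out["distance_sd"] >= sd_flag
    return out
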