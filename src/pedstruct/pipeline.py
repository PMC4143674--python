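"""End-to-end pipeline: QC -> kinship -> PCA (three approaches) -> outliers.

The pipeline is a pure function of (input files, RunConfig, seed): rerunning
with the same configuration reproduces every artifact bit-for-bit.  Each
stage logs samples/SNPs in and out, and the manifest reconciles the counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .genotypes import GenotypeMatrix, load_genotypes
from .outliers import (GenerationalTrajectory, OutlierReport, family_centroids,
                       generational_trajectory, loo_sd_distance, marryin_flags,
                       rank_and_flag)
from .pca import PCAResult, pca_all, pca_unrelated, pca_weighted, scree_report, write_evec
from .pedigree import Pedigree, kinship_matrix, max_unrelated_genotyped_set
from .qc import call_rate_filter, drop_mz_twins, hwe_exact, ld_prune, qq_summary

log = logging.getLogger(__name__)

APPROACHES = ("all", "weighted", "unrelated")


@dataclass
class RunConfig:
    input: str
    format: str | None = None          # ped | bed | vcf | None = infer
    fam: str | None = None             # pedigree for VCF input
    outdir: str = "pedstruct_out"
    seed: int = 0
    # QC
    mz_identity_threshold: float = 0.999
    min_snp_call_rate: float = 0.98
    min_sample_call_rate: float = 0.95
    ld_r2_max: float = 0.5
    ld_window: int = 50
    ld_step: int = 5
    hwe_on_all_samples: bool = False
    # kinship / unrelated subset
    kinship_threshold: float = 0.0
    # PCA / outliers
    approaches: tuple[str, ...] = APPROACHES
    k: dict | None = None              # per-approach retained PCs; None = scree
    sd_flag: float = 2.0
    max_pcs: int = 20

    def resolved_approaches(self) -> tuple[str, ...]:
        if self.approaches in ("every", ("every",)):
            return APPROACHES
        ap = ((self.approaches,) if isinstance(self.approaches, str)
              else tuple(self.approaches))
        bad = set(ap) - set(APPROACHES)
        if bad:
            raise ValueError(f"unknown approaches {sorted(bad)}")
        return ap


@dataclass
class RunArtifacts:
    config: RunConfig
    genotypes: GenotypeMatrix          # post-QC
    pedigree: Pedigree                 # restricted to post-QC samples
    unrelated: list
    pca: dict[str, PCAResult]
    retained_k: dict[str, int]
    outliers: dict[str, OutlierReport]
    flagged: dict[str, pd.DataFrame]
    trajectories: dict[str, dict[str, GenerationalTrajectory]]
    stage_counts: list[dict] = field(default_factory=list)


def _stage(counts: list, name: str, g: GenotypeMatrix, t0: float,
           **extra) -> None:
    rec = dict(stage=name, samples=g.n_samples, snps=g.n_snps,
               seconds=round(time.time() - t0, 3), **extra)
    counts.append(rec)
    log.info("stage %-16s samples=%d snps=%d (%.2fs)", name, g.n_samples,
             g.n_snps, rec["seconds"])


def run_pipeline(cfg: RunConfig, write: bool = True) -> RunArtifacts:
    """Execute the full analysis; optionally write artifacts to
    ``cfg.outdir`` (eigenvectors, QC and outlier reports, plot tables,
    manifest)."""
    counts: list[dict] = []
    t0 = time.time()
    g, ped = load_genotypes(cfg.input, cfg.format, fam=cfg.fam)
    if ped is None:
        raise ValueError("pedigree structure required: supply fam= for VCF")
    _stage(counts, "load", g, t0)

    t0 = time.time()
    g, dropped = drop_mz_twins(g, ped, cfg.mz_identity_threshold, cfg.seed)
    _stage(counts, "drop_mz_twins", g, t0, dropped=[list(k) for k in dropped])

    t0 = time.time()
    g = call_rate_filter(g, cfg.min_snp_call_rate, cfg.min_sample_call_rate)
    _stage(counts, "call_rate", g, t0)

    t0 = time.time()
    g = ld_prune(g, cfg.ld_r2_max, cfg.ld_window, cfg.ld_step)
    _stage(counts, "ld_prune", g, t0)

    ped_qc = ped.restrict(g.samples)
    kin = kinship_matrix(ped_qc)
    unrelated = max_unrelated_genotyped_set(
        ped_qc, kin, cfg.kinship_threshold,
        missing_counts=g.sample_missing_counts())
    unrelated_keys = [m.key for m in unrelated]

    t0 = time.time()
    hwe = hwe_exact(g, None if cfg.hwe_on_all_samples else unrelated_keys)
    qq = qq_summary(hwe.pvalues)
    _stage(counts, "hwe", g, t0, lambda_gc=round(qq.lambda_gc, 4),
           n_unrelated=len(unrelated_keys))

    pca_results: dict[str, PCAResult] = {}
    retained: dict[str, int] = {}
    reports: dict[str, OutlierReport] = {}
    flagged: dict[str, pd.DataFrame] = {}
    trajectories: dict[str, dict[str, GenerationalTrajectory]] = {}
    user_k = cfg.k or {}
    for approach in cfg.resolved_approaches():
        t0 = time.time()
        if approach == "all":
            res = pca_all(g, n_components=cfg.max_pcs)
        elif approach == "weighted":
            res = pca_weighted(g, ped_qc, n_components=cfg.max_pcs)
        else:
            res = pca_unrelated(g, unrelated_keys, project_all=True,
                                n_components=cfg.max_pcs)
        _, suggested = scree_report(res)
        k = int(user_k.get(approach, 0)) or max(suggested, 1)
        k = min(k, res.n_components)
        rep = loo_sd_distance(res, ped_qc, k)
        fl = rank_and_flag(rep, cfg.sd_flag)
        trajectories[approach] = {
            fid: generational_trajectory(res, ped_qc, fid, k)
            for fid in fl.loc[fl.flagged, "fid"]}
        pca_results[approach], retained[approach] = res, k
        reports[approach], flagged[approach] = rep, fl
        _stage(counts, f"pca_{approach}", g, t0, k=k,
               flagged=[str(x) for x in fl.loc[fl.flagged, "fid"]])

    art = RunArtifacts(config=cfg, genotypes=g, pedigree=ped_qc,
                       unrelated=unrelated, pca=pca_results,
                       retained_k=retained, outliers=reports, flagged=flagged,
                       trajectories=trajectories, stage_counts=counts)
    if write:
        _write_artifacts(art, hwe, qq)
    return art


def _config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(asdict(cfg), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_artifacts(art: RunArtifacts, hwe, qq) -> None:
    out = Path(art.config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    hwe.table.to_csv(out / "hwe_report.tsv", sep="\t", index=False)
    qq.table.to_csv(out / "qq_table.tsv", sep="\t", index=False)
    art.pedigree.to_dataframe().to_csv(out / "pedigree.tsv", sep="\t",
                                       index=False)
    for approach, res in art.pca.items():
        write_evec(res, out / f"pca_{approach}.evec")
        scree, suggested = scree_report(res)
        scree.to_csv(out / f"scree_{approach}.tsv", sep="\t", index=False)
        art.flagged[approach].to_csv(out / f"outliers_{approach}.tsv",
                                     sep="\t", index=False)
        art.flagged[approach].to_json(out / f"outliers_{approach}.json",
                                      orient="records", indent=2)
        for fid, traj in art.trajectories[approach].items():
            traj.per_generation.to_csv(
                out / f"trajectory_{approach}_{fid}.tsv", sep="\t",
                index=False)
    for name, df in make_plot_data(art).items():
        df.to_csv(out / f"plot_{name}.csv", index=False)
    manifest = dict(tool="pedstruct", version=__version__,
                    config=asdict(art.config),
                    config_hash=_config_hash(art.config),
                    stages=art.stage_counts,
                    n_unrelated=len(art.unrelated),
                    retained_k=art.retained_k)
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    with open(out / "summary.txt", "w") as fh:
        fh.write(summary_text(art))


def summary_text(art: RunArtifacts) -> str:
    lines = [f"pedstruct {__version__} run summary",
             f"samples: {art.genotypes.n_samples}  "
             f"snps: {art.genotypes.n_snps}  "
             f"families: {len(art.pedigree.families)}  "
             f"unrelated: {len(art.unrelated)}", ""]
    for approach, fl in art.flagged.items():
        k = art.retained_k[approach]
        lines.append(f"approach {approach} (k={k}): "
                     "family distances (SD), descending")
        for r in fl.itertuples():
            mark = "  << flagged" if r.flagged else ""
            lines.append(f"  {r.fid:>10}  n={r.n:<4d} {r.distance_sd:6.2f}{mark}")
        lines.append("")
    return "\n".join(lines)


def make_plot_data(art: RunArtifacts) -> dict[str, pd.DataFrame]:
    """Tidy tables for the three standard figures: PC scatter with family
    centroids, per-family PC1 strip, and generational diagrams for flagged
    families."""
    tables: dict[str, pd.DataFrame] = {}
    for approach, res in art.pca.items():
        k = art.retained_k[approach]
        kk = max(k, min(2, res.n_components))
        sc = res.scores_frame().iloc[:, :2 + kk]
        sc["role"] = "individual"
        cen = family_centroids(res, art.pedigree, kk)
        cen = cen.rename(columns={c: c for c in cen.columns})
        cen["iid"] = ""
        cen["role"] = np.where(cen.fid == "__global__", "global_centroid",
                               "family_centroid")
        tables[f"scatter_{approach}"] = pd.concat(
            [sc, cen.drop(columns="n")], ignore_index=True)

        strip = res.scores_frame()[["fid", "iid", "PC1"]].copy()
        strip["projected"] = res.projected
        tables[f"strip_{approach}"] = strip.sort_values(
            ["fid", "iid"]).reset_index(drop=True)

        rows = []
        for fid, traj in art.trajectories[approach].items():
            t = traj.per_individual.copy()
            t.insert(0, "fid", fid)
            rows.append(t)
        if rows:
            tables[f"generational_{approach}"] = pd.concat(
                rows, ignore_index=True)
    return tables
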