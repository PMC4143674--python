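"""Synthetic admixed multigenerational pedigrees with gene-dropped genotypes.

The generator emulates a sample of large admixed families of the kind seen
in Mexican American family studies: K ancestral populations differentiated
from a common ancestral allele-frequency pool under the Balding-Nichols
model, founders and marry-ins drawing individual admixture proportions from
a Dirichlet, and genotypes transmitted down each pedigree by gene dropping.
SNPs are simulated independent (no linkage), emulating a post-LD-pruning
panel.  Outlier families are planted by shifting the founding couple's
admixture toward one ancestry; marry-ins always draw from the base
Dirichlet, which is what produces the generational regression of an outlier
family toward the sample mean.

Default study conditions: 20 families of 22-86 genotyped members spanning 4
generations, K = 3 ancestries at F = 0.1 differentiation, base admixture
Dirichlet(4.4, 3.2, 0.4) (roughly a 55/40/5 mix with realistic
between-individual spread).

All randomness flows from ``SimConfig.seed``: identical config gives
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix, write_genotypes
from .pedigree import Pedigree, validate_pedigree

__all__ = ["SimConfig", "OutlierSpec", "TruthRecord", "SimResult",
           "simulate_frequencies", "build_pedigree", "assign_admixture",
           "gene_drop", "simulate_study", "emit"]


@dataclass(frozen=True)
class OutlierSpec:
    """Plant family ``fid`` as an ancestry outlier.

    Affected generation-0 members' admixture vectors a become
    (1 - delta) a + delta e_ancestry (a simplex shift toward one ancestral
    population; delta = 1 reaches the corner).  ``scope`` selects who is
    affected:

    * ``"gen0"`` (default) — every generation-0 member, founding couple and
      marry-ins alike: an endogamous family whose spouses come from the
      same distinct subgroup, the strongest form of family-level
      stratification.
    * ``"founders"`` — the founding couple only; marry-ins keep drawing
      from the base Dirichlet, so each later generation regresses halfway
      back toward the sample mean (the generational-dilution phenomenon).
    """

    fid: str
    ancestry: int           # index into the K ancestral populations
    delta: float            # shift magnitude in [0, 1]
    scope: str = "gen0"     # "gen0" | "founders"

    def __post_init__(self) -> None:
        if not (0.0 <= self.delta <= 1.0):
            raise ValueError("delta must lie in [0, 1] (simplex shift)")
        if self.scope not in ("gen0", "founders"):
            raise ValueError("scope must be 'gen0' or 'founders'")


@dataclass(frozen=True)
class SimConfig:
    n_families: int = 20
    family_size_range: tuple[int, int] = (22, 86)
    n_generations: int = 4
    n_snps: int = 5_000
    K: int = 3
    fst: tuple[float, ...] | float = 0.1
    admixture_alpha: tuple[float, ...] = (4.4, 3.2, 0.4)
    outlier_spec: tuple[OutlierSpec, ...] = ()
    missing_rate: float = 0.0
    mz_twin_pairs: int = 0
    marry_in_prob: float = 0.75
    family_size_targets: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ValueError("missing_rate must be in [0, 1]")
        if self.K < 1 or len(self.admixture_alpha) != self.K:
            raise ValueError("admixture_alpha length must equal K")
        for f in self.fst_per_pop():
            if not (0.0 <= f < 1.0):
                raise ValueError("per-population F must be in [0, 1)")

    def fst_per_pop(self) -> tuple[float, ...]:
        f = self.fst
        return tuple(f for _ in range(self.K)) if np.isscalar(f) else tuple(f)

    def family_ids(self) -> list[str]:
        return [f"F{i + 1:02d}" for i in range(self.n_families)]


@dataclass
class TruthRecord:
    """Ground truth for parameter-recovery checks."""

    admixture: dict[tuple[str, str], np.ndarray]   # true proportions per ind
    outlier_families: dict[str, OutlierSpec]
    ancestral_freqs: np.ndarray                    # length n_snps
    pop_freqs: np.ndarray                          # K x n_snps


@dataclass
class SimResult:
    genotypes: GenotypeMatrix
    pedigree: Pedigree
    truth: TruthRecord
    config: SimConfig


def simulate_frequencies(cfg: SimConfig, rng: np.random.Generator
                         ) -> tuple[np.ndarray, np.ndarray]:
    """Ancestral frequencies p ~ U(0.05, 0.95) and per-population
    frequencies Beta(p (1-F)/F, (1-p) (1-F)/F) (Balding-Nichols); F = 0
    reproduces the ancestral frequency exactly."""
    p = rng.uniform(0.05, 0.95, size=cfg.n_snps)
    pops = np.empty((cfg.K, cfg.n_snps))
    for k, F in enumerate(cfg.fst_per_pop()):
        if F == 0.0:
            pops[k] = p
        else:
            c = (1.0 - F) / F
            pops[k] = rng.beta(p * c, (1.0 - p) * c)
    return p, pops


def _expected_size(lam: float, n_generations: int, p_marry: float) -> float:
    size, couples = 2.0, 1.0
    for g in range(1, n_generations):
        children = couples * lam
        p = p_marry if g < n_generations - 1 else 0.0
        size += children * (1.0 + p)
        couples = children * p
    return size


def _solve_rate(target: float, n_generations: int, p_marry: float) -> float:
    lo, hi = 0.05, 30.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _expected_size(mid, n_generations, p_marry) < target:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def build_pedigree(cfg: SimConfig, rng: np.random.Generator) -> Pedigree:
    """Grow each family from a founder couple: Poisson offspring per couple,
    children marrying in new generation-0 spouses to continue lines.  Family
    sizes are forced into ``family_size_range`` by resampling, with the
    Poisson rate adapted toward the per-family target on each retry."""
    lo, hi = cfg.family_size_range
    if cfg.n_generations < 1:
        raise ValueError("need at least 1 generation")
    if cfg.n_generations == 1 and lo > 2:
        raise ValueError("founder-couple-only families have size 2, below "
                         f"the requested minimum {lo}")
    targets = cfg.family_size_targets
    if targets is not None and len(targets) != cfg.n_families:
        raise ValueError("family_size_targets length must equal n_families")

    records: list[dict] = []
    for f_idx, fid in enumerate(cfg.family_ids()):
        target = (targets[f_idx] if targets is not None
                  else int(rng.integers(lo, hi + 1)))
        lam = _solve_rate(target, cfg.n_generations, cfg.marry_in_prob)
        # explicit targets are honored to within 10% so experiments can pin
        # relative family sizes; otherwise anywhere in range is accepted
        tol = (max(2, round(0.1 * target)) if targets is not None
               else max(target - lo, hi - target))
        for attempt in range(500):
            recs, size = _grow_family(fid, lam, cfg, rng)
            if lo <= size <= hi and abs(size - target) <= tol:
                break
            lam = float(np.clip(lam * (target / max(size, 1)) ** 0.5,
                                0.05, 30.0))
        else:
            raise RuntimeError(
                f"family {fid}: could not reach size in [{lo}, {hi}] with "
                f"{cfg.n_generations} generations (last size {size})")
        records.extend(recs)
    return validate_pedigree(records)


def _grow_family(fid: str, lam: float, cfg: SimConfig,
                 rng: np.random.Generator) -> tuple[list[dict], int]:
    counter = 0

    def new_iid() -> str:
        nonlocal counter
        counter += 1
        return f"{fid}_{counter:03d}"

    recs: list[dict] = []

    def add(iid, father, mother, sex) -> str:
        recs.append(dict(fid=fid, iid=iid, father=father, mother=mother,
                         sex=sex, genotyped=True))
        return iid

    dad = add(new_iid(), None, None, "male")
    mom = add(new_iid(), None, None, "female")
    couples = [(dad, mom)]
    for g in range(1, cfg.n_generations):
        last = g == cfg.n_generations - 1
        next_couples = []
        for fa, mo in couples:
            for _ in range(rng.poisson(lam)):
                sex = "male" if rng.random() < 0.5 else "female"
                child = add(new_iid(), fa, mo, sex)
                if not last and rng.random() < cfg.marry_in_prob:
                    sp_sex = "female" if sex == "male" else "male"
                    spouse = add(new_iid(), None, None, sp_sex)
                    pair = ((child, spouse) if sex == "male"
                            else (spouse, child))
                    next_couples.append(pair)
        couples = next_couples
    return recs, len(recs)


def assign_admixture(ped: Pedigree, cfg: SimConfig,
                     rng: np.random.Generator) -> dict[tuple[str, str], np.ndarray]:
    """Draw generation-0 admixture proportions.

    In outlier families the planted shift applies to the founding couple
    (scope ``"founders"``, with marry-ins drawing from the base Dirichlet)
    or to every generation-0 member (scope ``"gen0"``).  Non-founders'
    expected admixture (mean of the parents', recursively) is filled in for
    the truth record — their realized genotypes inherit alleles, not
    proportions.
    """
    from .outliers import marryin_flags
    outliers = {s.fid: s for s in cfg.outlier_spec}
    for spec in outliers.values():
        if spec.fid not in ped.families:
            raise ValueError(f"outlier fid {spec.fid!r} not in pedigree")
        if not (0 <= spec.ancestry < cfg.K):
            raise ValueError(f"ancestry index {spec.ancestry} out of range")
    alpha = np.asarray(cfg.admixture_alpha, float)
    admix: dict[tuple[str, str], np.ndarray] = {}
    for fid in ped.family_ids:
        flags = marryin_flags(ped, fid)
        spec = outliers.get(fid)
        # draw in sorted-iid order for record-order invariance
        for ind in sorted(ped.families[fid], key=lambda m: m.iid):
            if ind.generation != 0:
                continue
            a = rng.dirichlet(alpha)
            if spec is not None and (spec.scope == "gen0"
                                     or not flags[ind.iid]):
                e = np.zeros(cfg.K)
                e[spec.ancestry] = 1.0
                a = (1.0 - spec.delta) * a + spec.delta * e
                a = np.clip(a, 0.0, None)
                a /= a.sum()
            admix[ind.key] = a
        for ind in sorted(ped.families[fid],
                          key=lambda m: (m.generation, m.iid)):
            if ind.generation > 0:
                fa, mo = ped.parents(ind)
                admix[ind.key] = 0.5 * (admix[fa.key] + admix[mo.key])
    return admix


def gene_drop(ped: Pedigree, admixture: dict, pop_freqs: np.ndarray,
              cfg: SimConfig, rng: np.random.Generator) -> GenotypeMatrix:
    """Drop alleles through the pedigree, SNPs independent.

    A generation-0 individual with admixture a draws each allele
    Bernoulli(a . p_j); a non-founder receives one allele from each parent,
    chosen uniformly and independently per SNP.  Missingness is masked
    uniformly at ``missing_rate``.
    """
    m = pop_freqs.shape[1]
    haplos: dict[tuple[str, str], np.ndarray] = {}
    order = sorted(ped, key=lambda i: (i.generation, i.fid, i.iid))
    for ind in order:
        if ind.generation == 0:
            q = admixture[ind.key] @ pop_freqs
            haplos[ind.key] = (rng.random((2, m)) < q).astype(np.int8)
        else:
            fa, mo = ped.parents(ind)
            h = np.empty((2, m), dtype=np.int8)
            cols = np.arange(m)
            h[0] = haplos[fa.key][rng.integers(2, size=m), cols]
            h[1] = haplos[mo.key][rng.integers(2, size=m), cols]
            haplos[ind.key] = h

    samples = [i.key for i in order if i.genotyped]
    dosages = np.stack([haplos[k].sum(axis=0) for k in samples])
    if cfg.missing_rate > 0:
        mask = rng.random(dosages.shape) < cfg.missing_rate
        dosages[mask] = -1
    snps = _snp_table(m)
    return GenotypeMatrix(dosages, samples, snps)


def _snp_table(m: int, n_chrom: int = 22, spacing: int = 200_000
               ) -> pd.DataFrame:
    """Evenly spaced SNP metadata across autosomes; ref A, alt G.  The
    spacing is nominal — simulated SNPs carry no linkage regardless."""
    per = int(np.ceil(m / n_chrom))
    chrom = [str(j // per + 1) for j in range(m)]
    pos = [(j % per) * spacing + 10_001 for j in range(m)]
    return pd.DataFrame(dict(
        snp_id=[f"snp{j + 1:06d}" for j in range(m)],
        chrom=chrom, pos=pos, ref="A", alt="G"))


def _add_mz_twins(g: GenotypeMatrix, ped: Pedigree, n_pairs: int,
                  rng: np.random.Generator) -> tuple[GenotypeMatrix, Pedigree]:
    recs = [dict(fid=i.fid, iid=i.iid, father=i.father, mother=i.mother,
                 sex=i.sex, genotyped=i.genotyped) for i in ped]
    nonfounders = [i for i in ped if i.generation > 0 and i.genotyped]
    chosen = rng.choice(len(nonfounders), size=n_pairs, replace=False)
    dosage_rows = [g.dosages]
    samples = list(g.samples)
    for c in chosen:
        orig = nonfounders[int(c)]
        twin = f"{orig.iid}MZ"
        recs.append(dict(fid=orig.fid, iid=twin, father=orig.father,
                         mother=orig.mother, sex=orig.sex, genotyped=True))
        row = g.dosages[[g.samples.index(orig.key)]]
        dosage_rows.append(row)
        samples.append((orig.fid, twin))
    g2 = GenotypeMatrix(np.concatenate(dosage_rows), samples, g.snps)
    return g2, validate_pedigree(recs)


def simulate_study(cfg: SimConfig) -> SimResult:
    """End-to-end simulation: frequencies, pedigrees, admixture, gene drop,
    and optional MZ-twin duplication, all driven by ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    anc, pops = simulate_frequencies(cfg, rng)
    ped = build_pedigree(cfg, rng)
    admix = assign_admixture(ped, cfg, rng)
    g = gene_drop(ped, admix, pops, cfg, rng)
    if cfg.mz_twin_pairs:
        g, ped = _add_mz_twins(g, ped, cfg.mz_twin_pairs, rng)
    truth = TruthRecord(admixture=admix,
                        outlier_families={s.fid: s for s in cfg.outlier_spec},
                        ancestral_freqs=anc, pop_freqs=pops)
    return SimResult(genotypes=g, pedigree=ped, truth=truth, config=cfg)


def emit(result: SimResult, outdir, formats: tuple[str, ...] = ("bed",)
         ) -> dict[str, Path]:
    """Write genotypes (PLINK binary by default; optionally ped/map and
    VCF) plus truth tables.  Re-loading the PLINK output round-trips to the
    identical dosage matrix and pedigree."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for fmt in formats:
        target = outdir / ("genotypes.vcf" if fmt == "vcf" else "genotypes")
        write_genotypes(result.genotypes, target, format=fmt,
                        ped=result.pedigree)
        paths[fmt] = target
    adm = pd.DataFrame(
        [(fid, iid, *a) for (fid, iid), a in sorted(result.truth.admixture.items())],
        columns=["fid", "iid",
                 *[f"anc{k + 1}" for k in range(result.config.K)]])
    adm.to_csv(outdir / "truth_admixture.tsv", sep="\t", index=False)
    fam_truth = pd.DataFrame(
        [dict(fid=fid, outlier=fid in result.truth.outlier_families)
         for fid in result.pedigree.family_ids])
    fam_truth.to_csv(outdir / "truth_families.tsv", sep="\t", index=False)
    freqs = pd.DataFrame(result.truth.pop_freqs.T,
                         columns=[f"pop{k + 1}"
                                  for k in range(result.config.K)])
    freqs.insert(0, "snp_id", result.genotypes.snps.snp_id)
    freqs.insert(1, "ancestral", result.truth.ancestral_freqs)
    freqs.to_csv(outdir / "truth_frequencies.tsv", sep="\t", index=False)
    paths["truth"] = outdir
    return paths
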