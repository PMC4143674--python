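"""Genotype matrix container and PLINK/VCF input-output.

Dosages count copies of the alternate allele (0, 1, 2) with ``-1`` as the
single missing sentinel, samples keyed by (fid, iid), and SNP metadata kept
as a pandas DataFrame (snp_id, chrom, pos, ref, alt).  Positions are 1-based
throughout, following PLINK/VCF convention.

PLINK binary (.bed v1.9 SNP-major bit encoding) and text (.ped/.map) codecs
are implemented here; VCF parsing is delegated to cyvcf2, VCF writing emits
plain text.  In .bim files allele 1 is the counted (alt) allele and allele 2
the reference, and the .bed two-bit codes follow the PLINK 1.9 layout
(00 = hom A1, 01 = missing, 10 = het, 11 = hom A2).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .pedigree import Pedigree, read_fam

__all__ = ["GenotypeMatrix", "load_genotypes", "write_genotypes"]

MISSING = -1

SNP_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt"]


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs alt-allele dosage matrix with SNP metadata."""

    dosages: np.ndarray                 # int8, (n_samples, n_snps), -1 missing
    samples: list[tuple[str, str]]      # ordered (fid, iid)
    snps: pd.DataFrame                  # columns SNP_COLUMNS

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.shape != (len(self.samples), len(self.snps)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs")
        if self.snps["snp_id"].duplicated().any():
            dup = self.snps.loc[self.snps["snp_id"].duplicated(), "snp_id"].iloc[0]
            raise ValueError(f"duplicated snp_id {dup!r}")
        self.snps = self.snps.reset_index(drop=True)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def missing_mask(self) -> np.ndarray:
        return self.dosages == MISSING

    def snp_call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=0)

    def sample_call_rate(self) -> np.ndarray:
        return 1.0 - self.missing_mask().mean(axis=1)

    def sample_missing_counts(self) -> dict[tuple[str, str], int]:
        counts = self.missing_mask().sum(axis=1)
        return {k: int(c) for k, c in zip(self.samples, counts)}

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(self, dosages=self.dosages[idx],
                       samples=[self.samples[i] for i in idx])

    def take_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return replace(self, dosages=self.dosages[:, idx],
                       snps=self.snps.iloc[idx].reset_index(drop=True))

    def subset_samples(self, keys) -> "GenotypeMatrix":
        keyset = [tuple(k) for k in keys]
        pos = {k: i for i, k in enumerate(self.samples)}
        return self.take_samples([pos[k] for k in keyset])


# ---------------------------------------------------------------------------
# PLINK text (.ped/.map)

def _read_ped_map(prefix: Path) -> tuple[GenotypeMatrix, Pedigree]:
    mp = pd.read_csv(f"{prefix}.map", sep=r"\s+", header=None, dtype=str,
                     names=["chrom", "snp_id", "cm", "pos"])
    m = len(mp)
    fam_rows, allele_rows = [], []
    with open(f"{prefix}.ped") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(
                    f"{prefix}.ped line {ln}: expected {6 + 2 * m} fields "
                    f"for {m} SNPs, got {len(parts)}")
            fam_rows.append(parts[:6])
            allele_rows.append(parts[6:])
    alleles = np.array(allele_rows, dtype="U4").reshape(len(fam_rows), m, 2)

    # .ped carries no ref/alt designation: the counted (alt) allele is the
    # lexicographically larger of the two observed alleles
    dosages = np.full((len(fam_rows), m), MISSING, dtype=np.int8)
    ref_l, alt_l = [], []
    for j in range(m):
        col = alleles[:, j, :]
        obs = sorted(set(col.ravel()) - {"0"})
        if len(obs) > 2:
            raise ValueError(f"SNP {mp.snp_id[j]}: more than two alleles {obs}")
        if not obs:
            ref, alt = "0", "0"
        elif len(obs) == 1:
            ref, alt = obs[0], "0"
        else:
            ref, alt = obs
        ref_l.append(ref)
        alt_l.append(alt)
        valid = (col != "0").all(axis=1)
        dosages[valid, j] = (col[valid] == alt).sum(axis=1)

    snps = pd.DataFrame(dict(snp_id=mp.snp_id, chrom=mp.chrom,
                             pos=mp.pos.astype(int), ref=ref_l, alt=alt_l))
    fam = pd.DataFrame(fam_rows, columns=["fid", "iid", "father", "mother",
                                          "sex", "pheno"])
    ped = _ped_from_fam_df(fam)
    g = GenotypeMatrix(dosages, [(r.fid, r.iid) for r in fam.itertuples()], snps)
    return g, ped


def _ped_from_fam_df(fam: pd.DataFrame) -> Pedigree:
    from .pedigree import validate_pedigree
    recs = [dict(fid=r.fid, iid=r.iid, father=r.father, mother=r.mother,
                 sex=r.sex, genotyped=True) for r in fam.itertuples()]
    return validate_pedigree(recs)


def _write_ped_map(g: GenotypeMatrix, ped: Pedigree | None, prefix: Path) -> None:
    g.snps[["chrom", "snp_id", "pos"]].assign(cm=0)[
        ["chrom", "snp_id", "cm", "pos"]].to_csv(
        f"{prefix}.map", sep="\t", header=False, index=False)
    ref = g.snps["ref"].to_numpy()
    alt = g.snps["alt"].to_numpy()
    # dosage -> allele pair, column-wise
    pair = np.empty((4, g.n_snps, 2), dtype="U4")
    pair[0] = np.stack([ref, ref], axis=1)
    pair[1] = np.stack([ref, alt], axis=1)
    pair[2] = np.stack([alt, alt], axis=1)
    pair[3] = "0"
    with open(f"{prefix}.ped", "w") as fh:
        for i, key in enumerate(g.samples):
            fid, iid = key
            if ped is not None and key in ped:
                ind = ped[key]
                fa, mo = ind.father or "0", ind.mother or "0"
                sex = {"male": "1", "female": "2", "unknown": "0"}[ind.sex]
            else:
                fa = mo = sex = "0"
            d = g.dosages[i].astype(np.int64) % 4  # -1 -> 3 (missing slot)
            cells = pair[d, np.arange(g.n_snps)]
            fh.write(" ".join([fid, iid, fa, mo, sex, "0"]
                              + list(cells.ravel())) + "\n")


# ---------------------------------------------------------------------------
# PLINK binary (.bed/.bim/.fam)

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])
# two-bit code -> alt dosage (A1 counted): 00 hom A1 -> 2, 01 missing,
# 10 het -> 1, 11 hom A2 -> 0
_CODE_TO_DOSAGE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_DOSAGE_TO_CODE = {0: 0b11, 1: 0b10, 2: 0b00, MISSING: 0b01}

_DECODE_LUT = np.zeros((256, 4), dtype=np.int8)
for _byte in range(256):
    for _k in range(4):
        _DECODE_LUT[_byte, _k] = _CODE_TO_DOSAGE[(_byte >> (2 * _k)) & 0b11]


def _read_bed(prefix: Path) -> tuple[GenotypeMatrix, Pedigree]:
    bim = pd.read_csv(f"{prefix}.bim", sep=r"\s+", header=None, dtype=str,
                      names=["chrom", "snp_id", "cm", "pos", "a1", "a2"])
    snps = pd.DataFrame(dict(snp_id=bim.snp_id, chrom=bim.chrom,
                             pos=bim.pos.astype(int), ref=bim.a2, alt=bim.a1))
    ped = read_fam(f"{prefix}.fam")
    fam = pd.read_csv(f"{prefix}.fam", sep=r"\s+", header=None, dtype=str,
                      usecols=[0, 1], names=["fid", "iid"])
    samples = [(r.fid, r.iid) for r in fam.itertuples()]
    n, m = len(samples), len(snps)
    raw = np.fromfile(f"{prefix}.bed", dtype=np.uint8)
    if bytes(raw[:3]) != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed: not a SNP-major PLINK 1 .bed file")
    bpv = (n + 3) // 4  # bytes per variant
    body = raw[3:]
    if body.size != bpv * m:
        raise ValueError(f"{prefix}.bed: size {body.size} != {bpv}*{m}")
    decoded = _DECODE_LUT[body.reshape(m, bpv)].reshape(m, bpv * 4)[:, :n]
    return GenotypeMatrix(decoded.T.copy(), samples, snps), ped


def _write_bed(g: GenotypeMatrix, ped: Pedigree | None, prefix: Path) -> None:
    bim = pd.DataFrame(dict(chrom=g.snps.chrom, snp_id=g.snps.snp_id, cm=0,
                            pos=g.snps.pos, a1=g.snps.alt, a2=g.snps.ref))
    bim.to_csv(f"{prefix}.bim", sep="\t", header=False, index=False)
    rows = []
    for key in g.samples:
        fid, iid = key
        if ped is not None and key in ped:
            ind = ped[key]
            rows.append([fid, iid, ind.father or "0", ind.mother or "0",
                         {"male": "1", "female": "2", "unknown": "0"}[ind.sex],
                         "0"])
        else:
            rows.append([fid, iid, "0", "0", "0", "0"])
    pd.DataFrame(rows).to_csv(f"{prefix}.fam", sep="\t", header=False,
                              index=False)
    n, m = g.n_samples, g.n_snps
    bpv = (n + 3) // 4
    codes = np.zeros((m, bpv * 4), dtype=np.uint8)
    d = g.dosages.T  # SNP-major
    code = np.where(d == MISSING, 0b01,
                    np.where(d == 0, 0b11, np.where(d == 1, 0b10, 0b00)))
    codes[:, :n] = code
    packed = (codes.reshape(m, bpv, 4)
              * np.array([1, 4, 16, 64], dtype=np.uint8)).sum(
                  axis=2, dtype=np.uint8)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# VCF

def _read_vcf(path: Path, fam: Path | None = None
              ) -> tuple[GenotypeMatrix, Pedigree | None]:
    from cyvcf2 import VCF
    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    dosage_cols, meta = [], []
    seen = set()
    for v in vcf:
        if v.ID in seen:
            raise ValueError(f"duplicated snp_id {v.ID!r} in {path}")
        seen.add(v.ID)
        if len(v.ALT) != 1:
            raise ValueError(f"{v.ID}: only biallelic records supported")
        gts = np.array([[a, b] for a, b, *_ in v.genotypes], dtype=np.int16)
        dos = gts.sum(axis=1).astype(np.int8)
        dos[(gts < 0).any(axis=1)] = MISSING
        dosage_cols.append(dos)
        meta.append((v.ID or f"{v.CHROM}:{v.POS}", v.CHROM, v.POS, v.REF,
                     v.ALT[0]))
    snps = pd.DataFrame(meta, columns=SNP_COLUMNS)
    ped = read_fam(fam) if fam is not None else None
    if ped is not None:
        by_iid = {i.iid: i for i in ped}
        samples = [(by_iid[s].fid, s) if s in by_iid else ("0", s)
                   for s in sample_ids]
    else:
        samples = [("0", s) for s in sample_ids]
    dosages = (np.stack(dosage_cols, axis=1) if dosage_cols
               else np.empty((len(samples), 0), dtype=np.int8))
    return GenotypeMatrix(dosages, samples, snps), ped


_GT_STR = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}


def _write_vcf(g: GenotypeMatrix, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=pedstruct\n")
        for chrom in pd.unique(g.snps.chrom):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(iid for _, iid in g.samples) + "\n")
        for j, snp in enumerate(g.snps.itertuples()):
            gts = "\t".join(_GT_STR[int(d)] for d in g.dosages[:, j])
            fh.write(f"{snp.chrom}\t{snp.pos}\t{snp.snp_id}\t{snp.ref}\t"
                     f"{snp.alt}\t.\tPASS\t.\tGT\t{gts}\n")


# ---------------------------------------------------------------------------
# public API

def _infer_format(path: str) -> str:
    s = str(path)
    if s.endswith((".vcf", ".vcf.gz")):
        return "vcf"
    for ext, fmt in ((".bed", "bed"), (".ped", "ped")):
        if s.endswith(ext):
            return fmt
    if os.path.exists(s + ".bed"):
        return "bed"
    if os.path.exists(s + ".ped"):
        return "ped"
    raise ValueError(f"cannot infer genotype format from {path!r}")


def load_genotypes(path, format: str | None = None, fam=None
                   ) -> tuple[GenotypeMatrix, Pedigree | None]:
    """Load genotypes (and pedigree columns where the format carries them).

    ``path`` is a PLINK prefix for ped/bed formats, or a .vcf path; ``fam``
    optionally supplies pedigree structure for VCF input.  Returns the
    alt-dosage matrix and the pedigree (None for VCF without ``fam``).
    """
    fmt = format or _infer_format(path)
    prefix = Path(str(path).removesuffix(".bed").removesuffix(".ped"))
    if fmt == "ped":
        return _read_ped_map(prefix)
    if fmt == "bed":
        return _read_bed(prefix)
    if fmt == "vcf":
        return _read_vcf(Path(path), fam)
    raise ValueError(f"unknown format {fmt!r}")


def write_genotypes(g: GenotypeMatrix, path, format: str = "bed",
                    ped: Pedigree | None = None) -> None:
    """Write genotypes as PLINK bed/bim/fam, ped/map, or plain-text VCF."""
    if format == "bed":
        _write_bed(g, ped, Path(path))
    elif format == "ped":
        _write_ped_map(g, ped, Path(path))
    elif format == "vcf":
        p = str(path)
        _write_vcf(g, Path(p if p.endswith(".vcf") else p + ".vcf"))
    else:
        raise ValueError(f"unknown format {format!r}")
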