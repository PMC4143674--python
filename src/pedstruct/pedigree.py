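"""Pedigree representation, kinship, and maximal unrelated subsets.

A pedigree is a forest of directed parent->child graphs partitioned into
families.  Founders and marry-ins are the generation-0 individuals: members
with no parents recorded in the pedigree.  Kinship coefficients are computed
from pedigree structure alone by the classical recursive algorithm, and the
maximal set of pairwise-unrelated genotyped individuals is extracted per
family by exact branch-and-bound on the relatedness graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "KinshipMatrix",
    "PedigreeError",
    "validate_pedigree",
    "read_fam",
    "kinship_matrix",
    "founders_and_marryins",
    "max_unrelated_genotyped_set",
]

SEX_CODES = {"1": "male", "2": "female", "0": "unknown",
             1: "male", 2: "female", 0: "unknown",
             "male": "male", "female": "female", "unknown": "unknown"}

MISSING_PARENT = {None, "", "0", 0}


class PedigreeError(ValueError):
    """Structural problem in pedigree records (cycles, missing parents...)."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.

    ``generation`` is 0 iff both parents are absent from the pedigree
    (founders and marry-ins), otherwise 1 + max of the parents' generations.
    """

    fid: str
    iid: str
    father: str | None
    mother: str | None
    sex: str
    genotyped: bool
    generation: int

    @property
    def key(self) -> tuple[str, str]:
        return (self.fid, self.iid)

    @property
    def is_founder(self) -> bool:
        return self.generation == 0


@dataclass
class Pedigree:
    """Collection of individuals keyed by (fid, iid), partitioned by family."""

    individuals: dict[tuple[str, str], Individual]

    @property
    def families(self) -> dict[str, list[Individual]]:
        fams: dict[str, list[Individual]] = {}
        for ind in self.individuals.values():
            fams.setdefault(ind.fid, []).append(ind)
        return fams

    @property
    def family_ids(self) -> list[str]:
        return sorted(self.families)

    def __len__(self) -> int:
        return len(self.individuals)

    def __iter__(self):
        return iter(self.individuals.values())

    def __contains__(self, key: tuple[str, str]) -> bool:
        return tuple(key) in self.individuals

    def __getitem__(self, key: tuple[str, str]) -> Individual:
        return self.individuals[tuple(key)]

    def members(self, fid: str) -> list[Individual]:
        return [i for i in self.individuals.values() if i.fid == fid]

    def genotyped(self) -> list[Individual]:
        return [i for i in self.individuals.values() if i.genotyped]

    def parents(self, ind: Individual) -> tuple[Individual | None, Individual | None]:
        fa = self.individuals.get((ind.fid, ind.father)) if ind.father else None
        mo = self.individuals.get((ind.fid, ind.mother)) if ind.mother else None
        return fa, mo

    def restrict(self, keys: Iterable[tuple[str, str]]) -> "Pedigree":
        """Subset to ``keys``; parent links to removed members are severed
        and generations recomputed (used after sample-level QC)."""
        keep = {tuple(k) for k in keys}
        records = []
        for k in keep:
            ind = self.individuals[k]
            father = ind.father if (ind.fid, ind.father) in keep else None
            mother = ind.mother if (ind.fid, ind.mother) in keep else None
            # both-or-neither parent rule: sever the orphaned link pair
            if father is None or mother is None:
                father = mother = None
            records.append(dict(fid=ind.fid, iid=ind.iid, father=father,
                                mother=mother, sex=ind.sex,
                                genotyped=ind.genotyped))
        return validate_pedigree(records)

    def to_dataframe(self) -> pd.DataFrame:
        """Tabular export: PLINK fam columns plus a generation column."""
        rows = [
            dict(fid=i.fid, iid=i.iid, father=i.father or "0",
                 mother=i.mother or "0",
                 sex={"male": 1, "female": 2, "unknown": 0}[i.sex],
                 genotyped=int(i.genotyped), generation=i.generation)
            for i in self.individuals.values()
        ]
        return pd.DataFrame(rows)


@dataclass
class KinshipMatrix:
    """Symmetric matrix of pedigree kinship coefficients phi.

    phi(i, i) = (1 + f_i) / 2 with f_i the inbreeding coefficient (kinship of
    i's parents); phi between members of different families is exactly 0.
    """

    values: np.ndarray
    index: list[tuple[str, str]]
    _pos: dict[tuple[str, str], int] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._pos = {k: n for n, k in enumerate(self.index)}

    def phi(self, a: tuple[str, str], b: tuple[str, str]) -> float:
        return float(self.values[self._pos[tuple(a)], self._pos[tuple(b)]])

    def submatrix(self, keys: Sequence[tuple[str, str]]) -> np.ndarray:
        idx = [self._pos[tuple(k)] for k in keys]
        return self.values[np.ix_(idx, idx)]


def _norm_parent(x) -> str | None:
    if x in MISSING_PARENT:
        return None
    return str(x)


def validate_pedigree(raw_records: Iterable[Mapping]) -> Pedigree:
    """Build a validated :class:`Pedigree` from individual records.

    Each record needs ``fid, iid, father, mother, sex, genotyped`` (parent
    id ``0``/``None``/``""`` means absent).  Raises :class:`PedigreeError` on
    single-parent records, parents referenced but not present in the same
    family, or ancestry cycles.  Generations are assigned topologically, so
    the numbering is independent of record order.
    """
    recs = []
    seen: set[tuple[str, str]] = set()
    for r in raw_records:
        fid, iid = str(r["fid"]), str(r["iid"])
        if (fid, iid) in seen:
            raise PedigreeError(f"duplicate individual ({fid}, {iid})")
        seen.add((fid, iid))
        father = _norm_parent(r.get("father"))
        mother = _norm_parent(r.get("mother"))
        if (father is None) != (mother is None):
            raise PedigreeError(
                f"({fid}, {iid}): single-parent record (father={father!r}, "
                f"mother={mother!r}); both parents must be present or absent")
        sex = SEX_CODES.get(r.get("sex", 0))
        if sex is None:
            raise PedigreeError(f"({fid}, {iid}): unrecognized sex code {r.get('sex')!r}")
        recs.append((fid, iid, father, mother, sex, bool(r.get("genotyped", True))))

    for fid, iid, father, mother, _, _ in recs:
        for p in (father, mother):
            if p is not None and (fid, p) not in seen:
                raise PedigreeError(f"({fid}, {iid}): parent {p!r} not in family {fid}")

    # topological generation numbering with cycle detection
    parents = {(fid, iid): (father, mother) for fid, iid, father, mother, _, _ in recs}
    generation: dict[tuple[str, str], int] = {}

    def assign(key: tuple[str, str], stack: tuple) -> int:
        if key in generation:
            return generation[key]
        if key in stack:
            cyc = " -> ".join(f"{k[1]}" for k in stack + (key,))
            raise PedigreeError(f"ancestry cycle detected in family {key[0]}: {cyc}")
        fa, mo = parents[key]
        if fa is None:
            g = 0
        else:
            fid = key[0]
            g = 1 + max(assign((fid, fa), stack + (key,)),
                        assign((fid, mo), stack + (key,)))
        generation[key] = g
        return g

    for key in parents:
        assign(key, ())

    individuals = {
        (fid, iid): Individual(fid, iid, father, mother, sex, genotyped,
                               generation[(fid, iid)])
        for fid, iid, father, mother, sex, genotyped in recs
    }
    ped = Pedigree(individuals)
    for fid, members in ped.families.items():
        if not any(m.generation == 0 for m in members):
            raise PedigreeError(f"family {fid} has no generation-0 individual")
    return ped


def read_fam(path) -> Pedigree:
    """Read pedigree structure from PLINK .fam (or the first 6 columns of a
    .ped) — fid, iid, father, mother, sex, phenotype.  All listed samples are
    marked genotyped."""
    df = pd.read_csv(path, sep=r"\s+", header=None, dtype=str,
                     usecols=range(6),
                     names=["fid", "iid", "father", "mother", "sex", "pheno"])
    recs = [dict(fid=r.fid, iid=r.iid, father=r.father, mother=r.mother,
                 sex=r.sex, genotyped=True) for r in df.itertuples()]
    return validate_pedigree(recs)


def kinship_matrix(ped: Pedigree) -> KinshipMatrix:
    """Pedigree kinship by the standard recursion.

    phi(i, i) = (1 + phi(father_i, mother_i)) / 2 and, for i != j with i of
    the later (or equal) generation, phi(i, j) = (phi(father_i, j) +
    phi(mother_i, j)) / 2.  Founders of distinct lineages are unrelated, and
    members of different families have kinship 0 by construction.
    """
    index = sorted(ped.individuals)
    n = len(index)
    values = np.zeros((n, n))
    pos = {k: i for i, k in enumerate(index)}

    for fid, members in ped.families.items():
        order = sorted(members, key=lambda m: (m.generation, m.iid))
        cache: dict[tuple, float] = {}

        def phi(a: Individual, b: Individual) -> float:
            ka, kb = a.key, b.key
            if ka > kb:
                ka, kb, a, b = kb, ka, b, a
            got = cache.get((ka, kb))
            if got is not None:
                return got
            if a is b:
                if a.father is None:
                    val = 0.5
                else:
                    fa, mo = ped.parents(a)
                    val = 0.5 * (1.0 + phi(fa, mo))
            else:
                # recurse on the individual of the later generation
                hi, lo = (a, b) if a.generation >= b.generation else (b, a)
                if hi.father is None:
                    val = 0.0  # two distinct founders: unrelated
                else:
                    fa, mo = ped.parents(hi)
                    val = 0.5 * (phi(fa, lo) + phi(mo, lo))
            cache[(ka, kb)] = val
            return val

        for i, a in enumerate(order):
            for b in order[i:]:
                v = phi(a, b)
                ia, ib = pos[a.key], pos[b.key]
                values[ia, ib] = values[ib, ia] = v

    return KinshipMatrix(values=values, index=index)


def founders_and_marryins(ped: Pedigree) -> list[Individual]:
    """All generation-0 individuals: the founding couples plus the unrelated
    spouses who married into the pedigree.  Genotype status is not filtered
    here — that happens in downstream subset selection."""
    return sorted((i for i in ped if i.generation == 0),
                  key=lambda i: (i.fid, i.iid))


def _max_independent_set_bb(adj: list[int], order_cost: list[tuple], n: int) -> int:
    """Exact maximum independent set by branch-and-bound over bitsets.

    Vertices are assumed pre-sorted by deterministic preference; include-first
    exploration returns, among maximum-cardinality sets, the one greedily
    preferring low-index vertices."""
    best_mask = 0
    best_size = -1
    full = (1 << n) - 1

    def rec(chosen: int, chosen_size: int, cand: int) -> None:
        nonlocal best_mask, best_size
        if chosen_size + cand.bit_count() <= best_size:
            return
        if cand == 0:
            if chosen_size > best_size:
                best_size, best_mask = chosen_size, chosen
            return
        v = (cand & -cand).bit_length() - 1  # lowest-index candidate
        rec(chosen | (1 << v), chosen_size + 1, cand & ~adj[v] & ~(1 << v))
        rec(chosen, chosen_size, cand & ~(1 << v))

    rec(0, 0, full)
    return best_mask


def _greedy_independent_set(adj: list[int], n: int) -> int:
    mask, blocked = 0, 0
    for v in range(n):
        if not (blocked >> v) & 1:
            mask |= 1 << v
            blocked |= adj[v] | (1 << v)
    return mask


def max_unrelated_genotyped_set(
    ped: Pedigree,
    kin: KinshipMatrix,
    threshold: float = 0.0,
    missing_counts: Mapping[tuple[str, str], int] | None = None,
    max_exact: int = 150,
) -> list[Individual]:
    """Maximum-cardinality set of genotyped individuals that are pairwise
    unrelated (kinship <= ``threshold``), solved exactly within each family.

    Ties between equally large sets are broken deterministically by
    preferring (lower generation, fewer missing genotypes, lexicographic
    iid).  Families larger than ``max_exact`` genotyped members fall back to
    a greedy heuristic under the same ordering.  The default threshold 0
    selects pedigree-exact unrelateds: on pedigrees without inbreeding loops
    this is precisely the genotyped founders and marry-ins.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    missing_counts = missing_counts or {}
    chosen: list[Individual] = []
    for fid in ped.family_ids:
        members = [m for m in ped.families[fid] if m.genotyped]
        if not members:
            warnings.warn(f"family {fid} has no genotyped individuals",
                          stacklevel=2)
            continue
        members.sort(key=lambda m: (m.generation,
                                    missing_counts.get(m.key, 0), m.iid))
        n = len(members)
        phi = kin.submatrix([m.key for m in members])
        adj = [0] * n
        for i in range(n):
            for j in range(i + 1, n):
                if phi[i, j] > threshold:
                    adj[i] |= 1 << j
                    adj[j] |= 1 << i
        if n <= max_exact:
            mask = _max_independent_set_bb(adj, members, n)
        else:  # pragma: no cover - very large families only
            mask = _greedy_independent_set(adj, n)
        chosen.extend(members[i] for i in range(n) if (mask >> i) & 1)
    return sorted(chosen, key=lambda m: (m.fid, m.iid))
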