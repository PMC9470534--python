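"""Pedigree data model, kinship, relatedness graph and pseudo-sample construction.

Families are represented explicitly (PED-style), kinship is computed by the
standard recursion over pedigree founders (founders assumed non-inbred and
mutually unrelated), and cryptic relatedness between families enters as an
*input* table of inferred kinship estimates. The relatedness graph is used to
select a maximal set of unrelated individuals (one per connected component).

Pseudocontrols are built from untransmitted alleles of unaffected,
non-excluded parents (each such parent contributes a sample size of 0.5);
pseudocases are case alleles not attributable to sampled unaffected ancestors
and not de novo, with a fractional contributing sample size of
``1 - sum of kinship coefficients with those ancestors``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

MALE = "male"
FEMALE = "female"


@dataclass
class Individual:
    """One pedigree member.

    ``excluded_parent`` marks a parent with an ASD diagnosis or intellectual
    disability; such parents never seed transmission analysis and are not
    eligible unaffected ancestors. ``cognitive_impairment`` is a tri-state
    phenotype flag (None = unknown).
    """

    id: str
    family_id: str
    father_id: Optional[str] = None
    mother_id: Optional[str] = None
    sex: Optional[str] = None
    affected: bool = False
    excluded_parent: bool = False
    cognitive_impairment: Optional[bool] = None
    sequenced: bool = True
    twin_group: Optional[str] = None


class PedigreeError(ValueError):
    pass


class Pedigree:
    """A single family: members indexed by id, parent links forming a DAG."""

    def __init__(self, family_id: str, members: Iterable[Individual]):
        self.family_id = family_id
        self.members: dict[str, Individual] = {}
        for ind in members:
            if ind.id in self.members:
                raise PedigreeError(f"duplicate individual id {ind.id!r} in family {family_id!r}")
            self.members[ind.id] = ind
        self._validate()
        self._kinship_cache: dict[tuple[str, str], float] = {}
        self._depth_cache: dict[str, int] = {}

    def _validate(self) -> None:
        for ind in self.members.values():
            for pid, want_sex, label in (
                (ind.father_id, MALE, "father"),
                (ind.mother_id, FEMALE, "mother"),
            ):
                if pid is None:
                    continue
                parent = self.members.get(pid)
                if parent is None:
                    raise PedigreeError(
                        f"{label} {pid!r} of {ind.id!r} not found in family {self.family_id!r}"
                    )
                if parent.sex is None:
                    parent.sex = want_sex
                elif parent.sex != want_sex:
                    raise PedigreeError(f"{label} {pid!r} of {ind.id!r} is not {want_sex}")
        # parent-child links must be acyclic
        g = nx.DiGraph()
        g.add_nodes_from(self.members)
        for ind in self.members.values():
            for pid in (ind.father_id, ind.mother_id):
                if pid is not None:
                    g.add_edge(pid, ind.id)
        if not nx.is_directed_acyclic_graph(g):
            raise PedigreeError(f"parent-child links are cyclic in family {self.family_id!r}")

    def __contains__(self, iid: str) -> bool:
        return iid in self.members

    def __getitem__(self, iid: str) -> Individual:
        try:
            return self.members[iid]
        except KeyError:
            raise KeyError(f"unknown individual id {iid!r} in family {self.family_id!r}") from None

    def parents(self, iid: str) -> list[Individual]:
        ind = self[iid]
        return [self.members[p] for p in (ind.father_id, ind.mother_id) if p is not None]

    def offspring(self, iid: str) -> list[Individual]:
        return [m for m in self.members.values() if iid in (m.father_id, m.mother_id)]

    def founders(self) -> list[Individual]:
        return [m for m in self.members.values() if m.father_id is None and m.mother_id is None]

    def depth(self, iid: str) -> int:
        """Generation depth: founders are 0."""
        if iid in self._depth_cache:
            return self._depth_cache[iid]
        parents = self.parents(iid)
        d = 0 if not parents else 1 + max(self.depth(p.id) for p in parents)
        self._depth_cache[iid] = d
        return d


def kinship_coefficient(ped: Pedigree, a: str, b: str) -> float:
    """Kinship coefficient phi(a, b) by the standard recursion.

    Founders are assumed non-inbred and mutually unrelated, so
    phi(x, x) = 1/2 + phi(father, mother)/2 and, for a != b with a at least
    as deep as b, phi(a, b) = (phi(father_a, b) + phi(mother_a, b)) / 2 with
    missing parents contributing 0. Symmetric in (a, b), in [0, 0.5].
    """
    ped[a], ped[b]  # raise KeyError on unknown ids
    return _kinship(ped, a, b)


def _kinship(ped: Pedigree, a: str, b: str) -> float:
    key = (a, b) if a <= b else (b, a)
    cached = ped._kinship_cache.get(key)
    if cached is not None:
        return cached
    if a == b:
        ind = ped[a]
        phi = 0.5
        if ind.father_id is not None and ind.mother_id is not None:
            phi += 0.5 * _kinship(ped, ind.father_id, ind.mother_id)
        ped._kinship_cache[key] = phi
        return phi
    # recurse on the deeper individual so we always move toward founders
    if ped.depth(a) < ped.depth(b):
        a, b = b, a
    ind = ped[a]
    if ind.father_id is None and ind.mother_id is None:
        phi = 0.0  # two distinct founders, or founder vs non-ancestor
    else:
        phi = 0.0
        for pid in (ind.father_id, ind.mother_id):
            if pid is not None:
                phi += 0.5 * _kinship(ped, pid, b)
    ped._kinship_cache[key] = phi
    return phi


# ---------------------------------------------------------------------------
# PED format IO
# ---------------------------------------------------------------------------

_PED_COLUMNS = ["family_id", "id", "father_id", "mother_id", "sex", "phenotype"]
_PED_OPTIONAL = ["excluded_parent", "twin_group", "cognitive_impairment", "sequenced"]


def read_ped(path) -> list[Pedigree]:
    """Read a 6+-column PED file (FID IID PAT MAT SEX PHENO [extras]).

    0 encodes a missing parent/sex/phenotype. Optional extension columns, in
    order: excluded_parent (0/1), twin_group (0 = none), cognitive_impairment
    (0/1/NA), sequenced (0/1). Tab- or whitespace-delimited; lines starting
    with '#' are ignored.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 6:
                raise PedigreeError(f"{path}:{lineno}: expected >= 6 columns, got {len(parts)}")
            rows.append(parts)
    families: dict[str, list[Individual]] = {}
    for parts in rows:
        fid, iid, pat, mat, sex, pheno = parts[:6]
        extras = parts[6:]
        ind = Individual(
            id=iid,
            family_id=fid,
            father_id=None if pat == "0" else pat,
            mother_id=None if mat == "0" else mat,
            sex={"1": MALE, "2": FEMALE}.get(sex),
            affected=pheno == "2",
        )
        if len(extras) >= 1:
            ind.excluded_parent = extras[0] == "1"
        if len(extras) >= 2 and extras[1] != "0":
            ind.twin_group = extras[1]
        if len(extras) >= 3 and extras[2].upper() != "NA":
            ind.cognitive_impairment = extras[2] == "1"
        if len(extras) >= 4:
            ind.sequenced = extras[3] == "1"
        families.setdefault(fid, []).append(ind)
    return [Pedigree(fid, members) for fid, members in families.items()]


def write_ped(pedigrees: Iterable[Pedigree], path) -> None:
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(_PED_COLUMNS + _PED_OPTIONAL) + "\n")
        for ped in pedigrees:
            for ind in ped.members.values():
                ci = "NA" if ind.cognitive_impairment is None else int(ind.cognitive_impairment)
                fh.write(
                    "\t".join(
                        str(x)
                        for x in (
                            ped.family_id,
                            ind.id,
                            ind.father_id or "0",
                            ind.mother_id or "0",
                            {MALE: "1", FEMALE: "2"}.get(ind.sex, "0"),
                            "2" if ind.affected else "1",
                            int(ind.excluded_parent),
                            ind.twin_group or "0",
                            ci,
                            int(ind.sequenced),
                        )
                    )
                    + "\n"
                )


# ---------------------------------------------------------------------------
# Relatedness graph and unrelated selection
# ---------------------------------------------------------------------------

def build_relatedness_graph(
    pedigrees: Sequence[Pedigree],
    inferred: Optional[pd.DataFrame] = None,
    threshold: float = 0.1,
    x_mode: bool = False,
) -> nx.Graph:
    """Relatedness graph over all individuals.

    Declared edges connect within-family pairs with pedigree kinship >= 1/8
    (first- and second-degree relatives). ``inferred`` is an optional
    (id1, id2, kinship) table of genotype-based estimates for pairs without a
    known familial relationship; pairs at or above ``threshold`` gain an edge
    tagged ``inferred_kinship``. In ``x_mode`` father-son pairs are treated
    as unrelated (no X sharing).
    """
    g = nx.Graph()
    for ped in pedigrees:
        ids = list(ped.members)
        g.add_nodes_from(ids)
        for i, a in enumerate(ids):
            for b in ids[i + 1 :]:
                phi = kinship_coefficient(ped, a, b)
                if phi < 0.125:
                    continue
                if x_mode and _is_father_son(ped, a, b):
                    continue
                degree = "declared_first_degree" if phi >= 0.25 else "declared_second_degree"
                g.add_edge(a, b, source=degree, kinship=phi)
    if inferred is not None and len(inferred):
        for row in inferred.itertuples(index=False):
            id1, id2, phi = row[0], row[1], float(row[2])
            if not 0.0 <= phi <= 0.5:
                raise ValueError(f"inferred kinship {phi} for ({id1}, {id2}) outside [0, 0.5]")
            g.add_node(id1)
            g.add_node(id2)
            if id1 != id2 and phi >= threshold and not g.has_edge(id1, id2):
                g.add_edge(id1, id2, source="inferred_kinship", kinship=phi)
    return g


def _is_father_son(ped: Pedigree, a: str, b: str) -> bool:
    ia, ib = ped[a], ped[b]
    return (ia.sex == MALE and ib.sex == MALE) and (ib.father_id == a or ia.father_id == b)


def select_unrelated(
    g: nx.Graph, affected_ids: Optional[set[str]] = None
) -> set[str]:
    """One individual per connected component, deterministically.

    Tie-break: affected before unaffected (to maximize case yield), then
    lexicographically smallest id.
    """
    affected_ids = affected_ids or set()
    chosen = set()
    for comp in nx.connected_components(g):
        chosen.add(min(comp, key=lambda i: (i not in affected_ids, str(i))))
    return chosen


# ---------------------------------------------------------------------------
# Contributing sample sizes and pseudo-samples
# ---------------------------------------------------------------------------

@dataclass
class ContributionWeight:
    individual_id: str
    weight: float
    ancestors: tuple[str, ...] = ()


def _eligible_ancestor(ind: Individual) -> bool:
    return ind.sequenced and not ind.affected and not ind.excluded_parent


def most_recent_unaffected_ancestors(ped: Pedigree, case_id: str) -> list[str]:
    """Closest sequenced, unaffected, non-excluded ancestor on each lineage.

    The search ascends each parental lineage and stops at the first eligible
    ancestor found on it; ineligible ancestors are passed through.
    """
    found: list[str] = []

    def ascend(iid: Optional[str]) -> None:
        if iid is None or iid not in ped:
            return
        ind = ped[iid]
        if _eligible_ancestor(ind):
            found.append(iid)
            return
        ascend(ind.father_id)
        ascend(ind.mother_id)

    case = ped[case_id]
    ascend(case.father_id)
    ascend(case.mother_id)
    return found


def contributing_sample_size(ped: Pedigree, case_id: str) -> ContributionWeight:
    """1 minus the summed kinship with the sampled unaffected ancestors.

    Both unaffected sequenced parents -> 0.5; a duo -> 0.75; no sequenced
    unaffected ancestors -> 1.0. Floored at 0 for pathological pedigrees.
    """
    case = ped[case_id]
    if not case.affected:
        raise ValueError(f"{case_id!r} is not an affected individual")
    ancestors = most_recent_unaffected_ancestors(ped, case_id)
    w = 1.0 - sum(kinship_coefficient(ped, case_id, a) for a in ancestors)
    return ContributionWeight(case_id, max(0.0, w), tuple(ancestors))


def _one_per_twin_group(members: Iterable[Individual]) -> list[Individual]:
    seen: set[str] = set()
    out = []
    for m in sorted(members, key=lambda x: x.id):
        if m.twin_group is not None:
            if m.twin_group in seen:
                continue
            seen.add(m.twin_group)
        out.append(m)
    return out


def construct_pseudocontrols(
    pedigrees: Sequence[Pedigree], variants: pd.DataFrame
) -> tuple[pd.Series, float]:
    """Per-gene untransmitted allele counts from eligible parents.

    Eligible parents are unaffected, non-excluded, sequenced parents of at
    least one sequenced affected offspring. An allele of such a parent counts
    when no affected offspring of that parent carries it (matched on
    ``allele_id``). Each eligible parent contributes 0.5 to the effective
    sample size, whether or not it carries any variant.

    ``variants`` needs columns: individual_id, gene_id, allele_id.
    Returns (per-gene counts, effective sample size).
    """
    counts: dict[str, float] = {}
    n_parents = 0
    by_ind = variants.groupby("individual_id") if len(variants) else None
    for ped in pedigrees:
        for parent in ped.members.values():
            if not _eligible_ancestor(parent):
                continue
            kids = [
                k
                for k in _one_per_twin_group(ped.offspring(parent.id))
                if k.affected and k.sequenced
            ]
            if not kids:
                continue
            n_parents += 1
            if by_ind is None or parent.id not in by_ind.groups:
                continue
            kid_alleles: set = set()
            for k in kids:
                if k.id in by_ind.groups:
                    kid_alleles.update(by_ind.get_group(k.id)["allele_id"])
            for row in by_ind.get_group(parent.id).itertuples(index=False):
                if row.allele_id not in kid_alleles:
                    counts[row.gene_id] = counts.get(row.gene_id, 0.0) + 1.0
    return pd.Series(counts, dtype=float).sort_index(), 0.5 * n_parents


def construct_pseudocases(
    pedigrees: Sequence[Pedigree],
    variants: pd.DataFrame,
    dnv_alleles: Optional[set] = None,
) -> tuple[pd.Series, float]:
    """Per-gene weighted allele counts from cases, net of sampled ancestors.

    For every affected sequenced case with contributing weight > 0, alleles
    observed in any of its sampled unaffected ancestors or listed in
    ``dnv_alleles`` are removed; the rest contribute the case's weight to the
    gene count. Effective sample size is the sum of weights over included
    cases. Monozygotic twins are counted once.
    """
    dnv_alleles = dnv_alleles or set()
    counts: dict[str, float] = {}
    n_eff = 0.0
    by_ind = variants.groupby("individual_id") if len(variants) else None
    for ped in pedigrees:
        cases = [m for m in _one_per_twin_group(ped.members.values()) if m.affected and m.sequenced]
        for case in cases:
            cw = contributing_sample_size(ped, case.id)
            if cw.weight <= 0:
                continue
            n_eff += cw.weight
            if by_ind is None or case.id not in by_ind.groups:
                continue
            ancestor_alleles: set = set()
            for a in cw.ancestors:
                if a in by_ind.groups:
                    ancestor_alleles.update(by_ind.get_group(a)["allele_id"])
            for row in by_ind.get_group(case.id).itertuples(index=False):
                if row.allele_id in ancestor_alleles or row.allele_id in dnv_alleles:
                    continue
                counts[row.gene_id] = counts.get(row.gene_id, 0.0) + cw.weight
    return pd.Series(counts, dtype=float).sort_index(), n_eff
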