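import numpy as np
import pandas as pd
import pytest

from rarefam.pedigree import Individual, Pedigree


@pytest.fixture
def trio():
    return Pedigree(
        "fam1",
        [
            Individual("dad", "fam1", sex="male"),
            Individual("mom", "fam1", sex="female"),
            Individual("kid", "fam1", father_id="dad", mother_id="mom", affected=True),
        ],
    )


@pytest.fixture
def nuclear_family():
    """Two parents, two full siblings."""
    return Pedigree(
        "fam2",
        [
            Individual("dad", "fam2", sex="male"),
            Individual("mom", "fam2", sex="female"),
            Individual("sib1", "fam2", father_id="dad", mother_id="mom", affected=True),
            Individual("sib2", "fam2", father_id="dad", mother_id="mom"),
        ],
    )


@pytest.fixture
def half_sib_family():
    """One shared father, two mothers."""
    return Pedigree(
        "fam3",
        [
            Individual("dad", "fam3", sex="male"),
            Individual("mom1", "fam3", sex="female"),
            Individual("mom2", "fam3", sex="female"),
            Individual("h1", "fam3", father_id="dad", mother_id="mom1"),
            Individual("h2", "fam3", father_id="dad", mother_id="mom2"),
        ],
    )


@pytest.fixture
def three_generations():
    """Grandparents -> parents -> grandchild, with a marry-in founder."""
    return Pedigree(
        "fam4",
        [
            Individual("gpa", "fam4", sex="male"),
            Individual("gma", "fam4", sex="female"),
            Individual("dad", "fam4", father_id="gpa", mother_id="gma", sex="male"),
            Individual("mom", "fam4", sex="female"),
            Individual("kid", "fam4", father_id="dad", mother_id="mom", affected=True),
        ],
    )


def gene_drop_kinship(ped: Pedigree, a: str, b: str, n_drops: int, seed: int = 0) -> float:
    """Monte Carlo kinship oracle: drop founder alleles through the pedigree.

    The kinship coefficient is the probability that one allele drawn at
    random from each individual is identical by descent, estimated over
    ``n_drops`` independent gene drops (vectorized).
    """
    rng = np.random.default_rng(seed)
    order = sorted(ped.members, key=ped.depth)
    alleles: dict[str, np.ndarray] = {}
    next_founder_allele = 0
    for iid in order:
        ind = ped[iid]
        cols = []
        for pid in (ind.father_id, ind.mother_id):
            if pid is None:
                col = np.full(n_drops, next_founder_allele)
                next_founder_allele += 1
            else:
                parent = alleles[pid]
                pick = rng.integers(0, 2, size=n_drops)
                col = parent[np.arange(n_drops), pick]
            cols.append(col)
        alleles[iid] = np.column_stack(cols)
    A, B = alleles[a], alleles[b]
    ibd = sum((A[:, i] == B[:, j]).mean() for i in range(2) for j in range(2)) / 4.0
    return float(ibd)


def random_three_generation_pedigree(seed: int) -> Pedigree:
    """A randomized 3-generation family for property testing kinship."""
    rng = np.random.default_rng(seed)
    members = [
        Individual("gp1", "r", sex="male"),
        Individual("gp2", "r", sex="female"),
        Individual("gp3", "r", sex="male"),
        Individual("gp4", "r", sex="female"),
    ]
    n_left = int(rng.integers(1, 4))
    n_right = int(rng.integers(1, 4))
    parents_left = [
        Individual(f"pl{i}", "r", father_id="gp1", mother_id="gp2",
                   sex="male" if rng.random() < 0.5 else "female")
        for i in range(n_left)
    ]
    parents_right = [
        Individual(f"pr{i}", "r", father_id="gp3", mother_id="gp4",
                   sex="male" if rng.random() < 0.5 else "female")
        for i in range(n_right)
    ]
    members += parents_left + parents_right
    kids = []
    for i in range(int(rng.integers(1, 5))):
        pa = parents_left[int(rng.integers(n_left))]
        pb = parents_right[int(rng.integers(n_right))]
        if pa.sex == pb.sex:  # force an opposite-sex pairing
            pb = Individual(f"sp{i}", "r", sex="female" if pa.sex == "male" else "male")
            members.append(pb)
        father, mother = (pa, pb) if pa.sex == "male" else (pb, pa)
        kids.append(
            Individual(f"k{i}", "r", father_id=father.id, mother_id=mother.id)
        )
    members += kids
    return Pedigree("r", members)


@pytest.fixture
def variant_table():
    """Helper to build variant-observation frames tersely."""

    def make(rows):
        return pd.DataFrame(
            rows,
            columns=[
                "individual_id",
                "family_id",
                "gene_id",
                "variant_class",
                "allele_id",
                "af",
                "high_confidence",
                "pext",
                "inheritance",
                "chrom_class",
            ],
        )

    return make
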