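import random

import pytest

from chromorr.model import (Chromosome, ChromosomeStructure, GeneToken,
                            parse_structure)

# Mitochondrial gene orders of the sporozoan class Aconoidasida
# (asterisk = complementary strand; C/L = circular/linear chromosome).
ACONOIDASIDA_ROWS = [
    ("Leucocytozoon_fringillinarum", "C",
     "ss3 ls3 ls9 ss2 ls4 *cox3 ls8 ss5 ss1 cox1 cytb ls1 ss6 ls7 ss4"),
    ("Leucocytozoon_majoris", "C",
     "ss3 ls3 ls9 ss2 ls4 *cox3 ls8 ss5 ss1 cox1 cytb ls1 ss6 ls7"),
    ("Leucocytozoon_sabrazesi", "L",
     "ls1 ss4 ss6 ls7 ls6 ss3 ls3 ls9 ss2 ls4 ls5 *cox3 ls8 ss5 ss1 cox1 cytb ls2"),
    ("Plasmodium_berghei", "L",
     "ls1 ss4 ss6 ls7 ls6 ss3 ls3 ls9 ss2 ls4 ls5 *cox3 ls8 ss5 ss1 cox1 cytb ls2"),
    ("Plasmodium_falciparum", "L",
     "ss3 ls3 ls9 ss2 *cox3 ls8 ss5 ss1 cox1 cytb ls1 ss4 ss6 ls7"),
    ("Plasmodium_floridense", "L",
     "ss3 ls3 ls9 ss2 ls4 *cox3 ls8 ss5 ss1 cox1 cytb ls1 ss4 ss6 ls7"),
    ("Plasmodium_fragile", "C",
     "ls1 ss6 ls7 ss3 ls3 ls9 ss2 ls4 *cox3 ls8 ss5 ss1 cox1 cytb"),
    ("Plasmodium_gallinaceum", "L",
     "ls1 ss4 ss6 ls7 ls6 ss3 ls3 ls9 ss2 ls4 ls5 *cox3 ls8 ss5 ss1 cox1 cytb ls2"),
    ("Plasmodium_juxtanucleare", "L",
     "ls1 ss4 ss6 ls7 ls6 ss3 ls3 ls9 ss2 ls4 ls5 *cox3 ls8 ss5 ss1 cox1 cytb ls2"),
    ("Plasmodium_knowlesi", "C",
     "ls1 ss6 ls7 ss3 ls3 ls9 ss2 ls4 *cox3 ls8 ss5 ss1 cox1 cytb"),
    ("Plasmodium_mexicanum", "L",
     "ss3 ls3 ls9 ss2 *cox3 ls8 ss5 ss1 cox1 cytb ls1 ss4 ss6 ls7"),
    ("Plasmodium_reichenowi", "L",
     "ss3 ls3 ls9 ss2 *cox3 ls8 ss5 ss1 cox1 cytb ls1 ss4 ss6 ls7"),
    ("Plasmodium_relictum", "C",
     "ss3 ls3 ls9 ss2 ls4 *cox3 ls8 ss5 ss1 cox1 cytb ls1 ss4 ss6 ls7"),
    ("Plasmodium_simium", "C",
     "ls1 ss6 ls7 ss3 ls3 ls9 ss2 ls4 *cox3 cox1 cytb ls8 ss5 ss1"),
    ("Plasmodium_vivax", "C",
     "ls1 ss6 ls7 ss3 ls3 ls9 ss2 ls4 *cox3 ls8 ss5 ss1 cox1 cytb"),
    ("Babesia_bovis", "L",
     "cox1 *cox3 ls1 *ls2 *ls3 *cytb *ls4 ls5"),
    ("Theileria_parva", "L",
     "cox1 *cox3 ls1 *ls3 *cytb *ls5 ls4"),
    ("Theileria_annulata", "L",
     "cox1 *cox3 ls1 *ls3 *ls2 *cytb *ls5 ls4"),
]


@pytest.fixture(scope="session")
def mito_structures():
    return {name: parse_structure(f"{genes} ({topo})", "table1", name=name)
            for name, topo, genes in ACONOIDASIDA_ROWS}


def random_structure_over(rng, families, p_circular=0.5, max_chroms=None):
    toks = [GeneToken(f, None, rng.choice((1, -1))) for f in families]
    rng.shuffle(toks)
    k = rng.randint(1, max_chroms or len(toks))
    cuts = sorted(rng.sample(range(1, len(toks)), k - 1)) if k > 1 else []
    chroms, prev = [], 0
    for cut in cuts + [len(toks)]:
        part = tuple(toks[prev:cut])
        prev = cut
        if part:
            chroms.append(Chromosome(part, rng.random() < p_circular))
    return ChromosomeStructure(tuple(chroms)).canonical()


def random_pair(rng, max_genes=4, shared_range=None):
    """A random structure pair with overlapping gene content."""
    na = rng.randint(1, max_genes)
    nshared = rng.randint(0, na) if shared_range is None else \
        rng.randint(*shared_range)
    fams_a = [f"g{i}" for i in range(1, nshared + 1)] + \
             [f"p{i}" for i in range(na - nshared)]
    fams_b = [f"g{i}" for i in range(1, nshared + 1)] + \
             [f"q{i}" for i in range(rng.randint(0, max_genes - 1))]
    if not fams_a or not fams_b:
        return None
    return (random_structure_over(rng, fams_a),
            random_structure_over(rng, fams_b))
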