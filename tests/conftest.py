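import numpy as np
import pytest

from rohped.pedigree import Pedigree, PedigreeRecord
from rohped.simulate import SimConfig, emit_genotypes, gene_drop, simulate_pedigree


def make_pedigree(rows):
    """rows: (id, sire, dam) or (id, sire, dam, extra-kwargs dict)."""
    recs = []
    for row in rows:
        iid, sire, dam = row[:3]
        kw = row[3] if len(row) > 3 else {}
        recs.append(PedigreeRecord(id=iid, sire=sire or "", dam=dam or "", **kw))
    return Pedigree(recs)


@pytest.fixture(scope="session")
def halfsib_pedigree():
    # D and E share sire A; F is their offspring
    return make_pedigree(
        [("A", "", ""), ("B", "", ""), ("C", "", ""),
         ("D", "A", "B"), ("E", "A", "C"), ("F", "D", "E")]
    )


@pytest.fixture(scope="session")
def cousin_pedigree():
    # full sibs C, D marry unrelated founders; their children are first cousins
    return make_pedigree(
        [("A", "", ""), ("B", "", ""), ("U", "", ""), ("V", "", ""),
         ("C", "A", "B"), ("D", "A", "B"),
         ("E", "C", "U"), ("F", "D", "V"), ("G", "E", "F")]
    )


@pytest.fixture(scope="session")
def fullsib_pedigree():
    return make_pedigree(
        [("A", "", ""), ("B", "", ""),
         ("C", "A", "B"), ("D", "A", "B"), ("E", "C", "D")]
    )


@pytest.fixture(scope="session")
def small_sim():
    """One scaled-down end-to-end simulation shared across tests."""
    cfg = SimConfig.small(seed=1)
    ped = simulate_pedigree(cfg)
    truth, mosaics = gene_drop(ped, cfg)
    ds = emit_genotypes(mosaics, cfg, ped)
    return cfg, ped, truth, mosaics, ds


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
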