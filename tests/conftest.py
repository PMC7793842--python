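import numpy as np
import pytest

from hgpm import (
    FeatureCatalog,
    Mode,
    PharmacophoreModel,
    build_graph,
    make_feature_key,
)
from hgpm.features import CountedVector

RESIDUES = ["ARG63", "SER64", "THR65", "TYR214", "ILE211", "MET210",
            "TYR215", "VAL62", "GLY97", "PRO66", "LYS169", "ASP205"]
TYPES = ["H", "HBA", "HBD", "AR", "PI", "NI", "XBD"]


def key(i, mode=Mode.LIGAND_AWARE):
    """The i-th feature of a small deterministic alphabet."""
    return make_feature_key(
        TYPES[i % len(TYPES)], [f"A{i}"], [RESIDUES[i % len(RESIDUES)]], mode
    )


def model(features, frame=0, run="run1", system="sys", reference=False):
    return PharmacophoreModel(system, run, frame, frozenset(features),
                              is_reference=reference)


def graph_from_sets(sets, counts=None, catalog=None):
    """Build an HGPMGraph straight from observed feature-index sets."""
    keys = sorted({i for s in sets for i in s})
    catalog = catalog or FeatureCatalog([key(i) for i in keys])
    counted = []
    for j, s in enumerate(sets):
        mask = 0
        for i in s:
            mask |= 1 << catalog.index(key(i))
        counted.append(
            CountedVector(mask, (counts or {}).get(j, 1),
                          [("sys", "run1", j)], observed=True)
        )
    return build_graph(counted, catalog)


def random_mask_sets(rng, n_sets, n_bits, p=0.3):
    """Random duplicate-free family of non-empty bitmasks."""
    out = set()
    while len(out) < n_sets:
        mask = 0
        for b in range(n_bits):
            if rng.random() < p:
                mask |= 1 << b
        if mask:
            out.add(mask)
    return out


@pytest.fixture
def abc_catalog():
    return FeatureCatalog([key(0), key(1), key(2)])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
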