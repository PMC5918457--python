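"""Shared fixtures: small pedigrees, simulated studies, and the
session-scoped null calibration experiment used by the acceptance tests."""

from __future__ import annotations

import numpy as np
import pytest

from famrv.datatypes import GenotypeMatrix, PedigreeRecord, VariantRecord
from famrv.genetests import TestConfig
from famrv.pedigree import build_pedigree
from famrv.simulate import SimSpec, make_pedigree, run_calibration


@pytest.fixture
def trio_records():
    return [
        PedigreeRecord("F1", "dad", "0", "0", 1, 1),
        PedigreeRecord("F1", "mom", "0", "0", 2, 1),
        PedigreeRecord("F1", "kid", "dad", "mom", 2, 2),
    ]


@pytest.fixture
def trio_pedigree(trio_records):
    return build_pedigree(trio_records)


@pytest.fixture
def three_gen_pedigree():
    """8-member, 3-generation family: grandparents 1x2, their children 3
    and 5, marry-ins 4 and 6, grandchildren 7 (3x4) and 8 (6x5)."""
    return make_pedigree("gen3_8", 1)


def toy_genotypes(dosages, keys=None):
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    if keys is None:
        keys = [("F1", f"s{i + 1}") for i in range(n)]
    variants = [VariantRecord("1", 100 * (j + 1), f"v{j + 1}", "A", "G")
                for j in range(m)]
    return GenotypeMatrix(d, keys, variants)


@pytest.fixture
def make_genotypes():
    return toy_genotypes


# --- null calibration (shared by the type-I-error acceptance tests) -------

#: printed type-I-error surface being reproduced: {alpha: {method: (rate, se)}}
CALIBRATION_REFERENCE = {
    0.1: {"skat": (0.093, 0.024), "burden": (0.096, 0.023),
          "skato": (0.093, 0.022), "vt": (0.081, 0.020)},
    0.05: {"skat": (0.047, 0.016), "burden": (0.048, 0.017),
           "skato": (0.048, 0.016), "vt": (0.043, 0.016)},
    0.01: {"skat": (0.010, 0.006), "burden": (0.010, 0.007),
           "skato": (0.011, 0.007), "vt": (0.012, 0.008)},
}


def calibration_conditions(seed: int) -> tuple[SimSpec, TestConfig]:
    """The null design: 200 genes x 200 phenotype replicates on 50
    three-generation pedigrees of 8 (h2 = 0.3), >= 40,000 null tests."""
    spec = SimSpec(template="gen3_8", n_families=50, n_genes=200,
                   variants_per_gene=8, h2=0.3, n_replicates=200, seed=seed)
    cfg = TestConfig(seed=seed)
    return spec, cfg


@pytest.fixture(scope="session")
def null_calibration():
    spec, cfg = calibration_conditions(seed=2024)
    return run_calibration(spec, methods=("burden", "skat", "skato", "vt"),
                           alphas=(0.1, 0.05, 0.01), config=cfg)
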