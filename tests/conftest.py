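import io

import numpy as np
import pytest

from tcrspec.synthetic import SyntheticConfig, generate

VDJDB_HEADER = ("gene\tcdr3\tv.segm\tj.segm\tmhc.a\tmhc.b\tmhc.class\tspecies\t"
                "antigen.epitope\tantigen.gene\tantigen.species\tvdjdb.score")


def make_row(cdr3="CASSLGETQYF", chain="TRB", v="TRBV7-9", j="TRBJ2-5",
             mhc_a="HLA-A*02:01", mhc_b="B2M", mhc_class="MHCI",
             host="HomoSapiens", epitope="NLVPMVATV", epi_gene="pp65",
             epi_species="CMV", score="2"):
    return "\t".join([chain, cdr3, v, j, mhc_a, mhc_b, mhc_class, host,
                      epitope, epi_gene, epi_species, score])


@pytest.fixture
def toy_table():
    """Three clean rows in the VDJdb web-export dialect."""
    rows = [
        make_row(),
        make_row(cdr3="CASSIRSSYEQYF", v="TRBV19", j="TRBJ2-7",
                 epitope="GILGFVFTL", epi_gene="M", epi_species="InfluenzaA"),
        make_row(cdr3="CASSPDRGRYEQYF", v="TRBV5-1", j="TRBJ2-1",
                 epitope="TVYGFCLL", epi_gene="m139", epi_species="MCMV",
                 host="MusMusculus", score="3"),
    ]
    return io.StringIO(VDJDB_HEADER + "\n" + "\n".join(rows) + "\n")


@pytest.fixture(scope="session")
def small_synthetic():
    """A 3-class clean synthetic table shared by several tests."""
    cfg = SyntheticConfig(class_sizes=(60, 60, 60), seed=42)
    frame, truth = generate(cfg)
    return cfg, frame, truth


def finite_difference_grad(f, x, eps=1e-6):
    """Central finite differences of scalar f at array x."""
    x = np.asarray(x, dtype=np.float64)
    g = np.zeros_like(x)
    it = np.nditer(x, flags=["multi_index"])
    while not it.finished:
        idx = it.multi_index
        xp = x.copy(); xp[idx] += eps
        xm = x.copy(); xm[idx] -= eps
        g[idx] = (f(xp) - f(xm)) / (2 * eps)
        it.iternext()
    return g
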