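import numpy as np
import pandas as pd
import pytest

from socialqtl import QtlSpec, SimConfig, simulate_family
from socialqtl.gio import MarkerSet


@pytest.fixture(scope="session")
def small_null_family():
    """A small simulated family with no planted QTL."""
    cfg = SimConfig(n=30, chrom_lengths_cM=(50.0,), spacing_cM=5.0,
                    qtl=(), h2=0.4, seed=11)
    return simulate_family(cfg)


@pytest.fixture(scope="session")
def qtl_family():
    """A family with one planted directional testcross QTL."""
    cfg = SimConfig(
        n=60, chrom_lengths_cM=(60.0, 60.0), spacing_cM=5.0,
        qtl=(QtlSpec(0, 30.0, "ag",
                     {"delta_direct": 1.0, "iota_indirect": 0.6,
                      "eps_epistatic": 0.4}),),
        h2=0.4, seed=21,
    )
    return simulate_family(cfg)


@pytest.fixture()
def toy_marker_set():
    """Hand-built 4-individual, 3-marker set (testcross/intercross mix)."""
    gmap = pd.DataFrame({
        "marker": ["m1", "m2", "m3"],
        "chrom": [1, 1, 2],
        "pos_cM": [0.0, 10.0, 0.0],
    })
    geno = np.array([
        [0, 0, 2],
        [1, 1, 1],
        [0, 1, 0],
        [1, 0, 1],
    ], dtype=np.int8)
    return MarkerSet(
        individuals=["a", "b", "c", "d"],
        markers=["m1", "m2", "m3"],
        genotypes=geno,
        gmap=gmap,
    )
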