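import numpy as np
import pandas as pd
import pytest

import orgedit as oe
from orgedit.annotation import SampleDesign, sites_to_frame


@pytest.fixture(scope="session")
def small_frame():
    """Small annotation: 40 mitochondrial + 4 plastid sites over 8 transcripts."""
    return sites_to_frame(oe.gen_sites(40, 4, 8, seed=11))


@pytest.fixture(scope="session")
def small_truth(small_frame):
    mito = list(small_frame.index[small_frame["organelle"] == "mito"])
    return oe.gen_truth(small_frame, frac_increased=0.2, frac_decreased=0.1,
                        seed=12, effect_sites=mito)


@pytest.fixture(scope="session")
def small_matrix(small_truth):
    design = oe.default_design(replicates=2)
    return oe.gen_counts(small_truth, design, depth=2000, seed=13)


@pytest.fixture(scope="session")
def rescue_setup():
    """Matrix with wildtype, mutant and two fully rescued transgenic lines."""
    frame = sites_to_frame(oe.gen_sites(100, 0, 10, seed=21))
    truth = oe.gen_truth(frame, frac_increased=0.2, frac_decreased=0.1, seed=22)
    truth.add_rescued("rescued", level=1.0)
    design = oe.default_design() + [
        SampleDesign("tg-1", "rescued", 1, "transgenic", background="mutant"),
        SampleDesign("tg-2", "rescued", 2, "transgenic", background="mutant"),
    ]
    matrix = oe.gen_counts(truth, design, depth=2000, seed=23)
    results = oe.classify_all(matrix, "wildtype", "mutant")
    return truth, matrix, results
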