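import logging

import pytest

import lpcbps as lb

# keep expected-warning chatter (dropped genes, degenerate folds) out of output
logging.getLogger("lpcbps").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def line_cohort_zero_noise():
    """200 tumor samples on an exact line per process, no noise, no normals."""
    return lb.generate_cohort(
        n_tumor=200,
        n_normal=0,
        n_processes=2,
        genes_per_process=15,
        n_drivers=0,
        curve_shape="line",
        noise_sd=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def arc_cohort():
    """Default synthetic cohort: curved (arc) processes, normals, survival."""
    return lb.generate_cohort(seed=7)


@pytest.fixture(scope="session")
def arc_bps(arc_cohort):
    return lb.score_all(arc_cohort.expression, arc_cohort.genesets)
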