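import numpy as np
import pandas as pd
import pytest

from ceoseq import AlignmentRecord, ProtocolParams, build_synthetic_locus, simulate_locus


@pytest.fixture(scope="session")
def fibh_locus():
    """Default FibH-emulating synthetic locus (seed 0)."""
    return build_synthetic_locus(seed=0)


@pytest.fixture(scope="session")
def default_sim(fibh_locus):
    """One protocol run at the default parameters."""
    return simulate_locus(fibh_locus, ProtocolParams(), seed=0)


@pytest.fixture(scope="session")
def clean_meth_sim(fibh_locus):
    """Protocol run with an error-free methylation caller (the
    parameter-recovery condition)."""
    return simulate_locus(fibh_locus, ProtocolParams(meth_caller_error=0.0), seed=0)


def alignments_of(sim):
    return [
        AlignmentRecord(r.read_id, *r.truth, mean_q=r.mean_q) for r in sim.reads
    ]


def calls_frame(sim):
    rows = [
        (r.truth[0], pos, r.read_id, state)
        for r in sim.reads
        for pos, state in r.cg_calls
    ]
    return pd.DataFrame(rows, columns=["chromosome", "position", "read_id", "call"])


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
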