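import numpy as np
import pandas as pd
import pytest

from m6acomod.peaks import TranscriptModel, WindowCountTable, make_windows
from m6acomod.pipeline import PipelineConfig, run_on_dataset
from m6acomod.simulate import build_dataset


@pytest.fixture(scope="session")
def dataset0():
    """One synthetic end-to-end dataset shared across tests."""
    return build_dataset(seed=0)


@pytest.fixture(scope="session")
def result0(dataset0):
    return run_on_dataset(dataset0, PipelineConfig(seed=0))


@pytest.fixture()
def single_gene_windows():
    """One 250-bp single-exon gene tiled with the default 100/50 grid."""
    return make_windows({"gA": ("chr1", "+", [(1000, 1250)])})


def make_count_table(windows, ip, inp, lib_ip=1e7, lib_input=1e7, samples=("s1",)):
    """Small WindowCountTable from explicit per-window counts."""
    ip = np.atleast_2d(np.asarray(ip, dtype=int).T).T.reshape(len(windows), len(samples))
    inp = np.atleast_2d(np.asarray(inp, dtype=int).T).T.reshape(len(windows), len(samples))
    return WindowCountTable(
        windows,
        pd.DataFrame(ip, index=windows.index, columns=list(samples)),
        pd.DataFrame(inp, index=windows.index, columns=list(samples)),
        pd.Series(lib_ip, index=list(samples), dtype=float),
        pd.Series(lib_input, index=list(samples), dtype=float),
    )


@pytest.fixture()
def toy_model():
    """Transcript with 100-nt 5'UTR, 300-nt CDS, 200-nt 3'UTR on one exon."""
    return TranscriptModel("gA", "chr1", "+", [(0, 600)], 100, 300, 200)
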