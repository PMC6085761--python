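import numpy as np
import pandas as pd
import pytest

from methcanyon.core import Methylome
from methcanyon.pipeline import PipelineConfig, run_all


def make_methylome(
    positions, ratios, coverage=50, chrom="chr1", sample_id="S", group=None
) -> Methylome:
    positions = np.asarray(positions, dtype=np.int64)
    ratios = np.asarray(ratios, dtype=float)
    cov = np.full(len(positions), coverage, dtype=np.int64)
    df = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "meth_ratio": ratios, "coverage": cov}
    )
    return Methylome(sample_id, df, group=group)


@pytest.fixture(scope="session")
def pipeline_state():
    """One full default-cohort pipeline run shared by the end-to-end tests."""
    return run_all(PipelineConfig(seed=11))
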