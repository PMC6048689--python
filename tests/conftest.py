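import numpy as np
import pandas as pd
import pytest

from pulseprot.experiment import QuantMatrix, SampleInfo


def quant_from_ratios(ratio_hm: pd.DataFrame, samples, counts=None, abundance=None):
    """Build a QuantMatrix from a wide H/M ratio table.

    Channel intensities are filled in consistently (M = 1e6, H = M * ratio,
    L = 1e8) wherever the ratio is present; ratio counts default to 2.
    """
    sids = [s.sample_id for s in samples]
    ratio_hm = ratio_hm.copy()
    ratio_hm.columns = sids
    present = ratio_hm.notna()
    M = pd.DataFrame(1e6, index=ratio_hm.index, columns=sids).where(present)
    H = M * ratio_hm
    L = pd.DataFrame(1e8, index=ratio_hm.index, columns=sids).where(present)
    if counts is None:
        counts = pd.DataFrame(2.0, index=ratio_hm.index, columns=sids).where(present, 0.0)
    else:
        counts = counts.copy()
        counts.columns = sids
    fields = {
        "intensity_L": L,
        "intensity_M": M,
        "intensity_H": H,
        "ratio_HM": ratio_hm,
        "ratio_ML": M / L,
        "ratio_count_HM": counts,
        "ratio_count_ML": counts,
    }
    return QuantMatrix(list(samples), fields, abundance)


def make_samples(n, cue="Netrin1", modulator="none", pulse=5):
    return [
        SampleInfo(cue=cue, modulator=modulator, pulse_minutes=pulse, replicate_id=f"r{i + 1}")
        for i in range(n)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
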