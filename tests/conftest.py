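import numpy as np
import pandas as pd
import pytest

from defensin_cnv import prt_genotyping as prt
from defensin_cnv import synthetic_cohort as sc

CHANNELS = sc.DEFAULT_CHANNELS


def make_panel_frame(slope=0.5, intercept=0.0, copy_numbers=(2, 3, 4, 5, 6, 7),
                     channels=CHANNELS, noise=None, rng=None):
    """Reference-panel DataFrame with ratios affine in copy number.

    ``noise`` is an optional per-row additive perturbation of the ratio
    (callable rng draws used when given).
    """
    rows = []
    for i, cn in enumerate(copy_numbers):
        for assay, dye in channels:
            ratio = slope * cn + intercept
            if noise is not None:
                ratio += noise if np.isscalar(noise) else rng.normal(0, noise)
            ref_area = 5000.0
            rows.append((f"REF{i + 1:02d}", assay, dye, ratio * ref_area,
                         ref_area, cn))
    return pd.DataFrame(rows, columns=["sample_id", "assay", "dye", "test_area",
                                       "reference_area", "known_cn"])


def make_peaks_frame(sample_cns: dict, slope=0.5, intercept=0.0,
                     channels=CHANNELS):
    """Noise-free cohort peak table for samples with given true copy numbers."""
    rows = []
    for sid, cn in sample_cns.items():
        for assay, dye in channels:
            ratio = slope * cn + intercept
            ref_area = 4000.0
            rows.append((sid, assay, dye, ratio * ref_area, ref_area))
    return pd.DataFrame(rows, columns=["sample_id", "assay", "dye",
                                       "test_area", "reference_area"])


@pytest.fixture
def noise_free_model():
    panel = prt.parse_reference_panel(make_panel_frame())
    return prt.fit_calibration(panel)


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)
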