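"""Shared test utilities: raw-value profile builders."""

import numpy as np

from rbliquid.bins import CopyRatioProfile
from rbliquid.genome import GenomeBins
from rbliquid.segment import SegmentedProfile, cbs_segment


def profile_from_values(grid: GenomeBins, values: np.ndarray) -> CopyRatioProfile:
    """Wrap a raw per-bin log2 vector as an (uncentered) profile."""
    return CopyRatioProfile(grid=grid, log2=np.asarray(values, dtype=float))


def segmented_from_values(grid: GenomeBins, values: np.ndarray,
                          **cbs_kwargs) -> SegmentedProfile:
    defaults = dict(alpha=0.01, n_perm=200, min_width=3, seed=0)
    defaults.update(cbs_kwargs)
    return cbs_segment(profile_from_values(grid, values), **defaults)
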