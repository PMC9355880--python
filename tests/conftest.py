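import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from ervkit.catalog import RepeatFeature, derive_group


def make_feature(fid, start, end, name, chrom="chr1", strand="+", repclass="LTR"):
    return RepeatFeature(
        id=fid,
        chrom=chrom,
        start=start,
        end=end,
        strand=strand,
        name=name,
        repclass=repclass,
        group=derive_group(name),
        is_inner="int" in name,
    )


@pytest.fixture
def gaussian_panel():
    """Noiseless centered isotropic Gaussian panel (side 23, sigma 4 px)."""
    from ervkit.imaging import AverageImagePanel

    side, sigma, amp = 23, 4.0, 100.0
    yy, xx = np.mgrid[0:side, 0:side]
    c = side // 2
    data = amp * np.exp(-((xx - c) ** 2 + (yy - c) ** 2) / (2 * sigma**2))
    return AverageImagePanel(data=data, n_foci=1, pixel_size_xy=65.0), sigma, amp
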