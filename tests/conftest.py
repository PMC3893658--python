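import numpy as np
import pytest

from zeitgeber.cosinor import TimePointSeries


@pytest.fixture
def zt_grid():
    """Six 4-h time points replicated three times, the standard harvest design."""
    return np.tile([0.0, 4.0, 8.0, 12.0, 16.0, 20.0], 3)


def make_series(zt, values, analyte="gene", treatment="control"):
    return TimePointSeries(analyte, treatment, zt, values)
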