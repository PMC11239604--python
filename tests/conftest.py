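import numpy as np
import pytest

import hierpower as hp


@pytest.fixture
def design():
    """Reference design: 20 hospitals x 8 clinics x 6 providers x 6."""
    return hp.default_design()


@pytest.fixture
def vm():
    """Reference variance model: ICCs 0.05/0.01/0.01, 8 iid outcomes."""
    return hp.default_variance()


@pytest.fixture
def vm1():
    """Single-outcome variant of the reference variance model."""
    return hp.VarianceModel(Sigma=np.eye(1), composite_weights=np.array([1.0]))


@pytest.fixture
def subgroup_design():
    return hp.default_design(with_subgroups=True)
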