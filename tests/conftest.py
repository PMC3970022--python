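import datetime

import pytest

from mtai import PhantomParams, RegionAreas, generate_phantom

# areas of the worked bilateral example used throughout: a mild-AD case
# with identical MTL regions but clearly asymmetric indices
FIG_RIGHT = dict(A=326.5, B=201.4, C=189.7)
FIG_LEFT = dict(A=326.5, B=224.0, C=175.2)


@pytest.fixture
def worked_example_right():
    return RegionAreas("RIGHT", study_date=datetime.date(2014, 1, 1), **FIG_RIGHT)


@pytest.fixture
def worked_example_left():
    return RegionAreas("LEFT", study_date=datetime.date(2014, 1, 1), **FIG_LEFT)


@pytest.fixture(scope="session")
def default_phantom():
    params = PhantomParams()
    rois, truth = generate_phantom(params)
    return params, rois, truth
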