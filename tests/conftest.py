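import warnings

import pytest
from shapely.geometry import Polygon

import aerosurvey as a


@pytest.fixture(scope="session")
def still_cam():
    return a.get_camera("still_photo")


@pytest.fixture(scope="session")
def hd_cam():
    return a.get_camera("hd_video")


@pytest.fixture(scope="session")
def thermal_cam():
    return a.get_camera("thermal")


@pytest.fixture(scope="session")
def anchor_projection():
    return a.LocalTransverseMercator(-28.2, 31.95)


def make_square_area(side_m, projection, name="square"):
    sq = Polygon([(0, 0), (side_m, 0), (side_m, side_m), (0, side_m)])
    return a.SurveyArea(projection.unproject_geometry(sq), name)


@pytest.fixture(scope="session")
def km_square(anchor_projection):
    return make_square_area(1000.0, anchor_projection)


@pytest.fixture(autouse=True)
def _silence_altitude_band_warning():
    with warnings.catch_warnings():
        warnings.filterwarnings(
            "ignore", message="altitude .* outside the recommended")
        yield
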