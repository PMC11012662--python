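import math

import pytest
from hypothesis import HealthCheck, settings

from trunkmetrics import BackLandmarks, PixelPoint, make_template

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("ci")


#: Hand-drawn asymmetric fixture used across geometry tests.  Every
#: expected value below was computed independently (trigonometry and
#: trapezoid areas by hand) before the implementation existed.
F1_POINTS = {
    "shoulder_left": (300.0, 250.0),
    "shoulder_right": (700.0, 280.0),
    "axilla_left": (330.0, 390.0),
    "axilla_right": (660.0, 370.0),
    "waist_left": (430.0, 620.0),
    "waist_right": (590.0, 600.0),
    "iliac_left": (410.0, 760.0),
    "iliac_right": (610.0, 770.0),
    "c7": (510.0, 200.0),
}

# atan(30/400), -atan(20/330), -atan(20/160) in degrees; interior
# dot-product angles at the waist vertices; LWA - RWA.
F1_EXPECTED_ANGLES = {
    "SHA": math.degrees(math.atan(30 / 400)),       # 4.289153
    "AHA": -math.degrees(math.atan(20 / 330)),      # -3.468229
    "WHA": -math.degrees(math.atan(20 / 160)),      # -7.125016
    "LWA": math.degrees(math.acos(-30200 / (math.sqrt(62900) * math.sqrt(20000)))),
    "RWA": math.degrees(math.acos(-37700 / (math.sqrt(57800) * math.sqrt(29300)))),
}
F1_EXPECTED_ANGLES["WAD"] = F1_EXPECTED_ANGLES["LWA"] - F1_EXPECTED_ANGLES["RWA"]

# Trapezoid areas: parallel horizontal sides between plumbline x=510 and
# the trunk edge, times half the level gap.
F1_EXPECTED_AREAS = {
    "shoulder_left_px2": (210 + 180) / 2 * 140,   # 27300
    "shoulder_right_px2": (190 + 150) / 2 * 90,   # 15300
    "waist_left_px2": (180 + 80) / 2 * 230,       # 29900
    "waist_right_px2": (150 + 80) / 2 * 230,      # 26450
    "pelvic_left_px2": (80 + 100) / 2 * 140,      # 12600
    "pelvic_right_px2": (80 + 100) / 2 * 170,     # 15300
}
F1_EXPECTED_RATIOS = {
    "SA": 27300 / 15300,
    "WA": 29900 / 26450,
    "PA": 12600 / 15300,
    "TA": (27300 + 29900 + 12600) / (15300 + 26450 + 15300),
}


def build_landmarks(points: dict, photo_id: str = "F1", **kwargs) -> BackLandmarks:
    return BackLandmarks(
        photo_id=photo_id, **{k: PixelPoint(*v) for k, v in points.items()}, **kwargs
    )


@pytest.fixture
def f1() -> BackLandmarks:
    return build_landmarks(F1_POINTS)


@pytest.fixture
def template() -> BackLandmarks:
    return make_template(1500, 1000)
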