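import pathlib

import pytest

from adherit.plate_io import (read_pair_manifest, read_plate_layouts,
                              read_plate_readings,
                              read_standard_curve_points)
from adherit.simulate import GenerativeConfig, make_fixture_study


@pytest.fixture(scope="session")
def default_config() -> GenerativeConfig:
    return GenerativeConfig(seed=11)


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, default_config) -> pathlib.Path:
    """A complete synthetic study written to disk once per session."""
    out = tmp_path_factory.mktemp("study")
    make_fixture_study(default_config, out)
    return out


@pytest.fixture(scope="session")
def fixture_study(fixture_dir):
    """(readings, layouts, pairs, curve_points) re-read from the fixture."""
    readings = read_plate_readings(fixture_dir / "readings.csv")
    layouts = read_plate_layouts(fixture_dir / "layouts.csv")
    pairs = read_pair_manifest(fixture_dir / "pairs.csv")
    curve_points = read_standard_curve_points(fixture_dir / "standard_curve.csv")
    return readings, layouts, pairs, curve_points
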