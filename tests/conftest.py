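import numpy as np
import pytest

from phragmovol import fixtures


@pytest.fixture(scope="session")
def specimens():
    return {r.specimen_id: r for r in fixtures.load_specimens()}


@pytest.fixture(scope="session")
def nm1():
    return fixtures.load_series("Nm.1")


@pytest.fixture(scope="session")
def nm2():
    return fixtures.load_series("Nm.2")


@pytest.fixture(scope="session")
def nautilus_series():
    """All packaged Nautilus series that carry volumes, keyed by id."""
    out = {}
    for sid in fixtures.list_series_ids():
        if sid.startswith("Nm"):
            continue
        s = fixtures.load_series(sid)
        if s.volume_mask.any():
            out[sid] = s
    return out


def make_series(chambers, volumes, widths=None, unit="ml", specimen_id="test"):
    chambers = np.asarray(chambers)
    volumes = np.asarray(volumes, dtype=float)
    if widths is None:
        widths = np.full(len(chambers), np.nan)
    return fixtures.ChamberSeries(
        specimen_id=specimen_id,
        volume_unit=unit,
        chambers=chambers,
        volumes=volumes,
        widths_mm=np.asarray(widths, dtype=float),
    )
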