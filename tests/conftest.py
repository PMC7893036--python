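import datetime as dt

import pytest

from thermotrack.config import DayBoundary, SeasonWindow, default_config


@pytest.fixture
def boundary() -> DayBoundary:
    return DayBoundary()


@pytest.fixture
def short_windows() -> tuple[SeasonWindow, SeasonWindow]:
    """Two 30-day seasons: enough days for models, fast to simulate."""
    return (
        SeasonWindow("drought", dt.date(2013, 9, 1), dt.date(2013, 9, 30), 132.0),
        SeasonWindow("non-drought", dt.date(2014, 9, 1), dt.date(2014, 9, 30), 277.0),
    )


@pytest.fixture
def small_config(short_windows):
    """A compact study: 2 gemsbok + 2 wildebeest over the short seasons."""
    return default_config(rng_seed=424242, n_gemsbok=2, n_wildebeest=2, season_windows=short_windows)
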