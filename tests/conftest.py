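import datetime as dt
import itertools

import numpy as np
import pytest

from socialunits import CensusRecord, SocietyParams, simulate_society

D0 = dt.date(2020, 10, 1)


@pytest.fixture
def make_record():
    """Factory for census records with auto-incrementing observation ids."""
    counter = itertools.count()

    def _make(
        ids,
        day: int = 0,
        session: str = "AM",
        cohesion: str = "single",
        complete: bool = True,
        n_unmarked: int = 0,
        date: dt.date | None = None,
    ) -> CensusRecord:
        return CensusRecord(
            date=date or (D0 + dt.timedelta(days=day)),
            session=session,
            observation_id=f"OBS{next(counter):05d}",
            cohesion=cohesion,
            individual_ids=frozenset(ids),
            n_unmarked=n_unmarked,
            complete=complete,
        )

    return _make


@pytest.fixture(scope="session")
def clean_society():
    """Small society observed perfectly, without fission or supergroups."""
    params = SocietyParams(
        n_units=3,
        unit_size_mean=10,
        study_start=dt.date(2020, 9, 1),
        study_end=dt.date(2021, 1, 1),
        fission_rate=0.0,
        marked_fraction=1.0,
        census_detect_prob=1.0,
        individual_miss_prob=0.0,
        census_incomplete_prob=0.0,
        seed=42,
    )
    truth, census, gps = simulate_society(params)
    return params, truth, census, gps


@pytest.fixture
def rng():
    return np.random.default_rng(0)
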