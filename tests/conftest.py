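import datetime as dt

import pytest
from hypothesis import settings

import dielclass as dc

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")

#: the survey site all fixtures use: boreal forest at 42.75 N, 141.45 E, UTC+9
STUDY_SITE = dict(latitude=42.75, longitude=141.45, utc_offset=9.0)


@pytest.fixture(scope="session")
def calendar() -> dc.SolarCalendar:
    return dc.SolarCalendar(**STUDY_SITE)


def make_events(rows):
    """rows: iterable of (camera, species, iso_timestamp)."""
    return [
        dc.DetectionEvent(cam, sp, dt.datetime.fromisoformat(ts))
        for cam, sp, ts in rows
    ]


@pytest.fixture(scope="session")
def spring_survey():
    """One simulated spring survey with the four canonical planted profiles."""
    profiles = [
        dc.SpeciesProfile("diurnal", 2.0, (dc.MixtureComponent(1.0, 13.0, 4.0),)),
        dc.SpeciesProfile("nocturnal", 2.0, (dc.MixtureComponent(1.0, 1.0, 4.0),)),
        dc.SpeciesProfile(
            "crepuscular", 2.0,
            (dc.MixtureComponent(0.5, 0.0, 8.0, "sunrise"),
             dc.MixtureComponent(0.5, 0.0, 8.0, "sunset")),
        ),
        dc.uniform_profile("uniform", 2.0),
    ]
    design = dc.SurveyDesign(n_cameras=8, start=dt.date(2013, 4, 1),
                             end=dt.date(2013, 6, 29), seed=11)
    events, effort, truth = dc.simulate_survey(profiles, design)
    return profiles, design, events, effort, truth
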