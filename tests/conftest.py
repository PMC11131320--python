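import datetime as dt

import pytest

from pncattr import CodeConfig, PncVisit, ScenarioConfig, generate_cohort, run_cohort


@pytest.fixture(scope="session")
def code_config():
    return CodeConfig()


def make_visits(layout, episode_id="E1", start=dt.date(2017, 1, 1)):
    """Visits from a day-ordered provider layout, e.g. "ABBA" or ["A","B"].

    The i-th element names the provider seen on day start+i; each provider's
    specialty defaults to obgyn ("16").
    """
    visits = []
    for i, prov in enumerate(layout):
        visits.append(
            PncVisit(
                episode_id=episode_id,
                sspi=f"{prov}|16",
                specialty_group="obgyn",
                visit_date=start + dt.timedelta(days=i),
                seq_index=i + 1,
            )
        )
    return visits


@pytest.fixture(scope="session")
def small_cohort():
    """A 400-episode labelled cohort spanning all regimes, with its pipeline run."""
    cohort = generate_cohort(ScenarioConfig(n_episodes=400, seed=11))
    result = run_cohort(cohort.claims, cohort.enrollment, cohort.deliveries)
    return cohort, result
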