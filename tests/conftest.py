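"""Shared fixtures: the study-sized design and synthetic dataset.

Expensive objects (design search, population, MCMC fits) are session-scoped
so the whole suite re-uses one instance; all seeds are fixed for exact
reproducibility.
"""

import numpy as np
import pandas as pd
import pytest

import capbws as cb


@pytest.fixture(scope="session")
def study_design():
    """Three questionnaire versions of the 16-item / 6-attribute / 16-task study."""
    return cb.generate_design(
        n_items=16, set_size=6, n_tasks=16, n_versions=3, n_iterations=10, seed=7
    )


@pytest.fixture(scope="session")
def population():
    return cb.default_population_config(seed=5)


@pytest.fixture(scope="session")
def truths(population):
    return cb.simulate_population(population)


@pytest.fixture(scope="session")
def responses(study_design, truths):
    return cb.simulate_responses(study_design, truths, seed=11)


@pytest.fixture(scope="session")
def reduced_posterior(responses):
    """Short-profile HB fit of the default 158-respondent synthetic dataset."""
    return cb.fit_hb(responses, config=cb.McmcConfig.reduced(seed=3))


@pytest.fixture(scope="session")
def responses_with_random_responder(study_design, responses):
    """The default dataset plus one planted uniform-random responder (id 159)."""
    rng = np.random.default_rng(99)
    tasks = study_design.tasks(1)
    rows = []
    for t in range(1, study_design.n_tasks + 1):
        b, w = rng.choice(study_design.set_size, size=2, replace=False)
        rows.append(
            {
                "respondent_id": 159,
                "task": t,
                "best_item": int(tasks[t - 1, b]),
                "worst_item": int(tasks[t - 1, w]),
            }
        )
    extra_resp = pd.DataFrame(
        [{"respondent_id": 159, "cohort": "psychiatric",
          "gender": "female", "version": 1}]
    )
    return cb.ResponseSet(
        respondents=pd.concat(
            [responses.respondents, extra_resp], ignore_index=True
        ),
        responses=pd.concat(
            [responses.responses, pd.DataFrame(rows)], ignore_index=True
        ),
        design=study_design,
    )


@pytest.fixture(scope="session")
def posterior_with_random_responder(responses_with_random_responder):
    return cb.fit_hb(
        responses_with_random_responder, config=cb.McmcConfig.reduced(seed=3)
    )
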