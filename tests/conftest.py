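import numpy as np
import pytest

from psybattery.scales import SCALES, SurveyResponse


def make_response(year=2017, age=14, gender="female", **scale_answers):
    """Build a SurveyResponse from {scale_id: {item: answer_index}} kwargs."""
    answers = {}
    for sid, items in scale_answers.items():
        for item, idx in items.items():
            answers[(sid, item)] = idx
    return SurveyResponse(year=year, age=age, gender=gender, answers=answers)


def complete_answers(scale_id, fill=0, rng=None):
    """All scored items of a scale answered (uniformly random with rng)."""
    d = SCALES[scale_id]
    out = {}
    for item in d.scored_items:
        if rng is None:
            out[item] = min(fill, d.levels[item] - 1)
        else:
            out[item] = int(rng.integers(0, d.levels[item]))
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_cohort():
    """A screened, scored analysis frame of a modest synthetic cohort."""
    from psybattery.battery import prepare_frame
    from psybattery.cohort import CohortConfig, generate_cohort

    cfg = CohortConfig()
    cfg.n_per_year = {2017: 500, 2018: 520, 2019: 480}
    raw = generate_cohort(cfg, seed=7)
    frame, report = prepare_frame(raw)
    return frame
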