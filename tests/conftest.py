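import datetime as dt

import pytest

from ewsmon import (
    Catalogue,
    EWSProfile,
    ItemResponse,
    ObservationStream,
    PromptRecord,
    SymptomItem,
    default_catalogue,
)

UTC = dt.timezone.utc
STUDY_START = dt.date(2020, 1, 1)


@pytest.fixture
def catalogue():
    return default_catalogue()


@pytest.fixture
def flat_catalogue():
    """Minimal branch-free catalogue: three root items, no children."""
    return Catalogue(
        [
            SymptomItem("A", "item A", "psychotic"),
            SymptomItem("B", "item B", "psychotic"),
            SymptomItem("C", "item C", "dysphoric"),
        ]
    )


@pytest.fixture
def flat_profile():
    """Weights {A: 0.5, B: 0.3, C: 0.2} via relevance tiers 3/2/1."""
    return EWSProfile("p1", {"A": 3, "B": 2, "C": 1})


def make_stream(catalogue, rating_maps, start=STUDY_START, spacing_hours=12, first_hour=9):
    """Build a completed-prompt stream from a list of {item: rating} maps.

    An entry of ``None`` becomes a missed prompt.
    """
    prompts = []
    t = dt.datetime.combine(start, dt.time(first_hour), tzinfo=UTC)
    for ratings in rating_maps:
        if ratings is None:
            prompts.append(PromptRecord(prompt_time=t, status="missed"))
        else:
            responses = [ItemResponse(i, float(r), t) for i, r in ratings.items()]
            prompts.append(PromptRecord(prompt_time=t, status="completed", responses=responses))
        t += dt.timedelta(hours=spacing_hours)
    return ObservationStream(
        participant_id="p1", catalogue=catalogue, prompts=prompts, study_start=start
    )


@pytest.fixture
def make_flat_stream(flat_catalogue):
    def _make(rating_maps, **kwargs):
        return make_stream(flat_catalogue, rating_maps, **kwargs)

    return _make
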