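import pytest
from hypothesis import settings

from multiarrange import StimulusSet, VocabularyItem, generate_stimulus_set
from multiarrange.rater_sim import default_dimensions

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def tiny_vocabulary() -> list[VocabularyItem]:
    """Smallest feasible design: 4 noun categories x 2, 2 verb categories x 2,
    2 adverbs -> 16 sentences."""
    vocab = []
    for cat, words in {
        "medicine": ["nurse", "dentist"],
        "manual_labor": ["plumber", "welder"],
        "sports": ["boxer", "swimmer"],
        "music": ["drummer", "pianist"],
    }.items():
        vocab += [VocabularyItem(w, "noun", cat) for w in words]
    vocab += [VocabularyItem(w, "verb", "communication") for w in ["praised", "thanked"]]
    vocab += [VocabularyItem(w, "verb", "physical") for w in ["pushed", "kicked"]]
    vocab += [
        VocabularyItem("Today", "adverb", "same_day"),
        VocabularyItem("Yesterday", "adverb", "previous_day"),
    ]
    return vocab


@pytest.fixture(scope="session")
def paper_stimuli() -> StimulusSet:
    return generate_stimulus_set(seed=1)


@pytest.fixture(scope="session")
def sentence_dims(paper_stimuli):
    return default_dimensions(paper_stimuli)


@pytest.fixture(scope="session")
def tiny_stimuli() -> StimulusSet:
    return generate_stimulus_set(tiny_vocabulary(), seed=3)
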