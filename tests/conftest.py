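import hypothesis
import pytest
from hypothesis import strategies as st

from dacpr_audit.records import (
    CallRecord,
    DacprBarrier,
    RecognizabilityBarrier,
)
from dacpr_audit.simulate import GeneratorParams, generate_cohort, paper_counts_cohort

hypothesis.settings.register_profile(
    "suite", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("suite")


@pytest.fixture(scope="session")
def paper_cohort():
    """The deterministic reference-count preset (1000 calls)."""
    return paper_counts_cohort()


@pytest.fixture(scope="session")
def small_cohort():
    """A seeded 400-call synthetic cohort for plumbing tests."""
    return generate_cohort(GeneratorParams(n=400, seed=11))


@pytest.fixture(scope="session")
def large_cohort():
    """A seeded 20000-call cohort for Monte-Carlo recovery checks."""
    return generate_cohort(GeneratorParams(n=20000, seed=7))


def _maybe(value_strategy):
    return st.one_of(st.none(), value_strategy)


times = st.floats(min_value=0, max_value=3600, allow_nan=False)


@st.composite
def call_records(draw, index: int = 0):
    """A random internally-consistent CallRecord."""
    recognized = draw(st.booleans())
    dacpr_given = draw(st.booleans()) if recognized else False
    return CallRecord(
        call_id=f"H{draw(st.integers(0, 10**9))}-{index}",
        recognized=recognized,
        alive_during_call=draw(st.booleans()),
        audio_available=draw(st.booleans()),
        cpr_in_progress=draw(st.booleans()),
        dacpr_compressions_given=dacpr_given,
        recognizability_barrier=draw(st.sampled_from(list(RecognizabilityBarrier))),
        dacpr_barrier=draw(st.sampled_from(list(DacprBarrier))),
        t_recognition_s=draw(_maybe(times)) if recognized else None,
        t_dispatch_s=draw(_maybe(times)),
        t_cpr_instruction_s=draw(_maybe(times)),
        t_first_compression_s=draw(_maybe(times)),
        t_first_dacpr_compression_s=draw(_maybe(times)) if dacpr_given else None,
        any_compression_during_call=draw(_maybe(st.booleans())),
        survived_30d=draw(_maybe(st.booleans())),
    )


@st.composite
def cohorts(draw, max_size: int = 30):
    n = draw(st.integers(0, max_size))
    records = [draw(call_records(index=i)) for i in range(n)]
    for i, r in enumerate(records):  # ensure unique ids
        r.call_id = f"H{i:04d}"
    return records
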