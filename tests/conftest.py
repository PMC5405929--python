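import pytest

from medadhere import (CarryoverPolicy, CmaPolicy, EpisodePolicy, WindowSpec,
                       fixture_two_patients)

# Parameter sets of the reference worked example: a 730-day follow-up window
# anchored at each patient's first event; the interior 1-year observation
# window starts 182 days in (the "months 6-18" window of the example).
SPEC_2Y = WindowSpec(fuw_duration=730)
SPEC_1Y = WindowSpec(fuw_duration=730, ow_offset=182, ow_duration=365)


@pytest.fixture(scope="session")
def fixture_table():
    return fixture_two_patients()


@pytest.fixture(scope="session")
def p76(fixture_table):
    from medadhere import events_from_frame
    return events_from_frame(fixture_table.for_patient("76"))


@pytest.fixture(scope="session")
def p37(fixture_table):
    from medadhere import events_from_frame
    return events_from_frame(fixture_table.for_patient("37"))


@pytest.fixture
def episode_policy_table2():
    """The carry-over setting of the reference episode scenarios:
    within-window carry-over, same medication only, dosage-aware."""
    def make(gap, change=False):
        return EpisodePolicy(
            permissible_gap=gap, gap_unit="days",
            medication_change_new_episode=change,
            carryover=CarryoverPolicy(True, True, True),
        )
    return make


def all_carryover_policies():
    """Every semantically distinct sweep policy."""
    out = [CarryoverPolicy(carryover_within_ow=False)]
    for same in (False, True):
        for dose in (False, True):
            out.append(CarryoverPolicy(True, same, dose))
    return out
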