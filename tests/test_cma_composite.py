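from datetime import date
from fractions import Fraction

import pytest

from medadhere import (CarryoverPolicy, CmaPolicy, EpisodePolicy, Event,
                       EventTable, SlidingSpec, WindowSpec, cma_per_episode,
                       cma_sliding_window, composite_to_frame)

from conftest import SPEC_2Y

PLAIN = CarryoverPolicy()
EPOL_90 = EpisodePolicy(90, "days", False, PLAIN)

# reference per-episode values (episode 1, episode 2) for patient 76
EXPECTED_EPISODE = {1: (100.3, 33.3), 2: (87.7, 39.5), 3: (100.0, 33.3),
                    4: (87.7, 39.5), 5: (84.8, 33.3), 6: (87.7, 39.5),
                    7: (87.7, 39.5), 8: (87.7, 39.5), 9: (87.7, 39.5)}
# reference sliding-window values (two consecutive 365-day windows)
EXPECTED_SLIDING = {1: (85.2, 30.6), 2: (98.6, 33.7), 3: (85.2, 30.6),
                    4: (98.6, 33.7), 5: (83.2, 30.6), 6: (83.8, 33.7),
                    7: (83.8, 47.7), 8: (83.8, 38.6), 9: (83.8, 47.7)}
TWO_YEARS_IN_TWO = SlidingSpec(start_offset=0, window_duration=365, step=365)


class TestPerEpisodeReference:
    @pytest.mark.parametrize("variant", range(1, 10))
    def test_patient_76_values(self, fixture_table, variant):
        res = [r for r in cma_per_episode(fixture_table, SPEC_2Y, EPOL_90,
                                          CmaPolicy(variant, PLAIN))
               if r.patient_id == "76"]
        assert [r.unit_index for r in res] == [1, 2]
        vals = [r.cma.value for r in res]
        for got, want in zip(vals, EXPECTED_EPISODE[variant]):
            assert got == pytest.approx(want, abs=0.05)

    def test_episode_durations_479_and_152(self, fixture_table):
        res = [r for r in cma_per_episode(fixture_table, SPEC_2Y, EPOL_90,
                                          CmaPolicy(5, PLAIN))
               if r.patient_id == "76"]
        assert [(r.unit_end - r.unit_start).days for r in res] == [479, 152]


class TestSlidingReference:
    @pytest.mark.parametrize("variant", range(1, 10))
    def test_patient_76_values(self, fixture_table, variant):
        res = [r for r in cma_sliding_window(fixture_table, SPEC_2Y,
                                             TWO_YEARS_IN_TWO,
                                             CmaPolicy(variant, PLAIN))
               if r.patient_id == "76"]
        assert [r.unit_index for r in res] == [1, 2]
        for got, want in zip([r.cma.value for r in res],
                             EXPECTED_SLIDING[variant]):
            assert got == pytest.approx(want, abs=0.05)

    def test_consecutive_windows_tile_the_ow(self, fixture_table):
        res = [r for r in cma_sliding_window(fixture_table, SPEC_2Y,
                                             TWO_YEARS_IN_TWO, CmaPolicy(7, PLAIN))
               if r.patient_id == "76"]
        assert res[0].unit_start == date(2035, 12, 13)
        assert res[0].unit_end == res[1].unit_start == date(2036, 12, 12)
        assert res[1].unit_end == date(2037, 12, 12)
        assert not any(r.partial for r in res)


def _one_patient_table(events):
    import pandas as pd
    from medadhere.event_store import COLUMNS
    rows = [("p", pd.Timestamp(date.fromordinal(e.t)), float(e.dose or 1),
             e.category, e.duration) for e in events]
    return EventTable(pd.DataFrame(rows, columns=COLUMNS))


class TestSlidingSemantics:
    def test_window_inside_long_gap_detects_interruption(self):
        """Windows lying wholly inside a supply gap longer than themselves:
        CMA7 drops to exactly 0% (persistence detection); CMA9, which by
        construction spreads each event's supply evenly to the next event,
        retains the diluted interval ratio instead."""
        d0 = date(2030, 1, 1).toordinal()
        tab = _one_patient_table([Event(d0, 30, Fraction(1), "m"),
                                  Event(d0 + 330, 30, Fraction(1), "m")])
        spec = WindowSpec(fuw_duration=365)
        ss = SlidingSpec(0, 73, step=73)  # five 73-day windows
        res7 = cma_sliding_window(tab, spec, ss, CmaPolicy(7, PLAIN))
        middle7 = [r.cma.value for r in res7 if r.unit_index in (2, 3, 4)]
        assert middle7 == [0.0, 0.0, 0.0]
        res9 = cma_sliding_window(tab, spec, ss, CmaPolicy(9, PLAIN))
        middle9 = [r.cma.value for r in res9 if r.unit_index in (2, 3, 4)]
        assert all(v == pytest.approx(100 * 30 / 330) for v in middle9)

    def test_window_before_first_event_scores_zero(self):
        d0 = date(2030, 1, 1)
        spec = WindowSpec(fuw_anchor=d0, fuw_duration=365)
        tab = _one_patient_table([Event(d0.toordinal() + 300, 30, Fraction(1), "m")])
        ss = SlidingSpec(0, 100, step=100)
        for v in (7, 9):
            res = cma_sliding_window(tab, spec, ss, CmaPolicy(v, PLAIN))
            assert res[0].cma.value == 0.0, v
            assert res[1].cma.value == 0.0, v

    def test_eventless_window_missing_for_event_anchored_variants(self):
        d0 = date(2030, 1, 1).toordinal()
        tab = _one_patient_table([Event(d0, 30, Fraction(1), "m")])
        spec = WindowSpec(fuw_duration=365)
        res = cma_sliding_window(tab, spec, SlidingSpec(0, 100, step=100),
                                 CmaPolicy(2, PLAIN))
        assert res[0].cma.value is not None
        assert res[1].cma.value is None
        assert "no medication event" in res[1].cma.reason

    def test_window_fully_covered_by_one_event_gives_100(self):
        d0 = date(2030, 1, 1).toordinal()
        tab = _one_patient_table([Event(d0, 400, Fraction(1), "m")])
        spec = WindowSpec(fuw_duration=365)
        res = cma_sliding_window(tab, spec, SlidingSpec(100, 100, step=400),
                                 CmaPolicy(7, PLAIN))
        assert res[0].cma.value == pytest.approx(100.0)

    def test_n_windows_spacing(self):
        d0 = date(2030, 1, 1).toordinal()
        tab = _one_patient_table([Event(d0, 30, Fraction(1), "m")])
        spec = WindowSpec(fuw_duration=400)
        res = cma_sliding_window(tab, spec,
                                 SlidingSpec(0, 100, n_windows=4),
                                 CmaPolicy(7, PLAIN))
        starts = [(r.unit_start - date(2030, 1, 1)).days for r in res]
        assert starts == [0, 100, 200, 300]  # step = (400-100)/3

    def test_trailing_partial_window_emitted_and_flagged(self):
        d0 = date(2030, 1, 1).toordinal()
        tab = _one_patient_table([Event(d0, 30, Fraction(1), "m")])
        spec = WindowSpec(fuw_duration=250)
        res = cma_sliding_window(tab, spec, SlidingSpec(0, 100, step=100),
                                 CmaPolicy(7, PLAIN))
        assert [(r.unit_end - r.unit_start).days for r in res] == [100, 100, 50]
        assert [r.partial for r in res] == [False, False, True]

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SlidingSpec(0, 100)  # neither step nor n_windows
        with pytest.raises(ValueError):
            SlidingSpec(0, 100, step=100, n_windows=3)
        d0 = date(2030, 1, 1)
        with pytest.raises(ValueError, match="step"):
            SlidingSpec(0, 100, step=0).windows(d0, date(2031, 1, 1))


class TestPerEpisodeSemantics:
    def test_single_event_episode_cma2_is_100(self):
        d0 = date(2030, 1, 1).toordinal()
        tab = _one_patient_table([Event(d0, 30, Fraction(1), "m"),
                                  Event(d0 + 200, 40, Fraction(1), "m")])
        spec = WindowSpec(fuw_duration=300)
        res = cma_per_episode(tab, spec, EpisodePolicy(50, "days", False, PLAIN),
                              CmaPolicy(2, PLAIN))
        # episode 1 = [0, 30): one event, supply fills it exactly
        assert res[0].cma.value == pytest.approx(100.0)

    def test_fully_covered_episode_scores_100_for_capped_variants(self):
        d0 = date(2030, 1, 1).toordinal()
        tab = _one_patient_table([Event(d0, 100, Fraction(1), "m"),
                                  Event(d0 + 90, 100, Fraction(1), "m")])
        spec = WindowSpec(fuw_duration=190)
        for v in (4, 6, 7, 9):
            res = cma_per_episode(tab, spec,
                                  EpisodePolicy(0, "days", False, PLAIN),
                                  CmaPolicy(v, PLAIN))
            assert len(res) == 1
            assert res[0].cma.value == pytest.approx(100.0), v

    def test_long_format_output(self, fixture_table):
        frame = composite_to_frame(
            cma_per_episode(fixture_table, SPEC_2Y, EPOL_90, CmaPolicy(9, PLAIN)))
        assert {"patient_id", "unit_index", "unit_start", "unit_end",
                "variant", "value_percent"} <= set(frame.columns)
        p76 = frame[frame["patient_id"] == "76"]
        assert list(p76["unit_days"]) == [479, 152]
        assert list(p76["value_percent"]) == [87.7, 39.5]
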