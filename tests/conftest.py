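import numpy as np
import pytest

from hivsurv.metrics import SurvivalSample


def harrell_oracle(times, events, scores):
    """Exhaustive O(n²) pair enumeration of Harrell's concordance.

    Usable: shorter time has the event, or tied times with exactly one
    event (the event subject is the case).  Tied event times unusable;
    tied scores count 1/2.
    """
    n = len(times)
    num = den = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            if times[i] == times[j]:
                if events[i] == events[j]:
                    continue
                case, other = (i, j) if events[i] else (j, i)
            elif times[i] < times[j]:
                if not events[i]:
                    continue
                case, other = i, j
            else:
                if not events[j]:
                    continue
                case, other = j, i
            den += 1
            if scores[case] > scores[other]:
                num += 1
            elif scores[case] == scores[other]:
                num += 0.5
    return num, den


def truncated_concordance_oracle(times, events, scores, horizon):
    """Censoring-free truncated concordance: cases = events by the horizon,
    comparators = subjects observed beyond it."""
    cases = np.where(events & (times <= horizon))[0]
    comps = np.where(times > horizon)[0]
    num = den = 0.0
    for i in cases:
        for j in comps:
            den += 1
            if scores[i] > scores[j]:
                num += 1
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den


@pytest.fixture
def mixed_sample():
    """Small censored sample with hand-checkable structure."""
    times = np.array([1.0, 2.0, 2.0, 3.0, 4.0, 5.0, 5.0, 6.0])
    events = np.array([1, 0, 1, 1, 0, 1, 0, 0], dtype=bool)
    scores = np.array([5.0, 3.0, 4.0, 4.0, 2.0, 1.5, 1.0, 0.5])
    return SurvivalSample(times, events, scores)
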