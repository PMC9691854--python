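import numpy as np
import pytest

from cagephys import task_engine as te


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_visits(corners, nosepokes=None, times=None, animal_id="r1"):
    """Build a time-ordered visit stream from corner numbers."""
    n = len(corners)
    if nosepokes is None:
        nosepokes = [1] * n
    if times is None:
        times = [float(i) for i in range(n)]
    return [
        te.VisitEvent(animal_id=animal_id, corner=c, time_min=t, nosepokes=p)
        for c, t, p in zip(corners, times, nosepokes)
    ]


def brute_force_sequencing_labels(visits, assigned, geometry=te.DEFAULT_GEOMETRY):
    """Independent replay oracle: recompute the correct corner from the full
    visit history at every visit, without the state machine."""
    labels = []
    diag = {assigned, geometry.opposite(assigned)}
    for i, v in enumerate(visits):
        correct = assigned
        for w in visits[:i]:
            if w.corner == correct and w.nosepokes >= 1:
                correct = geometry.opposite(correct)
        if v.corner == correct:
            labels.append(te.VisitLabel.CORRECT)
        elif v.corner in diag:
            labels.append(te.VisitLabel.PREVIOUSLY_CORRECT)
        else:
            labels.append(te.VisitLabel.LATERAL)
    return labels
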