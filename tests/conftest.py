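import numpy as np
import pandas as pd
import pytest


def trials_frame(choices, outcomes, valid=None, session=None,
                 block_type="right_better", subject_id="s0"):
    """Build a minimal event table from compact per-trial lists.

    ``choices``: iterable of 0/1 (left/right) or "left"/"right";
    ``outcomes``: iterable of 1/0 (reward/punishment) or names.
    """
    n = len(choices)
    choices = ["left" if c in (0, "left") else "right" for c in choices]
    outcomes = ["reward" if o in (1, "reward") else "punishment" for o in outcomes]
    valid = [True] * n if valid is None else list(valid)
    session = [0] * n if session is None else list(session)
    return pd.DataFrame({
        "subject_id": subject_id,
        "session": session,
        "trial": range(n),
        "block_id": 0,
        "block_type": block_type,
        "choice": [c if v else None for c, v in zip(choices, valid)],
        "outcome": [o if v else None for o, v in zip(outcomes, valid)],
        "valid": valid,
        "correct": [c == "right" for c in choices],
        "reversal_cause": None,
    })


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
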