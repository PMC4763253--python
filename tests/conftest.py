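import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from streamscore import glmm, listener, timeline

settings.register_profile("stable", derandomize=True, deadline=None)
settings.load_profile("stable")


@pytest.fixture(scope="session")
def objective_design():
    return timeline.make_session("exp1_objective", 11)


@pytest.fixture(scope="session")
def exp2_design():
    return timeline.make_session("exp2", 13)


@pytest.fixture(scope="session")
def small_cohort():
    return listener.default_cohort(4, seed=3)


@pytest.fixture(scope="session")
def exp2_session(exp2_design, small_cohort):
    return listener.simulate_session(exp2_design, small_cohort, seed=5)


def simulate_outcome_table(rng, n_subj=12, n_per=144, sigma=0.8,
                           coefs=(0.4, -1.0, -0.7, 1.2)):
    """Per-deviant hit/miss rows straight from the logistic model, for
    GLMM recovery tests that do not need the full listener."""
    b0, b_df, b_pos, b_per = coefs
    pos_levels = np.array(["early", "middle", "late"])
    rows = []
    for s in range(n_subj):
        u = rng.normal(0, sigma)
        df = rng.choice([4, 8], size=n_per)
        pos = rng.choice(pos_levels, size=n_per)
        per = rng.choice(["one_stream", "two_streams"], size=n_per)
        pos_num = np.array([glmm.POSITION_CODE[p] for p in pos])
        eta = (b0 + b_df * (df == 8) + b_pos * pos_num
               + b_per * (per == "one_stream") + u)
        hit = (rng.random(n_per) < 1.0 / (1.0 + np.exp(-eta))).astype(int)
        rows.append(pd.DataFrame({
            "subject": s, "delta_f": df, "position": pos,
            "percept": per, "hit": hit,
        }))
    return pd.concat(rows, ignore_index=True)
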