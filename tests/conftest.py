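import numpy as np
import pytest

from mdsinfer import LatentWorld, StudyDesign, simulate_study


@pytest.fixture(scope="session")
def small_design():
    """A compact 6-object design: fast, but every pipeline stage is exercised."""
    return StudyDesign(
        base_same_trials=60,
        base_different_trials=120,
        extra_same_per_object=10,
        n_participants=8,
    )


@pytest.fixture(scope="session")
def small_study(small_design):
    world = LatentWorld(seed=42)
    return simulate_study(small_design, world)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def trial_csv(tmp_path):
    """Write a trial CSV from rows of (participant, s1, s2, response, rt)."""

    def _write(rows, header="participant,stim_first,stim_second,response,rt_ms"):
        path = tmp_path / "trials.csv"
        path.write_text(
            "\n".join([header] + [",".join(map(str, r)) for r in rows]) + "\n",
            encoding="utf-8",
        )
        return path

    return _write
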