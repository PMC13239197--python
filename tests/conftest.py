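import hypothesis
import pandas as pd
import pytest

from offload_adherence import ScenarioConfig, Thresholds

hypothesis.settings.register_profile(
    "ci", derandomize=True, max_examples=50, deadline=None
)
hypothesis.settings.load_profile("ci")


@pytest.fixture
def thresholds():
    return Thresholds(th_min=0.2, th_max=1.0)


@pytest.fixture
def small_config():
    """A quick, clean scenario: few subjects, no doffed-device artifacts."""
    return ScenarioConfig(
        n_subjects=5, seed=11, n_high_noise_subjects=0, p_spike=0.0
    )


def make_classified_frame(rows, thresholds):
    """Build an aligned frame from (steps, standing_s, v_avg[, extras]) tuples
    and classify it — shared helper for metric tests."""
    from offload_adherence import classify_epochs

    base = pd.DataFrame(
        {
            "epoch_start": pd.date_range("2024-01-01", periods=len(rows), freq="15s"),
            "steps": [r[0] for r in rows],
            "standing_time_s": [r[1] for r in rows],
            "v_avg": [r[2] for r in rows],
        }
    )
    for key in ("vane_steps", "vane_walking_time_s", "vane_upright_time_s"):
        if rows and len(rows[0]) > 3 and key in rows[0][3]:
            base[key] = [r[3].get(key, 0.0) for r in rows]
    return classify_epochs(base, thresholds)
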