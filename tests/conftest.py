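import numpy as np
import pandas as pd
import pytest

from actisym.ingest import EpochFrame
from actisym.nonwear import WearMask


def make_epochframe(
    t_smooth: np.ndarray,
    rocam: np.ndarray | float = 0.1,
    enmo: np.ndarray | float = 0.05,
    start: str = "2024-03-04 00:00",
) -> EpochFrame:
    """Build a minute-grid EpochFrame directly from arrays (no raw signal)."""
    n = len(t_smooth)
    rocam = np.full(n, rocam, float) if np.isscalar(rocam) else np.asarray(rocam, float)
    enmo = np.full(n, enmo, float) if np.isscalar(enmo) else np.asarray(enmo, float)
    idx = pd.date_range(start, periods=n, freq="1min")
    minute = pd.DataFrame(
        {
            "enmo": enmo,
            "rocam": rocam,
            "t_smooth": np.asarray(t_smooth, float),
            "light_mean": np.zeros(n),
            "wear": np.ones(n, bool),
        },
        index=idx,
    )
    five = pd.DataFrame(
        {"z_angle": np.zeros(n * 12)},
        index=pd.date_range(start, periods=n * 12, freq="5s"),
    )
    return EpochFrame(start_time=idx[0], minute=minute, five_sec=five, sample_rate=1.0)


def make_wearmask(n_minutes: int, nonworn: list[tuple[int, int]] = (),
                  start: str = "2024-03-04 00:00") -> WearMask:
    worn = np.ones(n_minutes, bool)
    for a, b in nonworn:
        worn[a:b] = False
    return WearMask(
        index=pd.date_range(start, periods=n_minutes, freq="1min"),
        worn=worn,
        provenance=np.where(worn, "", "pass1"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
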