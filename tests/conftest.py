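import numpy as np
import pandas as pd
import pytest

from actirhythm.io import DayMatrix, EpochSeries


@pytest.fixture
def square_wave_series() -> EpochSeries:
    """Six aligned days of a noiseless square wave: active 07:00-21:00 at
    600 counts/epoch, zero otherwise, 30-s epochs starting at midnight."""
    ppd = 2880
    clock_h = (np.arange(ppd) * 30) / 3600.0
    day = np.where((clock_h >= 7) & (clock_h < 21), 600.0, 0.0)
    return EpochSeries(
        participant_id="square",
        start=pd.Timestamp("2021-03-01 00:00:00"),
        epoch_length=30,
        activity=np.tile(day, 6),
    )


@pytest.fixture
def square_wave_daymatrix(square_wave_series) -> DayMatrix:
    from actirhythm.io import trim_to_full_days

    return trim_to_full_days(square_wave_series, bins_per_day=96)
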