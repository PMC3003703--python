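import math

import numpy as np
import pandas as pd
import pytest

from aquaskinner.arena import ArenaGeometry
from aquaskinner.controller import LOG_COLUMNS
from aquaskinner.tracking import TrackingParams


@pytest.fixture(scope="session")
def geometry() -> ArenaGeometry:
    return ArenaGeometry()


@pytest.fixture(scope="session")
def tracking_params() -> TrackingParams:
    return TrackingParams()


def make_record(
    positions,
    tick_rate_hz: float = 10.0,
    channel: int = 0,
    red=(2, 2, 2, 2),
    blue=(0, 0, 0, 0),
    shock_ticks=(),
    qc_flags=None,
    g: ArenaGeometry = ArenaGeometry(),
) -> pd.DataFrame:
    """Construct a schema-complete trial record from a position list."""
    from aquaskinner.arena import quadrant_of

    rows = []
    shock_ticks = set(shock_ticks)
    for i, (x, y) in enumerate(positions):
        flag = qc_flags[i] if qc_flags is not None else "accepted"
        quad = quadrant_of((x, y), g).name if flag == "accepted" else ""
        rows.append(
            [
                round(i / tick_rate_hz, 3),
                channel,
                x,
                y,
                0.0,
                150,
                quad,
                *red,
                *blue,
                int(i in shock_ticks),
                1.2 if i in shock_ticks else 0.0,
                flag,
            ]
        )
    return pd.DataFrame(rows, columns=LOG_COLUMNS)
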