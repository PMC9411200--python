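import numpy as np
import pandas as pd
import pytest

from chronotel import (
    LightSchedule,
    LightSegment,
    TelemetrySeries,
    default_scenario,
    simulate_subject,
    make_preset,
)


@pytest.fixture(scope="session")
def ld_schedule() -> LightSchedule:
    """12 days of 12L:12D, lights on 06:00 / off 18:00, starting at lights-on."""
    return LightSchedule(
        segments=[LightSegment("LD", days=12, lights_on=6.0, lights_off=18.0)],
        start_clock=6.0,
    )


@pytest.fixture(scope="session")
def dd_schedule() -> LightSchedule:
    """11 days of DD, released from an LD cycle whose last lights-off was
    12 h before the record starts."""
    return LightSchedule(
        segments=[LightSegment("DD", days=11)],
        start_clock=6.0,
        reference_lights_off_h=-12.0,
    )


def make_square_series(
    n_days: int = 4,
    on_h: float = 12.0,
    off_h: float = 24.0,
    high: float = 20.0,
    low: float = 0.0,
    bin_width: float = 6.0,
    tb_high: float = 37.5,
    tb_low: float = 36.5,
) -> TelemetrySeries:
    """Noiseless square-wave telemetry: active (high counts, high T_b) between
    ``on_h`` and ``off_h`` within each 24-h day."""
    per_day = int(round(24 * 60 / bin_width))
    t = np.arange(n_days * per_day) * bin_width / 60.0
    tod = np.mod(t, 24.0)
    active = (tod >= on_h) & (tod < off_h)
    lma = np.where(active, high, low)
    tb = np.where(active, tb_high, tb_low)
    return TelemetrySeries(
        start_time=pd.Timestamp("2020-01-01 06:00:00"),
        bin_width=bin_width,
        lma=lma,
        tb=tb,
        missing_mask=np.zeros(len(t), dtype=bool),
        subject_id="square",
    )


@pytest.fixture(scope="session")
def square_series() -> TelemetrySeries:
    return make_square_series()


@pytest.fixture(scope="session")
def spf_ld_subject(ld_schedule):
    """One simulated SPF subject under 12 LD days (seeded)."""
    cfg = make_preset("SPF-LD")
    cfg.seed = 11
    return simulate_subject(cfg, ld_schedule, subject_id="spf-0",
                            group_label="SPF-LD")


@pytest.fixture(scope="session")
def gf_dd_subject(dd_schedule):
    """One simulated GF subject under 11 DD days (seeded)."""
    cfg = make_preset("GF-DD")
    cfg.seed = 12
    return simulate_subject(cfg, dd_schedule, subject_id="gf-0",
                            group_label="GF-DD")
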