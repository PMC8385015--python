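"""Bundled reference data.

Ships the published 24-h mouse free-plasma concentration series (hourly, nM)
for the ATM inhibitor AZD0156 (10 mg/kg oral) and SN38 (the active metabolite
of irinotecan, 50 mg/kg IP), the matched stepwise reservoir table used to
mimic those profiles on-chip, and the reported spheroid/xenograft response
summary used in worked examples.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
import yaml

from .pk import ConcentrationSeries
from .schedule import ExposureSchedule, ReservoirStep, DEFAULT_FLOW_UL_MIN

__all__ = [
    "ANALYTES",
    "load_invivo_series",
    "load_reservoir_table",
    "published_reservoir_schedule",
    "reported_response",
]

ANALYTES = ("AZD0156", "SN38")


def _data_path(name: str):
    return resources.files("pkchip.data").joinpath(name)


def load_invivo_series(analyte: str) -> ConcentrationSeries:
    """The 24-h in vivo free plasma concentration series for one analyte.

    Samples run hourly from 1 h to 24 h post dose; the pre-dose concentration
    is zero but is not part of the table (use
    :meth:`~pkchip.pk.ConcentrationSeries.with_leading_zero` to anchor it).
    """
    if analyte not in ANALYTES:
        raise ValueError(f"unknown analyte {analyte!r}; available: {ANALYTES}")
    with resources.as_file(_data_path("invivo_free_conc_24h.csv")) as path:
        df = pd.read_csv(path)
    sub = df[df["analyte"] == analyte]
    return ConcentrationSeries(
        analyte=analyte,
        times=sub["time_h"].to_numpy(float),
        concentrations=sub["conc_nM"].to_numpy(float),
        provenance="observed",
    )


def load_reservoir_table() -> pd.DataFrame:
    """The published stepwise reservoir table (long format).

    Columns ``reservoir,start_h,duration_h,analyte,conc_nM``.  Reservoir 1 of
    the physical manifold holds drug-free medium for priming/washes; the
    seven drug steps occupy reservoirs 2–8 and their durations sum to the
    24-h cycle.
    """
    with resources.as_file(_data_path("reservoir_schedule_24h.csv")) as path:
        return pd.read_csv(path)


def published_reservoir_schedule(
    flow_rate: float = DEFAULT_FLOW_UL_MIN,
) -> ExposureSchedule:
    """The published 24-h stepwise schedule as an :class:`ExposureSchedule`.

    Both analytes share the step timing, so the table collapses to one
    schedule whose steps carry an AZD0156 and an SN38 concentration each.
    """
    df = load_reservoir_table()
    steps = []
    for (res, start, dur), grp in df.groupby(
        ["reservoir", "start_h", "duration_h"], sort=True
    ):
        concs = dict(zip(grp["analyte"], grp["conc_nM"].astype(float)))
        steps.append(
            ReservoirStep(
                index=int(res) - 1,  # renumber drug steps 1..7
                concentrations=concs,
                start_time=float(start),
                duration=float(dur),
            )
        )
    steps.sort(key=lambda s: s.start_time)
    return ExposureSchedule(steps=steps, cycle_length=24.0, flow_rate=flow_rate)


def reported_response() -> dict:
    """Published response summary used as worked-example inputs.

    Keys: ``relative_volume_day7`` (percent of untreated control, perfused
    chip), ``percent_gi`` (in vitro day 7 and in vivo day 15 %GI per
    schedule) and ``static_reference`` (flat-exposure comparison settings).
    """
    return yaml.safe_load(_data_path("reported_response.yaml").read_text())
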