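"""Tabular I/O for events, summaries and puncta (CSV/JSON)."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Sequence

import pandas as pd

from .density import PunctaAnnotation
from .events import SynapticEvent
from .quantal import QuantalSummary

__all__ = [
    "events_to_frame",
    "write_events_csv",
    "read_events_csv",
    "write_summary_csv",
    "write_puncta_csv",
    "read_puncta_csv",
]


def events_to_frame(events: Sequence[SynapticEvent]) -> pd.DataFrame:
    """One row per event: onset_s, peak_s, amplitude_mv, kind, is_failure."""
    return pd.DataFrame(
        [
            {
                "onset_s": ev.onset_s,
                "peak_s": ev.peak_s,
                "amplitude_mv": ev.amplitude_mv,
                "kind": ev.kind,
                "is_failure": ev.is_failure,
            }
            for ev in events
        ]
    )


def write_events_csv(events: Sequence[SynapticEvent], path: str | Path) -> None:
    events_to_frame(events).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[SynapticEvent]:
    df = pd.read_csv(path)
    return [
        SynapticEvent(
            onset_s=row.onset_s,
            peak_s=row.peak_s,
            amplitude_mv=row.amplitude_mv,
            kind=row.kind,
            is_failure=bool(row.is_failure),
        )
        for row in df.itertuples()
    ]


def write_summary_csv(summaries, path: str | Path) -> None:
    """Per-synapse quantal summaries, one row per NMJ."""
    rows = []
    for s in summaries:
        d = dataclasses.asdict(s) if dataclasses.is_dataclass(s) else dict(s)
        rows.append(d)
    pd.DataFrame(rows).to_csv(path, index=False)


def write_puncta_csv(ann: PunctaAnnotation, path: str | Path) -> None:
    df = pd.DataFrame(ann.coordinates_um, columns=["x_um", "y_um"])
    df.insert(0, "marker", ann.marker)
    df["roi_area_um2"] = ann.roi_area_um2
    df.to_csv(path, index=False)


def read_puncta_csv(path: str | Path) -> PunctaAnnotation:
    df = pd.read_csv(path)
    if df.empty:
        raise ValueError("empty puncta table")
    return PunctaAnnotation(
        marker=str(df["marker"].iloc[0]),
        coordinates_um=df[["x_um", "y_um"]].to_numpy(dtype=float),
        roi_area_um2=float(df["roi_area_um2"].iloc[0]),
    )
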