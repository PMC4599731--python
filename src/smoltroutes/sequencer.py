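"""Collapse raw detections into detection sequences.

A detection sequence is a maximal run of one tag's detections at one array
in which every consecutive pair is (1) less than ``max_gap_hours`` apart in
time and (2) at most ``max_step_km`` apart along the curtain.  A gap of
exactly one hour breaks a sequence (strict "less than"); a step of exactly
1.6 km does not (inclusive).  Because the step rule is measured in chainage
km, the two receivers flanking the island gap (8.0 km apart) always break a
sequence even though they are adjacent in index; ``step_mode="index"``
restores the index-difference (<= 2 receivers) alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .geometry import ReceiverArrayGeometry
from .io import Detection

__all__ = ["DetectionSequence", "build_sequences", "within_sequence_drift", "sequence_frame"]


@dataclass(frozen=True)
class DetectionSequence:
    """A maximal run of detections of one tag at one array."""

    tag_id: str
    array_name: str
    ordinal: int
    first_time: pd.Timestamp
    last_time: pd.Timestamp
    first_receiver: int
    last_receiver: int
    n_detections: int


def _order_key(d: Detection):
    # identical timestamps tie-broken by receiver index ascending
    return (d.timestamp, d.receiver_index)


def build_sequences(
    detections: list[Detection],
    geom: ReceiverArrayGeometry,
    max_gap_hours: float = 1.0,
    max_step_km: float = 1.6,
    step_mode: str = "km",
    max_step_receivers: int = 2,
) -> list[DetectionSequence]:
    """Greedy left-to-right segmentation of one tag's detections at one array.

    Input must be time-sorted and homogeneous in tag and array; every
    detection ends up in exactly one sequence, ordinals assigned by start
    time.
    """
    if step_mode not in ("km", "index"):
        raise ValueError(f"step_mode must be 'km' or 'index', got {step_mode!r}")
    if not detections:
        return []
    tags = {d.tag_id for d in detections}
    arrays = {d.array_name for d in detections}
    if len(tags) > 1 or len(arrays) > 1:
        raise ValueError(f"mixed tags {tags} or arrays {arrays} passed to build_sequences")
    for a, b in zip(detections, detections[1:]):
        if _order_key(b) < _order_key(a):
            raise ValueError("detections must be sorted by (timestamp, receiver)")

    runs: list[list[Detection]] = [[detections[0]]]
    for prev, cur in zip(detections, detections[1:]):
        gap_h = (cur.timestamp - prev.timestamp).total_seconds() / 3600.0
        if step_mode == "km":
            step_ok = (
                abs(geom.receiver_chainage(cur.receiver_index) - geom.receiver_chainage(prev.receiver_index))
                <= max_step_km
            )
        else:
            step_ok = abs(cur.receiver_index - prev.receiver_index) <= max_step_receivers
        if gap_h < max_gap_hours and step_ok:
            runs[-1].append(cur)
        else:
            runs.append([cur])

    out = []
    for ordinal, run in enumerate(runs, start=1):
        out.append(
            DetectionSequence(
                tag_id=run[0].tag_id,
                array_name=run[0].array_name,
                ordinal=ordinal,
                first_time=run[0].timestamp,
                last_time=run[-1].timestamp,
                first_receiver=run[0].receiver_index,
                last_receiver=run[-1].receiver_index,
                n_detections=len(run),
            )
        )
    return out


def within_sequence_drift(seq: DetectionSequence, geom: ReceiverArrayGeometry) -> float:
    """Signed east-west drift (km, east positive) from a sequence's first to last receiver."""
    return geom.delta_x(seq.first_receiver, seq.last_receiver)


def sequence_frame(
    detections: list[Detection],
    geometries: dict[str, ReceiverArrayGeometry],
    **kwargs,
) -> pd.DataFrame:
    """Segment a mixed detection list into sequences, grouped by (tag, array).

    Arrays without an entry in ``geometries`` get a uniform-spacing stand-in
    (their sequences are only used for presence, not displacement).
    """
    rows = []
    groups: dict[tuple[str, str], list[Detection]] = {}
    for d in sorted(detections, key=lambda d: (d.tag_id, d.array_name, d.timestamp, d.receiver_index)):
        groups.setdefault((d.tag_id, d.array_name), []).append(d)
    for (tag, array), dets in groups.items():
        geom = geometries.get(array)
        if geom is None:
            n = max(d.receiver_index for d in dets)
            geom = ReceiverArrayGeometry(
                array_name=array, n_receivers=max(n, 2), gap_after_index=1, gap_km=0.8
            )
        for seq in build_sequences(dets, geom, **kwargs):
            rows.append(
                {
                    "tag_id": seq.tag_id,
                    "array": seq.array_name,
                    "ordinal": seq.ordinal,
                    "first_time": seq.first_time,
                    "first_receiver": seq.first_receiver,
                    "last_time": seq.last_time,
                    "last_receiver": seq.last_receiver,
                    "n_detections": seq.n_detections,
                }
            )
    cols = [
        "tag_id",
        "array",
        "ordinal",
        "first_time",
        "first_receiver",
        "last_time",
        "last_receiver",
        "n_detections",
    ]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["tag_id", "array", "ordinal"]).reset_index(drop=True)
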