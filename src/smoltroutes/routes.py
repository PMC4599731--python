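"""Migration-route classification and per-smolt movement covariates.

A smolt's route at the upstream curtain (NSOG) is read off its first two
detection sequences there:

* ``COUNTERCLOCKWISE`` -- the second sequence begins *west* of where the
  first ended (a westward loop);
* ``CLOCKWISE`` -- the second sequence begins east of where the first ended;
* ``LINEAR`` -- the second sequence begins at the same receiver, or the smolt
  has a single sequence and is next seen at the downstream curtain (QCS);
* ``UNCLASSIFIED`` -- a single sequence and no downstream detection: the
  three behavioural classes cannot cover such fish, so they are excluded
  from route proportions;
* ``JUAN_DE_FUCA`` -- detected on the westward-exit curtain; tallied
  separately and excluded from the NSOG analyses.

Apparent survival is the bare detection indicator at the downstream curtain:
any QCS detection marks a survivor, absence is treated as mortality (death
confounded with non-detection).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .geometry import ReceiverArrayGeometry

__all__ = [
    "LINEAR",
    "COUNTERCLOCKWISE",
    "CLOCKWISE",
    "UNCLASSIFIED",
    "JUAN_DE_FUCA",
    "classify_route",
    "lateral_metrics",
    "assign_survival",
    "build_route_records",
    "route_tallies",
]

LINEAR = "LINEAR"
COUNTERCLOCKWISE = "COUNTERCLOCKWISE"
CLOCKWISE = "CLOCKWISE"
UNCLASSIFIED = "UNCLASSIFIED"
JUAN_DE_FUCA = "JUAN_DE_FUCA"

ROUTE_CLASSES = (LINEAR, COUNTERCLOCKWISE, CLOCKWISE)


def classify_route(nsog_sequences: pd.DataFrame, has_qcs: bool) -> str:
    """Route class from a tag's NSOG sequences (ordinal-sorted) and QCS presence.

    With two or more sequences the comparison is between the first sequence's
    last receiver and the second sequence's first receiver; receiver index
    increases westward.
    """
    n = len(nsog_sequences)
    if n == 0:
        raise ValueError("classify_route requires at least one NSOG sequence")
    seqs = nsog_sequences.sort_values("ordinal")
    if n == 1:
        return LINEAR if has_qcs else UNCLASSIFIED
    end1 = int(seqs.iloc[0]["last_receiver"])
    start2 = int(seqs.iloc[1]["first_receiver"])
    if start2 > end1:
        return COUNTERCLOCKWISE
    if start2 < end1:
        return CLOCKWISE
    return LINEAR


def lateral_metrics(
    nsog_sequences: pd.DataFrame, geom: ReceiverArrayGeometry
) -> tuple[float, float, float]:
    """(dx12_km, dx23_km, duration12_h) between consecutive NSOG sequences.

    dx12 is the signed east-west displacement (east positive) from the end of
    the first sequence to the start of the second; dx23 analogously for the
    second and third.  Missing sequences yield NaN.
    """
    seqs = nsog_sequences.sort_values("ordinal")
    dx12 = dx23 = duration12 = np.nan
    if len(seqs) >= 2:
        dx12 = geom.delta_x(int(seqs.iloc[0]["last_receiver"]), int(seqs.iloc[1]["first_receiver"]))
        duration12 = (
            seqs.iloc[1]["first_time"] - seqs.iloc[0]["last_time"]
        ).total_seconds() / 3600.0
    if len(seqs) >= 3:
        dx23 = geom.delta_x(int(seqs.iloc[1]["last_receiver"]), int(seqs.iloc[2]["first_receiver"]))
    return dx12, dx23, duration12


def assign_survival(
    first_nsog_time: pd.Timestamp,
    qcs_times: pd.Series | list,
    release_date: pd.Timestamp,
) -> tuple[bool, float, float]:
    """(survived_qcs, nsog_to_qcs_days, entry_to_nsog_days) for one tag."""
    qcs_times = list(qcs_times)
    survived = len(qcs_times) > 0
    nsog_to_qcs = np.nan
    if survived:
        first_qcs = min(qcs_times)
        if first_qcs < first_nsog_time:
            warnings.warn(
                "QCS detection precedes first NSOG detection; survivor status retained",
                stacklevel=2,
            )
        nsog_to_qcs = (first_qcs - first_nsog_time).total_seconds() / 86400.0
    entry_to_nsog = (first_nsog_time - release_date).total_seconds() / 86400.0
    return survived, nsog_to_qcs, entry_to_nsog


def build_route_records(
    sequences: pd.DataFrame,
    deployments: pd.DataFrame,
    geom: ReceiverArrayGeometry,
) -> pd.DataFrame:
    """One route record per tag with >= 1 NSOG sequence or any JDF detection.

    ``sequences`` is the output of :func:`smoltroutes.sequencer.sequence_frame`
    over all arrays; ``deployments`` a frame of tag metadata.  JDF-detected
    tags are recorded with route JUAN_DE_FUCA and no NSOG covariates.
    """
    dep = deployments.set_index("tag_id")
    rows = []
    for tag, tag_seqs in sequences.groupby("tag_id"):
        if tag not in dep.index:
            warnings.warn(f"tag {tag!r} has detections but no deployment record; skipped")
            continue
        meta = dep.loc[tag]
        nsog = tag_seqs[tag_seqs["array"] == "NSOG"].sort_values("ordinal")
        qcs = tag_seqs[tag_seqs["array"] == "QCS"]
        jdf = tag_seqs[tag_seqs["array"] == "JDF"]
        base = {
            "tag_id": tag,
            "species": meta["species"],
            "population": meta["population"],
            "release_year": int(meta["release_year"]),
            "fork_length_mm": float(meta["fork_length_mm"]),
            "tag_model": meta.get("tag_model", ""),
        }
        if len(jdf) > 0:
            rows.append(
                {
                    **base,
                    "route": JUAN_DE_FUCA,
                    "p_initial": np.nan,
                    "arrival_date": pd.NaT,
                    "julian_day": np.nan,
                    "initial_strait": "",
                    "drift1_km": np.nan,
                    "dx12_km": np.nan,
                    "dx23_km": np.nan,
                    "duration12_h": np.nan,
                    "n_nsog_sequences": len(nsog),
                    "survived_qcs": len(qcs) > 0,
                    "nsog_to_qcs_days": np.nan,
                    "entry_to_nsog_days": np.nan,
                }
            )
            continue
        if len(nsog) == 0:
            continue
        first = nsog.iloc[0]
        route = classify_route(nsog, has_qcs=len(qcs) > 0)
        dx12, dx23, duration12 = lateral_metrics(nsog, geom)
        survived, nsog_to_qcs, entry_to_nsog = assign_survival(
            first["first_time"], qcs["first_time"], meta["release_date"]
        )
        rows.append(
            {
                **base,
                "route": route,
                "p_initial": int(first["first_receiver"]),
                "arrival_date": first["first_time"],
                "julian_day": int(first["first_time"].dayofyear),
                "initial_strait": geom.strait_of(int(first["first_receiver"])).value,
                "drift1_km": geom.delta_x(int(first["first_receiver"]), int(first["last_receiver"])),
                "dx12_km": dx12,
                "dx23_km": dx23,
                "duration12_h": duration12,
                "n_nsog_sequences": len(nsog),
                "survived_qcs": survived,
                "nsog_to_qcs_days": nsog_to_qcs,
                "entry_to_nsog_days": entry_to_nsog,
            }
        )
    cols = [
        "tag_id",
        "species",
        "population",
        "release_year",
        "fork_length_mm",
        "tag_model",
        "route",
        "p_initial",
        "arrival_date",
        "julian_day",
        "initial_strait",
        "drift1_km",
        "dx12_km",
        "dx23_km",
        "duration12_h",
        "n_nsog_sequences",
        "survived_qcs",
        "nsog_to_qcs_days",
        "entry_to_nsog_days",
    ]
    return pd.DataFrame(rows, columns=cols)


def route_tallies(records: pd.DataFrame) -> pd.DataFrame:
    """Per release-group route counts and proportions of classified fish.

    Groups are (species, population, release_year).  The proportion
    denominator is linear + counterclockwise + clockwise; UNCLASSIFIED and
    JUAN_DE_FUCA fish are excluded from it.  Groups with zero classified
    fish get NaN proportions.
    """
    rows = []
    for (species, pop, year), grp in records.groupby(["species", "population", "release_year"]):
        n_lin = int((grp["route"] == LINEAR).sum())
        n_ccw = int((grp["route"] == COUNTERCLOCKWISE).sum())
        n_cw = int((grp["route"] == CLOCKWISE).sum())
        n_classified = n_lin + n_ccw + n_cw
        denom = n_classified if n_classified > 0 else np.nan
        rows.append(
            {
                "species": species,
                "population": pop,
                "release_year": year,
                "n_detected": int((grp["route"] != JUAN_DE_FUCA).sum()),
                "n_linear": n_lin,
                "n_counterclockwise": n_ccw,
                "n_clockwise": n_cw,
                "n_classified": n_classified,
                "n_jdf": int((grp["route"] == JUAN_DE_FUCA).sum()),
                "prop_linear": n_lin / denom,
                "prop_counterclockwise": n_ccw / denom,
                "prop_clockwise": n_cw / denom,
            }
        )
    return pd.DataFrame(rows).sort_values(["species", "release_year", "population"]).reset_index(drop=True)
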