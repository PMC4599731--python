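"""Agent-based synthetic telemetry generator with ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, not the oceanography that produces it.  Each simulated smolt is
released in spring, swims to the upstream receiver curtain (NSOG) at about
1 body length per second (clamped to 13-17 km/day over ground), crosses the
curtain at a receiver drawn from a Malaspina-skewed arrival distribution,
and then follows one of three behaviour classes:

* ``linear`` -- a single crossing, then onward migration to the downstream
  curtain (QCS) ~250 km away;
* ``ccw`` -- after the first crossing the smolt drifts west by a lognormal
  loop amplitude over a lognormal dwell time and re-crosses at a more
  westerly receiver (optionally a third, eastward-displaced crossing closes
  the loop);
* ``cw`` -- the mirror image, displaced east.

Each crossing is detected as a whole with probability equal to the tag
model's detection efficiency (V7 ~0.675, V9 ~0.90); a detected crossing
emits a short burst of pings at the ping interval.  Mortality before QCS is
a per-fish Bernoulli draw whose log-odds are the baseline
``log(exp(-hazard * transit_days))`` odds shifted by configurable modifiers
on the (2-SD-standardized) entry position, Julian arrival day and milling
duration, so that with all modifiers zero the realized survival matches the
closed form ``exp(-hazard * transit)``.

All randomness flows from one ``numpy`` generator seeded by the caller;
identical (config, seed) pairs give identical output tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from ._study_table import study_groups
from .geometry import ReceiverArrayGeometry, default_nsog_geometry

__all__ = [
    "ReleaseGroupConfig",
    "MovementConfig",
    "DetectionConfig",
    "MortalityConfig",
    "SimulationConfig",
    "default_config",
    "study_release_groups",
    "simulate",
    "make_study_deployments",
]

SECONDS_PER_DAY = 86400.0


@dataclass
class ReleaseGroupConfig:
    species: str
    population: str
    origin: str
    release_year: int
    n: int
    fl_mean_mm: float
    fl_sd_mm: float
    tag_model: str
    # release window (uniform draw), emulating mid-April to late-May releases
    release_start: str = ""
    release_end: str = ""

    def __post_init__(self):
        if self.n <= 0:
            raise ValueError(f"release group {self.population} {self.release_year}: n must be > 0")
        if not self.release_start:
            self.release_start = f"{self.release_year}-04-20"
        if not self.release_end:
            self.release_end = f"{self.release_year}-05-20"


@dataclass
class MovementConfig:
    ground_speed_bl_s: float = 1.0
    speed_min_km_per_day: float = 13.0
    speed_max_km_per_day: float = 17.0
    p_linear: float = 0.65
    p_ccw: float = 0.25
    p_cw: float = 0.10
    # lognormal loop amplitude, km; mean ~ 8.9 km
    loop_amplitude_logmean: float = math.log(7.0)
    loop_amplitude_logsd: float = 0.7
    loop_min_km: float = 1.8
    # lognormal dwell between crossings, hours; mean ~ 74 h
    dwell_logmean: float = math.log(45.0)
    dwell_logsd: float = 1.0
    dwell_min_h: float = 1.1
    third_crossing_prob: float = 0.5
    p_jdf: float = 0.014
    malaspina_arrival_prob: float = 0.66
    current_drift_km_per_day: float = 0.0  # hook for superimposed westward drift

    def __post_init__(self):
        probs = (self.p_linear, self.p_ccw, self.p_cw)
        if any(not 0 <= p <= 1 for p in probs) or abs(sum(probs) - 1.0) > 1e-9:
            raise ValueError(f"behaviour-class probabilities {probs} must lie in [0,1] and sum to 1")
        if not 0 <= self.p_jdf <= 1 or not 0 <= self.malaspina_arrival_prob <= 1:
            raise ValueError("p_jdf and malaspina_arrival_prob must lie in [0, 1]")


@dataclass
class DetectionConfig:
    efficiency: dict = field(default_factory=lambda: {"V7": 0.675, "V9": 0.90})
    ping_interval_s: float = 60.0
    detection_radius_km: float = 0.4
    pings_min: int = 2
    pings_max: int = 6

    def __post_init__(self):
        for model, eff in self.efficiency.items():
            if not 0.0 <= eff <= 1.0:
                raise ValueError(f"efficiency for {model} must lie in [0, 1], got {eff}")


@dataclass
class MortalityConfig:
    baseline_daily_hazard: float = 0.058
    beta_strait_sog: float = 0.0      # log-odds shift for main-strait entrants
    beta_p_initial: float = 0.5       # per 2 SD of entry receiver index (west positive)
    beta_julian: float = -0.3         # per 2 SD of Julian arrival day
    beta_duration: float = -0.8       # per 2 SD of milling duration (loopers)


@dataclass
class SimulationConfig:
    release_groups: list = field(default_factory=lambda: study_release_groups())
    movement: MovementConfig = field(default_factory=MovementConfig)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    mortality: MortalityConfig = field(default_factory=MortalityConfig)
    geometry: ReceiverArrayGeometry = field(default_factory=default_nsog_geometry)
    qcs_n_receivers: int = 44
    jdf_n_receivers: int = 36
    nsog_to_qcs_km: float = 250.0
    release_to_nsog_km: float = 150.0

    def to_dict(self) -> dict:
        d = {
            "release_groups": [asdict(g) for g in self.release_groups],
            "movement": asdict(self.movement),
            "detection": asdict(self.detection),
            "mortality": asdict(self.mortality),
            "geometry": {
                "array_name": self.geometry.array_name,
                "n_receivers": self.geometry.n_receivers,
                "spacing_km": self.geometry.spacing_km,
                "gap_after_index": self.geometry.gap_after_index,
                "gap_km": self.geometry.gap_km,
                "malaspina_indices": sorted(self.geometry.malaspina_indices),
                "gap_mode": self.geometry.gap_mode,
            },
            "qcs_n_receivers": self.qcs_n_receivers,
            "jdf_n_receivers": self.jdf_n_receivers,
            "nsog_to_qcs_km": self.nsog_to_qcs_km,
            "release_to_nsog_km": self.release_to_nsog_km,
        }
        return d


def study_release_groups() -> list[ReleaseGroupConfig]:
    """Release groups mirroring the study's printed cohort structure."""
    groups = []
    for row in study_groups().itertuples(index=False):
        groups.append(
            ReleaseGroupConfig(
                species=row.species,
                population=row.population,
                origin=row.origin,
                release_year=int(row.release_year),
                n=int(row.n_released),
                fl_mean_mm=float(row.fl_mean_mm),
                fl_sd_mm=float(row.fl_sd_mm),
                tag_model=row.tag_model,
            )
        )
    return groups


def default_config() -> SimulationConfig:
    return SimulationConfig()


def make_study_deployments(seed: int = 0) -> pd.DataFrame:
    """Deployment table matching the study's group structure: per-group
    release counts equal the printed numbers, fork lengths drawn at the
    printed mean/SD."""
    rng = np.random.default_rng(seed)
    rows = []
    for g in study_release_groups():
        start = pd.Timestamp(g.release_start, tz="UTC")
        end = pd.Timestamp(g.release_end, tz="UTC")
        span_s = (end - start).total_seconds()
        for i in range(g.n):
            fl = max(50.0, rng.normal(g.fl_mean_mm, g.fl_sd_mm))
            rel = start + pd.Timedelta(seconds=float(rng.uniform(0, span_s)))
            rows.append(
                {
                    "tag_id": f"{g.species[:2]}{g.release_year}{g.population[:3]}{i:04d}",
                    "species": g.species,
                    "population": g.population,
                    "origin": g.origin,
                    "fork_length_mm": round(fl, 1),
                    "release_date": rel.floor("min"),
                    "release_year": g.release_year,
                    "tag_model": g.tag_model,
                }
            )
    return pd.DataFrame(rows)


def _logit(p: float) -> float:
    return math.log(p / (1.0 - p))


def _invlogit(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def _clamp(v, lo, hi):
    return max(lo, min(hi, v))


def _same_side_drift(geom: ReceiverArrayGeometry, receiver: int, drift: int) -> int:
    """Within-crossing drift of +/-1 receiver, kept on the entry's side of the
    island gap and inside the array."""
    target = _clamp(receiver + drift, 1, geom.n_receivers)
    if target != receiver and geom.spans_gap(receiver, target):
        return receiver
    return target


def simulate(config: SimulationConfig, seed: int) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Run the generator: returns (deployments, detections, truth).

    Detections carry columns (timestamp, tag_id, array, receiver); truth one
    row per smolt with the behaviour class, crossing geometry and survival
    actually imposed.
    """
    rng = np.random.default_rng(seed)
    geom = config.geometry
    mov = config.movement
    det = config.detection
    mort = config.mortality
    n_rec = geom.n_receivers
    mal = sorted(geom.malaspina_indices)
    sog = [i for i in range(1, n_rec + 1) if i not in geom.malaspina_indices]

    deployments: list[dict] = []
    fish: list[dict] = []

    for g in config.release_groups:
        if g.tag_model not in det.efficiency:
            raise ValueError(f"no detection efficiency configured for tag model {g.tag_model!r}")
        start = pd.Timestamp(g.release_start, tz="UTC")
        end = pd.Timestamp(g.release_end, tz="UTC")
        span_s = max((end - start).total_seconds(), 0.0)
        for i in range(g.n):
            tag = f"{g.species[:2]}{g.release_year}{g.population[:3]}{i:04d}"
            fl = max(50.0, rng.normal(g.fl_mean_mm, g.fl_sd_mm))
            release = start + pd.Timedelta(seconds=float(rng.uniform(0, span_s)))
            deployments.append(
                {
                    "tag_id": tag,
                    "species": g.species,
                    "population": g.population,
                    "origin": g.origin,
                    "fork_length_mm": round(fl, 1),
                    "release_date": release.floor("min"),
                    "release_year": g.release_year,
                    "tag_model": g.tag_model,
                }
            )
            # 1 BL/s over ground, clamped to the observed 13-17 km/day band
            speed = _clamp(
                fl / 1000.0 * mov.ground_speed_bl_s * SECONDS_PER_DAY / 1000.0,
                mov.speed_min_km_per_day,
                mov.speed_max_km_per_day,
            )

            if rng.uniform() < mov.p_jdf:
                fish.append(
                    {
                        "tag_id": tag,
                        "species": g.species,
                        "tag_model": g.tag_model,
                        "behavior": "jdf",
                        "release": release,
                        "speed_km_d": speed,
                        "crossings": [],
                        "jdf_time": release
                        + pd.Timedelta(days=config.release_to_nsog_km / speed),
                        "jdf_receiver": int(rng.integers(1, config.jdf_n_receivers + 1)),
                    }
                )
                continue

            u = rng.uniform()
            behavior = "linear" if u < mov.p_linear else ("ccw" if u < mov.p_linear + mov.p_ccw else "cw")

            if rng.uniform() < mov.malaspina_arrival_prob:
                entry = int(rng.choice(mal))
            else:
                entry = int(rng.choice(sog))
            # keep the drawn loop direction geometrically expressible
            if behavior == "ccw" and entry == n_rec:
                entry = n_rec - 1
            if behavior == "cw" and entry == 1:
                entry = 2

            travel_days = config.release_to_nsog_km / speed + float(rng.uniform(0.0, 1.0))
            t1 = release + pd.Timedelta(days=travel_days)

            def one_crossing(receiver: int, t_start: pd.Timestamp, keep_feasible: str | None):
                drift = int(rng.choice([-1, 0, 1], p=[0.2, 0.6, 0.2]))
                exit_r = _same_side_drift(geom, receiver, drift)
                if keep_feasible == "ccw" and exit_r == n_rec:
                    exit_r = receiver
                if keep_feasible == "cw" and exit_r == 1:
                    exit_r = receiver
                n_pings = int(rng.integers(det.pings_min, det.pings_max + 1))
                t_end = t_start + pd.Timedelta(seconds=det.ping_interval_s * (n_pings - 1))
                return {
                    "entry": receiver,
                    "exit": exit_r,
                    "t_start": t_start,
                    "t_end": t_end,
                    "n_pings": n_pings,
                }

            crossings = [one_crossing(entry, t1, behavior if behavior in ("ccw", "cw") else None)]
            dwell_total = 0.0
            dwell1 = np.nan
            if behavior in ("ccw", "cw"):
                amp = max(mov.loop_min_km, float(rng.lognormal(mov.loop_amplitude_logmean, mov.loop_amplitude_logsd)))
                shift = max(1, round(amp / geom.spacing_km))
                dwell1 = max(mov.dwell_min_h, float(rng.lognormal(mov.dwell_logmean, mov.dwell_logsd)))
                exit1 = crossings[0]["exit"]
                # optional ambient westward drift accumulated over the dwell
                amp += mov.current_drift_km_per_day * dwell1 / 24.0 * (1 if behavior == "ccw" else -1)
                amp = max(mov.loop_min_km, amp)
                shift = max(1, round(amp / geom.spacing_km))
                if behavior == "ccw":
                    target = min(n_rec, exit1 + shift)
                else:
                    target = max(1, exit1 - shift)
                t2 = crossings[0]["t_end"] + pd.Timedelta(hours=dwell1)
                crossings.append(one_crossing(target, t2, None))
                dwell_total += dwell1
                if rng.uniform() < mov.third_crossing_prob:
                    amp2 = max(
                        mov.loop_min_km,
                        float(rng.lognormal(mov.loop_amplitude_logmean, mov.loop_amplitude_logsd)),
                    )
                    shift2 = max(1, round(amp2 / geom.spacing_km))
                    exit2 = crossings[1]["exit"]
                    target3 = max(1, exit2 - shift2) if behavior == "ccw" else min(n_rec, exit2 + shift2)
                    if target3 != exit2:
                        dwell2 = max(mov.dwell_min_h, float(rng.lognormal(mov.dwell_logmean, mov.dwell_logsd)))
                        t3 = crossings[1]["t_end"] + pd.Timedelta(hours=dwell2)
                        crossings.append(one_crossing(target3, t3, None))
                        dwell_total += dwell2

            fish.append(
                {
                    "tag_id": tag,
                    "species": g.species,
                    "tag_model": g.tag_model,
                    "behavior": behavior,
                    "release": release,
                    "speed_km_d": speed,
                    "entry_receiver": entry,
                    "crossings": crossings,
                    "dwell1_h": dwell1,
                    "dwell_total_h": dwell_total,
                    "julian": int(t1.dayofyear),
                }
            )

    # --- survival pass: standardize modifier covariates per species over the cohort
    def z_of(values: np.ndarray) -> np.ndarray:
        sd = values.std(ddof=1) if len(values) > 1 else 0.0
        if sd == 0.0:
            return np.zeros_like(values, dtype=float)
        return (values - values.mean()) / (2.0 * sd)

    by_species: dict[str, list[int]] = {}
    for idx, f in enumerate(fish):
        if f["behavior"] != "jdf":
            by_species.setdefault(f["species"], []).append(idx)
    for species, idxs in by_species.items():
        p_init = np.array([fish[i]["entry_receiver"] for i in idxs], dtype=float)
        julian = np.array([fish[i]["julian"] for i in idxs], dtype=float)
        loopers = [i for i in idxs if fish[i]["behavior"] in ("ccw", "cw")]
        dwell = np.array([fish[i]["dwell1_h"] for i in loopers], dtype=float)
        zp, zj = z_of(p_init), z_of(julian)
        zd = z_of(dwell) if len(dwell) else np.array([])
        zd_map = dict(zip(loopers, zd))
        for i, zpi, zji in zip(idxs, zp, zj):
            f = fish[i]
            transit = config.nsog_to_qcs_km / f["speed_km_d"]
            base_surv = math.exp(-mort.baseline_daily_hazard * transit)
            base_surv = _clamp(base_surv, 1e-9, 1 - 1e-9)
            eta = _logit(base_surv)
            eta += mort.beta_strait_sog * (0.0 if f["entry_receiver"] in geom.malaspina_indices else 1.0)
            eta += mort.beta_p_initial * zpi
            eta += mort.beta_julian * zji
            eta += mort.beta_duration * zd_map.get(i, 0.0)
            f["survival_prob"] = _invlogit(eta)
            f["transit_days"] = transit
            f["survived"] = bool(rng.uniform() < f["survival_prob"])

    # --- detection emission
    det_rows: list[dict] = []

    def emit_crossing(tag: str, array: str, crossing: dict, eff: float):
        if rng.uniform() >= eff:
            return
        entry, exit_r, n_pings = crossing["entry"], crossing["exit"], crossing["n_pings"]
        for p in range(n_pings):
            # receiver path interpolates entry -> exit over the ping burst
            frac = p / max(n_pings - 1, 1)
            receiver = int(round(entry + frac * (exit_r - entry)))
            ts = crossing["t_start"] + pd.Timedelta(seconds=det.ping_interval_s * p)
            det_rows.append({"timestamp": ts, "tag_id": tag, "array": array, "receiver": receiver})

    truth_rows: list[dict] = []
    for f in fish:
        eff = det.efficiency[f["tag_model"]]
        if f["behavior"] == "jdf":
            emit_crossing(
                f["tag_id"],
                "JDF",
                {
                    "entry": f["jdf_receiver"],
                    "exit": f["jdf_receiver"],
                    "t_start": f["jdf_time"],
                    "n_pings": int(rng.integers(det.pings_min, det.pings_max + 1)),
                },
                eff,
            )
            truth_rows.append(
                {
                    "tag_id": f["tag_id"],
                    "behavior": "jdf",
                    "p_initial_true": np.nan,
                    "exit1_receiver": np.nan,
                    "entry2_receiver": np.nan,
                    "dx12_true_km": np.nan,
                    "dwell1_h": np.nan,
                    "n_crossings": 0,
                    "survived_true": False,
                    "transit_days": np.nan,
                    "survival_prob": np.nan,
                }
            )
            continue
        for crossing in f["crossings"]:
            emit_crossing(f["tag_id"], "NSOG", crossing, eff)
        if f["survived"]:
            t_qcs = f["crossings"][-1]["t_end"] + pd.Timedelta(days=f["transit_days"])
            qcs_receiver = int(rng.integers(1, config.qcs_n_receivers + 1))
            emit_crossing(
                f["tag_id"],
                "QCS",
                {
                    "entry": qcs_receiver,
                    "exit": qcs_receiver,
                    "t_start": t_qcs,
                    "n_pings": int(rng.integers(det.pings_min, det.pings_max + 1)),
                },
                eff,
            )
        crossings = f["crossings"]
        dx12_true = (
            geom.delta_x(crossings[0]["exit"], crossings[1]["entry"]) if len(crossings) >= 2 else np.nan
        )
        truth_rows.append(
            {
                "tag_id": f["tag_id"],
                "behavior": f["behavior"],
                "p_initial_true": f["entry_receiver"],
                "exit1_receiver": crossings[0]["exit"],
                "entry2_receiver": crossings[1]["entry"] if len(crossings) >= 2 else np.nan,
                "dx12_true_km": dx12_true,
                "dwell1_h": f["dwell1_h"],
                "n_crossings": len(crossings),
                "survived_true": f["survived"],
                "transit_days": f["transit_days"],
                "survival_prob": f["survival_prob"],
            }
        )

    deployments_df = pd.DataFrame(deployments)
    detections_df = pd.DataFrame(det_rows, columns=["timestamp", "tag_id", "array", "receiver"])
    if len(detections_df):
        detections_df = detections_df.sort_values(["tag_id", "timestamp", "receiver"]).reset_index(drop=True)
    truth_df = pd.DataFrame(truth_rows)
    # conservation check: every detection's tag exists, no detection precedes release
    release_by_tag = deployments_df.set_index("tag_id")["release_date"]
    if len(detections_df):
        unknown = set(detections_df["tag_id"]) - set(release_by_tag.index)
        if unknown:
            raise AssertionError(f"generator emitted detections for unknown tags {unknown}")
    return deployments_df, detections_df, truth_df
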