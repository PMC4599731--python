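"""End-to-end orchestration: simulate -> sequence -> classify -> stats -> survive -> report.

Every stage reads and writes the pipeline's CSV formats, so a stage can be
re-entered from its input files and reproduce its outputs exactly.  All
randomness flows from one root seed; a run manifest records the config
hash, the seed, and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from importlib.metadata import PackageNotFoundError, version
from pathlib import Path

import pandas as pd
import yaml

from . import io as tio
from .geometry import ReceiverArrayGeometry
from .movstats import (
    big_westward_tally,
    confound_correlations,
    duration_by_route,
    kendall_tau,
    ranksum_test,
    route_proportion_anova,
    signed_rank_zero_test,
    species_proportion_ttest,
    strait_use_test,
)
from .routes import COUNTERCLOCKWISE, JUAN_DE_FUCA, build_route_records, route_tallies
from .sequencer import sequence_frame
from .simdata import SimulationConfig, simulate
from .survival import SurvivalModel

__all__ = ["RunManifest", "run_all", "stage_sequence", "stage_classify", "stage_stats", "stage_survive"]


def _pkg_version() -> str:
    try:
        return version("smoltroutes")
    except PackageNotFoundError:  # running from a source tree
        return "0.0.0+src"


@dataclass
class RunManifest:
    config_hash: str
    seed: int
    package_version: str = field(default_factory=_pkg_version)
    stages: list = field(default_factory=list)

    def record(self, stage: str, outputs: dict[str, int]) -> None:
        self.stages.append({"stage": stage, "outputs": outputs})

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "config_hash": self.config_hash,
                    "seed": self.seed,
                    "package_version": self.package_version,
                    "stages": self.stages,
                },
                fh,
                indent=2,
            )


def config_hash(config: SimulationConfig) -> str:
    payload = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_sequence(detections_csv: Path, geom: ReceiverArrayGeometry, out_csv: Path) -> pd.DataFrame:
    detections = tio.read_detections(detections_csv)
    seqs = sequence_frame(detections, {geom.array_name: geom})
    tio.write_table(seqs, out_csv)
    return seqs


def stage_classify(
    sequences_csv: Path, deployments_csv: Path, geom: ReceiverArrayGeometry, out_csv: Path
) -> pd.DataFrame:
    seqs = tio.read_table(sequences_csv, parse_dates=["first_time", "last_time"])
    deployments = tio.deployments_to_frame(tio.read_deployments(deployments_csv))
    records = build_route_records(seqs, deployments, geom)
    tio.write_table(records, out_csv)
    return records


def _stats_battery(records: pd.DataFrame, geom: ReceiverArrayGeometry) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run the per-species test battery; returns (results table, tallies)."""
    rows = []

    def add(species, result):
        rows.append(
            {
                "species": species,
                "test": result.test_name,
                "statistic": result.statistic,
                "p_value": result.p_value,
                "n": result.n,
                **{f"est_{k}": v for k, v in result.estimates.items()},
            }
        )

    nsog = records[records["route"] != JUAN_DE_FUCA]
    tallies = route_tallies(records)
    for species, grp in nsog.groupby("species"):
        try:
            add(species, strait_use_test(grp["p_initial"].dropna().astype(int).to_numpy(), geom))
            add(species, signed_rank_zero_test(grp["drift1_km"].dropna().to_numpy()))
            dx12 = grp["dx12_km"].dropna().to_numpy()
            if len(dx12):
                add(species, signed_rank_zero_test(dx12))
            dx23 = grp["dx23_km"].dropna().to_numpy()
            if len(dx23):
                add(species, signed_rank_zero_test(dx23))
            pair = grp.dropna(subset=["dx12_km", "duration12_h"])
            if len(pair) >= 2 and pair["dx12_km"].nunique() > 1 and pair["duration12_h"].nunique() > 1:
                add(species, kendall_tau(pair["duration12_h"], pair["dx12_km"].abs()))
            st = tallies[tallies["species"] == species]
            if (st["n_classified"] > 0).sum() >= 2:
                add(species, route_proportion_anova(st))
            surv_by_route = grp[grp["survived_qcs"] == True]  # noqa: E712
            if surv_by_route["route"].nunique() >= 2:
                try:
                    add(species, duration_by_route(grp))
                except ValueError:
                    pass
        except ValueError as err:
            warnings.warn(f"stats battery ({species}): {err}", stacklevel=2)
    # cross-species comparisons
    sp = sorted(nsog["species"].unique())
    if len(sp) == 2:
        a = nsog[nsog["species"] == sp[0]]["dx12_km"].dropna().to_numpy()
        b = nsog[nsog["species"] == sp[1]]["dx12_km"].dropna().to_numpy()
        if len(a) and len(b):
            add(f"{sp[0]} vs {sp[1]}", ranksum_test(a, b))
        ta = tallies[tallies["species"] == sp[0]]["prop_counterclockwise"].dropna().to_numpy()
        tb = tallies[tallies["species"] == sp[1]]["prop_counterclockwise"].dropna().to_numpy()
        if len(ta) >= 2 and len(tb) >= 2:
            add(f"{sp[0]} vs {sp[1]} ({COUNTERCLOCKWISE.lower()})", species_proportion_ttest(ta, tb))
    return pd.DataFrame(rows), tallies


def stage_stats(
    records_csv: Path, geom: ReceiverArrayGeometry, out_dir: Path
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    records = tio.read_table(records_csv, parse_dates=["arrival_date"])
    results, tallies = _stats_battery(records, geom)
    correlations = confound_correlations(records)
    westward = big_westward_tally(records)
    tio.write_table(results, out_dir / "stats_results.csv")
    tio.write_table(tallies, out_dir / "route_tallies.csv")
    tio.write_table(correlations, out_dir / "confound_correlations.csv")
    tio.write_table(westward, out_dir / "big_westward.csv")
    return results, tallies, correlations, westward


def stage_survive(records_csv: Path, out_dir: Path) -> dict[str, object]:
    records = tio.read_table(records_csv, parse_dates=["arrival_date"])
    out: dict[str, object] = {}
    for species in sorted(records["species"].unique()):
        for model_set in ("entry", "lateral"):
            key = f"{species}_{model_set}"
            try:
                results = SurvivalModel(records, species, model_set).fit()
            except ValueError as err:
                warnings.warn(f"survival models ({key}): {err}", stacklevel=2)
                continue
            out[key] = results
            tio.write_table(results.ranking, out_dir / f"model_ranking_{key}.csv")
            tio.write_table(results.averaged.reset_index(), out_dir / f"averaged_coefficients_{key}.csv")
            for term in results.significant_terms():
                base = term.split(":")[-1].split("[")[0]
                if base in results.model.design.scalers:
                    curve = results.predict(base)
                    tio.write_table(curve, out_dir / f"prediction_{key}_{base}.csv")
    return out


def _report(outdir: Path, tallies: pd.DataFrame, stats_df: pd.DataFrame, survive: dict) -> str:
    lines = ["# Pipeline report", "", "## Route proportions by release group", ""]
    lines.append(tallies.to_string(index=False, float_format=lambda v: f"{v:.3f}"))
    lines += ["", "## Hypothesis tests", ""]
    if len(stats_df):
        lines.append(
            stats_df[["species", "test", "statistic", "p_value", "n"]].to_string(
                index=False, float_format=lambda v: f"{v:.4g}"
            )
        )
    for key, results in survive.items():
        lines += ["", f"## Survival models: {key}", "", results.summary()]
    text = "\n".join(lines) + "\n"
    (outdir / "report.md").write_text(text)
    return text


def run_all(config: SimulationConfig, seed: int, outdir: str | Path) -> RunManifest:
    """Run every stage on a fresh simulation, writing all tables under outdir."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config_hash=config_hash(config), seed=seed)
    geom = config.geometry

    deployments, detections, truth = simulate(config, seed)
    if len(deployments) == 0:
        raise RuntimeError("simulate produced no deployments")
    tio.write_table(deployments, outdir / "deployments.csv")
    tio.write_table(detections, outdir / "detections.csv")
    tio.write_table(truth, outdir / "truth.csv")
    manifest.record(
        "simulate",
        {"deployments": len(deployments), "detections": len(detections), "truth": len(truth)},
    )

    seqs = stage_sequence(outdir / "detections.csv", geom, outdir / "sequences.csv")
    manifest.record("sequence", {"sequences": len(seqs)})

    records = stage_classify(outdir / "sequences.csv", outdir / "deployments.csv", geom, outdir / "route_records.csv")
    manifest.record("classify", {"route_records": len(records)})

    stats_df, tallies, correlations, westward = stage_stats(outdir / "route_records.csv", geom, outdir)
    manifest.record("stats", {"tests": len(stats_df), "groups": len(tallies)})

    survive = stage_survive(outdir / "route_records.csv", outdir)
    manifest.record("survive", {"model_sets": len(survive)})

    _report(outdir, tallies, stats_df, survive)
    manifest.record("report", {"files": 1})
    manifest.write(outdir / "manifest.json")
    return manifest
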