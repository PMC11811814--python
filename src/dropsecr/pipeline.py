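"""Stage-wise pipeline: simulate -> segment -> extract -> classify ->
quantify -> gate -> report.

Each stage reads its inputs from the output directory and writes plain
tab/comma-separated tables, so any stage can be rerun on its own; a
manifest records the package version, seeds and row counts. Every figure
written by the report stage has its underlying table written next to it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import AcquisitionSpec, AssayConstants, ChamberSpec, CHANNEL_A647, CHANNEL_ROS
from .synthgen import (
    CONDITION_PRESETS,
    REALISTIC_NOISE_SD,
    generate_image_series,
    generate_trace_set,
)
from . import imaging
from .nox import classify_table, fixed_threshold, fit_threshold, nox_frequency, signal_loss
from .secretion import (
    default_igg_curve,
    default_lactate_curve,
    igg_secretion_rate,
    lactate_secretion_rate,
    ros_slope,
    joint_phenotype_table,
)
from .stats import compare_distributions

log = logging.getLogger("dropsecr")

STAGES = ("simulate", "segment", "extract", "classify", "quantify", "gate", "report")

# stage -> (file it needs, stage that writes it)
_REQUIRES = {
    "classify": ("traces.tsv", "extract"),
    "quantify": ("calls.tsv", "classify"),
    "gate": ("estimates.tsv", "quantify"),
    "report": ("phenotypes.tsv", "gate"),
}


@dataclass
class PipelineConfig:
    """Fully serializable run configuration (written next to the outputs)."""

    seed: int = 0
    n_droplets: int = 2000
    n_frames: int = 6
    interval_s: float = 600.0
    lambda_occupancy: float = 0.3
    conditions: tuple[str, ...] = ("control", "day3")
    n_replicates: int = 3  # synthetic "mice" per condition
    noise: str = "realistic"  # "realistic" | "none"
    imaging: bool = False  # render + re-extract images instead of passing traces
    threshold_mode: str = "fixed"  # "fixed" | "control"
    threshold_pct: float = 10.3
    igg_upper: float = 285.0  # 258.0 selects the alternative published bound
    stages: tuple[str, ...] = STAGES

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        kwargs = {k: v for k, v in raw.items() if k in {f.name for f in dataclasses.fields(cls)}}
        for key in ("conditions", "stages"):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        return cls(**kwargs)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["conditions"] = list(d["conditions"])
        d["stages"] = list(d["stages"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


def demo_config(seed: int = 0) -> PipelineConfig:
    """The bundled demo: 2,000 droplets, 6 frames, 3 synthetic mice for
    each of two conditions, realistic noise, fixed threshold."""
    return PipelineConfig(seed=seed)


def _require(outdir: Path, stage: str) -> None:
    need = _REQUIRES.get(stage)
    if need is None:
        return
    fname, producer = need
    if not (outdir / fname).exists():
        raise FileNotFoundError(
            f"stage '{stage}' needs {fname}, which is missing; rerun stage '{producer}'"
        )


def run_pipeline(
    config: PipelineConfig,
    outdir: str | Path,
    stages: tuple[str, ...] | None = None,
    dry_run: bool = False,
) -> Path:
    """Run the requested stages, writing all outputs under ``outdir``."""
    outdir = Path(outdir)
    stages = tuple(stages or config.stages)
    if dry_run:
        for s in stages:
            print(f"would run: {s}")
        return outdir
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config_resolved.yaml")
    manifest = {"version": __version__, "seed": config.seed, "rows": {}}

    acq = AcquisitionSpec(
        n_frames=config.n_frames,
        interval_s=config.interval_s,
        noise_sd=REALISTIC_NOISE_SD if config.noise == "realistic" else 0.0,
    )
    chamber = ChamberSpec(
        n_droplets=config.n_droplets, lambda_occupancy=config.lambda_occupancy
    )
    constants = AssayConstants(igg_upper=config.igg_upper)

    for stage in stages:
        log.info("stage: %s", stage)
        _require(outdir, stage)

        if stage == "simulate":
            all_traces, all_truth = [], []
            for ci, cond in enumerate(config.conditions):
                for rep in range(config.n_replicates):
                    seed = config.seed + 1000 * ci + rep
                    traces, truth = generate_trace_set(
                        chamber, acq, seed=seed, condition=cond
                    )
                    for df in (traces, truth):
                        df["replicate"] = rep
                        df["droplet_id"] = f"{cond}.m{rep}." + df["droplet_id"]
                    all_traces.append(traces)
                    all_truth.append(truth)
            traces = pd.concat(all_traces, ignore_index=True)
            truth = pd.concat(all_truth, ignore_index=True)
            traces.to_csv(outdir / "simulated_traces.tsv", sep="\t", index=False)
            truth.to_csv(outdir / "ground_truth.tsv", sep="\t", index=False)
            manifest["rows"]["simulated_traces"] = len(traces)
            if config.imaging:
                # render one replicate worth of images for the imaging stages
                sub = traces[traces["droplet_id"].str.startswith(
                    f"{config.conditions[0]}.m0.")]
                generate_image_series(sub, chamber, acq, seed=config.seed,
                                      outdir=outdir / "images")

        elif stage == "segment":
            if config.imaging and (outdir / "images").exists():
                images, layout = imaging.read_image_series(outdir / "images")
                regions = [
                    imaging.segment_droplets(images[CHANNEL_A647][t], frame_index=t)
                    for t in range(layout["n_frames"])
                ]
                np.save(outdir / "n_regions.npy", np.array([len(r) for r in regions]))
                manifest["rows"]["segmented_frame0"] = len(regions[0])
            else:
                log.info("trace-level run: no images to segment")

        elif stage == "extract":
            if config.imaging and (outdir / "images").exists():
                images, layout = imaging.read_image_series(outdir / "images")
                regions = [
                    imaging.segment_droplets(images[CHANNEL_A647][t], frame_index=t)
                    for t in range(layout["n_frames"])
                ]
                tracks = imaging.track_droplets(regions)
                traces = imaging.extract_traces(tracks, regions, images, acq)
                traces["condition"] = config.conditions[0]
            else:
                traces = pd.read_csv(outdir / "simulated_traces.tsv", sep="\t")
            traces.to_csv(outdir / "traces.tsv", sep="\t", index=False)
            manifest["rows"]["traces"] = len(traces)

        elif stage == "classify":
            traces = pd.read_csv(outdir / "traces.tsv", sep="\t")
            if config.threshold_mode == "control":
                ctrl = traces[
                    (traces["condition"] == "control") & (traces["channel"] == CHANNEL_A647)
                ]
                losses = [
                    signal_loss(g["droplet_mean"].to_numpy())
                    for _, g in ctrl.groupby("droplet_id")
                ]
                model = fit_threshold(losses)
            else:
                model = fixed_threshold(config.threshold_pct)
            calls = classify_table(traces, model)
            # keep the replicate tag for per-mouse frequencies
            calls["replicate"] = calls["droplet_id"].str.split(".").str[1]
            calls.to_csv(outdir / "calls.tsv", sep="\t", index=False)
            manifest["rows"]["calls"] = len(calls)

        elif stage == "quantify":
            traces = pd.read_csv(outdir / "traces.tsv", sep="\t")
            calls = pd.read_csv(outdir / "calls.tsv", sep="\t").set_index("droplet_id")
            igg_curve = default_igg_curve()
            lac_curve = default_lactate_curve()
            rows = []
            a647 = traces[traces["channel"] == CHANNEL_A647]
            lact = dict(iter(traces[traces["channel"] == "lactate_probe"].groupby("droplet_id")))
            ros = dict(iter(traces[traces["channel"] == CHANNEL_ROS].groupby("droplet_id")))
            for did, grp in a647.groupby("droplet_id", sort=False):
                if grp["track_quality"].iloc[0] != "ok" or grp["n_cells"].iloc[0] < 1:
                    continue
                label = calls.loc[did, "label"]
                est_i = igg_secretion_rate(grp, igg_curve, constants, nox_label=label)
                est_l = lactate_secretion_rate(
                    lact[did], lac_curve, constants, n_cells=int(grp["n_cells"].iloc[0])
                )
                rgrp = ros[did].sort_values("frame")
                slope = ros_slope(rgrp["cell_mean"].to_numpy(), rgrp["time_s"].to_numpy(), constants)
                rows.append(
                    {
                        "droplet_id": did,
                        "igg_rate_per_s": est_i.rate,
                        "igg_gate": est_i.gate,
                        "lactate_rate_amol_s": est_l.rate,
                        "lactate_gate": est_l.gate,
                        "ros_slope_au_per_10min": slope,
                    }
                )
            est = pd.DataFrame(rows)
            est.to_csv(outdir / "estimates.tsv", sep="\t", index=False)
            manifest["rows"]["estimates"] = len(est)

        elif stage == "gate":
            calls = pd.read_csv(outdir / "calls.tsv", sep="\t")
            est = pd.read_csv(outdir / "estimates.tsv", sep="\t")
            joint = calls.merge(est, on="droplet_id", how="inner")
            joint.to_csv(outdir / "phenotypes.tsv", sep="\t", index=False)
            manifest["rows"]["phenotypes"] = len(joint)

        elif stage == "report":
            joint = pd.read_csv(outdir / "phenotypes.tsv", sep="\t")
            freq = nox_frequency(joint, by=["condition", "replicate"])
            freq.to_csv(outdir / "nox_frequency.csv", index=False)
            stats_out = {}
            pos = joint[joint["label"] == "NOX_drop_pos"]["lactate_rate_amol_s"].dropna()
            neg = joint[joint["label"] == "NOX_drop_neg"]["lactate_rate_amol_s"].dropna()
            if len(pos) >= 2 and len(neg) >= 2:
                ks = compare_distributions(pos, neg)
                stats_out["lactate_nox_pos_vs_neg"] = {
                    "test": ks.test, "statistic": ks.statistic, "p": ks.p,
                    "stars": ks.stars, "n": list(ks.group_sizes),
                }
            summary = (
                joint.groupby(["condition", "label"])
                .agg(
                    n=("droplet_id", "size"),
                    lactate_median=("lactate_rate_amol_s", "median"),
                    ros_median=("ros_slope_au_per_10min", "median"),
                )
                .reset_index()
            )
            summary.to_csv(outdir / "summary.csv", index=False, float_format="%.6g")
            with open(outdir / "stats.json", "w") as fh:
                json.dump(stats_out, fh, indent=1, sort_keys=True)
            _write_figures(outdir, joint, freq)
            manifest["rows"]["summary"] = len(summary)

        else:
            raise ValueError(f"unknown stage {stage!r}")

    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return outdir


def _write_figures(outdir: Path, joint: pd.DataFrame, freq: pd.DataFrame) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 2, figsize=(9, 4))
    groups = [g for _, g in joint.groupby("label")]
    data = [g["lactate_rate_amol_s"].dropna() for g in groups]
    labels = [g["label"].iloc[0] for g in groups]
    if all(len(d) for d in data):
        parts = axes[0].violinplot(data, showmedians=True, quantiles=[[0.25, 0.75]] * len(data))
        axes[0].set_xticks(range(1, len(labels) + 1), labels)
    axes[0].set_ylabel("lactate secretion rate (amol/s)")
    # underlying table already written as phenotypes.tsv
    if not freq.empty:
        x = np.arange(len(freq))
        axes[1].bar(x, freq["pct_positive"])
        axes[1].set_xticks(x, [f"{c}/{r}" for c, r in zip(freq["condition"], freq["replicate"])],
                           rotation=45)
        axes[1].set_ylabel("NOX-active droplets (%)")
    fig.tight_layout()
    fig.savefig(outdir / "report.png", dpi=120)
    plt.close(fig)
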