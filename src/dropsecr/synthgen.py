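"""Synthetic droplet chambers, calibration standards and expression matrices.

Forward model of the droplet assay, with known ground truth for every
downstream stage:

* the oxidation-sensitive A647 channel of a NOX-active droplet decays
  exponentially, S(t) = S0 * exp(-k t), with k chosen so that the loss
  between the first and the last frame equals the planted terminal loss;
* the IgG immunoassay readout is the relocation ratio
  beadline / droplet produced by the saturating-exponential calibration
  at the accumulated in-droplet IgG concentration (rate * t);
* the lactate probe intensity follows the linear calibration at the
  accumulated lactate concentration;
* the intracellular ROS channel of a cell rises linearly at the planted
  slope (a.u. per 10 min).

All channels carry additive, iid Gaussian frame noise; identical seeds
give bit-identical outputs.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (
    AcquisitionSpec,
    AssayConstants,
    ChamberSpec,
    PhenotypeSpec,
    CHANNEL_A647,
    CHANNEL_CELL_STAIN,
    CHANNEL_LACTATE,
    CHANNEL_ROS,
)
from .secretion import (
    CalibrationCurve,
    default_igg_curve,
    default_lactate_curve,
    igg_conc_nm_from_rate,
    lactate_conc_um_from_rate,
)

# baseline intensities of the rendered/simulated channels (a.u.)
A647_BASE = 200.0
CELLSTAIN_DISK = 40.0
CELLSTAIN_BLOB = 150.0
ROS_DISK_BG = 20.0
ROS_CELL_BASE = 30.0
CELL_RADIUS_PX = 3
CELL_AREA_FRACTION = (CELL_RADIUS_PX / 12) ** 2  # vs default droplet radius

#: per-channel Gaussian frame-noise SDs used for "realistic" runs
#: (~2% of the A647 baseline, matching a control-derived threshold
#: in the ~10% range)
REALISTIC_NOISE_SD = {
    CHANNEL_CELL_STAIN: 2.0,
    CHANNEL_LACTATE: 2.0,
    CHANNEL_ROS: 2.0,
    CHANNEL_A647: 4.0,
}


@dataclass(frozen=True)
class PhenotypeSampler:
    """Sampling distribution over single-cell phenotypes.

    ``nox_fraction`` is the probability that a cell has active NOXes;
    active cells draw a terminal A647 loss uniformly from
    ``loss_range`` (percent). Secretion rates are uniform over their
    ranges; ``igg_sc_fraction`` of cells secrete IgG at all.
    """

    nox_fraction: float = 0.0
    loss_range: tuple[float, float] = (15.0, 45.0)
    igg_sc_fraction: float = 0.2
    igg_range: tuple[float, float] = (9.0, 285.0)
    lactate_range: tuple[float, float] = (0.1, 0.8)
    ros_range: tuple[float, float] = (2.0, 30.0)

    def sample(self, n: int, rng: np.random.Generator) -> list[PhenotypeSpec]:
        out = []
        for i in range(n):
            active = bool(rng.random() < self.nox_fraction)
            loss = float(rng.uniform(*self.loss_range)) if active else 0.0
            igg = (
                float(rng.uniform(*self.igg_range))
                if rng.random() < self.igg_sc_fraction
                else 0.0
            )
            out.append(
                PhenotypeSpec(
                    cell_id=f"cell{i:06d}",
                    nox_active=active,
                    terminal_loss_pct=loss,
                    igg_rate=igg,
                    lactate_rate=float(rng.uniform(*self.lactate_range)),
                    ros_slope=float(rng.uniform(*self.ros_range)),
                )
            )
        return out


#: condition presets select phenotype sampling distributions; NOX-active
#: fractions follow the immunization-day estimates the assay reports,
#: and the ROS-scavenger (NAC) condition abolishes A647 decay entirely.
CONDITION_PRESETS: dict[str, PhenotypeSampler] = {
    "control": PhenotypeSampler(nox_fraction=0.0),
    "nac": PhenotypeSampler(nox_fraction=0.0),
    "day0": PhenotypeSampler(nox_fraction=0.12),
    "day3": PhenotypeSampler(nox_fraction=0.31),
    "day7": PhenotypeSampler(nox_fraction=0.12),
    "day14": PhenotypeSampler(nox_fraction=0.59),
    "mpla": PhenotypeSampler(nox_fraction=0.40),
}


def _decay_rate(terminal_loss_pct: float, t_last: float) -> float:
    if terminal_loss_pct <= 0:
        return 0.0
    if terminal_loss_pct >= 100:
        raise ValueError("terminal_loss_pct must be < 100 for a finite decay rate")
    return -math.log1p(-terminal_loss_pct / 100.0) / t_last


def generate_trace_set(
    chamber: ChamberSpec,
    acq: AcquisitionSpec,
    phenotypes: list[PhenotypeSpec] | PhenotypeSampler | None = None,
    seed: int = 0,
    igg_curve: CalibrationCurve | None = None,
    lactate_curve: CalibrationCurve | None = None,
    constants: AssayConstants | None = None,
    condition: str = "control",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-droplet, per-frame, per-channel mean-intensity traces.

    Returns ``(traces, truth)``: a long table with columns (droplet_id,
    frame, time_s, channel, droplet_mean, beadline_mean, cell_mean,
    n_cells, track_quality, condition) and the ground-truth table of
    planted phenotypes.
    """
    rng = np.random.default_rng(seed)
    constants = constants or AssayConstants()
    igg_curve = igg_curve or default_igg_curve()
    lactate_curve = lactate_curve or default_lactate_curve()
    n = chamber.n_droplets

    if phenotypes is None:
        phenotypes = CONDITION_PRESETS.get(condition, PhenotypeSampler()).sample(n, rng)
    elif isinstance(phenotypes, PhenotypeSampler):
        phenotypes = phenotypes.sample(n, rng)
    if len(phenotypes) != n:
        raise ValueError(f"need {n} phenotypes, got {len(phenotypes)}")

    times = np.asarray(acq.times_s)
    t_last = times[-1]
    rows = []
    truth_rows = []
    for i, ph in enumerate(phenotypes):
        did = f"d{i:06d}"
        if ph.n_cells_in_droplet is not None:
            n_cells = int(ph.n_cells_in_droplet)
        else:
            n_cells = int(rng.poisson(chamber.lambda_occupancy))
        has_cell = n_cells >= 1

        # A647: exponential decay for NOX-active occupied droplets
        if has_cell and ph.nox_active and ph.terminal_loss_pct > 0:
            k = _decay_rate(ph.terminal_loss_pct, t_last)
            a647 = A647_BASE * np.exp(-k * times)
        else:
            a647 = np.full_like(times, A647_BASE)

        # IgG relocation readout on the nanoparticle beadline
        igg_rate = ph.igg_rate if has_cell else 0.0
        conc_nm = igg_conc_nm_from_rate(igg_rate, times, constants)
        relocation = np.asarray(igg_curve.forward(conc_nm), dtype=float)
        beadline_a647 = relocation * a647

        # lactate probe intensity from accumulated concentration
        lac_rate = ph.lactate_rate if has_cell else 0.0
        conc_um = lactate_conc_um_from_rate(lac_rate, times, constants)
        lactate = np.asarray(lactate_curve.forward(conc_um), dtype=float)

        # intracellular ROS: linear rise of the cell signal
        if has_cell:
            ros_cell = ROS_CELL_BASE + ph.ros_slope * times / constants.ros_window_s
        else:
            ros_cell = np.zeros_like(times)
        ros_droplet = ROS_DISK_BG + n_cells * CELL_AREA_FRACTION * ros_cell

        stain_cell = np.full_like(times, CELLSTAIN_BLOB if has_cell else 0.0)
        stain_droplet = np.full_like(times, CELLSTAIN_DISK)

        per_channel = {
            CHANNEL_CELL_STAIN: (stain_droplet, stain_droplet, stain_cell),
            CHANNEL_LACTATE: (lactate, lactate, lactate),
            CHANNEL_ROS: (ros_droplet, ros_droplet, ros_cell),
            CHANNEL_A647: (a647, beadline_a647, a647),
        }
        for ch in acq.channels:
            dm, bm, cm = per_channel[ch]
            sd = acq.channel_noise(ch)
            if sd > 0:
                dm = np.maximum(dm + rng.normal(0, sd, dm.shape), 0.0)
                bm = np.maximum(bm + rng.normal(0, sd, bm.shape), 0.0)
                cm = np.maximum(cm + rng.normal(0, sd, cm.shape), 0.0)
            for f in range(acq.n_frames):
                rows.append(
                    (did, f, times[f], ch, dm[f], bm[f], cm[f], n_cells, "ok", condition)
                )
        truth_rows.append(
            {
                "droplet_id": did,
                "cell_id": ph.cell_id,
                "nox_active": ph.nox_active and has_cell,
                "terminal_loss_pct": ph.terminal_loss_pct if has_cell else 0.0,
                "igg_rate": igg_rate,
                "lactate_rate": lac_rate,
                "ros_slope": ph.ros_slope if has_cell else 0.0,
                "n_cells": n_cells,
                "condition": condition,
            }
        )

    traces = pd.DataFrame(
        rows,
        columns=[
            "droplet_id", "frame", "time_s", "channel",
            "droplet_mean", "beadline_mean", "cell_mean",
            "n_cells", "track_quality", "condition",
        ],
    )
    return traces, pd.DataFrame(truth_rows)


# ---------------------------------------------------------------------------
# image rendering


@dataclass
class ImageSeries:
    """Rendered chamber: per-channel (T, H, W) uint16 stacks plus layout
    metadata and pixel-level ground truth."""

    images: dict[str, np.ndarray]
    layout: dict
    truth: pd.DataFrame  # droplet_id, row, col, radius_px, edge_flag, n_cells
    cells: pd.DataFrame  # droplet_id, row, col

    def write(self, outdir: str | Path) -> None:
        import tifffile

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for ch, stack in self.images.items():
            for t in range(stack.shape[0]):
                tifffile.imwrite(outdir / f"ch_{ch}_t{t:02d}.tif", stack[t])
        with open(outdir / "layout.json", "w") as fh:
            json.dump(self.layout, fh, indent=1)
        self.truth.to_csv(outdir / "pixel_truth.tsv", sep="\t", index=False)
        self.cells.to_csv(outdir / "cell_truth.tsv", sep="\t", index=False)


def _disk_coords(r0: int, c0: int, radius: int, shape) -> tuple[np.ndarray, np.ndarray]:
    from skimage.draw import disk

    return disk((r0, c0), radius, shape=shape)


def _place_droplets(
    n: int, radius: int, rng: np.random.Generator, max_dim: int = 4096
) -> tuple[np.ndarray, int, int]:
    pitch = 2 * radius + 6
    ncols = math.ceil(math.sqrt(n))
    nrows = math.ceil(n / ncols)
    width = (ncols + 1) * pitch
    height = (nrows + 1) * pitch
    if width > max_dim or height > max_dim:
        raise ValueError(
            f"cannot place {n} droplets of radius {radius} within a "
            f"{max_dim}x{max_dim} px chamber"
        )
    pos = np.empty((n, 2), dtype=float)
    i = 0
    for r in range(nrows):
        for c in range(ncols):
            if i >= n:
                break
            # jittered hexagonal-ish packing: odd rows offset half a pitch
            off = pitch // 2 if r % 2 else 0
            pos[i] = (
                (r + 0.75) * pitch + rng.uniform(-1.5, 1.5),
                (c + 0.65) * pitch + off + rng.uniform(-1.5, 1.5),
            )
            i += 1
    return pos, height, width


def generate_image_series(
    traces: pd.DataFrame,
    chamber: ChamberSpec,
    acq: AcquisitionSpec,
    seed: int = 0,
    outdir: str | Path | None = None,
) -> ImageSeries:
    """Render the simulated traces as multi-channel 16-bit image stacks.

    Droplets are filled disks on a jittered grid (static across frames);
    cells are Gaussian blobs in the cell-stain channel and small flat
    disks in the ROS channel; the IgG beadline is a short bright segment
    at droplet center in the A647 channel. Background pixels inside each
    disk are compensated so the disk-mean intensity of every channel
    equals the input trace value to within quantization.
    """
    rng = np.random.default_rng(seed)
    ids = traces["droplet_id"].drop_duplicates().to_numpy()
    n = len(ids)
    radius = chamber.droplet_radius_px
    pos, H, W = _place_droplets(n, radius, rng)

    # tile boundaries of the stitched 10x10 (default) acquisition array;
    # a grid whose tiles are smaller than a few droplets is meaningless
    # (tiny test chambers), so tile lines apply only above that scale
    gr, gc = chamber.tile_grid
    row_lines = [H * i / gr for i in range(1, gr)] if H / gr >= 4 * radius else []
    col_lines = [W * j / gc for j in range(1, gc)] if W / gc >= 4 * radius else []

    def near_line(v: float, lines) -> bool:
        return any(abs(v - L) <= radius + 1 for L in lines)

    edge = np.array(
        [
            near_line(p[0], row_lines)
            or near_line(p[1], col_lines)
            or p[0] < radius + 1
            or p[0] > H - radius - 2
            or p[1] < radius + 1
            or p[1] > W - radius - 2
            for p in pos
        ]
    )

    wide = traces.pivot_table(
        index=["droplet_id", "frame"],
        columns="channel",
        values=["droplet_mean", "beadline_mean", "cell_mean"],
        sort=False,
    )
    n_cells = traces.groupby("droplet_id", sort=False)["n_cells"].first()

    # fixed cell positions inside each droplet (static chamber)
    cell_rows = []
    cell_pos: dict[str, np.ndarray] = {}
    for i, did in enumerate(ids):
        k = int(n_cells[did])
        pts = []
        while len(pts) < k:
            ang = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(0, 0.5 * radius)
            p = (pos[i, 0] + rad * math.sin(ang), pos[i, 1] + rad * math.cos(ang))
            if all((p[0] - q[0]) ** 2 + (p[1] - q[1]) ** 2 > 25 for q in pts):
                pts.append(p)
        cell_pos[did] = np.array(pts).reshape(-1, 2)
        for p in pts:
            cell_rows.append({"droplet_id": did, "row": p[0], "col": p[1]})

    disk_cache = [
        _disk_coords(int(round(p[0])), int(round(p[1])), radius, (H, W)) for p in pos
    ]
    vmax = 2 ** acq.bit_depth - 1
    images: dict[str, np.ndarray] = {}
    for ch in acq.channels:
        stack = np.zeros((acq.n_frames, H, W), dtype=np.uint16)
        for t in range(acq.n_frames):
            frame = np.zeros((H, W), dtype=float)
            for i, did in enumerate(ids):
                rr, cc = disk_cache[i]
                npix = rr.size
                target = float(wide.loc[(did, t), ("droplet_mean", ch)])
                if ch == CHANNEL_A647:
                    bead = float(wide.loc[(did, t), ("beadline_mean", ch)])
                    r0 = int(round(pos[i, 0]))
                    c0 = int(round(pos[i, 1]))
                    half = radius // 2
                    br = np.repeat([r0 - 1, r0], 2 * half + 1)
                    bc = np.tile(np.arange(c0 - half, c0 + half + 1), 2)
                    nb = br.size
                    bg = (target * npix - bead * nb) / (npix - nb)
                    frame[rr, cc] = max(bg, 0.0)
                    frame[br, bc] = bead
                elif ch == CHANNEL_CELL_STAIN and len(cell_pos[did]):
                    blob = np.zeros(npix)
                    for p in cell_pos[did]:
                        d2 = (rr - p[0]) ** 2 + (cc - p[1]) ** 2
                        blob += CELLSTAIN_BLOB * np.exp(-d2 / (2 * 1.5**2))
                    bg = (target * npix - blob.sum()) / npix
                    frame[rr, cc] = np.maximum(bg + blob, 0.0)
                elif ch == CHANNEL_ROS and len(cell_pos[did]):
                    cm = float(wide.loc[(did, t), ("cell_mean", ch)])
                    inside = np.zeros(npix, dtype=bool)
                    for p in cell_pos[did]:
                        d2 = (rr - p[0]) ** 2 + (cc - p[1]) ** 2
                        inside |= d2 <= CELL_RADIUS_PX**2
                    nc = int(inside.sum())
                    bg = (target * npix - cm * nc) / max(npix - nc, 1)
                    vals = np.full(npix, max(bg, 0.0))
                    vals[inside] = cm
                    frame[rr, cc] = vals
                else:
                    frame[rr, cc] = target
            stack[t] = np.clip(np.rint(frame), 0, vmax).astype(np.uint16)
        images[ch] = stack

    truth = pd.DataFrame(
        {
            "droplet_id": ids,
            "row": pos[:, 0],
            "col": pos[:, 1],
            "radius_px": radius,
            "edge_flag": edge,
            "n_cells": n_cells.loc[ids].to_numpy(),
        }
    )
    layout = {
        "height": H,
        "width": W,
        "tile_grid": list(chamber.tile_grid),
        "row_lines": row_lines,
        "col_lines": col_lines,
        "n_frames": acq.n_frames,
        "interval_s": acq.interval_s,
        "channels": list(acq.channels),
    }
    series = ImageSeries(images, layout, truth, pd.DataFrame(cell_rows, columns=["droplet_id", "row", "col"]))
    if outdir is not None:
        series.write(outdir)
    return series


# ---------------------------------------------------------------------------
# calibration standards


def generate_calibration_standards(
    curve: CalibrationCurve,
    concentrations,
    replicates: int = 3,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Standards table (concentration, readout, replicate) from a forward
    calibration model plus Gaussian readout noise."""
    conc = np.asarray(concentrations, dtype=float)
    if conc.size == 0:
        raise ValueError("empty concentration list")
    if np.any(conc < 0):
        raise ValueError("concentrations must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        readout = np.asarray(curve.forward(conc), dtype=float)
        if noise_sd > 0:
            readout = readout + rng.normal(0, noise_sd, readout.shape)
        for c, r in zip(conc, readout):
            rows.append({"concentration": c, "readout": r, "replicate": rep})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# expression matrices

#: day-0-like splenic B-cell composition; germinal-center fraction 0.34
DEFAULT_COMPOSITION = {
    "gcbc": 0.34,
    "plasma_cell": 0.09,
    "mbc": 0.09,
    "activated_b": 0.11,
    "naive_b": 0.03,
    "immature_b": 0.34,
}

DEFAULT_ZONE_SPLIT = {"gc_dz": 0.61, "gc_lz": 0.39}
DEFAULT_PC_STATES = {
    "mature_pc": 0.37,
    "apoptotic_pc": 0.38,
    "immature_pc": 0.15,
    "plasmablast": 0.10,
}


def generate_rna_matrix(
    composition: dict[str, float] | None = None,
    marker_config: dict | None = None,
    nox_positive_fraction: float | dict[str, float] = 0.0,
    n_cells: int = 5000,
    seed: int = 0,
    noise_sd: float = 0.25,
    n_filler_genes: int = 200,
    ighg_fraction: float = 0.5,
    day: str = "day0",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cells x genes log2-fold-change matrix with planted annotations.

    Each cell's own subset markers are shifted up (~+2 log2FC); NOX
    gene-set values are > 0 for at least one gene in planted NOX-positive
    cells and <= 0 for all genes otherwise; housekeeping and filler genes
    are zero-mean noise. Returns ``(matrix, truth)``.
    """
    from .rna import NOX_GENE_SET, HOUSEKEEPING_GENES, default_marker_config

    rng = np.random.default_rng(seed)
    marker_config = marker_config or default_marker_config()
    subsets_cfg = marker_config["subsets"]
    composition = composition or DEFAULT_COMPOSITION
    unknown = set(composition) - set(subsets_cfg)
    if unknown:
        raise ValueError(f"unknown subsets in composition: {sorted(unknown)}")
    total = sum(composition.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"composition fractions must sum to 1, got {total}")

    zones = marker_config.get("gc_zones", {})
    pc_states = marker_config.get("pc_states", {})
    genes: list[str] = []
    for block in (subsets_cfg, zones, pc_states):
        for gl in block.values():
            genes.extend(g for g in gl if g not in genes)
    for g in list(NOX_GENE_SET) + list(HOUSEKEEPING_GENES) + ["IGHG1"]:
        if g not in genes:
            genes.append(g)
    genes.extend(f"GENE{i:04d}" for i in range(n_filler_genes))
    gidx = {g: j for j, g in enumerate(genes)}

    subset_names = list(composition)
    probs = np.array([composition[s] for s in subset_names])
    subset_of = rng.choice(len(subset_names), size=n_cells, p=probs)

    mat = rng.normal(0.0, noise_sd, (n_cells, len(genes))) if noise_sd > 0 else np.zeros((n_cells, len(genes)))
    truth_rows = []
    zone_names = list(DEFAULT_ZONE_SPLIT)
    zone_p = np.array(list(DEFAULT_ZONE_SPLIT.values()))
    pc_names = list(DEFAULT_PC_STATES)
    pc_p = np.array(list(DEFAULT_PC_STATES.values()))

    for i in range(n_cells):
        subset = subset_names[subset_of[i]]
        for g in subsets_cfg[subset]:
            mat[i, gidx[g]] += rng.uniform(1.5, 2.5)

        if isinstance(nox_positive_fraction, dict):
            p_pos = nox_positive_fraction.get(subset, 0.0)
        else:
            p_pos = float(nox_positive_fraction)
        nox_pos = bool(rng.random() < p_pos)
        set_vals = rng.uniform(-0.8, 0.0, len(NOX_GENE_SET))
        if nox_pos:
            n_up = int(rng.integers(1, 4))
            up = rng.choice(len(NOX_GENE_SET), size=n_up, replace=False)
            set_vals[up] = rng.uniform(0.3, 1.2, n_up)
        for g, v in zip(NOX_GENE_SET, set_vals):
            mat[i, gidx[g]] = v

        zone = ""
        pc_state = ""
        if subset == "gcbc" and zones:
            zone = zone_names[int(rng.choice(len(zone_names), p=zone_p))]
            for g in zones[zone]:
                mat[i, gidx[g]] += rng.uniform(1.5, 2.5)
        if subset == "plasma_cell" and pc_states:
            pc_state = pc_names[int(rng.choice(len(pc_names), p=pc_p))]
            for g in pc_states[pc_state]:
                mat[i, gidx[g]] += rng.uniform(1.5, 2.5)

        ighg = subset == "plasma_cell" and rng.random() < ighg_fraction
        if ighg:
            mat[i, gidx["IGHG1"]] += rng.uniform(1.5, 2.5)

        truth_rows.append(
            {
                "cell_id": f"c{i:06d}",
                "subset": subset,
                "nox_mrna": "pos" if nox_pos else "neg",
                "zone": zone,
                "pc_state": pc_state,
                "ighg_expresser": ighg,
                "day": day,
            }
        )

    truth = pd.DataFrame(truth_rows)
    matrix = pd.DataFrame(mat, index=truth["cell_id"], columns=genes)
    return matrix, truth
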