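"""On-disk formats: EMG CSV + sidecar metadata, SWC reconstructions with
per-neuron and per-spine CSV tables, and multi-page TIFF histology fields
with ROI/cell CSVs.

All tabular formats are plain delimited text.  SWC follows the v1
convention: one node per line (``id type x y z radius parent``), soma as
type 1, dendrites as type 3, coordinates and radii in µm.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ConfigurationError
from .histology import CellRecord, HistologyField
from .protocol import EMGSweep
from .spines import Branch, NeuronReconstruction, SpineAnnotation

# --------------------------------------------------------------------------
# EMG cohorts
# --------------------------------------------------------------------------

EMG_CSV = "emg.csv"
EMG_META = "emg_meta.yaml"


def write_emg_cohort(
    cohort: dict[str, dict[float, list[EMGSweep]]], out_dir: str | Path
) -> Path:
    """Write a cohort as a long-format CSV plus a YAML sidecar.

    CSV columns: ``animal_id, interval_ms, trial, sweep, sample_idx, mv``
    (trial groups 10 sweeps).  The sidecar records the sampling rate,
    stimulus intensity and per-interval onset indices.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    frames = []
    meta_intervals: dict[float, dict] = {}
    sampling_rate = None
    intensity = None
    for animal_id in sorted(cohort):
        for iv in sorted(cohort[animal_id]):
            sweeps = cohort[animal_id][iv]
            for k, sw in enumerate(sweeps):
                sampling_rate = sw.sampling_rate_hz
                intensity = sw.intensity_T
                meta_intervals[float(iv)] = {
                    "control_onset_idx": int(sw.control_onset_idx),
                    "test_onset_idx": int(sw.test_onset_idx),
                    "n_samples": int(sw.samples.size),
                }
                frames.append(
                    pd.DataFrame(
                        {
                            "animal_id": animal_id,
                            "interval_ms": iv,
                            "trial": k // 10 + 1,
                            "sweep": k % 10 + 1,
                            "sample_idx": np.arange(sw.samples.size),
                            "mv": sw.samples,
                        }
                    )
                )
    if not frames:
        raise ConfigurationError("empty cohort")
    pd.concat(frames, ignore_index=True).to_csv(out / EMG_CSV, index=False, float_format="%.10g")
    meta = {
        "sampling_rate_hz": float(sampling_rate),
        "intensity_T": float(intensity),
        "intervals": {float(k): v for k, v in sorted(meta_intervals.items())},
    }
    (out / EMG_META).write_text(yaml.safe_dump(meta, sort_keys=True))
    return out


def read_emg_cohort(in_dir: str | Path) -> dict[str, dict[float, list[EMGSweep]]]:
    """Read a cohort written by :func:`write_emg_cohort`."""
    in_dir = Path(in_dir)
    meta = yaml.safe_load((in_dir / EMG_META).read_text())
    df = pd.read_csv(in_dir / EMG_CSV)
    fs = float(meta["sampling_rate_hz"])
    intensity = float(meta["intensity_T"])
    cohort: dict[str, dict[float, list[EMGSweep]]] = {}
    for (animal_id, iv), sub in df.groupby(["animal_id", "interval_ms"], sort=True):
        ivm = meta["intervals"][float(iv)]
        sweeps = []
        for (_, _), ssub in sub.groupby(["trial", "sweep"], sort=True):
            ssub = ssub.sort_values("sample_idx")
            sweeps.append(
                EMGSweep(
                    samples=ssub.mv.to_numpy(dtype=float),
                    sampling_rate_hz=fs,
                    control_onset_idx=int(ivm["control_onset_idx"]),
                    test_onset_idx=int(ivm["test_onset_idx"]),
                    intensity_T=intensity,
                )
            )
        cohort.setdefault(str(animal_id), {})[float(iv)] = sweeps
    return cohort


# --------------------------------------------------------------------------
# Neuron reconstructions (SWC + CSV)
# --------------------------------------------------------------------------

NEURONS_CSV = "neurons.csv"
SPINES_CSV = "spines.csv"


def write_swc(neuron: NeuronReconstruction, path: str | Path) -> None:
    """Write one reconstruction as SWC (soma type 1, dendrites type 3)."""
    lines = ["# id type x y z radius parent"]
    soma_radius = neuron.soma_max_diameter_um / 2.0
    lines.append(f"1 1 0 0 0 {soma_radius:.4f} -1")
    next_id = 2
    for branch in neuron.branches:
        parent = 1
        for pt in branch.points[1:]:  # first point sits at the soma
            lines.append(
                f"{next_id} 3 {pt[0]:.4f} {pt[1]:.4f} {pt[2]:.4f} 0.5000 {parent}"
            )
            parent = next_id
            next_id += 1
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path: str | Path) -> list[Branch]:
    """Read an SWC file into branches rooted at the soma.

    Each child of the soma node starts a branch; branch ids are assigned in
    node order (``b00``, ``b01``, ...), matching the writer's convention.
    """
    nodes: dict[int, tuple[int, np.ndarray, int]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        nid, ntype = int(parts[0]), int(parts[1])
        xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
        parent = int(parts[6])
        nodes[nid] = (ntype, xyz, parent)
    soma_ids = [nid for nid, (t, _, _) in nodes.items() if t == 1]
    if not soma_ids:
        raise ConfigurationError(f"{path}: SWC file has no soma (type 1) node")
    soma = soma_ids[0]
    children: dict[int, list[int]] = {}
    for nid, (_, _, parent) in nodes.items():
        children.setdefault(parent, []).append(nid)
    branches = []
    for b, start in enumerate(sorted(children.get(soma, []))):
        pts = [nodes[soma][1]]
        nid = start
        while True:
            pts.append(nodes[nid][1])
            nxt = sorted(children.get(nid, []))
            if not nxt:
                break
            nid = nxt[0]
        branches.append(Branch(branch_id=f"b{b:02d}", points=np.array(pts)))
    return branches


def write_neuron_cohort(
    cohort: list[tuple[NeuronReconstruction, list[SpineAnnotation]]],
    out_dir: str | Path,
) -> Path:
    """Write a cohort as per-neuron SWC files plus neuron and spine CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    neuron_rows, spine_rows = [], []
    for neuron, spines in cohort:
        write_swc(neuron, out / f"{neuron.neuron_id}.swc")
        neuron_rows.append(
            {
                "neuron_id": neuron.neuron_id,
                "soma_area_um2": neuron.soma_area_um2,
                "soma_max_diameter_um": neuron.soma_max_diameter_um,
                "soma_min_diameter_um": neuron.soma_min_diameter_um,
                "lamina_IX": neuron.lamina_IX,
                "soma_visible": neuron.soma_visible,
            }
        )
        for s in spines:
            spine_rows.append(
                {
                    "neuron_id": s.neuron_id,
                    "branch_id": s.branch_id,
                    "distance_um": s.distance_um,
                    "spine_length_um": s.spine_length_um,
                    "neck_length_um": s.neck_length_um,
                    "head_diameter_um": s.head_diameter_um,
                }
            )
    pd.DataFrame(neuron_rows).to_csv(out / NEURONS_CSV, index=False, float_format="%.10g")
    pd.DataFrame(
        spine_rows,
        columns=["neuron_id", "branch_id", "distance_um", "spine_length_um",
                 "neck_length_um", "head_diameter_um"],
    ).to_csv(out / SPINES_CSV, index=False, float_format="%.10g")
    return out


def read_neuron_cohort(
    in_dir: str | Path,
) -> list[tuple[NeuronReconstruction, list[SpineAnnotation]]]:
    """Read SWC files + neuron/spine CSVs written by
    :func:`write_neuron_cohort`.  Spines referencing a branch id absent from
    the reconstruction (orphan branches) raise an error."""
    in_dir = Path(in_dir)
    neurons_df = pd.read_csv(in_dir / NEURONS_CSV)
    spines_path = in_dir / SPINES_CSV
    spines_df = pd.read_csv(spines_path) if spines_path.exists() else pd.DataFrame()
    cohort = []
    for _, row in neurons_df.iterrows():
        nid = str(row.neuron_id)
        branches = read_swc(in_dir / f"{nid}.swc")
        neuron = NeuronReconstruction(
            neuron_id=nid,
            soma_area_um2=float(row.soma_area_um2),
            soma_max_diameter_um=float(row.soma_max_diameter_um),
            soma_min_diameter_um=float(row.soma_min_diameter_um),
            lamina_IX=bool(row.lamina_IX),
            soma_visible=bool(row.soma_visible),
            branches=branches,
        )
        spines = []
        if not spines_df.empty:
            known = {b.branch_id for b in branches}
            for _, srow in spines_df[spines_df.neuron_id == nid].iterrows():
                if str(srow.branch_id) not in known:
                    raise ConfigurationError(
                        f"spine references orphan branch {srow.branch_id!r} of neuron {nid}"
                    )
                spines.append(
                    SpineAnnotation(
                        neuron_id=nid,
                        branch_id=str(srow.branch_id),
                        distance_um=float(srow.distance_um),
                        spine_length_um=float(srow.spine_length_um),
                        neck_length_um=float(srow.neck_length_um),
                        head_diameter_um=float(srow.head_diameter_um),
                    )
                )
        cohort.append((neuron, spines))
    return cohort


# --------------------------------------------------------------------------
# Histology fields
# --------------------------------------------------------------------------

FIELD_TIF = "field.tif"
ROI_CSV = "roi.csv"
CELLS_CSV = "cells.csv"
FIELD_META = "field_meta.yaml"


def write_histology_field(fld: HistologyField, out_dir: str | Path) -> Path:
    """Write a field as a multi-page TIFF (one page per channel, channel
    order recorded in the sidecar) plus ROI polygon and cell-record CSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    names = sorted(fld.channels)
    stack = np.stack([fld.channels[n].astype(np.float32) for n in names])
    tifffile.imwrite(out / FIELD_TIF, stack, photometric="minisblack")
    pd.DataFrame(fld.roi, columns=["row", "col"]).to_csv(
        out / ROI_CSV, index=False, float_format="%.10g"
    )
    pd.DataFrame(
        [
            {
                "row": c.centroid[0],
                "col": c.centroid[1],
                "chat_positive": c.chat_positive,
                "tdtomato_positive": c.tdtomato_positive,
            }
            for c in fld.cell_records
        ],
        columns=["row", "col", "chat_positive", "tdtomato_positive"],
    ).to_csv(out / CELLS_CSV, index=False, float_format="%.10g")
    meta = {
        "channels": names,
        "pixel_size_um": float(fld.pixel_size_um),
        "background": float(fld.background),
        "suggested_threshold": float(fld.suggested_threshold),
    }
    (out / FIELD_META).write_text(yaml.safe_dump(meta, sort_keys=True))
    return out


def read_histology_field(in_dir: str | Path) -> HistologyField:
    in_dir = Path(in_dir)
    meta = yaml.safe_load((in_dir / FIELD_META).read_text())
    stack = tifffile.imread(in_dir / FIELD_TIF)
    if stack.ndim == 2:
        stack = stack[None]
    channels = {name: stack[i].astype(float) for i, name in enumerate(meta["channels"])}
    roi = pd.read_csv(in_dir / ROI_CSV).to_numpy(dtype=float)
    cells_df = pd.read_csv(in_dir / CELLS_CSV)
    cells = [
        CellRecord(
            centroid=(float(r.row), float(r.col)),
            chat_positive=bool(r.chat_positive),
            tdtomato_positive=bool(r.tdtomato_positive),
        )
        for r in cells_df.itertuples()
    ]
    return HistologyField(
        channels=channels,
        roi=roi,
        cell_records=cells,
        pixel_size_um=float(meta["pixel_size_um"]),
        background=float(meta["background"]),
        suggested_threshold=float(meta["suggested_threshold"]),
    )
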