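"""Dendritic spine morphometry on reconstructed alpha-motor neurons.

Takes finished neuron reconstructions (soma geometry plus dendritic
polylines) and per-spine annotations, screens neurons against the
alpha-motor-neuron inclusion criteria, classifies each spine as *thin*
(head diameter <= neck length) or *mushroom* (head diameter > neck length),
and computes spine densities (spines per µm of dendrite), Sholl regional
profiles in 40-µm bins from the soma, and spine-size summaries.

Distances are geodesic path lengths along the dendrite, in µm.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, ReflexMorphError

#: Half-open Sholl bins (µm from the soma along the dendrite).
SHOLL_BINS: tuple[tuple[float, float], ...] = ((0.0, 40.0), (40.0, 80.0), (80.0, 120.0))
SHOLL_BIN_NAMES: tuple[str, ...] = ("proximal", "medial", "distal")
SPINE_CLASSES: tuple[str, ...] = ("thin", "mushroom")

#: Inclusion thresholds for alpha-motor neurons (strict inequalities).
MIN_SOMA_DIAMETER_UM = 25.0
MIN_SOMA_AREA_UM2 = 450.0


@dataclass
class Branch:
    """One dendritic branch as a 3-D polyline rooted at the soma."""

    branch_id: str
    points: np.ndarray  # (k, 3) coordinates in µm; first point at the soma

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or self.points.shape[0] < 2:
            raise ConfigurationError("a branch needs at least two 3-D points")

    @property
    def arc_lengths_um(self) -> np.ndarray:
        """Cumulative geodesic distance from the soma at each node."""
        seg = np.linalg.norm(np.diff(self.points, axis=0), axis=1)
        return np.concatenate([[0.0], np.cumsum(seg)])

    @property
    def length_um(self) -> float:
        return float(self.arc_lengths_um[-1])


@dataclass
class NeuronReconstruction:
    neuron_id: str
    soma_area_um2: float
    soma_max_diameter_um: float
    soma_min_diameter_um: float
    lamina_IX: bool
    soma_visible: bool
    branches: list[Branch] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.soma_max_diameter_um < self.soma_min_diameter_um:
            raise ConfigurationError("soma max diameter must be >= min diameter")

    @property
    def total_dendrite_length_um(self) -> float:
        return float(sum(b.length_um for b in self.branches))


@dataclass
class SpineAnnotation:
    """One dendritic spine.

    ``spine_length_um`` is the distance from the dendrite to the tip of the
    spine head; ``head_diameter_um`` is the maximum diameter of the
    bulb-shaped head; ``neck_length_um`` the length of the neck between
    dendrite and head base.  The class label is derived solely from
    (head diameter, neck length).
    """

    neuron_id: str
    branch_id: str
    distance_um: float
    spine_length_um: float
    neck_length_um: float
    head_diameter_um: float

    def __post_init__(self) -> None:
        if self.distance_um < 0:
            raise ConfigurationError("spine distance from soma must be >= 0")
        if self.spine_length_um < 0 or self.neck_length_um < 0:
            raise ConfigurationError("spine and neck lengths must be >= 0")

    @property
    def spine_class(self) -> str:
        return classify_spine(self.head_diameter_um, self.neck_length_um)


def classify_spine(head_diameter_um: float, neck_length_um: float) -> str:
    """Thin/mushroom rule: thin iff head diameter <= neck length.

    Mushroom spines have a head wider than their neck is long; the tie goes
    to thin.  Only these two classes are distinguished.
    """
    if head_diameter_um <= 0:
        raise ConfigurationError("head diameter must be positive")
    if neck_length_um < 0:
        raise ConfigurationError("neck length must be >= 0")
    return "thin" if head_diameter_um <= neck_length_um else "mushroom"


def apply_inclusion(neuron: NeuronReconstruction) -> tuple[bool, list[str]]:
    """Screen one reconstruction against the alpha-motor-neuron criteria.

    A neuron is included iff it sits in lamina IX, has a visible cell body,
    soma max diameter > 25 µm, soma cross-sectional area > 450 µm², and more
    than one dendritic branch.  Returns the verdict and every failed
    criterion (empty list when included).
    """
    for name in ("soma_area_um2", "soma_max_diameter_um", "lamina_IX", "soma_visible"):
        if getattr(neuron, name, None) is None:
            raise ConfigurationError(f"neuron {neuron.neuron_id}: missing field {name}")
    reasons = []
    if not neuron.lamina_IX:
        reasons.append("not located in lamina IX")
    if not neuron.soma_visible:
        reasons.append("cell body not visible")
    if not neuron.soma_max_diameter_um > MIN_SOMA_DIAMETER_UM:
        reasons.append("diameter not > 25 µm")
    if not neuron.soma_area_um2 > MIN_SOMA_AREA_UM2:
        reasons.append("cross-sectional area not > 450 µm²")
    if len(neuron.branches) < 2:
        reasons.append("not more than one dendritic branch")
    return (len(reasons) == 0, reasons)


def spine_density(spine_count: int, dendrite_length_um: float) -> float:
    """Spines per µm of dendrite."""
    if dendrite_length_um <= 0:
        raise ConfigurationError("dendrite length must be positive")
    if spine_count < 0:
        raise ConfigurationError("spine count must be >= 0")
    return spine_count / dendrite_length_um


def _dendrite_length_in_bins(neuron: NeuronReconstruction) -> np.ndarray:
    """Dendritic length (µm) of the neuron inside each Sholl bin."""
    out = np.zeros(len(SHOLL_BINS))
    for b in neuron.branches:
        L = b.length_um
        for i, (lo, hi) in enumerate(SHOLL_BINS):
            out[i] += max(0.0, min(L, hi) - lo)
    return out


@dataclass
class ShollProfile:
    """Per-bin spine counts, dendritic lengths, and densities, by class.

    Bins are half-open ([0,40), [40,80), [80,120) µm); a spine at exactly
    40 µm falls in the medial bin.  Spines at >= 120 µm are excluded from
    the profile (but kept in whole-neuron totals).  Densities are NaN where
    a neuron has no dendrite in a bin.
    """

    neuron_id: str
    bin_lengths_um: np.ndarray
    counts: dict[str, np.ndarray]  # keys: total, thin, mushroom -> (3,) ints

    def density(self, spine_class: str = "total") -> np.ndarray:
        c = self.counts[spine_class].astype(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            d = np.where(self.bin_lengths_um > 0, c / self.bin_lengths_um, np.nan)
        return d

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, name in enumerate(SHOLL_BIN_NAMES):
            rows.append(
                {
                    "neuron_id": self.neuron_id,
                    "region": name,
                    "bin_length_um": self.bin_lengths_um[i],
                    **{f"count_{c}": int(self.counts[c][i]) for c in ("total", *SPINE_CLASSES)},
                    **{f"density_{c}": self.density(c)[i] for c in ("total", *SPINE_CLASSES)},
                }
            )
        return pd.DataFrame(rows)


def sholl_profile(
    neuron: NeuronReconstruction, spines: list[SpineAnnotation]
) -> ShollProfile:
    """Regional spine-density profile in 40-µm bins from the soma."""
    lengths = _dendrite_length_in_bins(neuron)
    counts = {c: np.zeros(len(SHOLL_BINS), dtype=int) for c in ("total", *SPINE_CLASSES)}
    for s in spines:
        if s.distance_um < 0:
            raise ConfigurationError("negative spine distance")
        for i, (lo, hi) in enumerate(SHOLL_BINS):
            if lo <= s.distance_um < hi:
                counts["total"][i] += 1
                counts[s.spine_class][i] += 1
                break
    return ShollProfile(neuron_id=neuron.neuron_id, bin_lengths_um=lengths, counts=counts)


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        return float("nan")
    return float(np.std(x, ddof=1) / np.sqrt(x.size))


def size_summary(spines: list[SpineAnnotation], pooling: str = "per_spine") -> pd.DataFrame:
    """Mean ± SEM of spine length and head width, total and per class.

    ``pooling='per_spine'`` pools all spines (the denominator is the spine
    count); ``pooling='per_neuron'`` averages within each neuron first and
    treats neurons as the unit of analysis.  Classes with no spines yield
    NaN, never zero.
    """
    if not spines:
        raise ConfigurationError("size_summary needs at least one spine")
    if pooling not in ("per_spine", "per_neuron"):
        raise ConfigurationError("pooling must be 'per_spine' or 'per_neuron'")
    df = pd.DataFrame(
        {
            "neuron_id": [s.neuron_id for s in spines],
            "spine_class": [s.spine_class for s in spines],
            "spine_length_um": [s.spine_length_um for s in spines],
            "head_diameter_um": [s.head_diameter_um for s in spines],
        }
    )
    rows = []
    for cls in ("total", *SPINE_CLASSES):
        sub = df if cls == "total" else df[df.spine_class == cls]
        if pooling == "per_neuron" and not sub.empty:
            sub = sub.groupby("neuron_id", as_index=False)[
                ["spine_length_um", "head_diameter_um"]
            ].mean()
        n = len(sub)
        rows.append(
            {
                "spine_class": cls,
                "n": n,
                "mean_length_um": sub.spine_length_um.mean() if n else np.nan,
                "sem_length_um": _sem(sub.spine_length_um.to_numpy()) if n else np.nan,
                "mean_head_um": sub.head_diameter_um.mean() if n else np.nan,
                "sem_head_um": _sem(sub.head_diameter_um.to_numpy()) if n else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("spine_class")


def summarize_neuron(
    neuron: NeuronReconstruction, spines: list[SpineAnnotation]
) -> dict[str, float]:
    """Whole-neuron spine densities (total/thin/mushroom) and counts."""
    length = neuron.total_dendrite_length_um
    by_class = {c: 0 for c in SPINE_CLASSES}
    for s in spines:
        by_class[s.spine_class] += 1
    total = sum(by_class.values())
    out = {
        "neuron_id": neuron.neuron_id,
        "dendrite_length_um": length,
        "n_spines": total,
        "density_total": spine_density(total, length),
    }
    for c in SPINE_CLASSES:
        out[f"n_{c}"] = by_class[c]
        out[f"density_{c}"] = spine_density(by_class[c], length)
    return out


def cohort_spine_table(
    cohort: list[tuple[NeuronReconstruction, list[SpineAnnotation]]],
    include_all: bool = False,
) -> pd.DataFrame:
    """Per-neuron density table over a cohort, after inclusion screening."""
    rows = []
    for neuron, spines in cohort:
        included, reasons = apply_inclusion(neuron)
        if not included and not include_all:
            continue
        row = summarize_neuron(neuron, spines)
        row["included"] = included
        row["exclusion_reasons"] = "; ".join(reasons)
        rows.append(row)
    if not rows:
        raise ReflexMorphError("no neuron passed the inclusion screen")
    return pd.DataFrame(rows)


def neuron_summary(
    cohort: list[tuple[NeuronReconstruction, list[SpineAnnotation]]] | list[NeuronReconstruction],
) -> pd.Series:
    """Group mean ± SEM of soma area, max/min diameter, total dendrite length.

    Accepts either reconstructions or (reconstruction, spines) pairs; only
    neurons passing the inclusion screen contribute.
    """
    neurons = [item[0] if isinstance(item, tuple) else item for item in cohort]
    neurons = [n for n in neurons if apply_inclusion(n)[0]]
    if not neurons:
        raise ReflexMorphError("neuron_summary: empty group after inclusion screening")
    fields = {
        "soma_area_um2": [n.soma_area_um2 for n in neurons],
        "soma_max_diameter_um": [n.soma_max_diameter_um for n in neurons],
        "soma_min_diameter_um": [n.soma_min_diameter_um for n in neurons],
        "total_dendrite_length_um": [n.total_dendrite_length_um for n in neurons],
    }
    out = {"n_neurons": len(neurons)}
    for k, v in fields.items():
        arr = np.asarray(v, dtype=float)
        out[f"{k}_mean"] = float(arr.mean())
        out[f"{k}_sem"] = _sem(arr)
    return pd.Series(out)
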