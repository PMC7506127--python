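"""DVH computation and dose-volume plan metrics.

Implements the evaluation endpoints of a three-way MR-linac plan
comparison: cumulative DVHs, Vp (percent of a target covered by its
prescription), Dq% point doses, Dmax/Dmean, the homogeneity index

    HI = (D2% - D98%) / D50%

(0 is perfectly homogeneous; reported as a fraction), and the
van't Riet conformity index

    CI = TV_PTV^2 / (V_PTV * TV)

where TV is the treated volume of the prescription isodose (clipped to
the body, since Monte Carlo grids deposit dose in the surrounding air)
and TV_PTV its overlap with the target.  CI is 1 for perfect conformity.

Dmax is the single hottest voxel; Dmean the arithmetic in-mask mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterator, Mapping, Optional

import numpy as np

from .grid import DoseGrid, StructureMask, StructureSet, _check_same_grid

__all__ = [
    "DVH",
    "MetricSet",
    "compute_dvh",
    "dose_at_volume",
    "volume_at_dose",
    "homogeneity_index",
    "conformity_index",
    "extract_plan_metrics",
    "PQM_METRIC_IDS",
]


@dataclass(frozen=True)
class DVH:
    """Cumulative dose-volume histogram of one structure.

    ``cumulative_volume_fraction[i]`` is the fraction of the structure
    volume receiving at least ``bin_edges_Gy[i]``; it is 1.0 at 0 Gy and
    non-increasing.
    """

    structure: str
    bin_edges_Gy: np.ndarray
    cumulative_volume_fraction: np.ndarray
    total_volume_cc: float

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges_Gy, dtype=np.float64)
        cum = np.asarray(self.cumulative_volume_fraction, dtype=np.float64)
        if edges.ndim != 1 or edges.shape != cum.shape:
            raise ValueError("bin edges and cumulative curve must be 1-D and aligned")
        if np.any(np.diff(edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if np.any(np.diff(cum) > 1e-12):
            raise ValueError("cumulative volume fraction must be non-increasing")
        object.__setattr__(self, "bin_edges_Gy", edges)
        object.__setattr__(self, "cumulative_volume_fraction", cum)

    @property
    def bin_width_Gy(self) -> float:
        return float(self.bin_edges_Gy[1] - self.bin_edges_Gy[0])

    @property
    def mean_dose_Gy(self) -> float:
        """Mean dose reconstructed from the cumulative curve (bin midpoints)."""
        diff = -np.diff(self.cumulative_volume_fraction)
        mid = 0.5 * (self.bin_edges_Gy[:-1] + self.bin_edges_Gy[1:])
        return float(np.sum(diff * mid))


def compute_dvh(
    dose: DoseGrid, mask: StructureMask, bin_width_Gy: float = 0.01
) -> DVH:
    """Cumulative DVH from the multiset of in-mask voxel doses."""
    _check_same_grid(dose.grid, mask.grid)
    if mask.is_empty():
        raise ValueError(f"mask {mask.name!r} is empty")
    if bin_width_Gy <= 0:
        raise ValueError("bin_width_Gy must be positive")
    doses = np.sort(dose.values[mask.voxels])
    n = doses.size
    # edges start at 0 and extend past the hottest voxel so the curve closes at 0
    n_edges = int(np.ceil(max(doses[-1], 0.0) / bin_width_Gy)) + 2
    edges = bin_width_Gy * np.arange(n_edges)
    cum = 1.0 - np.searchsorted(doses, edges, side="left") / n
    return DVH(
        structure=mask.name,
        bin_edges_Gy=edges,
        cumulative_volume_fraction=cum,
        total_volume_cc=mask.volume_cc,
    )


def dose_at_volume(dvh: DVH, q_percent: float) -> float:
    """Dq%: the minimum dose received by the hottest q% of the structure.

    Linear interpolation on the cumulative curve; at plateaus the tie is
    broken toward the higher dose (conservative "hottest q%"), so for a
    two-voxel structure at 10 and 20 Gy, D50 is 20 Gy and D100 is 10 Gy.
    """
    if not 0 < q_percent <= 100:
        raise ValueError(f"q_percent must be in (0, 100], got {q_percent}")
    f = q_percent / 100.0
    cum = dvh.cumulative_volume_fraction
    edges = dvh.bin_edges_Gy
    at_least = np.nonzero(cum >= f - 1e-12)[0]
    if at_least.size == 0:  # q below the resolution of the top bin
        return float(edges[0])
    i = int(at_least[-1])
    if cum[i] <= f + 1e-12 or i == cum.size - 1:
        return float(edges[i])
    # strictly between two curve points: interpolate down the falling edge
    frac = (cum[i] - f) / (cum[i] - cum[i + 1])
    return float(edges[i] + frac * (edges[i + 1] - edges[i]))


def volume_at_dose(dvh: DVH, d_Gy: float) -> float:
    """Vd: percent of the structure volume receiving at least ``d_Gy``."""
    if d_Gy < 0:
        raise ValueError(f"d_Gy must be >= 0, got {d_Gy}")
    return float(
        100.0 * np.interp(d_Gy, dvh.bin_edges_Gy, dvh.cumulative_volume_fraction)
    )


def homogeneity_index(d2: float, d98: float, d50: float) -> float:
    """HI = (D2% - D98%) / D50%, as a fraction; 0 is perfectly homogeneous."""
    if d50 <= 0:
        raise ValueError(f"D50 must be positive, got {d50}")
    if d2 < d98 - 1e-9:
        raise ValueError(f"D2 ({d2}) must be >= D98 ({d98})")
    return float(max(d2 - d98, 0.0) / d50)


def conformity_index(
    target: StructureMask,
    dose: DoseGrid,
    prescription_Gy: float,
    body: StructureMask,
) -> float:
    """van't Riet CI of a target with respect to its prescription isodose.

    The treated volume TV is restricted to the body.  A vanishing TV
    (no voxel reaches the prescription) yields CI = 0.
    """
    _check_same_grid(target.grid, dose.grid)
    if prescription_Gy <= 0:
        raise ValueError("prescription_Gy must be positive")
    if not target.issubset(body):
        raise ValueError(f"target {target.name!r} is not contained in the body")
    treated = body.voxels & (dose.values >= prescription_Gy)
    tv = int(treated.sum())
    if tv == 0:
        return 0.0
    v_ptv = target.voxel_count
    tv_ptv = int((treated & target.voxels).sum())
    return float(tv_ptv**2 / (v_ptv * tv))


#: the 15 submetric identifiers scored by the plan-quality metric, in table order
PQM_METRIC_IDS = (
    "pgtv_tb:v_rx",
    "pgtv_tb:ci",
    "pgtv_tb:hi",
    "gtv_nd:v_rx",
    "gtv_nd:ci",
    "gtv_nd:hi",
    "ptv:v_rx",
    "ptv:ci",
    "ptv:hi",
    "brain_stem:d_max",
    "brain_stem_prv:d_max",
    "spinal_cord:d_max",
    "spinal_cord_prv:d_max",
    "parotids:d_mean",
    "normal_tissue:d_mean",
)


@dataclass
class MetricSet(Mapping):
    """Named scalar dosimetric parameters of one plan.

    Holds the 15 plan-quality submetrics plus the skin and air-interface
    Dmean/Dmax endpoints.  Values: Vp in percent, HI/CI as fractions,
    doses in Gy.
    """

    values: Dict[str, float] = field(default_factory=dict)

    def __getitem__(self, key: str) -> float:
        return self.values[key]

    def __iter__(self) -> Iterator[str]:
        return iter(self.values)

    def __len__(self) -> int:
        return len(self.values)

    def to_dict(self) -> Dict[str, float]:
        return dict(self.values)


_TARGET_STRUCTURES = ("pgtv_tb", "gtv_nd", "ptv")
_DMAX_STRUCTURES = ("brain_stem", "brain_stem_prv", "spinal_cord", "spinal_cord_prv")


def extract_plan_metrics(
    dose: DoseGrid,
    structs: StructureSet,
    prescriptions: Mapping[str, float],
    bin_width_Gy: float = 0.01,
    interface_names: Optional[tuple] = None,
) -> MetricSet:
    """Compute every evaluation endpoint of one plan.

    Parameters
    ----------
    prescriptions
        Map from target structure name to prescription dose in Gy
        (e.g. ``{"pgtv_tb": 69.96, "gtv_nd": 69.96, "ptv": 60.06}``).
    interface_names
        Air-interface shell structures to report Dmean/Dmax for; by
        default every structure whose name ends in ``"_interface"``.
    """
    required = (
        _TARGET_STRUCTURES
        + _DMAX_STRUCTURES
        + ("body", "parotid_l", "parotid_r", "normal_tissue", "skin")
    )
    structs.require(*required)
    missing_rx = [t for t in _TARGET_STRUCTURES if t not in prescriptions]
    if missing_rx:
        raise KeyError(f"prescription missing for targets: {missing_rx}")
    if interface_names is None:
        interface_names = tuple(n for n in structs if n.endswith("_interface"))

    body = structs["body"]
    out: Dict[str, float] = {}

    for name in _TARGET_STRUCTURES:
        rx = float(prescriptions[name])
        target = structs[name]
        dvh = compute_dvh(dose, target, bin_width_Gy)
        d2 = dose_at_volume(dvh, 2.0)
        d50 = dose_at_volume(dvh, 50.0)
        d98 = dose_at_volume(dvh, 98.0)
        out[f"{name}:v_rx"] = volume_at_dose(dvh, rx)
        out[f"{name}:hi"] = homogeneity_index(d2, d98, d50)
        out[f"{name}:ci"] = conformity_index(target, dose, rx, body)

    for name in _DMAX_STRUCTURES:
        out[f"{name}:d_max"] = float(dose.values[structs[name].voxels].max())

    parotids = structs["parotid_l"].voxels | structs["parotid_r"].voxels
    out["parotids:d_mean"] = float(dose.values[parotids].mean())
    out["normal_tissue:d_mean"] = float(
        dose.values[structs["normal_tissue"].voxels].mean()
    )

    for name in ("skin",) + tuple(interface_names):
        in_mask = dose.values[structs[name].voxels]
        out[f"{name}:d_mean"] = float(in_mask.mean())
        out[f"{name}:d_max"] = float(in_mask.max())

    return MetricSet(out)
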