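"""Paired three-condition plan comparison.

Conditions are labelled ``B0`` (optimized without magnetic field),
``B15_RECAL`` (same segments recalculated at 1.5 T) and ``B15_REOPT``
(reoptimized at 1.5 T with the original cost function).  Differences are
taken as (1.5-T plan) - (0-T plan), so positive values mark an increase
under the magnetic field.

Statistics follow the conventions of the clinical analysis they mirror:

* Summary rows report the mean with the POPULATION standard deviation
  (divide by n), and the midpoint median.
* The Wilcoxon signed-rank test drops zero differences, uses mid-ranks
  for ties, takes W as the smaller signed-rank sum, and converts to a
  two-sided p with the normal approximation (tie-corrected variance, no
  continuity correction) — the asymptotic output SPSS prints.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .grid import DoseGrid, GridMismatchError
from .dosimetry import MetricSet

__all__ = [
    "CONDITIONS",
    "CONTRASTS",
    "SummaryStats",
    "PairedComparison",
    "CohortScores",
    "summarize",
    "wilcoxon_signed_rank",
    "paired_difference_table",
    "dose_difference_map",
    "render_difference_map",
    "present_round",
]

#: canonical plan-condition labels, in presentation order
CONDITIONS = ("B0", "B15_RECAL", "B15_REOPT")

#: paired contrasts reported by default, as (a, b) evaluated b - a
CONTRASTS = (
    ("B0", "B15_RECAL"),
    ("B0", "B15_REOPT"),
    ("B15_RECAL", "B15_REOPT"),
)


def present_round(x: float, ndigits: int = 1) -> float:
    """Round half away from zero (presentation convention)."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


@dataclass(frozen=True)
class SummaryStats:
    mean: float
    sd: float
    median: float
    n: int


def summarize(values: Sequence[float], population_sd: bool = True) -> SummaryStats:
    """Mean, standard deviation and median of a metric across a cohort.

    The standard deviation divides by n by default (population form);
    pass ``population_sd=False`` for the n-1 sample form.
    """
    arr = np.asarray(values, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("summarize requires at least one value")
    ddof = 0 if population_sd else 1
    sd = 0.0 if arr.size == 1 and ddof == 1 else float(arr.std(ddof=ddof))
    return SummaryStats(
        mean=float(arr.mean()), sd=sd, median=float(np.median(arr)), n=arr.size
    )


@dataclass(frozen=True)
class PairedComparison:
    """Wilcoxon signed-rank comparison of paired samples b vs a (d = b - a)."""

    mean_diff: float
    sd_diff: float
    median_a: float
    median_b: float
    W_statistic: float
    z: float
    p_two_sided: float
    n_effective: int
    normal_approx_reliable: bool


def wilcoxon_signed_rank(
    pairs_a: Sequence[float], pairs_b: Sequence[float]
) -> PairedComparison:
    """Two-sided Wilcoxon signed-rank test on paired data.

    Differences ``d = b - a``; zeros are dropped; |d| is ranked with
    mid-ranks; W is the smaller of the positive/negative rank sums; z
    uses the tie-corrected variance without continuity correction and p
    is the two-sided normal tail.  With fewer than 5 nonzero differences
    the normal approximation is flagged unreliable (but still computed);
    with none, W/z/p are NaN.
    """
    a = np.asarray(pairs_a, dtype=np.float64)
    b = np.asarray(pairs_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired samples must be 1-D and of equal length")
    d = b - a
    nz = d[d != 0]
    n = nz.size
    base = dict(
        mean_diff=float(d.mean()),
        sd_diff=float(d.std(ddof=0)),
        median_a=float(np.median(a)),
        median_b=float(np.median(b)),
        n_effective=n,
    )
    if n == 0:
        return PairedComparison(
            **base,
            W_statistic=math.nan,
            z=math.nan,
            p_two_sided=math.nan,
            normal_approx_reliable=False,
        )
    ranks = stats.rankdata(np.abs(nz))
    w_pos = float(ranks[nz > 0].sum())
    w_neg = float(ranks[nz < 0].sum())
    w = min(w_pos, w_neg)
    mu = n * (n + 1) / 4.0
    # tie correction: subtract sum(t^3 - t)/48 over groups of tied |d|
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    if var <= 0:  # all |d| identical and n == 1-ish degenerate case
        z = math.nan
        p = math.nan
    else:
        # direction-sensitive z from the positive-rank sum (flips sign when
        # a and b are swapped); p is the symmetric two-sided tail
        z = (w_pos - mu) / math.sqrt(var)
        p = min(1.0, 2.0 * stats.norm.sf(abs(z)))
    reliable = n >= 5
    if not reliable:
        warnings.warn(
            f"only {n} nonzero differences; normal approximation unreliable",
            stacklevel=2,
        )
    return PairedComparison(
        **base, W_statistic=w, z=float(z), p_two_sided=float(p),
        normal_approx_reliable=reliable,
    )


@dataclass(frozen=True)
class CohortScores:
    """Per-patient values of one scalar metric under each plan condition."""

    patient_ids: Tuple
    conditions: Tuple[str, ...]
    values: np.ndarray  # patients x conditions

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=np.float64)
        if values.shape != (len(self.patient_ids), len(self.conditions)):
            raise ValueError("values must be a patients x conditions matrix")
        if np.isnan(values).any():
            raise ValueError("paired comparison requires complete data (no NaNs)")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "patient_ids", tuple(self.patient_ids))
        object.__setattr__(self, "conditions", tuple(self.conditions))

    def column(self, condition: str) -> np.ndarray:
        return self.values[:, self.conditions.index(condition)]

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, value_column: str = "value"
    ) -> "CohortScores":
        """Build from a tidy frame with columns patient, condition, value."""
        wide = frame.pivot(index="patient", columns="condition", values=value_column)
        conditions = [c for c in CONDITIONS if c in wide.columns]
        wide = wide[conditions]
        if wide.isna().any().any():
            raise ValueError("missing patient/condition cells in cohort data")
        return cls(tuple(wide.index), tuple(conditions), wide.to_numpy())


def paired_difference_table(
    metric_sets: Mapping, contrasts: Sequence[Tuple[str, str]] = CONTRASTS
) -> pd.DataFrame:
    """Per-metric paired differences across plan conditions.

    Parameters
    ----------
    metric_sets
        Mapping ``(patient_id, condition) -> MetricSet`` (or any mapping
        of metric name to value); every patient must have every
        condition, with identical metric names throughout.

    Returns
    -------
    DataFrame with one row per (metric, contrast): mean difference,
    population sd, median difference, Wilcoxon W and two-sided p, and
    the number of patients.  Sign convention: ``b - a``, positive marks
    an increase in the later (1.5-T) condition.
    """
    keys = list(metric_sets)
    patients = sorted({k[0] for k in keys})
    needed_conditions = sorted({c for pair in contrasts for c in pair})
    missing = [
        (p, c) for p in patients for c in needed_conditions if (p, c) not in metric_sets
    ]
    if missing:
        raise KeyError(f"missing patient/condition pairs: {missing}")
    metric_names = list(metric_sets[keys[0]])

    rows: List[dict] = []
    for metric in metric_names:
        for cond_a, cond_b in contrasts:
            a = np.array([float(metric_sets[(p, cond_a)][metric]) for p in patients])
            b = np.array([float(metric_sets[(p, cond_b)][metric]) for p in patients])
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cmp = wilcoxon_signed_rank(a, b)
            d = b - a
            rows.append(
                {
                    "metric": metric,
                    "contrast": f"{cond_b}-{cond_a}",
                    "mean_diff": cmp.mean_diff,
                    "sd_diff": cmp.sd_diff,
                    "median_diff": float(np.median(d)),
                    "W": cmp.W_statistic,
                    "p": cmp.p_two_sided,
                    "n": len(patients),
                }
            )
    return pd.DataFrame(rows)


def dose_difference_map(
    dose_a: DoseGrid, dose_b: DoseGrid, clip_cGy: float = 700.0
) -> Tuple[DoseGrid, DoseGrid]:
    """Voxel-wise dose difference (b - a) in centigray.

    Returns ``(clipped, raw)``: the first clipped to ``±clip_cGy`` for
    rendering, the second unclipped for export.  Antisymmetric in its
    arguments before clipping.
    """
    if dose_a.grid.shape != dose_b.grid.shape or dose_a.grid.spacing_mm != dose_b.grid.spacing_mm:
        raise GridMismatchError("dose grids do not share a voxel grid")
    raw = (dose_b.values - dose_a.values) * 100.0
    clipped = np.clip(raw, -clip_cGy, clip_cGy)
    return DoseGrid(dose_a.grid, clipped), DoseGrid(dose_a.grid, raw)


def render_difference_map(
    diff: DoseGrid, path, slice_indices: Sequence[int] | None = None,
    clip_cGy: float = 700.0,
) -> None:
    """Render transversal slices of a difference map (cGy) to a PNG."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    nz = diff.grid.shape[2]
    if slice_indices is None:
        slice_indices = [nz // 4, nz // 2, (3 * nz) // 4]
    fig, axes = plt.subplots(1, len(slice_indices), figsize=(4 * len(slice_indices), 4))
    if len(slice_indices) == 1:
        axes = [axes]
    for ax, k in zip(axes, slice_indices):
        im = ax.imshow(
            diff.values[:, :, k].T, cmap="RdBu_r", vmin=-clip_cGy, vmax=clip_cGy,
            origin="lower",
        )
        ax.set_title(f"slice {k}")
        ax.set_xticks([])
        ax.set_yticks([])
    fig.colorbar(im, ax=axes, label="dose difference (cGy)", shrink=0.8)
    fig.savefig(path, dpi=100, metadata={"Software": None})
    plt.close(fig)
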