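"""Plan-quality metric (PQM) scoring.

A plan is scored by 15 submetrics, each mapped through a piecewise-linear
value function onto a fixed 0-10 point range and summed:

    S = sum_i S_i,             i = 1..15

    S_i = clamp((M_i - M_il) / (M_iu - M_il), 0, 1) * (S_imax - S_imin)   (Vp, CI)
    S_i = clamp((M_iu - M_i) / (M_iu - M_il), 0, 1) * (S_imax - S_imin)   (all others)

where M_il and M_iu are the evaluation interval of metric M_i.  Coverage
and conformity improve upward; HI and all OAR doses improve downward.
Values outside the interval saturate at 0 or 10, so S is bounded in
[0, 150].  All submetrics are equally weighted.

The default evaluation intervals cover three targets (coverage,
conformity, homogeneity each) and six organ-at-risk dose limits; the
table is user-replaceable (intervals are by construction adapted to the
cohort being compared).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence

import yaml

__all__ = [
    "MetricDef",
    "PQMTable",
    "PQMResult",
    "submetric_score",
    "total_score",
    "default_table",
    "load_table",
    "save_table",
]

INCREASING = "increasing"
DECREASING = "decreasing"


@dataclass(frozen=True)
class MetricDef:
    """One submetric: evaluation interval, direction, and point range."""

    metric_id: str
    lower_limit: float
    upper_limit: float
    direction: str
    s_min: float = 0.0
    s_max: float = 10.0

    def __post_init__(self) -> None:
        if self.direction not in (INCREASING, DECREASING):
            raise ValueError(
                f"{self.metric_id}: direction must be "
                f"'{INCREASING}' or '{DECREASING}', got {self.direction!r}"
            )
        if not self.lower_limit < self.upper_limit:
            raise ValueError(
                f"{self.metric_id}: lower limit {self.lower_limit} must be "
                f"< upper limit {self.upper_limit}"
            )
        if not self.s_min < self.s_max:
            raise ValueError(f"{self.metric_id}: s_min must be < s_max")


@dataclass(frozen=True)
class PQMTable:
    """Ordered collection of submetric definitions with unique ids."""

    defs: Sequence[MetricDef]

    def __post_init__(self) -> None:
        defs = tuple(self.defs)
        ids = [d.metric_id for d in defs]
        if len(set(ids)) != len(ids):
            raise ValueError("metric ids must be unique")
        object.__setattr__(self, "defs", defs)

    @property
    def k(self) -> int:
        return len(self.defs)

    @property
    def metric_ids(self) -> List[str]:
        return [d.metric_id for d in self.defs]

    @property
    def max_total(self) -> float:
        return sum(d.s_max for d in self.defs)


@dataclass(frozen=True)
class PQMResult:
    """Per-submetric scores and their sum for one plan."""

    per_metric_scores: Dict[str, float]
    total: float


def submetric_score(value: float, metric_def: MetricDef) -> float:
    """Piecewise-linear value function of one submetric, saturating at the
    interval limits."""
    import math

    if not math.isfinite(value):
        raise ValueError(f"{metric_def.metric_id}: value must be finite, got {value}")
    span = metric_def.upper_limit - metric_def.lower_limit
    if metric_def.direction == INCREASING:
        frac = (value - metric_def.lower_limit) / span
    else:
        frac = (metric_def.upper_limit - value) / span
    frac = min(max(frac, 0.0), 1.0)
    return metric_def.s_min + frac * (metric_def.s_max - metric_def.s_min)


def total_score(metrics: Mapping[str, float], table: PQMTable) -> PQMResult:
    """Score a full plan; every table metric must be present in ``metrics``."""
    missing = [d.metric_id for d in table.defs if d.metric_id not in metrics]
    if missing:
        raise KeyError(f"metrics missing for submetrics: {missing}")
    scores = {
        d.metric_id: submetric_score(float(metrics[d.metric_id]), d)
        for d in table.defs
    }
    return PQMResult(per_metric_scores=scores, total=float(sum(scores.values())))


def default_table() -> PQMTable:
    """The default 15-submetric evaluation table.

    Target rows use Vp (%, prescription coverage), CI and HI; OAR rows
    use Dmax or Dmean in Gy.  Vp and CI score upward, everything else
    downward.
    """
    rows = [
        ("pgtv_tb:v_rx", 80.0, 95.0, INCREASING),
        ("pgtv_tb:ci", 0.0, 1.0, INCREASING),
        ("pgtv_tb:hi", 0.0, 0.2, DECREASING),
        ("gtv_nd:v_rx", 80.0, 95.0, INCREASING),
        ("gtv_nd:ci", 0.0, 1.0, INCREASING),
        ("gtv_nd:hi", 0.0, 0.2, DECREASING),
        ("ptv:v_rx", 90.0, 95.0, INCREASING),
        ("ptv:ci", 0.6, 1.0, INCREASING),
        ("ptv:hi", 0.0, 0.3, DECREASING),
        ("brain_stem:d_max", 25.0, 40.0, DECREASING),
        ("brain_stem_prv:d_max", 30.0, 45.0, DECREASING),
        ("spinal_cord:d_max", 30.0, 40.0, DECREASING),
        ("spinal_cord_prv:d_max", 35.0, 45.0, DECREASING),
        ("parotids:d_mean", 40.0, 55.0, DECREASING),
        ("normal_tissue:d_mean", 10.0, 30.0, DECREASING),
    ]
    return PQMTable([MetricDef(mid, lo, hi, direction) for mid, lo, hi, direction in rows])


def _table_to_records(table: PQMTable) -> List[dict]:
    return [
        {
            "metric_id": d.metric_id,
            "lower_limit": d.lower_limit,
            "upper_limit": d.upper_limit,
            "direction": d.direction,
            "s_min": d.s_min,
            "s_max": d.s_max,
        }
        for d in table.defs
    ]


def save_table(table: PQMTable, path: str | Path) -> None:
    """Write a table as YAML (or JSON if the suffix is ``.json``)."""
    path = Path(path)
    records = _table_to_records(table)
    if path.suffix == ".json":
        path.write_text(json.dumps(records, indent=2))
    else:
        path.write_text(yaml.safe_dump(records, sort_keys=False))


def load_table(path: str | Path) -> PQMTable:
    """Read a table from YAML/JSON written by :func:`save_table`."""
    path = Path(path)
    text = path.read_text()
    records = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    return PQMTable([MetricDef(**rec) for rec in records])
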