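"""Resource-cost escalation model and the full-factorial scenario design.

Each resource type carries a base unit-cost coefficient (physician 1.00,
nurse 0.80, clerk 0.60, bed 0.50, triage area 0.40, in currency-free
units).  Cost levels delta_0.0 .. delta_0.3 escalate every coefficient by
successive percentage increases (20%, 30%, 50%), each applied to the
previous level (so the physician coefficient runs 1.00, 1.20, 1.56, 2.34);
the reported per-level multiplier is 1 + that level's percentage.  A
scenario's cost at a level is the count-weighted sum of the level's
coefficients; per-patient and waiting-time costs scale that by the
scenario's simulated throughput and waiting time.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import product

import numpy as np
import pandas as pd

from .simulate import RESOURCE_FIELDS, ResourceConfig

__all__ = [
    "DEFAULT_BASE_COEFFICIENTS",
    "DEFAULT_ESCALATIONS",
    "DEFAULT_LEVELS",
    "DEFAULT_GRID_LEVELS",
    "CostTable",
    "ScenarioCost",
    "escalate_coefficients",
    "build_grid",
    "grid_configs",
    "scenario_cost",
    "cost_benefit",
]

DEFAULT_BASE_COEFFICIENTS: dict[str, float] = {
    "pn": 1.00, "nn": 0.80, "cn": 0.60, "bn": 0.50, "tn": 0.40,
}
DEFAULT_ESCALATIONS: tuple[float, ...] = (0.20, 0.30, 0.50)
DEFAULT_LEVELS: tuple[str, ...] = ("d0.0", "d0.1", "d0.2", "d0.3")

DEFAULT_GRID_LEVELS: dict[str, tuple[int, ...]] = {
    "pn": (1, 2, 3), "nn": (1, 2, 3), "cn": (1, 2), "bn": (1, 2, 3), "tn": (1, 2),
}


def _round2(x: float) -> float:
    return float(Decimal(repr(x)).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


@dataclass
class CostTable:
    """Escalated cost-coefficient matrix (levels x resource types).

    ``raw`` keeps the unrounded recursion; ``rounded()`` is the 2-decimal
    half-up reporting form whose cells, column sums and cumulative
    multipliers are the published ones.
    """

    raw: pd.DataFrame  # index: level labels, columns: resource fields
    escalations: tuple[float, ...]
    multipliers: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        # the reported per-level multiplier: 1 + that level's escalation %
        self.multipliers = (1.0, *(1.0 + p for p in self.escalations))

    @property
    def levels(self) -> tuple[str, ...]:
        return tuple(self.raw.index)

    def rounded(self) -> pd.DataFrame:
        return self.raw.map(_round2)

    def column_sums(self) -> pd.Series:
        return self.rounded().sum(axis=0).map(_round2)

    def coefficient(self, resource: str, level: str, rounded: bool = True) -> float:
        if level not in self.raw.index:
            raise KeyError(f"unknown cost level {level!r}")
        if resource not in self.raw.columns:
            raise KeyError(f"unknown resource type {resource!r}")
        v = float(self.raw.loc[level, resource])
        return _round2(v) if rounded else v

    def to_csv(self, path) -> None:
        out = self.rounded().copy()
        out["pct"] = [0.0, *self.escalations]
        out["cumulative"] = [_round2(m) for m in self.multipliers]
        out.to_csv(path, index_label="level")

    @classmethod
    def from_csv(cls, path) -> "CostTable":
        df = pd.read_csv(path, index_col="level")
        df.index.name = None
        escalations = tuple(float(p) for p in df["pct"].iloc[1:])
        raw = df.drop(columns=["pct", "cumulative"])
        return cls(raw=raw, escalations=escalations)


def escalate_coefficients(
    base: dict[str, float] | None = None,
    escalations: tuple[float, ...] | None = None,
    level_labels: tuple[str, ...] | None = None,
) -> CostTable:
    """Build the escalated coefficient matrix by the level-k recursion."""
    base = dict(base) if base is not None else dict(DEFAULT_BASE_COEFFICIENTS)
    escalations = tuple(escalations) if escalations is not None else DEFAULT_ESCALATIONS
    if any(v <= 0 for v in base.values()):
        raise ValueError("base coefficients must be positive")
    if any(p < 0 for p in escalations):
        raise ValueError("escalation percentages must be non-negative")
    labels = level_labels or tuple(
        f"d0.{k}" for k in range(len(escalations) + 1)
    )
    if len(labels) != len(escalations) + 1:
        raise ValueError("need one level label per escalation step plus the base")
    rows = [dict(base)]
    for pct in escalations:
        rows.append({r: v * (1.0 + pct) for r, v in rows[-1].items()})
    raw = pd.DataFrame(rows, index=list(labels))
    return CostTable(raw=raw, escalations=escalations)


def build_grid(
    levels: dict[str, tuple[int, ...]] | None = None,
    replicates: int = 2,
) -> pd.DataFrame:
    """Full-factorial scenario design, lexicographic in (pn, nn, cn, bn, tn).

    With the default level sets (3*3*2*3*2 = 108 scenarios) and 2
    replicates this is the balanced 216-row design whose input columns have
    the published descriptive statistics.
    """
    levels = levels or DEFAULT_GRID_LEVELS
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    for r in RESOURCE_FIELDS:
        if not levels.get(r):
            raise ValueError(f"empty level set for resource {r}")
    rows = []
    scenario = 0
    for combo in product(*(levels[r] for r in RESOURCE_FIELDS)):
        for rep in range(replicates):
            rows.append({**dict(zip(RESOURCE_FIELDS, combo)), "scenario": scenario,
                         "replicate": rep})
        scenario += 1
    return pd.DataFrame(rows)


def grid_configs(
    levels: dict[str, tuple[int, ...]] | None = None,
    waiting_capacity: int = 50,
) -> list[ResourceConfig]:
    """The unique scenario configurations of the factorial design, in order."""
    grid = build_grid(levels, replicates=1)
    return [
        ResourceConfig(**{f: int(row[f]) for f in RESOURCE_FIELDS},
                       waiting_capacity=waiting_capacity)
        for _, row in grid.iterrows()
    ]


def scenario_cost(
    config: ResourceConfig | dict[str, int],
    table: CostTable,
    level: str,
    rounded: bool = True,
) -> float:
    """Count-weighted coefficient sum of one scenario at one cost level."""
    counts = config.as_dict() if isinstance(config, ResourceConfig) else dict(config)
    unknown = set(counts) - set(table.raw.columns)
    if unknown:
        raise KeyError(f"unknown resource type(s): {sorted(unknown)}")
    return float(sum(
        n * table.coefficient(r, level, rounded=rounded) for r, n in counts.items()
    ))


@dataclass(frozen=True)
class ScenarioCost:
    """Escalated cost position of one scenario against its simulated outcomes."""

    level: str
    base_cost: float        # count-weighted sum at the base level
    level_cost: float       # count-weighted sum at ``level``
    cost_pnt: float         # throughput-scaled cost: sum(pnt) * level_cost
    cost_wt: float | None   # waiting-scaled cost: sum(wt/pnt) * level_cost
    total_pnt: int
    revenue: float
    net: float | None
    breakeven: bool | None
    wt_defined: bool


def cost_benefit(
    daily: pd.DataFrame,
    config: ResourceConfig | dict[str, int],
    table: CostTable,
    level: str,
    revenue_per_patient: float = 1.0,
) -> ScenarioCost:
    """Cost-benefit position of one scenario's simulated days at one level.

    ``daily`` needs ``pnt`` and ``wt`` columns (one row per simulated day).
    The waiting cost sums wt/pnt over days; days with zero throughput make
    it undefined and it is flagged rather than computed.
    """
    if daily.empty:
        raise ValueError("daily outcomes are empty")
    base_level = table.levels[0]
    c0 = scenario_cost(config, table, base_level)
    ck = scenario_cost(config, table, level)
    total_pnt = int(daily["pnt"].sum())
    cost_pnt = float(total_pnt * ck)
    wt_defined = bool((daily["pnt"] > 0).all()) and not daily["wt"].isna().any()
    if wt_defined:
        ratio = float((daily["wt"] / daily["pnt"]).sum())
        cost_wt = ratio * ck
        revenue = revenue_per_patient * total_pnt
        net = revenue - cost_pnt - cost_wt
        breakeven = net >= 0.0
    else:
        cost_wt = None
        revenue = revenue_per_patient * total_pnt
        net = None
        breakeven = None
    return ScenarioCost(
        level=level, base_cost=c0, level_cost=ck, cost_pnt=cost_pnt,
        cost_wt=cost_wt, total_pnt=total_pnt, revenue=revenue, net=net,
        breakeven=breakeven, wt_defined=wt_defined,
    )
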