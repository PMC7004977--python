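"""Recommendation engine over the effort-reduction surfaces.

Candidate designs are first filtered to those with absolute scaled bias
strictly below 1% and every replicate converged — the study's
reliability bar.  The remaining configurations are then narrowed by the
decision maker's attributes: whether population reduction is itself a
goal (forces removal trapping), whether the method must be
non-invasive (excludes removal), how risk-averse they are (minimize
variance instead of cost), which equipment is already on hand (its
purchase cost drops out), and whether labor is the binding constraint
(labor share breaks cost ties).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from wildens import costs
from wildens.effort import ReductionCell

BIAS_THRESHOLD = 0.01

_EQUIPMENT_FOR_METHOD = {"camera": "cameras", "removal": "traps", "fecal": "lab_access"}


@dataclass
class Preference:
    """Decision-maker attributes steering the recommendation."""

    removal_goal: bool = False
    non_invasive_required: bool = False
    risk_averse: bool = False
    labor_limited: bool = False
    equipment_on_hand: set = field(default_factory=set)

    def __post_init__(self) -> None:
        unknown = set(self.equipment_on_hand) - {"cameras", "traps", "lab_access"}
        if unknown:
            raise ValueError(f"unknown equipment labels: {sorted(unknown)}")
        if self.removal_goal and self.non_invasive_required:
            raise ValueError(
                "population reduction requires trapping; it cannot be non-invasive"
            )


@dataclass
class Recommendation:
    """Chosen method and effort with the branch decisions that led there."""

    method: str
    effort: costs.EffortConfig
    cost_usd: float
    variance: float
    rationale: list


def filter_bias(
    cells: list[ReductionCell], threshold: float = BIAS_THRESHOLD
) -> list[ReductionCell]:
    """Keep cells with |scaled bias| strictly below the threshold and all
    replicates converged."""
    return [
        c
        for c in cells
        if c.abs_scaled_bias < threshold and c.prop_converged == 1.0
    ]


def _effective_cost(cell: ReductionCell, pref: Preference) -> tuple[float, float]:
    """(cost, labor_share), re-costed from the ledger only when needed.

    The cell's own cost is authoritative; the itemized ledger is
    consulted to zero equipment already on hand and to compute the
    labor share for tie-breaking.  Lab access on hand changes nothing
    for the default ledgers: the study already assumed genetic work is
    sent out and no lab equipment is purchased.
    """
    method = cell.effort.method
    owned = _EQUIPMENT_FOR_METHOD.get(method) in pref.equipment_on_hand and method != "fecal"
    cost = cell.cost_usd
    labor_share = 0.0
    if owned or pref.labor_limited:
        bd = costs.cost_breakdown(
            method, cell.effort.n_units, cell.effort.n_days, owned_equipment=owned
        )
        labor_share = bd["by_category"].get("labor", 0.0) / max(bd["total"], 1e-9)
        if owned:
            cost = bd["total"]
    return cost, labor_share


def recommend(
    cells_by_method: dict[str, list[ReductionCell]],
    pref: Preference,
    threshold: float = BIAS_THRESHOLD,
) -> Recommendation:
    """Pick the effort configuration satisfying the preference branches.

    Branch order: bias filter -> removal-goal / non-invasive gates ->
    equipment-on-hand recosting -> minimize variance (risk averse) or
    cost, labor share breaking cost ties -> deterministic tie-break on
    fewer units, then fewer days.
    """
    rationale = [f"bias filter: |scaled bias| < {threshold:.0%} and full convergence"]
    admissible: dict[str, list[ReductionCell]] = {
        m: filter_bias(cells, threshold) for m, cells in cells_by_method.items()
    }

    if pref.removal_goal:
        admissible = {m: c for m, c in admissible.items() if m == "removal"}
        rationale.append("population reduction is a goal: removal trapping only")
    if pref.non_invasive_required:
        admissible = {m: c for m, c in admissible.items() if m != "removal"}
        rationale.append("non-invasive requirement: removal trapping excluded")

    candidates = [c for cells in admissible.values() for c in cells]
    if not candidates:
        raise ValueError("no configuration satisfies the bias criterion")

    if pref.equipment_on_hand:
        rationale.append(
            f"equipment on hand ({', '.join(sorted(pref.equipment_on_hand))}): "
            "purchase costs zeroed"
        )

    scored = []
    for c in candidates:
        cost, labor_share = _effective_cost(c, pref)
        scored.append((c, cost, labor_share))

    if pref.risk_averse:
        rationale.append("risk averse: minimizing variance")
        key = lambda t: (t[0].variance, t[1], t[0].effort.n_units, t[0].effort.n_days)
    elif pref.labor_limited:
        rationale.append("labor limited: minimizing cost, labor share breaks ties")
        key = lambda t: (
            round(t[1], 2),
            t[2],
            t[0].effort.n_units,
            t[0].effort.n_days,
        )
    else:
        rationale.append("minimizing total cost")
        key = lambda t: (t[1], t[0].effort.n_units, t[0].effort.n_days)

    best, best_cost, _ = min(scored, key=key)
    rationale.append(
        f"selected {best.effort.method} with {best.effort.n_units} units "
        f"x {best.effort.n_days} days"
    )
    return Recommendation(
        method=best.effort.method,
        effort=best.effort,
        cost_usd=best_cost,
        variance=best.variance,
        rationale=rationale,
    )


def render_tree(cells_by_method: dict, threshold: float = BIAS_THRESHOLD) -> str:
    """Plain-text sketch of the decision tree over the passing sets."""
    lines = [f"Designs with |scaled bias| < {threshold:.0%}:"]
    for method, cells in sorted(cells_by_method.items()):
        passing = filter_bias(cells, threshold)
        lines.append(f"  {method}: {len(passing)} passing configuration(s)")
        if passing:
            cheapest = min(passing, key=lambda c: (c.cost_usd, c.effort.n_units))
            steadiest = min(passing, key=lambda c: (c.variance, c.cost_usd))
            lines.append(
                f"    min cost: {cheapest.effort.n_units} units x "
                f"{cheapest.effort.n_days} days (${cheapest.cost_usd:,.0f})"
            )
            lines.append(
                f"    min variance: {steadiest.effort.n_units} units x "
                f"{steadiest.effort.n_days} days (var {steadiest.variance:.3g})"
            )
    return "\n".join(lines)


__all__ = [
    "BIAS_THRESHOLD",
    "Preference",
    "Recommendation",
    "filter_bias",
    "recommend",
    "render_tree",
]
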