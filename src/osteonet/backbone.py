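"""Hub / bottleneck / backbone classification of an interaction network.

Hubs are the top-decile nodes by degree, bottlenecks the top-decile nodes by
betweenness centrality, and their union is the network backbone — the
principal structure through which information flows.  A fourth role captures
an *upstream signal*: a protein with hub-grade connectivity that nevertheless
sits at the periphery of the network (low betweenness, high eccentricity, low
closeness), the pattern expected of an early activator feeding into the
backbone rather than relaying traffic inside it.  An upstream-signal node is
excluded from the backbone by definition.

The decile size rounds up (on 24 nodes, the "top 10%" is 3 nodes) and ties
with the cutoff value are all included, so the call is deterministic and
label-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from statistics import median

from .topology import NetworkTopology

__all__ = [
    "RoleAssignment",
    "top_decile",
    "competition_ranks",
    "upstream_signal_flag",
    "classify_roles",
]


@dataclass
class RoleAssignment:
    identifier: str
    is_hub: bool
    is_bottleneck: bool
    is_backbone: bool
    is_upstream_signal: bool
    rank_k: int
    rank_bc: int


def top_decile(values: dict[str, float], fraction: float = 0.10) -> set[str]:
    """The ceil(fraction * N) highest-valued keys, expanded across ties.

    Every key whose value equals the cutoff (the fraction-quantile order
    statistic) is included, so the result never depends on key order.
    """
    if not values:
        raise ValueError("empty value map")
    if not 0.0 < fraction <= 1.0:
        raise ValueError(f"fraction {fraction} outside (0, 1]")
    m = math.ceil(fraction * len(values))
    ordered = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    cutoff = ordered[m - 1][1]
    return {k for k, v in values.items() if v >= cutoff}


def competition_ranks(values: dict[str, float]) -> dict[str, int]:
    """1 = highest value; ties share the better (smaller) rank."""
    ordered = sorted(values.items(), key=lambda kv: (-kv[1], kv[0]))
    ranks: dict[str, int] = {}
    for i, (k, v) in enumerate(ordered):
        if i and v == ordered[i - 1][1]:
            ranks[k] = ranks[ordered[i - 1][0]]
        else:
            ranks[k] = i + 1
    return ranks


def _median_of(report: NetworkTopology, attr: str) -> float:
    return median(getattr(nt, attr) for nt in report.per_node)


def upstream_signal_flag(
    report: NetworkTopology, node: str, fraction: float = 0.10
) -> bool:
    """True iff ``node`` is hub-grade by degree but peripheral otherwise.

    Criteria (all required): degree in the top decile; BC below the network
    median; Ecc strictly above the median; CC strictly below the median.
    "Low"/"high" are operationalized as strict median comparisons; the decile
    fraction is configurable.
    """
    nt = report.node(node)  # raises KeyError for unknown nodes
    hub_grade = node in top_decile({x.identifier: x.k for x in report.per_node}, fraction)
    return (
        hub_grade
        and nt.bc < _median_of(report, "bc")
        and nt.ecc > _median_of(report, "ecc")
        and nt.cc < _median_of(report, "cc")
    )


def classify_roles(
    report: NetworkTopology, fraction: float = 0.10
) -> list[RoleAssignment]:
    """Assign hub / bottleneck / backbone / upstream-signal roles.

    Upstream-signal nodes are removed from the hub and bottleneck sets so
    that backbone membership and the upstream role stay mutually exclusive;
    backbone = hubs | bottlenecks on the remainder.
    """
    k_map = {nt.identifier: float(nt.k) for nt in report.per_node}
    bc_map = {nt.identifier: nt.bc for nt in report.per_node}
    hub_candidates = top_decile(k_map, fraction)
    bottleneck_candidates = top_decile(bc_map, fraction)
    upstream = {
        v for v in hub_candidates if upstream_signal_flag(report, v, fraction)
    }
    hubs = hub_candidates - upstream
    bottlenecks = bottleneck_candidates - upstream
    rank_k = competition_ranks(k_map)
    rank_bc = competition_ranks(bc_map)
    return [
        RoleAssignment(
            identifier=v,
            is_hub=v in hubs,
            is_bottleneck=v in bottlenecks,
            is_backbone=v in hubs or v in bottlenecks,
            is_upstream_signal=v in upstream,
            rank_k=rank_k[v],
            rank_bc=rank_bc[v],
        )
        for v in sorted(k_map)
    ]
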