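"""Group-level consensus ("common") networks, named structures, and the
link-weight hierarchy.

Subjects' region-scale networks are matched by region name.  A link is
retained in the common network when it appears (W > 0) in at least
``ceil(tau * N)`` subjects; its common weight is the mean of the subject
weights over the subjects where it is present, which keeps the common
weight inside the range of the contributing weights for any tau.

Two named structures are tracked per subject: the *triangle* (all three
links among pre-SMA, Broca's area and ventral premotor area) and the *V*
(both links from Wernicke's area to BA and to v-preMA).  The five core
links are ranked by common weight into the hierarchy A..E::

    A: BA - preMA    B: preSMA - preMA    C: preSMA - BA
    D: BA - WA       E: WA - preMA
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

from .config import ValidationError

__all__ = [
    "ROLES",
    "CORE_LINKS",
    "CommonNetwork",
    "StructureReport",
    "LinkRank",
    "link_frequency",
    "build_common_network",
    "detect_structures",
    "rank_links",
]

log = logging.getLogger(__name__)

#: the four functional roles of the core language regions
ROLES = ("preSMA", "BA", "preMA", "WA")

#: named core links in role space, strongest-first by the published hierarchy
CORE_LINKS: dict[str, tuple[str, str]] = {
    "A": ("BA", "preMA"),
    "B": ("preSMA", "preMA"),
    "C": ("preSMA", "BA"),
    "D": ("BA", "WA"),
    "E": ("WA", "preMA"),
}

TRIANGLE_ROLES = ("preSMA", "BA", "preMA")


def _pair(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def _has_link(net: nx.Graph, a: str, b: str) -> bool:
    return net.has_edge(a, b) and net[a][b].get("W", 0.0) > 0.0


def link_frequency(nets: Sequence[nx.Graph]) -> dict[tuple[str, str], int]:
    """Count, per region pair, the subjects whose network carries the link."""
    if not nets:
        raise ValidationError("need at least one subject network")
    counts: dict[tuple[str, str], int] = {}
    for net in nets:
        for u, v, d in net.edges(data=True):
            if d.get("W", 0.0) > 0.0:
                key = _pair(u, v)
                counts[key] = counts.get(key, 0) + 1
    return counts


@dataclass
class CommonNetwork:
    """Group-level consensus network over region names."""

    group: str
    n_subjects: int
    tau: float
    graph: nx.Graph  # nodes: region (attr mean_size); edges: W_common, f, retained

    def weight(self, a: str, b: str) -> float | None:
        if self.graph.has_edge(a, b) and self.graph[a][b]["retained"]:
            return self.graph[a][b]["W_common"]
        return None


def build_common_network(
    nets: Sequence[nx.Graph], tau: float = 1.0, group: str = ""
) -> CommonNetwork:
    """Consensus network retaining links present in >= ceil(tau * N) subjects.

    ``W_common`` is the mean subject weight over subjects where the link is
    present; node ``mean_size`` is the mean region size over subjects where
    the region appears.
    """
    if not (0.0 < tau <= 1.0):
        raise ValidationError(f"tau must lie in (0, 1], got {tau}")
    if not nets:
        raise ValidationError("need at least one subject network")
    N = len(nets)
    need = math.ceil(tau * N)
    counts = link_frequency(nets)

    G = nx.Graph()
    node_sizes: dict[str, list[int]] = {}
    for net in nets:
        for n, d in net.nodes(data=True):
            node_sizes.setdefault(n, []).append(int(d.get("size", 0)))
    for region, sizes in node_sizes.items():
        G.add_node(region, mean_size=sum(sizes) / len(sizes), n_subjects=len(sizes))

    for (a, b), f in counts.items():
        weights = [
            net[a][b]["W"] for net in nets if net.has_edge(a, b) and net[a][b].get("W", 0.0) > 0.0
        ]
        G.add_edge(
            a,
            b,
            W_common=sum(weights) / len(weights),
            f=f,
            retained=f >= need,
        )
    return CommonNetwork(group, N, tau, G)


@dataclass
class StructureReport:
    """Per-subject and per-group presence of the triangle and V structures."""

    group: str
    n_subjects: int
    triangle_per_subject: list[bool]
    v_per_subject: list[bool]
    missing_roles: list[dict[str, list[str]]] = field(default_factory=list)

    @property
    def triangle_count(self) -> int:
        return sum(self.triangle_per_subject)

    @property
    def v_count(self) -> int:
        return sum(self.v_per_subject)

    @property
    def triangle_fraction(self) -> float:
        return self.triangle_count / self.n_subjects

    @property
    def v_fraction(self) -> float:
        return self.v_count / self.n_subjects

    def to_dict(self) -> dict:
        return {
            "group": self.group,
            "n_subjects": self.n_subjects,
            "triangle": {
                "per_subject": self.triangle_per_subject,
                "count": self.triangle_count,
                "fraction": self.triangle_fraction,
            },
            "v": {
                "per_subject": self.v_per_subject,
                "count": self.v_count,
                "fraction": self.v_fraction,
            },
        }


def _resolve_roles(roles: Mapping[str, str]) -> dict[str, str]:
    """Invert a region-name -> role mapping into role -> region-name."""
    inv: dict[str, str] = {}
    for region, role in roles.items():
        if role not in ROLES:
            raise ValidationError(f"unknown role {role!r} for region {region!r}; roles are {ROLES}")
        if role in inv:
            raise ValidationError(f"role {role!r} assigned to both {inv[role]!r} and {region!r}")
        inv[role] = region
    return inv


def detect_structures(
    nets: Sequence[nx.Graph], roles: Mapping[str, str], group: str = ""
) -> StructureReport:
    """Flag the triangle and V structures in each subject network.

    ``roles`` maps region names to the four roles (preSMA, BA, preMA, WA).
    A structure whose role is not resolvable in a subject (region absent) is
    marked absent and logged.
    """
    if not nets:
        raise ValidationError("need at least one subject network")
    inv = _resolve_roles(roles)
    tri_flags: list[bool] = []
    v_flags: list[bool] = []
    missing_log: list[dict[str, list[str]]] = []
    for idx, net in enumerate(nets):
        missing = [role for role in ROLES if inv.get(role) not in net]
        if missing:
            log.info("subject %d: roles %s unresolved; structures involving them absent", idx, missing)
        missing_log.append({"subject": [str(idx)], "missing": missing})

        def has(r1: str, r2: str) -> bool:
            a, b = inv.get(r1), inv.get(r2)
            return a is not None and b is not None and a in net and b in net and _has_link(net, a, b)

        tri_flags.append(has("preSMA", "BA") and has("preSMA", "preMA") and has("BA", "preMA"))
        v_flags.append(has("WA", "BA") and has("WA", "preMA"))
    return StructureReport(group, len(nets), tri_flags, v_flags, missing_log)


@dataclass(frozen=True)
class LinkRank:
    label: str  # A..E
    regions: tuple[str, str]
    weight: float | None  # None when the link is missing from the common network
    tied_with: tuple[str, ...] = ()

    @property
    def present(self) -> bool:
        return self.weight is not None


def rank_links(
    common: CommonNetwork,
    roles: Mapping[str, str],
    named: Mapping[str, tuple[str, str]] = CORE_LINKS,
) -> list[LinkRank]:
    """Rank the named core links by common weight, descending.

    Missing links are listed last and flagged; exact weight ties are flagged
    on every member of the tie, never silently ordered.
    """
    inv = _resolve_roles(roles)
    weights: dict[str, float | None] = {}
    regions: dict[str, tuple[str, str]] = {}
    for label, (r1, r2) in named.items():
        a, b = inv.get(r1), inv.get(r2)
        regions[label] = (a or r1, b or r2)
        weights[label] = common.weight(a, b) if a is not None and b is not None else None

    present = sorted(
        (lab for lab, w in weights.items() if w is not None),
        key=lambda lab: (-weights[lab], lab),
    )
    absent = sorted(lab for lab, w in weights.items() if w is None)
    ranked: list[LinkRank] = []
    for lab in present:
        ties = tuple(
            other for other in present if other != lab and weights[other] == weights[lab]
        )
        ranked.append(LinkRank(lab, regions[lab], weights[lab], ties))
    for lab in absent:
        ranked.append(LinkRank(lab, regions[lab], None))
    return ranked
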