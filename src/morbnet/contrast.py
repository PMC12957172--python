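"""Between-network contrasts: A-not-in-B difference networks and
subgroup-unique significant pairs.

A difference network keeps the significant edges of an index subgroup's
network that are absent (by unordered pair identity) from a comparison
subgroup's network, with the index subgroup's SCI weights.  A
subgroup-unique pair is a significant edge present in exactly one of the
four diabetes-type x sex networks.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

from .errors import DataError
from .network import MultimorbidityNetwork


@dataclass(frozen=True)
class DifferenceNetwork:
    """Edges of subgroup A's network absent from subgroup B's network."""

    index_label: str
    comparison_label: str
    edges: tuple[tuple[str, str, float], ...]

    @property
    def edge_keys(self) -> frozenset[tuple[str, str]]:
        return frozenset((u, v) for u, v, _ in self.edges)

    @property
    def nodes(self) -> list[str]:
        return sorted({n for u, v, _ in self.edges for n in (u, v)})


def difference_network(
    a: MultimorbidityNetwork, b: MultimorbidityNetwork
) -> DifferenceNetwork:
    """Set difference of significant edge sets, keeping A's SCI weights."""
    b_keys = b.edge_keys
    edges = tuple(e for e in a.edges if (e[0], e[1]) not in b_keys)
    return DifferenceNetwork(
        index_label=a.label, comparison_label=b.label, edges=edges
    )


def unique_pairs(
    networks: Mapping[str, MultimorbidityNetwork] | Sequence[MultimorbidityNetwork],
) -> dict[str, list[tuple[str, str, float]]]:
    """Significant pairs present in exactly one of the four subgroup networks.

    Returns subgroup label -> [(code_i, code_j, SCI in that subgroup), ...],
    each list sorted by pair identity.  Requires exactly four networks; the
    result does not depend on the order in which they are supplied.
    """
    nets = (
        list(networks.values()) if isinstance(networks, Mapping) else list(networks)
    )
    if len(nets) != 4:
        raise DataError(f"unique_pairs expects exactly 4 networks, got {len(nets)}")
    labels = [n.label for n in nets]
    if len(set(labels)) != 4:
        raise DataError("unique_pairs: subgroup labels must be distinct")
    membership: dict[tuple[str, str], list[MultimorbidityNetwork]] = {}
    for net in nets:
        for key in net.edge_keys:
            membership.setdefault(key, []).append(net)
    out: dict[str, list[tuple[str, str, float]]] = {n.label: [] for n in nets}
    for key, members in membership.items():
        if len(members) != 1:
            continue
        net = members[0]
        weight = net.graph[key[0]][key[1]]["weight"]
        out[net.label].append((key[0], key[1], weight))
    for label in out:
        out[label].sort()
    return out
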