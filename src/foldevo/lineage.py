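"""Complete genealogy of every selected individual.

The tree is a forest rooted at the founders.  Each node stores its sequence
and the mutation event on the edge from its parent (``None`` for founders
and for clone nodes created when stochastic selection picks the same pool
member more than once — those edges carry no mutation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .mutation import MutationEvent, MutationType


@dataclass
class LineageNode:
    id: str
    sequence: str
    generation: int
    parent_id: str | None = None
    event: MutationEvent | None = None


@dataclass
class LineageTree:
    nodes: dict[str, LineageNode] = field(default_factory=dict)

    def add_node(
        self,
        node_id: str,
        sequence: str,
        generation: int,
        parent_id: str | None = None,
        event: MutationEvent | None = None,
    ) -> None:
        if node_id in self.nodes:
            raise ValueError(f"duplicate node id {node_id}")
        if parent_id is not None and parent_id not in self.nodes:
            raise KeyError(f"parent {parent_id} not in tree")
        self.nodes[node_id] = LineageNode(node_id, sequence, generation, parent_id, event)

    def __contains__(self, node_id: str) -> bool:
        return node_id in self.nodes

    def __len__(self) -> int:
        return len(self.nodes)

    @property
    def roots(self) -> list[str]:
        return [n.id for n in self.nodes.values() if n.parent_id is None]

    def children(self, node_id: str) -> list[str]:
        return [n.id for n in self.nodes.values() if n.parent_id == node_id]

    def path_to_root(self, node_id: str) -> list[LineageNode]:
        """Nodes from the founder down to ``node_id`` (inclusive)."""
        if node_id not in self.nodes:
            raise KeyError(f"unknown individual {node_id}")
        path = []
        cur: str | None = node_id
        while cur is not None:
            node = self.nodes[cur]
            path.append(node)
            cur = node.parent_id
        return path[::-1]

    def validate(self) -> None:
        """Forest invariants: acyclic paths to roots, edge = node - root count."""
        n_edges = sum(1 for n in self.nodes.values() if n.parent_id is not None)
        if n_edges != len(self.nodes) - len(self.roots):
            raise AssertionError("edge count != node count - root count")
        for nid in self.nodes:
            seen = set()
            cur: str | None = nid
            while cur is not None:
                if cur in seen:
                    raise AssertionError(f"cycle through {cur}")
                seen.add(cur)
                cur = self.nodes[cur].parent_id

    # -- export -------------------------------------------------------------

    def to_newick(self) -> str:
        """One newick line per founder clade (leaf-and-internal node labels)."""
        kids: dict[str | None, list[str]] = {}
        for n in self.nodes.values():
            kids.setdefault(n.parent_id, []).append(n.id)

        def clade(nid: str) -> str:
            ch = kids.get(nid, [])
            if not ch:
                return nid
            return "(" + ",".join(clade(c) for c in sorted(ch)) + ")" + nid

        lines = [clade(r) + ";" for r in sorted(kids.get(None, []))]
        # round-trip through dendropy validates the syntax
        dendropy.TreeList.get(data="\n".join(lines), schema="newick")
        return "\n".join(lines)

    def edge_table(self) -> list[dict]:
        """One row per edge with the mutation annotation (for a companion TSV)."""
        rows = []
        for n in self.nodes.values():
            if n.parent_id is None:
                continue
            rows.append(
                {
                    "child": n.id,
                    "parent": n.parent_id,
                    "generation": n.generation,
                    "event": n.event.describe() if n.event else ".",
                }
            )
        return rows

    def to_dict(self) -> dict:
        return {
            nid: {
                "sequence": n.sequence,
                "generation": n.generation,
                "parent_id": n.parent_id,
                "event": _event_to_dict(n.event),
            }
            for nid, n in self.nodes.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "LineageTree":
        tree = cls()
        for nid, nd in d.items():
            tree.nodes[nid] = LineageNode(
                id=nid,
                sequence=nd["sequence"],
                generation=nd["generation"],
                parent_id=nd["parent_id"],
                event=_event_from_dict(nd["event"]),
            )
        return tree


def _event_to_dict(ev: MutationEvent | None) -> dict | None:
    if ev is None:
        return None
    return {
        "type": ev.type.value,
        "position": ev.position,
        "end": ev.end,
        "payload": ev.payload,
    }


def _event_from_dict(d: dict | None) -> MutationEvent | None:
    if d is None:
        return None
    return MutationEvent(
        type=MutationType(d["type"]),
        position=d["position"],
        end=d["end"],
        payload=d["payload"],
    )
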