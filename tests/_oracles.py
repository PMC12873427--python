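"""Independent brute-force oracles used to cross-check the package.

These deliberately re-derive geometry and graph searches with plain
loops / exhaustive enumeration, sharing no code with the implementation
paths they check.
"""

from __future__ import annotations

import math

import numpy as np


def brute_force_hbond_edges(frame, topology, node_ids, d_da_max,
                            angle_min_deg, use_hydrogens, box=None):
    """All-pairs hydrogen-bond edge set over node_ids (sorted pairs).

    A pair bonds when the heavy-atom distance is <= d_da_max and, in
    hydrogen mode, some hydrogen of either atom (same residue, within
    1.25 Å) makes a D-H...A angle >= angle_min_deg.
    """
    node_ids = sorted(int(i) for i in node_ids)
    id_to_row = {int(a): r for r, a in enumerate(topology.atom_ids)}
    rows = [id_to_row[i] for i in node_ids]
    keys = [f"{topology.chain_ids[r]}:{topology.residue_names[r]}:"
            f"{topology.residue_numbers[r]}" for r in range(topology.n_atoms)]

    def hydrogens_of(row):
        out = []
        for r in range(topology.n_atoms):
            if str(topology.elements[r]).upper() != "H":
                continue
            if keys[r] != keys[row]:
                continue
            if np.linalg.norm(frame[r] - frame[row]) <= 1.25:
                out.append(r)
        return out

    def dist(a, b):
        d = frame[b] - frame[a]
        if box is not None:
            d = d - np.asarray(box) * np.round(d / np.asarray(box))
        return float(np.linalg.norm(d))

    def angle_at_h(d_row, h_row, a_row):
        v1 = frame[d_row] - frame[h_row]
        v2 = frame[a_row] - frame[h_row]
        c = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
        return math.degrees(math.acos(max(-1.0, min(1.0, c))))

    hmap = {r: hydrogens_of(r) for r in rows}
    edges = set()
    for a in range(len(rows)):
        for b in range(a + 1, len(rows)):
            ra, rb = rows[a], rows[b]
            if dist(ra, rb) > d_da_max:
                continue
            if not use_hydrogens:
                edges.add((node_ids[a], node_ids[b]))
                continue
            ok = False
            for d_row, acc in ((ra, rb), (rb, ra)):
                for h in hmap[d_row]:
                    if angle_at_h(d_row, h, acc) >= angle_min_deg:
                        ok = True
            if ok:
                edges.add((node_ids[a], node_ids[b]))
    return edges


def exhaustive_shortest_path(adjacency, sources, sinks, relays):
    """Exhaustive DFS over all simple paths source -> sink whose interior
    nodes are relays; returns the minimum hop count or None.  Only viable
    for tiny graphs (<= ~30 nodes)."""
    best = [None]

    def dfs(node, visited, length):
        if best[0] is not None and length >= best[0]:
            return
        for nxt in adjacency.get(node, ()):
            if nxt in visited:
                continue
            if nxt in sinks:
                total = length + 1
                if best[0] is None or total < best[0]:
                    best[0] = total
            if nxt in relays:
                dfs(nxt, visited | {nxt}, length + 1)

    for s in sources:
        dfs(s, {s}, 0)
    return best[0]
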