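"""Independent brute-force oracles used to verify the implementation.

Everything here is written from first principles on adjacency dicts and
plain Python sets — deliberately sharing no code path (and no networkx,
scipy or statsmodels call) with the package under test.
"""

from __future__ import annotations

from itertools import combinations


def _adjacency(nodes, edges):
    adj = {n: set() for n in nodes}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    return adj


def _bfs_distances(adj, source):
    dist = {source: 0}
    frontier = [source]
    while frontier:
        nxt = []
        for u in frontier:
            for v in adj[u]:
                if v not in dist:
                    dist[v] = dist[u] + 1
                    nxt.append(v)
        frontier = nxt
    return dist


def _all_shortest_paths(adj, dist, source, target):
    """Enumerate every shortest source->target path explicitly (DFS backwards
    along distance-decreasing edges)."""
    if target not in dist:
        return []
    paths = []

    def back(node, suffix):
        if node == source:
            paths.append([source] + suffix)
            return
        for prev in adj[node]:
            if dist.get(prev, -1) == dist[node] - 1:
                back(prev, [node] + suffix)

    back(target, [])
    return paths


def brute_betweenness(nodes, edges, normalized=True):
    """Endpoint-excluded betweenness by explicit path enumeration."""
    nodes = list(nodes)
    adj = _adjacency(nodes, edges)
    score = {n: 0.0 for n in nodes}
    for s, t in combinations(nodes, 2):
        dist = _bfs_distances(adj, s)
        paths = _all_shortest_paths(adj, dist, s, t)
        if not paths:
            continue
        for path in paths:
            for interior in path[1:-1]:
                score[interior] += 1.0 / len(paths)
    n = len(nodes)
    if normalized and n >= 3:
        scale = (n - 1) * (n - 2) / 2.0
        score = {k: v / scale for k, v in score.items()}
    return score


def brute_closeness(nodes, edges):
    """Reachability-weighted closeness: (r/S) * (r/(n-1))."""
    nodes = list(nodes)
    n = len(nodes)
    adj = _adjacency(nodes, edges)
    out = {}
    for v in nodes:
        dist = _bfs_distances(adj, v)
        reach = [d for u, d in dist.items() if u != v]
        r, total = len(reach), sum(reach)
        out[v] = (r / total) * (r / (n - 1)) if total > 0 and n > 1 else 0.0
    return out


def brute_core_numbers(nodes, edges):
    """Core number by checking, for each k, survival in the k-core obtained
    through exhaustive peeling."""
    nodes = set(nodes)
    out = {n: 0 for n in nodes}
    max_k = len(nodes)
    for k in range(1, max_k + 1):
        alive = set(nodes)
        changed = True
        while changed:
            changed = False
            for v in list(alive):
                deg = sum(1 for a, b in edges if a in alive and b in alive and v in (a, b))
                if deg < k:
                    alive.discard(v)
                    changed = True
        if not alive:
            break
        for v in alive:
            out[v] = k
    return out


def brute_degrees(nodes, edges):
    deg = {n: 0 for n in nodes}
    for a, b in edges:
        deg[a] += 1
        deg[b] += 1
    return deg


def brute_hypergeom_tail(k, n, K, N):
    """P(overlap >= k) by enumerating every size-n draw from an N-universe
    with a designated K-subset."""
    universe = list(range(N))
    special = set(range(K))
    hits = 0
    total = 0
    for draw in combinations(universe, n):
        total += 1
        if len(special.intersection(draw)) >= k:
            hits += 1
    return hits / total


def brute_predict(compounds, ligand_sets, threshold):
    """Nested-loop max-Tc prediction over plain Python bit sets."""
    out = set()
    for comp in compounds:
        cbits = {i for i, b in enumerate(comp.fingerprint) if b}
        for ls in ligand_sets:
            best = 0.0
            for lig in ls.ligands:
                lbits = {i for i, b in enumerate(lig) if b}
                union = cbits | lbits
                tc = len(cbits & lbits) / len(union) if union else 0.0
                best = max(best, tc)
            if best >= threshold:
                out.add((comp.compound_id, ls.target_id, round(best, 12)))
    return out
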