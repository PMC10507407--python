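"""Naive, enumeration-based topology oracle for small graphs.

Independent of the package implementation: works on a plain adjacency dict
(node -> set of neighbors), computes distances by breadth-first search, and
betweenness by explicitly enumerating every shortest path with a
distance-pruned depth-first search.  Intended for graphs of up to ~10 nodes.
"""

from collections import deque


def bfs_distances(adj, source):
    dist = {source: 0}
    q = deque([source])
    while q:
        v = q.popleft()
        for u in adj[v]:
            if u not in dist:
                dist[u] = dist[v] + 1
                q.append(u)
    return dist


def enumerate_shortest_paths(adj, s, t, dist_from_t):
    """All shortest s-t paths, by DFS extending only edges that stay on a
    shortest path (distance-to-target decreases by 1 each step)."""
    if t not in dist_from_t or s not in dist_from_t:
        return []
    paths = []

    def extend(path):
        v = path[-1]
        if v == t:
            paths.append(list(path))
            return
        for u in adj[v]:
            if dist_from_t.get(u, -2) == dist_from_t[v] - 1:
                path.append(u)
                extend(path)
                path.pop()

    extend([s])
    return paths


def naive_topology(adj):
    """degree, betweenness, eccentricity, closeness per node, plus the
    average clustering coefficient, all by direct enumeration."""
    nodes = sorted(adj)
    k = {v: len(adj[v]) for v in nodes}
    bc = {v: 0.0 for v in nodes}
    ecc = {}
    cc = {}
    dist_from = {v: bfs_distances(adj, v) for v in nodes}
    for v in nodes:
        d = dist_from[v]
        ecc[v] = max(d.values())
        total = sum(d.values())
        cc[v] = (len(d) - 1) / total if total else 0.0
    for i, s in enumerate(nodes):
        for t in nodes[i + 1 :]:
            paths = enumerate_shortest_paths(adj, s, t, dist_from[t])
            if not paths:
                continue
            for path in paths:
                for v in path[1:-1]:
                    bc[v] += 1.0 / len(paths)
    clustering = []
    for v in nodes:
        nbrs = sorted(adj[v])
        if len(nbrs) < 2:
            clustering.append(0.0)
            continue
        links = sum(
            1
            for i, a in enumerate(nbrs)
            for b in nbrs[i + 1 :]
            if b in adj[a]
        )
        clustering.append(2.0 * links / (len(nbrs) * (len(nbrs) - 1)))
    acc = sum(clustering) / len(nodes) if nodes else 0.0
    return {"k": k, "bc": bc, "ecc": ecc, "cc": cc, "acc": acc}


def random_connected_adj(rng, max_nodes=7):
    """Random connected simple graph as an adjacency dict."""
    while True:
        n = int(rng.integers(2, max_nodes + 1))
        p = float(rng.uniform(0.3, 0.9))
        adj = {i: set() for i in range(n)}
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < p:
                    adj[i].add(j)
                    adj[j].add(i)
        if len(bfs_distances(adj, 0)) == n:
            return adj
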