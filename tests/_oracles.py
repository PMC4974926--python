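"""Independent brute-force oracles used to validate the fast implementations.

Each oracle deliberately takes a different computational route from the
code under test: rarefaction by exhaustive subsample enumeration,
d-separation by undirected path blocking, partial correlation through
the precision matrix of the sample covariance.
"""

from itertools import combinations

import numpy as np


def rarefaction_by_enumeration(counts, n):
    """E[species in subsample of n] by enumerating all C(N, n) subsamples."""
    individuals = []
    for sp, c in enumerate(counts):
        individuals.extend([sp] * int(c))
    total = 0
    combos = list(combinations(range(len(individuals)), n))
    for combo in combos:
        total += len({individuals[i] for i in combo})
    return total / len(combos)


def all_undirected_paths(edges, x, y, nodes):
    """Simple undirected paths between x and y in a DAG's skeleton."""
    adj = {v: set() for v in nodes}
    for u, v in edges:
        adj[u].add(v)
        adj[v].add(u)
    paths = []

    def walk(node, path):
        if node == y:
            paths.append(list(path))
            return
        for nxt in adj[node]:
            if nxt not in path:
                path.append(nxt)
                walk(nxt, path)
                path.pop()

    walk(x, [x])
    return paths


def d_separated(edges, x, y, z, nodes):
    """Path-blocking d-separation check on a DAG given conditioning set z.

    A path is blocked if some non-collider on it is in z, or some
    collider on it has neither itself nor any descendant in z.
    """
    z = set(z)
    parents = {v: set() for v in nodes}
    children = {v: set() for v in nodes}
    for u, v in edges:
        parents[v].add(u)
        children[u].add(v)

    def descendants(v):
        seen, stack = set(), [v]
        while stack:
            cur = stack.pop()
            for ch in children[cur]:
                if ch not in seen:
                    seen.add(ch)
                    stack.append(ch)
        return seen

    for path in all_undirected_paths(edges, x, y, nodes):
        blocked = False
        for i in range(1, len(path) - 1):
            prev, node, nxt = path[i - 1], path[i], path[i + 1]
            is_collider = prev in parents[node] and nxt in parents[node]
            if is_collider:
                if node not in z and not (descendants(node) & z):
                    blocked = True
                    break
            elif node in z:
                blocked = True
                break
        if not blocked:
            return False
    return True


def partial_corr_by_precision(x, y, zs):
    """Partial correlation via the inverse of the sample covariance matrix."""
    mat = np.column_stack([x, y, *zs])
    cov = np.cov(mat, rowvar=False)
    prec = np.linalg.inv(np.atleast_2d(cov))
    return -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])


def all_dags_upper_triangular(n_nodes):
    """Every DAG on n labelled nodes whose edges respect the node order.

    Every DAG is isomorphic to exactly one of these (fix a topological
    order), so structural properties checked here cover all DAGs of
    that size.
    """
    slots = [(i, j) for i in range(n_nodes) for j in range(i + 1, n_nodes)]
    for mask in range(1 << len(slots)):
        yield [slots[k] for k in range(len(slots)) if mask >> k & 1]
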