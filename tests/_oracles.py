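"""Independent brute-force reference implementations used by the tests.

These deliberately use explicit python loops over nodes and neighbors (no
shared code with the package's vectorized implementations).
"""

import itertools

import numpy as np


def naive_mpnn(graph, params):
    """Doubly-looped message passing over an AlignedGraph.

    States live on [root] + slots; h0 = [1, presence]; per iteration, for
    every node i: m_i = sum over neighbors j of LeakyReLU(W_M [h_i, h_j,
    e_ij]); h_i <- LeakyReLU(W_U [h_i, m_i]).  Returns final slot states.
    """
    def lrelu(x):
        return np.where(x > 0, x, params.leaky_slope * x)

    E = graph.edge_order
    n = E.shape[0]
    h = np.concatenate([[1.0], np.asarray(graph.node_presence, dtype=float)])
    for _ in range(params.iterations):
        m = np.zeros((n, params.d_m))
        for i in range(n):
            for j in range(n):
                if E[i, j] > 0:
                    x = np.array([h[i], h[j], E[i, j]])
                    m[i] += lrelu(params.w_message @ x)
        h_new = np.empty(n)
        for i in range(n):
            u = params.w_update[0] * h[i] + params.w_update[1:] @ m[i]
            h_new[i] = u if u > 0 else params.leaky_slope * u
        h = h_new
    return h[1:]


def active_set_nnls(X, y):
    """Exhaustive non-negative least squares for small feature counts.

    Tries every support set: solves the unconstrained least squares on the
    subset, keeps candidates whose coefficients are all non-negative, and
    returns the feasible solution with the smallest residual.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    p = X.shape[1]
    best_coef = np.zeros(p)
    best_obj = float(y @ y)
    for r in range(1, p + 1):
        for support in itertools.combinations(range(p), r):
            sub = X[:, support]
            coef_s, *_ = np.linalg.lstsq(sub, y, rcond=None)
            if np.any(coef_s < -1e-12):
                continue
            resid = y - sub @ coef_s
            obj = float(resid @ resid)
            if obj < best_obj - 1e-12:
                best_obj = obj
                best_coef = np.zeros(p)
                best_coef[list(support)] = coef_s
    return best_coef


def enumerate_small_graphs(max_slots=4):
    """Deterministic family of aligned graphs with <= max_slots slots.

    Covers every presence pattern over a fixed slot layout combined with a
    systematic sweep of edge subsets (root-slot and slot-slot bonds) and
    bond orders in {1, 1.5, 2}; edges incident to vacant slots are dropped.
    """
    from kinetree.ligand_tree import AlignedGraph, GraphTemplate

    template = GraphTemplate(paths=((0,), (1,), (0, 0), (1, 0))[:max_slots])
    s = template.total_slots
    candidates = [(0, j) for j in range(1, s + 1)]
    candidates += [(i, j) for i in range(1, s + 1) for j in range(i + 1, s + 1)]
    orders = [1.0, 1.5, 2.0]
    graphs = []
    for bits in range(2 ** s):
        presence = np.array([(bits >> k) & 1 for k in range(s)], dtype=float)
        present = {0} | {k + 1 for k in range(s) if presence[k]}
        usable = [e for e in candidates if e[0] in present and e[1] in present]
        n_subsets = 2 ** len(usable)
        stride = max(1, n_subsets // 32)  # deterministic coverage cap
        for esel in range(0, n_subsets, stride):
            edge_order = np.zeros((s + 1, s + 1))
            for k, (i, j) in enumerate(usable):
                if (esel >> k) & 1:
                    o = orders[(bits + k + esel) % 3]
                    edge_order[i, j] = edge_order[j, i] = o
            graphs.append(
                AlignedGraph(
                    name=f"enum-{bits}-{esel}",
                    node_presence=presence.copy(),
                    edge_order=edge_order,
                    template=template,
                )
            )
    return graphs
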