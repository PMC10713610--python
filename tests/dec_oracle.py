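"""Brute-force DEC(+J) oracle by explicit enumeration.

Independent of montaves.dec_model: states are frozensets of area indices,
rates and cladogenetic events are written directly from the process
definition, and the likelihood is an explicit sum over all assignments of
states and cladogenetic events to internal nodes.  Only feasible for tiny
trees and catalogs; used to pin down the pruning implementation.
"""

import itertools

import numpy as np
import scipy.linalg

from montaves.treekit import TimeTree


def all_states(n_areas):
    areas = range(n_areas)
    out = [frozenset()]
    for k in range(1, n_areas + 1):
        out.extend(frozenset(c) for c in itertools.combinations(areas, k))
    return out


def transition_matrix(states, d, e, t):
    """exp(Q t) with Q written directly from the anagenetic rules."""
    n_areas = max((max(s) + 1 for s in states if s), default=1)
    idx = {s: i for i, s in enumerate(states)}
    q = np.zeros((len(states), len(states)))
    for s in states:
        if not s:
            continue  # null range absorbing
        for a in range(n_areas):
            if a in s:
                q[idx[s], idx[s - {a}]] += e
            else:
                q[idx[s], idx[s | {a}]] += d * len(s)
        q[idx[s], idx[s]] = -q[idx[s]].sum() + q[idx[s], idx[s]]
    return scipy.linalg.expm(q * t)


def clado_events(state, n_areas, j=0.0, y=1.0, s_w=1.0, v=1.0):
    """Ordered (left, right, probability) cladogenetic events."""
    ev = {}

    def add(l, r, w):
        if w > 0:
            ev[(l, r)] = ev.get((l, r), 0.0) + w

    if len(state) == 1:
        add(state, state, 2 * y)
    else:
        for a in state:
            single = frozenset([a])
            rest = state - single
            add(single, state, s_w)
            add(state, single, s_w)
            add(single, rest, v)
            if len(rest) > 1:
                add(rest, single, v)
    for a in range(n_areas):
        if a not in state:
            single = frozenset([a])
            add(state, single, j)
            add(single, state, j)
    total = sum(ev.values())
    return [(l, r, w / total) for (l, r), w in ev.items()]


def enumerate_likelihood(tree: TimeTree, tip_states, n_areas, d, e, j=0.0):
    """(lnL, marginals) by summation over every internal-node assignment.

    ``tip_states``: tip label -> frozenset of area indices.  Marginals are
    returned as {node: {state: probability}} for internal nodes.
    """
    states = all_states(n_areas)
    nonnull = [s for s in states if s]
    pmat = {
        i: transition_matrix(states, d, e, float(tree.brlen[i]))
        for i in range(tree.n_nodes)
        if i != tree.root
    }
    idx = {s: i for i, s in enumerate(states)}
    internals = [i for i in range(tree.n_nodes) if not tree.is_tip(i)]

    choices = []
    for v in internals:
        opts = []
        for s in nonnull:
            for l, r, p in clado_events(s, n_areas, j=j):
                opts.append((s, l, r, p))
        choices.append(opts)

    prior = 1.0 / len(nonnull)
    total = 0.0
    marg = {v: {s: 0.0 for s in nonnull} for v in internals}
    pos = {v: k for k, v in enumerate(internals)}

    for combo in itertools.product(*choices):
        assigned = {v: combo[pos[v]] for v in internals}
        w = prior  # uniform non-null root prior
        ok = True
        for v in internals:
            s_v, l_v, r_v, p_ev = assigned[v]
            w *= p_ev
            for child, daughter in zip(tree.children[v], (l_v, r_v)):
                if tree.is_tip(child):
                    s_c = tip_states[tree.labels[child]]
                else:
                    s_c = assigned[child][0]
                w *= pmat[child][idx[daughter], idx[s_c]]
                if w == 0:
                    ok = False
                    break
            if not ok:
                break
        if ok and w > 0:
            total += w
            for v in internals:
                marg[v][assigned[v][0]] += w

    for v in internals:
        for s in marg[v]:
            marg[v][s] /= total
    return np.log(total), marg
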