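"""Shared brute-force oracle for optimal-antichain region selection tests."""

import itertools

import numpy as np

from optopattern import segmentation as seg


class StubNode:
    def __init__(self, parent):
        self.parent = parent
        self.children = []
        self.eligible = True
        self.area = 1


class StubTree:
    """Random tree with one synthetic pixel per node (ids root-first)."""

    def __init__(self, n_nodes, rng):
        self.nodes = [StubNode(-1)]
        for i in range(1, n_nodes):
            p = int(rng.integers(0, i))
            self.nodes.append(StubNode(p))
            self.nodes[p].children.append(i)
        self.root = 0
        self.nodes[0].eligible = False
        side = int(np.ceil(np.sqrt(n_nodes)))
        self.shape = (side, side)
        self._direct = [np.array([i]) for i in range(n_nodes)]

    def node_pixels(self, nid):
        out, stack = [], [nid]
        while stack:
            n = stack.pop()
            out.append(self._direct[n])
            stack.extend(self.nodes[n].children)
        return np.concatenate(out)


def brute_force_antichain_optimum(tree, scores, thr):
    """Exhaustive search over all antichains of eligible scored nodes."""
    elig = [i for i, n in enumerate(tree.nodes) if n.eligible and i in scores]

    def is_ancestor(a, b):
        p = tree.nodes[b].parent
        while p != -1:
            if p == a:
                return True
            p = tree.nodes[p].parent
        return False

    best = 0.0
    for r in range(1, len(elig) + 1):
        for combo in itertools.combinations(elig, r):
            if any(is_ancestor(a, b) for a in combo for b in combo if a != b):
                continue
            best = max(best, sum(scores[i] - thr for i in combo))
    return best


def dp_selected_value(tree, scores, thr):
    """Total score of the regions the DP actually selected (read off the mask)."""
    mask = seg.select_nonoverlapping(tree, scores, thr)
    flat = mask.ravel()
    total = 0.0
    for lbl in np.unique(flat):
        if lbl == 0:
            continue
        px = frozenset(np.nonzero(flat == lbl)[0].tolist())
        nid = next(
            i for i in range(len(tree.nodes))
            if frozenset(tree.node_pixels(i).tolist()) == px
        )
        total += scores[nid] - thr
    return total
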