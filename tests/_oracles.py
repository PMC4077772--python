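"""Independent oracles used by the test suite.

These deliberately avoid the library's own code paths: topology search by
exhaustive enumeration with least-squares branch fitting, peptide masses via
pyteomics' composition arithmetic, LCS by brute-force subsequence
enumeration, and an exhaustive scan for the signal-cleavage rule.
"""

from __future__ import annotations

import itertools

import numpy as np


# ---------------------------------------------------------------- phylogeny

def enumerate_topologies(labels: list[str]):
    """All unrooted binary topologies over the labels, as edge lists.

    Nodes are leaf labels (str) or internal ids (int). Built by sequential
    taxon addition: each new leaf subdivides every existing edge in turn.
    (2n-5)!! topologies for n leaves.
    """
    a, b, c, *rest = labels
    base = [(a, 0), (b, 0), (c, 0)]
    trees = [base]
    next_internal = 1
    for leaf in rest:
        grown = []
        for tree in trees:
            for i, (u, v) in enumerate(tree):
                mid = next_internal
                new = tree[:i] + tree[i + 1:]
                new += [(u, mid), (mid, v), (leaf, mid)]
                grown.append(new)
        next_internal += 1
        trees = grown
    return trees


def _leaf_paths(edges, labels):
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)

    def path_edges(src, dst):
        stack = [(src, None, [])]
        while stack:
            node, prev, used = stack.pop()
            if node == dst:
                return used
            for nxt in adj[node]:
                if nxt != prev:
                    idx = edge_index[frozenset((node, nxt))]
                    stack.append((nxt, node, used + [idx]))
        raise AssertionError("disconnected tree")

    edge_index = {frozenset(e): i for i, e in enumerate(edges)}
    rows = []
    for i, j in itertools.combinations(range(len(labels)), 2):
        indicator = np.zeros(len(edges))
        for idx in path_edges(labels[i], labels[j]):
            indicator[idx] = 1.0
        rows.append(indicator)
    return np.array(rows)


def topology_splits(edges, labels):
    """Canonical non-trivial splits of an edge-list topology."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    label_set = set(labels)
    ref = min(label_set)
    splits = set()
    for u, v in edges:
        # leaves reachable from v without crossing (u, v)
        seen, stack = set(), [v]
        blocked = {u}
        while stack:
            node = stack.pop()
            if node in seen or node in blocked:
                continue
            seen.add(node)
            stack.extend(adj[node] - seen - blocked)
        side = frozenset(n for n in seen if isinstance(n, str))
        canon = frozenset(label_set - side) if ref in side else side
        if 2 <= len(canon) <= len(label_set) - 2:
            splits.add(canon)
    return splits


def least_squares_topology(dm_labels, dm_matrix):
    """Best topology by exhaustive least-squares fit; returns (splits, residual)."""
    d = np.array([dm_matrix[i, j]
                  for i, j in itertools.combinations(range(len(dm_labels)), 2)])
    best = None
    for edges in enumerate_topologies(list(dm_labels)):
        a_mat = _leaf_paths(edges, list(dm_labels))
        x, *_ = np.linalg.lstsq(a_mat, d, rcond=None)
        resid = float(np.sum((a_mat @ x - d) ** 2))
        if best is None or resid < best[1] - 1e-12:
            best = (topology_splits(edges, list(dm_labels)), resid)
    return best


def random_additive_matrix(labels, rng):
    """A random additive distance matrix from a random binary topology."""
    order = list(labels)
    rng.shuffle(order)
    edges = enumerate_topologies(order)[0]
    # randomise the attachment pattern by picking a random enumerated topology
    all_topos = enumerate_topologies(order)
    edges = all_topos[rng.integers(len(all_topos))]
    lengths = {frozenset(e): rng.uniform(0.1, 1.0) for e in edges}
    a_mat = _leaf_paths(edges, list(labels))
    x = np.array([lengths[frozenset(e)] for e in edges])
    cond = a_mat @ x
    n = len(labels)
    d = np.zeros((n, n))
    for (i, j), val in zip(itertools.combinations(range(n), 2), cond):
        d[i, j] = d[j, i] = val
    return d, topology_splits(edges, list(labels))


# ---------------------------------------------------------------- mass spec

def pyteomics_neutral_mass(sequence: str, amidated: bool) -> float:
    """Monoisotopic neutral mass via pyteomics composition arithmetic."""
    from pyteomics import mass
    m = mass.calculate_mass(sequence=sequence)
    if amidated:
        m += mass.calculate_mass(formula="NH2") - mass.calculate_mass(formula="OH")
    return m


# ------------------------------------------------------------------ synteny

def brute_force_lcs(seq_a, seq_b, match) -> int:
    """Longest common subsequence by enumerating subsequences of the shorter."""
    if len(seq_b) < len(seq_a):
        def flipped(b, a):
            return match(a, b)
        return brute_force_lcs(seq_b, seq_a, flipped)
    best = 0
    for r in range(len(seq_a), 0, -1):
        for sub in itertools.combinations(seq_a, r):
            # greedy check: can sub be matched in order within seq_b?
            j = 0
            hit = 0
            for a in sub:
                while j < len(seq_b) and not match(a, seq_b[j]):
                    j += 1
                if j == len(seq_b):
                    break
                hit += 1
                j += 1
            if hit == r:
                return r
    return best


# --------------------------------------------------------------- signal cut

def exhaustive_signal_scan(protein, window=7, threshold=1.6, limit=40):
    """Re-derivation of the signal-cut rule by explicit scanning.

    Returns the accepted cut position or None; written independently of the
    package (plain loops, no shared helpers).
    """
    kd = {
        "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
        "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
        "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9,
        "R": -4.5,
    }
    if len(protein) < 15:
        return None
    head = protein[:limit]
    if len(head) < window:
        return None
    means = [sum(kd[aa] for aa in head[s:s + window]) / window
             for s in range(len(head) - window + 1)]
    peak = max(means)
    if peak < threshold:
        return None
    core_start = means.index(peak)
    core_end = core_start + window
    for p in range(core_end, core_end + 9):
        if p < 3 or p >= len(protein):
            continue
        if protein[p - 1] in "AGSCTQ" and protein[p - 3] in "AVSCTGIL":
            return p
    return None


#: Published monoisotopic residue masses, retyped for the naive-sum oracle.
NAIVE_RESIDUE_TABLE = {
    "A": 71.03711, "R": 156.10111, "N": 114.04293, "D": 115.02694,
    "C": 103.00919, "E": 129.04259, "Q": 128.05858, "G": 57.02146,
    "H": 137.05891, "I": 113.08406, "L": 113.08406, "K": 128.09496,
    "M": 131.04049, "F": 147.06841, "P": 97.05276, "S": 87.03203,
    "T": 101.04768, "V": 99.06841, "W": 186.07931, "Y": 163.06333,
}


def naive_peptide_mass(sequence: str, amidated: bool) -> float:
    """Naive residue-by-residue summation over the published mass table."""
    total = 18.010565  # water
    if amidated:
        total -= 0.984016
    for aa in sequence:
        total += NAIVE_RESIDUE_TABLE[aa]
    return total
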