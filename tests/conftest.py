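"""Shared fixtures: tiny alignments, sample tables and synthetic datasets."""

import itertools

import numpy as np
import pytest

import barcodescreen as bs


@pytest.fixture
def make_alignment():
    def _make(seqs, ids=None, region_name=""):
        ids = ids or [f"s{i + 1}" for i in range(len(seqs))]
        return bs.MultipleAlignment.from_sequences(ids, seqs, region_name=region_name)

    return _make


@pytest.fixture(scope="session")
def scaled_dataset():
    """One deterministic scaled-down synthetic study (no captures)."""
    return bs.simulate_dataset(bs.SimulationConfig.scaled_down(seed=11))


@pytest.fixture(scope="session")
def table_one_style_samples():
    """32 accessions over 21 species, nine species with 2-3 accessions."""
    pairs = []
    for i in range(12):  # singletons
        pairs.append((f"acc{i:02d}", f"species{i:02d}"))
    k = 12
    for i, count in enumerate([2] * 7 + [3] * 2):
        sp = f"species{12 + i:02d}"
        for _ in range(count):
            pairs.append((f"acc{k:02d}", sp))
            k += 1
    return bs.SampleTable.from_pairs(pairs)


def brute_force_pi(seqs):
    """Independent Pi oracle: plain-python mean pairwise p with pairwise deletion."""
    ps = []
    for a, b in itertools.combinations(seqs, 2):
        kept = diff = 0
        for x, y in zip(a, b):
            if x in "ACGT" and y in "ACGT":
                kept += 1
                diff += x != y
        if kept:
            ps.append(diff / kept)
    return sum(ps) / len(ps) if ps else float("nan")


def random_additive_case(rng, n_taxa):
    """Random binary tree -> (labels, additive distance matrix, bipartition set).

    Built by successive random joins; path distances computed on the explicit
    parent structure, independently of any package tree code.
    """
    labels = [f"t{i}" for i in range(n_taxa)]
    parent = {}
    length = {}
    nodes = list(labels)
    counter = 0
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        a, b = nodes[j], nodes[i]
        new = f"n{counter}"
        counter += 1
        parent[a] = parent[b] = new
        length[a] = 0.05 + rng.random()
        length[b] = 0.05 + rng.random()
        nodes = [x for x in nodes if x not in (a, b)] + [new]
    root = nodes[0]

    def path_to_root(x):
        out = []
        while x != root:
            out.append(x)
            x = parent[x]
        return out

    n = n_taxa
    D = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        pa = path_to_root(labels[i])
        pb = path_to_root(labels[j])
        sa, sb = set(pa), set(pb)
        d = sum(length[x] for x in pa if x not in sb)
        d += sum(length[x] for x in pb if x not in sa)
        D[i, j] = D[j, i] = d

    def clade_tips(x):
        if x in labels:
            return {x}
        kids = [c for c, p in parent.items() if p == x]
        out = set()
        for c in kids:
            out |= clade_tips(c)
        return out

    all_tips = frozenset(labels)
    bips = set()
    for x in parent:
        below = frozenset(clade_tips(x))
        if 2 <= len(below) <= n - 2:
            bips.add(frozenset({below, all_tips - below}))
    return labels, D, bips


def distance_matrix_from(labels, D):
    n = len(labels)
    return bs.DistanceMatrix(
        ids=list(labels),
        p=np.asarray(D, dtype=float),
        diff_counts=np.zeros((n, n), dtype=np.int64),
        retained_sites=np.ones((n, n), dtype=np.int64),
    )
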