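"""Shared fixtures: toy trees, random-tree battery, brute-force parsimony oracle."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from cneloss.phylo import Phylogeny, Role, Status, parse_tree

# 12-leaf mammal-like fixture: seven loss-search species, three presence-only,
# two outgroups (mirrors the default synthetic tree).
FIXTURE_NEWICK = (
    "(((((((mouse:0.35,rat:0.33)mouse_rat:0.06,kangaroo_rat:0.33)mrk:0.02,"
    "guinea_pig:0.34)rodents:0.03,(human:0.07,rhesus:0.09)primates:0.06)"
    "euarchontoglires:0.02,(cow:0.20,(dog:0.17,horse:0.13)zooamata:0.02)"
    "laurasiatheria:0.02)boreoeutheria:0.01,elephant:0.17)eutheria:0.15,"
    "(opossum:0.36,platypus:0.46)outgroups:0.10)root;"
)
FIXTURE_ROLES = {
    "mouse": "loss_search",
    "rat": "loss_search",
    "guinea_pig": "loss_search",
    "cow": "loss_search",
    "horse": "loss_search",
    "dog": "loss_search",
    "elephant": "loss_search",
    "kangaroo_rat": "presence_only",
    "human": "presence_only",
    "rhesus": "presence_only",
    "opossum": "outgroup",
    "platypus": "outgroup",
}


@pytest.fixture(scope="session")
def mammal_tree() -> Phylogeny:
    return parse_tree(FIXTURE_NEWICK, FIXTURE_ROLES)


@pytest.fixture(scope="session")
def rodent_tree() -> Phylogeny:
    """Rodent clade with an explicit separating species and outgroup."""
    return parse_tree(
        "((((mouse:0.35,rat:0.33)mr:0.1,kangaroo_rat:0.35)mrk:0.03,"
        "guinea_pig:0.4)rod:0.05,out:0.5)root;",
        {
            "mouse": "loss_search",
            "rat": "loss_search",
            "kangaroo_rat": "loss_search",
            "guinea_pig": "loss_search",
            "out": "outgroup",
        },
    )


def status_vector(tree: Phylogeny, **overrides: str) -> dict[str, Status]:
    """All-conserved vector with keyword overrides ('lost'/'missing')."""
    sv = {leaf: Status.CONSERVED for leaf in tree.leaves}
    for sp, st in overrides.items():
        sv[sp] = Status(st)
    return sv


# ------------------------------------------------------- brute-force oracle


def dollo_oracle(
    tree: Phylogeny, lost: int, missing: int, placement: str = "ancestral"
) -> frozenset[int]:
    """Minimal-event Dollo loss placement by exhaustive enumeration.

    Enumerates antichains of branches whose clades contain no conserved leaf
    and at least one lost leaf, keeps those covering every lost leaf, takes
    the minimum event count, and breaks ties by total node depth: minimal
    (most ancestral branches) for the default rule, maximal (MRCA of the
    lost leaves) for the shallow rule. Independent of the production
    algorithm: no clade-maximality reasoning, just exhaustive search.
    """
    conserved = tree.all_leaves_mask & ~(lost | missing)
    if lost == 0:
        return frozenset()
    if conserved == 0:
        raise ValueError("no conserved leaf")
    candidates = [
        i
        for i in range(len(tree.names))
        if i != tree.root
        and tree.leaf_mask[i] & conserved == 0
        and tree.leaf_mask[i] & lost != 0
    ]
    best: list[tuple[int, frozenset[int]]] = []
    for size in range(1, len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            union = 0
            ok = True
            for i in combo:
                if tree.leaf_mask[i] & union:
                    ok = False
                    break
                union |= tree.leaf_mask[i]
            if not ok or (lost & ~union):
                continue
            depth_sum = sum(tree.depth[i] for i in combo)
            best.append((depth_sum, frozenset(combo)))
        if best:
            break
    if not best:
        raise ValueError("no consistent labeling")

    def key(entry):
        depth_sum, combo = entry
        return (depth_sum, sorted(tree.names[i] for i in combo))

    if placement == "ancestral":
        return min(best, key=key)[1]
    return max(best, key=key)[1]


def random_trees(n_trees: int, max_loss_leaves: int = 6, seed: int = 20240901):
    """Battery of random rooted trees with <= max_loss_leaves loss-search
    leaves plus one conserved outgroup; some are multifurcating."""
    rng = np.random.default_rng(seed)
    trees = []
    for t in range(n_trees):
        # half the battery at the maximum size (exhaustive 3^max vectors),
        # the rest smaller
        if t % 2 == 0:
            n_leaves = max_loss_leaves
        else:
            n_leaves = int(rng.integers(2, max_loss_leaves + 1))
        nodes = [f"s{i}" for i in range(n_leaves)]
        newicks = {name: name for name in nodes}
        while len(nodes) > 1:
            k = int(rng.integers(2, min(3, len(nodes)) + 1))
            picks = list(rng.choice(len(nodes), size=k, replace=False))
            merged = [nodes[i] for i in picks]
            for name in merged:
                nodes.remove(name)
            joined = ",".join(
                f"{newicks.pop(m)}:{rng.uniform(0.05, 0.5):.3f}" for m in merged
            )
            new = f"n{t}_{len(nodes)}_{len(newicks)}"
            nodes.append(new)
            newicks[new] = f"({joined}){new}"
        inner = newicks[nodes[0]]
        newick = f"({inner}:{rng.uniform(0.05, 0.5):.3f},og:0.4)root;"
        roles = {f"s{i}": "loss_search" for i in range(n_leaves)}
        roles["og"] = "outgroup"
        trees.append(parse_tree(newick, roles))
    return trees


def all_status_masks(tree: Phylogeny):
    """Every status vector over the loss-search leaves (outgroup conserved):
    yields (lost_mask, missing_mask) for all 3^n assignments."""
    loss_leaves = [
        leaf for leaf in tree.leaves if tree.roles[leaf] == Role.LOSS_SEARCH
    ]
    bits = [1 << tree.leaf_index[leaf] for leaf in loss_leaves]
    for combo in itertools.product((0, 1, 2), repeat=len(loss_leaves)):
        lost = missing = 0
        for state, bit in zip(combo, bits):
            if state == 1:
                lost |= bit
            elif state == 2:
                missing |= bit
        yield lost, missing
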