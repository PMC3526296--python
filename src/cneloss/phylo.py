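"""Rooted species tree with leaf roles and missing-data-aware loss parsimony.

A conserved non-coding element (CNE) is an ancestral character that is present
at the root and can only be lost (Dollo-style presence/absence evolution).
Given a per-species status vector in {CONSERVED, LOST, MISSING}, this module
places loss events on tree branches by parsimony, treating MISSING species as
uninformative, and enumerates/validates the branch combinations on which two
or more *independent* losses of the same element can be observed.

Leaves carry one of three roles:

``loss_search``
    high-quality genomes in which complete losses are called;
``presence_only``
    genomes where alignment counts as presence but absence is missing data
    (typically low-coverage assemblies);
``outgroup``
    species used only to establish that the element is ancestral.

Internally each node owns a bitmask over the leaf set, so parsimony
re-inference is a handful of integer operations and is memoised per tree —
the Monte-Carlo null model calls it millions of times.
"""

from __future__ import annotations

import enum
import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy

__all__ = [
    "Status",
    "Role",
    "Phylogeny",
    "parse_tree",
    "infer_loss_branches",
    "count_independent",
    "is_valid_combination",
    "enumerate_valid_combinations",
    "LossClassification",
]


class Status(str, enum.Enum):
    """Per-species presence status of a CNE."""

    CONSERVED = "conserved"
    LOST = "lost"
    MISSING = "missing"


class Role(str, enum.Enum):
    """Role of a leaf in the loss screen."""

    LOSS_SEARCH = "loss_search"
    PRESENCE_ONLY = "presence_only"
    OUTGROUP = "outgroup"


_ROLE_ALIASES = {r.value: r for r in Role}


@dataclass(frozen=True)
class LossClassification:
    """Outcome of :func:`count_independent` for one CNE."""

    label: str  # "no_loss" | "lineage_specific" | "independent"
    n_independent: int  # 0 unless label == "independent"


class Phylogeny:
    """Rooted tree with branch lengths, node depths and leaf roles.

    Branches are identified by the name of the node they lead *into* (their
    child node); the root has no branch. Unnamed internal nodes get
    deterministic derived names (concatenated initials of their sorted
    descendant leaf names, disambiguated with a numeric suffix on collision)
    so branch identities are stable across runs.
    """

    def __init__(
        self,
        names: Sequence[str],
        parent: Sequence[int],
        branch_length: Sequence[float],
        leaf_index: Mapping[str, int],
        roles: Mapping[str, Role],
    ) -> None:
        self.names = list(names)
        self.parent = list(parent)
        self.branch_length = list(branch_length)
        n = len(self.names)
        self.children: list[list[int]] = [[] for _ in range(n)]
        self.root = -1
        for i, p in enumerate(self.parent):
            if p < 0:
                self.root = i
            else:
                self.children[p].append(i)
        if self.root < 0:
            raise ValueError("tree has no root")
        # depth = edge count from root
        self.depth = [0] * n
        order = [self.root]
        for i in order:
            for c in self.children[i]:
                self.depth[c] = self.depth[i] + 1
                order.append(c)
        self._preorder = order
        self._postorder = order[::-1]
        self.node_index = {name: i for i, name in enumerate(self.names)}
        if len(self.node_index) != n:
            raise ValueError("node names are not unique")
        self.leaf_index = dict(leaf_index)  # leaf name -> bit position
        self.roles = dict(roles)
        self.n_leaves = len(self.leaf_index)
        # leaf bitmask per node
        self.leaf_mask = [0] * n
        for i in self._postorder:
            if not self.children[i]:
                self.leaf_mask[i] = 1 << self.leaf_index[self.names[i]]
            else:
                m = 0
                for c in self.children[i]:
                    m |= self.leaf_mask[c]
                self.leaf_mask[i] = m
        self.all_leaves_mask = self.leaf_mask[self.root]
        self.role_mask = {role: 0 for role in Role}
        for leaf, role in self.roles.items():
            self.role_mask[role] |= 1 << self.leaf_index[leaf]
        if self.role_mask[Role.OUTGROUP] == 0:
            raise ValueError("tree must contain at least one outgroup leaf")
        # root-to-node path length in branch-length units
        self.root_distance = [0.0] * n
        for i in self._preorder:
            if i != self.root:
                self.root_distance[i] = (
                    self.root_distance[self.parent[i]] + self.branch_length[i]
                )
        self._infer_cache: dict[tuple[int, int, str], frozenset[int]] = {}
        self._bit_to_leaf = {1 << b: name for name, b in self.leaf_index.items()}

    # ------------------------------------------------------------------ util

    @property
    def leaves(self) -> list[str]:
        return sorted(self.leaf_index, key=self.leaf_index.get)

    def is_leaf(self, i: int) -> bool:
        return not self.children[i]

    def species_mask(self, species: Iterable[str]) -> int:
        m = 0
        for s in species:
            m |= 1 << self.leaf_index[s]
        return m

    def mask_species(self, mask: int) -> set[str]:
        out = set()
        while mask:
            low = mask & -mask
            out.add(self._bit_to_leaf[low])
            mask ^= low
        return out

    def branch_id(self, name: str) -> int:
        try:
            i = self.node_index[name]
        except KeyError:
            raise KeyError(f"unknown node {name!r}") from None
        if i == self.root:
            raise ValueError("the root has no branch")
        return i

    def loss_search_capable_branches(self) -> list[str]:
        """Branches on which a loss event can ever be observed.

        A branch qualifies if at least one loss-search leaf lies below it
        (a call needs >=1 LOST leaf) and no outgroup leaf does (outgroups
        anchor ancestry and sit outside the loss screen). Presence-only
        leaves below such a branch do not disqualify it: an internal-branch
        loss shows loss or missing data for all descendant species.
        """
        ls = self.role_mask[Role.LOSS_SEARCH]
        og = self.role_mask[Role.OUTGROUP]
        return sorted(
            self.names[i]
            for i in self._preorder
            if i != self.root
            and self.leaf_mask[i] & ls
            and not self.leaf_mask[i] & og
        )

    # ----------------------------------------------------------- parsimony

    def infer_masks(
        self, lost: int, missing: int, placement: str = "ancestral"
    ) -> frozenset[int]:
        """Loss branches (node ids) for a status vector given as bitmasks.

        ``lost`` and ``missing`` are disjoint leaf bitmasks; every other leaf
        is conserved. Returns the branch set: one branch above each maximal
        clade whose leaves are all LOST-or-MISSING and which contains at
        least one LOST leaf.  ``placement="shallow"`` instead reports, inside
        each such maximal clade, the branch above the MRCA of its LOST
        leaves.
        """
        if lost & missing:
            raise ValueError("a leaf cannot be both lost and missing")
        key = (lost, missing, placement)
        cached = self._infer_cache.get(key)
        if cached is not None:
            return cached
        if placement not in ("ancestral", "shallow"):
            raise ValueError(f"unknown placement rule {placement!r}")
        absent = lost | missing
        result: list[int] = []
        if lost:
            if self.leaf_mask[self.root] & ~absent == 0:
                raise ValueError(
                    "every leaf is lost or missing; no conserved outgroup "
                    "anchors the element as ancestral"
                )
            stack = [self.root]
            while stack:
                i = stack.pop()
                lm = self.leaf_mask[i]
                if lm & lost == 0:
                    continue  # nothing to place below
                if lm & ~absent == 0:
                    # maximal all-lost-or-missing clade with >=1 LOST leaf
                    if placement == "shallow":
                        while True:
                            kids = [
                                c
                                for c in self.children[i]
                                if self.leaf_mask[c] & lost
                            ]
                            if len(kids) == 1:
                                i = kids[0]
                            else:
                                break
                    result.append(i)
                else:
                    stack.extend(self.children[i])
        out = frozenset(result)
        self._infer_cache[key] = out
        return out

    def status_masks(self, sv: Mapping[str, Status]) -> tuple[int, int]:
        """Validate a status vector and return (lost, missing) bitmasks."""
        lost = missing = 0
        for leaf, b in self.leaf_index.items():
            try:
                st = sv[leaf]
            except KeyError:
                raise ValueError(f"status vector lacks species {leaf!r}") from None
            if st == Status.LOST:
                if self.roles[leaf] != Role.LOSS_SEARCH:
                    raise ValueError(
                        f"{leaf!r} has role {self.roles[leaf].value} and "
                        "cannot be LOST"
                    )
                lost |= 1 << b
            elif st == Status.MISSING:
                missing |= 1 << b
            elif st != Status.CONSERVED:
                raise ValueError(f"bad status {st!r} for {leaf!r}")
        extra = set(sv) - set(self.leaf_index)
        if extra:
            raise ValueError(f"status vector names unknown species {sorted(extra)}")
        return lost, missing


# --------------------------------------------------------------- parse_tree


def _derived_name(leaf_names: Iterable[str]) -> str:
    return "".join(n[0] for n in sorted(leaf_names))


def parse_tree(newick_text: str, roles: Mapping[str, str | Role]) -> Phylogeny:
    """Parse a rooted Newick tree with branch lengths and attach leaf roles.

    ``roles`` must map every leaf name to one of ``loss_search``,
    ``presence_only`` or ``outgroup``. Internal nodes without labels are
    auto-named from the initials of their sorted descendant leaves.

    Raises ``ValueError`` for a leaf without a role, a role naming an unknown
    leaf, or a negative branch length.
    """
    tree = dendropy.Tree.get(
        data=newick_text,
        schema="newick",
        suppress_internal_node_taxa=False,
        preserve_underscores=True,
    )
    role_map: dict[str, Role] = {}
    for sp, r in roles.items():
        role_map[sp] = _ROLE_ALIASES[r] if isinstance(r, str) else Role(r)

    dn_nodes = list(tree.postorder_node_iter())
    names: list[str] = []
    parent: list[int] = []
    blen: list[float] = []
    idx_of: dict[int, int] = {}
    used_names: set[str] = set()
    leaf_names: list[str] = []

    def node_label(nd) -> str | None:
        if nd.taxon is not None and nd.taxon.label:
            return nd.taxon.label
        if nd.label:
            return nd.label
        return None

    for nd in dn_nodes:
        label = node_label(nd)
        if nd.is_leaf():
            if label is None:
                raise ValueError("leaf without a name in Newick input")
            name = label
            leaf_names.append(name)
        else:
            if label is None:
                name = _derived_name(
                    node_label(lf) for lf in nd.leaf_iter()
                )
            else:
                name = label
            k = 2
            base = name
            while name in used_names:
                name = f"{base}_{k}"
                k += 1
        if name in used_names:
            raise ValueError(f"duplicate node name {name!r}")
        used_names.add(name)
        idx_of[id(nd)] = len(names)
        names.append(name)
        bl = nd.edge.length
        if nd.parent_node is None:
            parent.append(-1)
            blen.append(0.0)
        else:
            if bl is None:
                raise ValueError(f"branch into {name!r} lacks a length")
            if bl < 0:
                raise ValueError(f"negative branch length on {name!r}")
            parent.append(-2)  # fill after all indices known
            blen.append(float(bl))
    for nd in dn_nodes:
        if nd.parent_node is not None:
            parent[idx_of[id(nd)]] = idx_of[id(nd.parent_node)]

    missing_roles = set(leaf_names) - set(role_map)
    if missing_roles:
        raise ValueError(f"no role supplied for leaves {sorted(missing_roles)}")
    unknown = set(role_map) - set(leaf_names)
    if unknown:
        raise ValueError(f"roles name unknown leaves {sorted(unknown)}")

    leaf_index = {name: b for b, name in enumerate(sorted(leaf_names))}
    return Phylogeny(names, parent, blen, leaf_index, role_map)


# ----------------------------------------------------- high-level operations


def infer_loss_branches(
    sv: Mapping[str, Status],
    tree: Phylogeny,
    placement: str = "ancestral",
) -> set[str]:
    """Infer the set of loss branches for one CNE's status vector.

    MISSING species are uninformative: the rule returns the branch above each
    maximal clade all of whose leaves are LOST or MISSING and which contains
    at least one LOST leaf. Equivalently, prune MISSING leaves, take maximal
    all-LOST clades, and map each pruned edge back to its most ancestral
    consistent original branch. Any two returned branches are separated by at
    least one CONSERVED leaf by construction.

    ``placement="shallow"`` maps each event to the MRCA of its LOST leaves
    instead (the most recent consistent branch).
    """
    lost, missing = tree.status_masks(sv)
    return {tree.names[i] for i in tree.infer_masks(lost, missing, placement)}


def count_independent(
    branches: Iterable[str], tree: Phylogeny
) -> LossClassification:
    """Classify a CNE by its inferred loss-branch set.

    0 branches -> ``no_loss``; 1 -> ``lineage_specific``; k>=2 ->
    ``independent`` with multiplicity k. Branch clades must be disjoint
    (guaranteed when the set comes from one :func:`infer_loss_branches`
    call); nested/overlapping clades raise ``ValueError``.
    """
    ids = [tree.branch_id(b) for b in branches]
    for a, b in itertools.combinations(ids, 2):
        if tree.leaf_mask[a] & tree.leaf_mask[b]:
            raise ValueError(
                "overlapping loss-branch clades: not a single inference result"
            )
    k = len(ids)
    if k == 0:
        return LossClassification("no_loss", 0)
    if k == 1:
        return LossClassification("lineage_specific", 0)
    return LossClassification("independent", k)


def is_valid_combination(
    tree: Phylogeny,
    combo: Iterable[str],
    missing: Iterable[str] = (),
    placement: str = "ancestral",
) -> bool:
    """Whether a branch set is observable as that exact set of independent losses.

    True iff (a) no leaf below any branch in ``combo`` is missing, and
    (b) labelling every leaf below the combo LOST and every other non-missing
    leaf CONSERVED, parsimony re-inference returns exactly ``combo``. This is
    the single source of truth for "independent lineage combinations": e.g.
    {mouse, rat} is invalid (re-inference merges the sisters into one loss in
    their common ancestor), and {mouse-rat ancestor, guinea pig} is invalid
    for a CNE with kangaroo rat missing because no conserved species then
    separates the two events.
    """
    ids = [tree.branch_id(b) for b in combo]
    if not ids:
        raise ValueError("combo must be non-empty")
    if len(set(ids)) != len(ids):
        raise ValueError("combo branches must be distinct")
    mmask = tree.species_mask(missing)
    lost = 0
    for i in ids:
        if tree.leaf_mask[i] & mmask:
            return False
        lost |= tree.leaf_mask[i]
    inferred = tree.infer_masks(lost, mmask, placement)
    return inferred == frozenset(ids)


def enumerate_valid_combinations(
    tree: Phylogeny, k: int, placement: str = "ancestral"
) -> list[frozenset[str]]:
    """All k-subsets of loss-search-capable branches observable as k
    independent losses with no missing data, in deterministic sorted order.
    """
    if k not in (2, 3):
        raise ValueError("k must be 2 or 3")
    capable = tree.loss_search_capable_branches()
    out = [
        frozenset(c)
        for c in itertools.combinations(capable, k)
        if is_valid_combination(tree, c, (), placement)
    ]
    out.sort(key=lambda s: tuple(sorted(s)))
    return out
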