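"""Place CNE losses on tree branches by parsimony, with missing data.

A loss shared by sister species is one event in their common ancestor; two
losses count as independent only if a species conserving the CNE separates
them. Missing data merges upward: a loss branch may end above species with
no usable assembly.
"""

from cneloss import (
    Status,
    count_independent,
    enumerate_valid_combinations,
    infer_loss_branches,
    is_valid_combination,
    parse_tree,
)

tree = parse_tree(
    "((((mouse:0.35,rat:0.33)mr:0.1,kangaroo_rat:0.35)mrk:0.03,"
    "guinea_pig:0.4)rod:0.05,opossum:0.5)root;",
    {
        "mouse": "loss_search",
        "rat": "loss_search",
        "kangaroo_rat": "loss_search",
        "guinea_pig": "loss_search",
        "opossum": "outgroup",
    },
)

conserved = {sp: Status.CONSERVED for sp in tree.leaves}

for label, overrides in [
    ("mouse + rat lost", {"mouse": Status.LOST, "rat": Status.LOST}),
    ("mouse + guinea pig lost", {"mouse": Status.LOST, "guinea_pig": Status.LOST}),
    ("mouse lost, rat missing", {"mouse": Status.LOST, "rat": Status.MISSING}),
]:
    sv = {**conserved, **overrides}
    branches = infer_loss_branches(sv, tree)
    cls = count_independent(branches, tree)
    print(f"{label:28s} -> loss branches {sorted(branches)} ({cls.label})")

print()
print("mouse+rat merge into one ancestral event; mouse+guinea pig stay two")
print("events because rat and kangaroo rat conserve the element in between;")
print("with rat missing, the single mouse loss could lie anywhere up to the")
print("mouse-rat ancestor and is reported on the most ancestral branch.")

print("\nvalid 2-branch combinations on this tree (no missing data):")
for combo in enumerate_valid_combinations(tree, 2):
    print("  " + " + ".join(sorted(combo)))
print("\n{mr, guinea_pig} valid?", is_valid_combination(tree, ["mr", "guinea_pig"]))
print("...with kangaroo rat missing?",
      is_valid_combination(tree, ["mr", "guinea_pig"], missing=["kangaroo_rat"]),
      "(no conserved separator left)")
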