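"""Build an analyzable CNE catalog from candidate conserved elements.

Constructs a small candidate set with one violation of each inclusion rule,
applies the filters and prints the audit. The accepted elements are the ones
any loss would later be called on: long enough, non-coding, non-repetitive,
unique in the reference and conserved out to an outgroup.
"""

from cneloss import CNERecord, apply_cne_filters, flag_ancestry, select_highly_conserved

candidates = [
    CNERecord("short", "chr1", 1000, 1068),          # 68 bp: under the 70 bp floor
    CNERecord("exonic", "chr1", 5000, 5200),         # overlaps a coding exon
    CNERecord("repeat", "chr1", 8000, 8200),         # overlaps a transposon
    CNERecord("coding_like", "chr1", 11_000, 11_200),  # Blastx E = 1e-6
    CNERecord("paralogous", "chr1", 14_000, 14_200),   # 2nd BLAT score 60
    CNERecord("recent", "chr1", 17_000, 17_200),       # no outgroup alignment
    CNERecord("good1", "chr1", 20_000, 20_180, constraint_rs=0.62, phylop_p=1e-25),
    CNERecord("good2", "chr1", 23_000, 23_120, constraint_rs=0.35, phylop_p=1e-8),
]
exons = [("chr1", 5100, 5150)]
repeats = [("chr1", 8100, 8120)]
accepted, report = apply_cne_filters(
    candidates,
    exon_track=exons,
    ncrna_transposon_pseudogene_track=repeats,
    blastx_hits={"coding_like": 1e-6},
    self_blat_hits={"paralogous": 60},
    outgroup_alignment={c.id: {"opossum"} for c in candidates if c.id != "recent"},
)

print(f"accepted {report.n_accepted} of {len(candidates)} candidates")
for row in report.rows.itertuples(index=False):
    verdict = "kept" if row.accepted else f"rejected ({row.reason})"
    print(f"  {row.id:12s} {verdict}")

# Ancestry: did the element exist before the mammalian radiation?  It does if
# >= 80% of its length aligns to a non-mammalian vertebrate.
anc = flag_ancestry(accepted[0], {"chicken": 150, "frog": 20})
print(f"\n{accepted[0].id} pre-mammalian ancestry: {anc} "
      f"(chicken covers 150/{accepted[0].length} bp)")

# The extremely conserved subset uses strict GERP/phyloP cuts (RS > 50%,
# P < 1e-20); only good1 qualifies here.
hc = select_highly_conserved(accepted)
print(f"highly conserved subset: {[c.id for c in hc]}")
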