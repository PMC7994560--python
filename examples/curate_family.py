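"""Curate a raw candidate set down to the non-redundant family and name it.

Builds a toy candidate set containing an alternative-transcript duplicate,
filters it with the keep-the-longest rule, and names the survivors by
chromosome position.
"""

from famkit.curation import CurationConfig, assign_names, filter_redundant
from famkit.io import GeneModel, ProteinRecord

records = [
    ProteinRecord("cand1", "MKVLWAALLVTFLAGCQA" * 10),          # full length
    ProteinRecord("cand1b", "MKVLWAALLVTFLAGCQA" * 8),          # truncated copy
    ProteinRecord("cand2", "GGDEFWQKTSNPHILMRA" * 9),
    ProteinRecord("cand3", "PYVRENDSKQACWILMTF" * 7),
]

kept, removed = filter_redundant(records, CurationConfig(identity_threshold=0.95))
print(f"kept {len(kept)} of {len(records)} candidates")
for removed_id, kept_id, identity in removed:
    print(f"  dropped {removed_id}: identical to {kept_id} "
          f"(identity {identity:.2f}) but shorter")

genes = [
    GeneModel("cand1", "chr2", "+", ((5000, 5539),)),
    GeneModel("cand2", "chr1", "-", ((900, 1385),)),
    GeneModel("cand3", "UNPLACED", "+", ((10, 387),)),
]
names = assign_names(genes, CurationConfig(name_prefix="VdbHLH"))
for gid, name in sorted(names.items(), key=lambda kv: kv[1]):
    print(f"  {name} <- {gid}")
# Placed genes are numbered along chr1..chr19 by start coordinate;
# unplaced scaffolds always receive the final numbers.
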