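"""Count ortholog/paralog pairs from clusters and summarize motifs.

Parses a tiny ortholog-cluster table (grape Vd, tomato Sl, Arabidopsis At),
counts cross- and within-species gene pairs, and summarizes motif
occurrences per subfamily.
"""

import io
import tempfile
from pathlib import Path

from famkit.io import MotifHit, read_clusters
from famkit.summaries import count_pairs, summarize_motifs

groups = """\
C1: Vd|VdbHLH013 Vd|VdbHLH037 Sl|Solyc09g065100 At|AT4G09820
C2: Vd|VdbHLH003 Sl|Solyc02g079810 Sl|Solyc08g081140
C3: Vd|VdbHLH089 At|AT1G22490
"""
with tempfile.TemporaryDirectory() as td:
    path = Path(td) / "groups.txt"
    path.write_text(groups)
    clusters = read_clusters(path)

counts = count_pairs(clusters)
print("ortholog pairs (cross-species, within one cluster):")
for (a, b), n in sorted(counts.ortholog_pairs.items()):
    print(f"  {a}-{b}: {n}")
print("paralog pairs (within-species):", counts.paralog_pairs)
# cluster C1 alone yields 2 Vd-Sl ortholog pairs (2 grape genes x 1 tomato
# gene ... plus C2's 2) and C2 contributes the single Sl paralog pair.

assignment = {"VdbHLH013": "III f", "VdbHLH037": "III f", "VdbHLH082": "III f",
              "VdbHLH003": "II", "VdbHLH089": "orphan"}
hits = [MotifHit(g, 2, 1) for g in assignment] + [
    MotifHit("VdbHLH013", 18, 120),
    MotifHit("VdbHLH037", 18, 118),
    MotifHit("VdbHLH082", 18, 121),
]
summary = summarize_motifs(hits, assignment, universal_fraction=0.9)
print("universal motifs (>=90% of members):", list(summary.universal_motifs))
print("subfamily-specific motifs:", summary.subfamily_specific)
# motif2 appears in every member (universal); motif18's carriers all sit in
# subfamily III f, the anthocyanin-associated clade.
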