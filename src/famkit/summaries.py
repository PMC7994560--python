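"""Motif-occurrence summaries per subfamily and ortholog/paralog pair counts.

Motif discovery and ortholog clustering themselves are upstream tools; this
module summarizes their tabular output.  An "orthologous gene pair" is any
cross-species pair co-occurring in one cluster; a "paralogous gene pair" is
any within-species pair in one cluster.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .io import ClusterSet, MotifHit


@dataclass(frozen=True)
class MotifSummary:
    motif_types_by_subfamily: dict[str, int]
    mean_motifs_per_gene: dict[str, float]
    universal_motifs: tuple[int, ...]
    subfamily_specific: dict[int, str]  # motif -> the one subfamily carrying it
    duplicated_hits: tuple[tuple[str, int], ...]  # (gene, motif) seen >1 time
    carriers: dict[int, frozenset[str]] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for subfam in sorted(self.motif_types_by_subfamily):
            rows.append(
                {
                    "subfamily": subfam,
                    "motif_types": self.motif_types_by_subfamily[subfam],
                    "mean_motifs_per_gene": round(
                        self.mean_motifs_per_gene[subfam], 3
                    ),
                }
            )
        return pd.DataFrame(rows)


def summarize_motifs(
    hits: list[MotifHit],
    assignment: dict[str, str],
    members: list[str] | None = None,
    universal_fraction: float = 0.9,
) -> MotifSummary:
    """Summarize motif occurrences against a subfamily assignment.

    ``members`` is the full family roster used as the denominator for the
    universality test (defaults to the genes in ``assignment``).  A motif is
    universal when carried by >= ``universal_fraction`` of all members, and
    subfamily-specific when all of its carriers sit in one subfamily.
    Duplicate (gene, motif) occurrences are flagged, since conserved motifs
    are expected once per gene.
    """
    members = members if members is not None else sorted(assignment)
    unassigned = sorted({h.gene_id for h in hits} - set(assignment))
    if unassigned:
        raise ValueError(f"hits for genes missing from assignment: {unassigned}")

    occurrence = Counter((h.gene_id, h.motif_id) for h in hits)
    duplicated = tuple(sorted(k for k, n in occurrence.items() if n > 1))

    carriers: dict[int, set[str]] = defaultdict(set)
    motifs_by_gene: dict[str, set[int]] = defaultdict(set)
    for h in hits:
        carriers[h.motif_id].add(h.gene_id)
        motifs_by_gene[h.gene_id].add(h.motif_id)

    subfamilies = sorted(set(assignment.values()))
    types_by_subfam: dict[str, int] = {}
    mean_by_subfam: dict[str, float] = {}
    for subfam in subfamilies:
        genes = [g for g, s in assignment.items() if s == subfam]
        motifs = set().union(*(motifs_by_gene.get(g, set()) for g in genes))
        types_by_subfam[subfam] = len(motifs)
        mean_by_subfam[subfam] = (
            sum(len(motifs_by_gene.get(g, set())) for g in genes) / len(genes)
        )

    universal = tuple(
        sorted(
            m for m, c in carriers.items()
            if len(c) >= universal_fraction * len(members)
        )
    )
    specific: dict[int, str] = {}
    for m, c in sorted(carriers.items()):
        labels = {assignment[g] for g in c}
        if len(labels) == 1:
            specific[m] = labels.pop()

    return MotifSummary(
        types_by_subfam,
        mean_by_subfam,
        universal,
        specific,
        duplicated,
        {m: frozenset(c) for m, c in carriers.items()},
    )


@dataclass(frozen=True)
class PairCounts:
    ortholog_pairs: dict[tuple[str, str], int]  # (species_a, species_b) sorted
    paralog_pairs: dict[str, int]

    def orthologs(self, a: str, b: str) -> int:
        return self.ortholog_pairs.get(tuple(sorted((a, b))), 0)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"kind": "ortholog", "species": f"{a}-{b}", "pairs": n}
            for (a, b), n in sorted(self.ortholog_pairs.items())
        ]
        rows += [
            {"kind": "paralog", "species": s, "pairs": n}
            for s, n in sorted(self.paralog_pairs.items())
        ]
        return pd.DataFrame(rows)


def count_pairs(
    clusters: ClusterSet, species: list[str] | None = None
) -> PairCounts:
    """Count within-cluster gene pairs.

    Ortholog pairs for species (a, b): sum over clusters of n_a * n_b.
    Paralog pairs for species s: sum over clusters of C(n_s, 2).
    ``species`` restricts and validates the tags considered (default: all
    tags present).
    """
    present = clusters.species
    if species is None:
        species = sorted(present)
    else:
        unknown = set(species) - present
        if unknown:
            raise ValueError(f"unknown species tag(s): {sorted(unknown)}")
    ortho: Counter[tuple[str, str]] = Counter()
    para: Counter[str] = Counter()
    for cluster in clusters.clusters:
        sizes = Counter(tag for tag, _ in cluster if tag in species)
        tags = sorted(sizes)
        for i, a in enumerate(tags):
            para[a] += sizes[a] * (sizes[a] - 1) // 2
            for b in tags[i + 1 :]:
                ortho[(a, b)] += sizes[a] * sizes[b]
    return PairCounts(
        {pair: ortho.get(pair, 0)
         for pair in [(a, b) for i, a in enumerate(sorted(species))
                      for b in sorted(species)[i + 1 :]]},
        {s: para.get(s, 0) for s in species},
    )
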