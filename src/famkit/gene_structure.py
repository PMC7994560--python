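"""Intron phases, symmetric exons and family-level structure statistics.

The phase of an intron is the position it interrupts relative to codon
boundaries: phase 0 falls between codons, phase 1 after the first
nucleotide of a codon, phase 2 after the second.  Computed on CDS exons
only (phase is a codon concept), the phase of intron k is simply the
cumulative CDS length of the first k exons mod 3.

An internal exon flanked by two introns of the same phase is "symmetric";
its length is necessarily a multiple of three, which is why symmetric
exons can be duplicated or shuffled without shifting the reading frame.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import pandas as pd

from .io import GeneModel


@dataclass(frozen=True)
class PhaseAnnotation:
    gene_id: str
    exon_lengths: tuple[int, ...]
    intron_phases: tuple[int, ...]
    symmetric_exons: tuple[tuple[int, int], ...]  # (1-based exon index, phase)

    def __post_init__(self) -> None:
        if len(self.intron_phases) != len(self.exon_lengths) - 1:
            raise ValueError(
                f"{self.gene_id}: {len(self.intron_phases)} phases for "
                f"{len(self.exon_lengths)} exons"
            )
        for idx, _ in self.symmetric_exons:
            if self.exon_lengths[idx - 1] % 3 != 0:
                raise ValueError(
                    f"{self.gene_id}: symmetric exon {idx} has length "
                    f"{self.exon_lengths[idx - 1]}, not a multiple of 3"
                )


def phases_from_lengths(exon_lengths: list[int] | tuple[int, ...]) -> list[int]:
    """Intron phases for a CDS exon-length tuple (transcription order)."""
    phases = []
    cumulative = 0
    for length in exon_lengths[:-1]:
        cumulative += length
        phases.append(cumulative % 3)
    return phases


def symmetric_from_lengths(
    exon_lengths: list[int] | tuple[int, ...]
) -> list[tuple[int, int]]:
    """Symmetric internal exons for a CDS exon-length tuple.

    Returns (1-based exon index, shared flanking phase) pairs.  First and
    last exons are never symmetric (they lack an intron on one side).
    """
    phases = phases_from_lengths(exon_lengths)
    out = []
    for i in range(1, len(phases)):
        if phases[i - 1] == phases[i]:
            out.append((i + 1, phases[i]))
    return out


def intron_phases(gene: GeneModel) -> list[int]:
    """Phase of each intron: cumulative CDS length mod 3, transcription order."""
    return phases_from_lengths(gene.exon_lengths)


def symmetric_exons(gene: GeneModel) -> list[tuple[int, int]]:
    """Internal exons whose flanking introns share a phase."""
    return symmetric_from_lengths(gene.exon_lengths)


def annotate(gene: GeneModel) -> PhaseAnnotation:
    return PhaseAnnotation(
        gene.gene_id,
        tuple(gene.exon_lengths),
        tuple(intron_phases(gene)),
        tuple(symmetric_exons(gene)),
    )


def validate_gff_phases(gene: GeneModel, declared: list[int]) -> list[int]:
    """Cross-check declared GFF3 CDS phase fields against recomputation.

    ``declared[k]`` is the GFF3 ``phase`` of exon k in transcription order
    (bases to skip to reach a codon boundary).  Returns the indices (0-based)
    of exons whose declared phase conflicts with the recomputed frame.
    """
    conflicts = []
    cumulative = 0
    for k, length in enumerate(gene.exon_lengths):
        expected = (3 - cumulative % 3) % 3
        if k < len(declared) and declared[k] != expected:
            conflicts.append(k)
        cumulative += length
    return conflicts


@dataclass(frozen=True)
class StructureSummary:
    n_genes: int
    n_exons: int
    n_introns: int
    phase_counts: dict[int, int]
    symmetric_counts: dict[int, int]  # keyed by flanking phase
    n_intronless: int
    mean_exons_by_subfamily: dict[str, float]

    def __post_init__(self) -> None:
        if sum(self.phase_counts.values()) != self.n_introns:
            raise ValueError("phase counts do not sum to the intron total")
        if self.n_exons != self.n_introns + self.n_genes:
            raise ValueError(
                f"exon/intron bookkeeping broken: {self.n_exons} exons, "
                f"{self.n_introns} introns, {self.n_genes} genes"
            )

    def to_frame(self) -> pd.DataFrame:
        rows = [
            ("n_genes", self.n_genes),
            ("n_exons", self.n_exons),
            ("n_introns", self.n_introns),
            ("n_intronless", self.n_intronless),
        ]
        rows += [(f"phase{p}_introns", self.phase_counts.get(p, 0)) for p in (0, 1, 2)]
        rows += [
            (f"symmetric_exons_phase{p}", self.symmetric_counts.get(p, 0))
            for p in (0, 1, 2)
        ]
        rows += [
            (f"mean_exons[{s}]", round(m, 3))
            for s, m in sorted(self.mean_exons_by_subfamily.items())
        ]
        return pd.DataFrame(rows, columns=["statistic", "value"])


def summarize_structures(
    genes: list[GeneModel], assignment: dict[str, str] | None = None
) -> StructureSummary:
    """Family-level totals: phase counts, symmetric exons, intronless genes,
    and mean exon count per subfamily (when an assignment is given)."""
    assignment = assignment if assignment is not None else {}
    if assignment:
        missing = [g.gene_id for g in genes if g.gene_id not in assignment]
        if missing:
            raise ValueError(f"genes missing from assignment: {missing}")
    phase_counter: Counter[int] = Counter()
    sym_counter: Counter[int] = Counter()
    n_exons = 0
    n_intronless = 0
    exons_by_subfamily: dict[str, list[int]] = {}
    for g in genes:
        ann = annotate(g)
        n_exons += len(ann.exon_lengths)
        phase_counter.update(ann.intron_phases)
        sym_counter.update(p for _, p in ann.symmetric_exons)
        if len(ann.exon_lengths) == 1:
            n_intronless += 1
        if assignment:
            exons_by_subfamily.setdefault(assignment[g.gene_id], []).append(
                len(ann.exon_lengths)
            )
    return StructureSummary(
        n_genes=len(genes),
        n_exons=n_exons,
        n_introns=n_exons - len(genes),
        phase_counts={p: phase_counter.get(p, 0) for p in (0, 1, 2)},
        symmetric_counts={p: sym_counter.get(p, 0) for p in (0, 1, 2)},
        n_intronless=n_intronless,
        mean_exons_by_subfamily={
            s: sum(v) / len(v) for s, v in exons_by_subfamily.items()
        },
    )


def per_gene_table(genes: list[GeneModel]) -> pd.DataFrame:
    """Per-gene structure table for export."""
    rows = []
    for g in genes:
        ann = annotate(g)
        rows.append(
            {
                "gene_id": g.gene_id,
                "chromosome": g.chromosome,
                "strand": g.strand,
                "n_exons": len(ann.exon_lengths),
                "exon_lengths": ",".join(map(str, ann.exon_lengths)),
                "intron_phases": ",".join(map(str, ann.intron_phases)),
                "symmetric_exons": ";".join(
                    f"{i}:{p}" for i, p in ann.symmetric_exons
                ),
            }
        )
    return pd.DataFrame(rows)
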