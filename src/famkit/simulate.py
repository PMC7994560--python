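"""Synthetic fixtures with known ground truth for every pipeline stage.

Each generator returns both the data object and the planted truth, computed
by logic independent of the module the data is meant to exercise, so that
recovery can be asserted without circularity.  Defaults mirror the family
characterized by the pipeline: 115 members, a 65-column domain alignment,
and a six-sample berry expression design with 6 planted veraison-specific
candidates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .io import AlignedBlock, ExpressionMatrix, GeneModel
from .phylogeny import DistanceMatrix

RESIDUES = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class SimSpec:
    """Parameters of all synthetic generators."""

    rng_seed: int = 0
    n_members: int = 115
    domain_length: int = 65
    #: planted per-column (residue, consensus rate); None -> uniform background
    planted_columns: tuple[tuple[str, float] | None, ...] | None = None
    default_rate: float = 0.55
    n_genes: int = 115
    #: explicit exon-length tuples; None -> random tuples
    exon_tuples: tuple[tuple[int, ...], ...] | None = None
    max_exons: int = 11
    n_candidates: int = 6
    on_level: float = 20.0
    off_level: float = 0.2
    on_threshold: float = 5.0
    off_threshold: float = 1.0
    n_leaves: int = 8
    branch_length_range: tuple[float, float] = (0.5, 2.0)

    def __post_init__(self) -> None:
        if self.planted_columns is not None:
            for col in self.planted_columns:
                if col is not None and not 0.0 <= col[1] <= 1.0:
                    raise ValueError("planted rates must be in [0, 1]")
        if not 0.0 <= self.default_rate <= 1.0:
            raise ValueError("default_rate must be in [0, 1]")


def sim_alignment(spec: SimSpec) -> tuple[AlignedBlock, dict[int, tuple[str, float]]]:
    """Simulate a gap-free domain alignment with planted column consensus.

    Each column is i.i.d.: the planted residue is drawn with its planted
    rate, otherwise a residue uniform over the remaining 19.  Truth maps
    1-based column -> (planted residue, planted rate).
    """
    rng = np.random.default_rng(spec.rng_seed)
    planted = spec.planted_columns
    if planted is None:
        planted = tuple(
            (RESIDUES[rng.integers(len(RESIDUES))], spec.default_rate)
            for _ in range(spec.domain_length)
        )
    if len(planted) != spec.domain_length:
        raise ValueError("planted_columns length must equal domain_length")
    columns = []
    truth: dict[int, tuple[str, float]] = {}
    for j, col in enumerate(planted, start=1):
        if col is None:
            columns.append(rng.choice(list(RESIDUES), size=spec.n_members))
            continue
        residue, rate = col
        truth[j] = (residue, rate)
        others = [r for r in RESIDUES if r != residue]
        hit = rng.random(spec.n_members) < rate
        draw = rng.choice(others, size=spec.n_members)
        columns.append(np.where(hit, residue, draw))
    grid = np.stack(columns, axis=1)
    ids = tuple(f"M{i + 1:03d}" for i in range(spec.n_members))
    rows = tuple("".join(r) for r in grid)
    return AlignedBlock(ids, rows), truth


def _hand_phases(exon_lengths: tuple[int, ...]) -> list[int]:
    """Cumulative-mod-3 phase oracle, independent of the analysis module."""
    total = 0
    out = []
    for length in exon_lengths[:-1]:
        total = total + length
        out.append(total - (total // 3) * 3)
    return out


def sim_genes(
    spec: SimSpec,
) -> tuple[list[GeneModel], dict[int, int], dict[int, int]]:
    """Simulate gene models from exon-length tuples on random strands.

    Returns (models, phase multiset truth, symmetric-exon count truth),
    the truths computed from the length tuples by a hand cumulative-mod-3
    oracle rather than by the structure-analysis code.
    """
    rng = np.random.default_rng(spec.rng_seed + 1)
    tuples = spec.exon_tuples
    if tuples is None:
        made = []
        for _ in range(spec.n_genes):
            n_exons = int(rng.integers(1, spec.max_exons + 1))
            lengths = [int(rng.integers(1, 300)) for _ in range(n_exons)]
            while sum(lengths) < 3 or sum(lengths) % 3 != 0:
                lengths[-1] += 1
            made.append(tuple(lengths))
        tuples = tuple(made)
    models = []
    phase_truth: dict[int, int] = {0: 0, 1: 0, 2: 0}
    sym_truth: dict[int, int] = {0: 0, 1: 0, 2: 0}
    for i, lengths in enumerate(tuples):
        chrom = f"chr{int(rng.integers(1, 20))}"
        strand = "+" if rng.random() < 0.5 else "-"
        start = int(rng.integers(1, 10_000_000))
        intervals = []
        pos = start
        # ascending genomic coordinates carry the lengths in genomic order,
        # which is reversed transcription order on the minus strand
        genomic_lengths = lengths if strand == "+" else lengths[::-1]
        for length in genomic_lengths:
            intervals.append((pos, pos + length - 1))
            pos += length + int(rng.integers(50, 500))  # intron gap
        if strand == "-":
            intervals = intervals[::-1]
        models.append(
            GeneModel(f"G{i + 1:03d}", chrom, strand, tuple(intervals))
        )
        phases = _hand_phases(lengths)
        for p in phases:
            phase_truth[p] += 1
        for a, b in zip(phases, phases[1:]):
            if a == b:
                sym_truth[a] += 1
    return models, phase_truth, sym_truth


def sim_expression(spec: SimSpec) -> tuple[ExpressionMatrix, list[str]]:
    """Simulate an RPKM matrix with planted veraison-specific candidates.

    Candidates get B2/B3 at the high level (>= on threshold) and B1/W* at
    the low level (< off threshold); each non-candidate violates at least
    one clause of the screen.  Truth is the planted candidate id list.
    """
    rng = np.random.default_rng(spec.rng_seed + 2)
    if spec.n_candidates > spec.n_genes:
        raise ValueError("more candidates than genes")
    ids = [f"G{i + 1:03d}" for i in range((spec.n_genes))]
    candidate_idx = set(
        rng.choice(spec.n_genes, size=spec.n_candidates, replace=False).tolist()
    )

    def high() -> float:
        return float(spec.on_level * (1.0 + rng.random()))

    def low() -> float:
        return float(spec.off_level * rng.random())

    values = []
    for i in range(spec.n_genes):
        if i in candidate_idx:
            row = (low(), high(), high(), low(), low(), low())
        else:
            kind = int(rng.integers(4))
            if kind == 0:  # constitutive in both colours
                row = tuple(high() for _ in range(6))
            elif kind == 1:  # on too early in black berries
                row = (high(), high(), high(), low(), low(), low())
            elif kind == 2:  # silent everywhere
                row = tuple(low() for _ in range(6))
            else:  # never switches on at veraison
                row = (low(), low(), high(), low(), low(), low())
        values.append(row)
    truth = [ids[i] for i in sorted(candidate_idx)]
    return ExpressionMatrix(tuple(ids), tuple(values)), truth


def _random_binary_tree(
    rng: np.random.Generator, labels: list[str], lo: float, hi: float
) -> dendropy.Tree:
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        node.edge.length = float(rng.uniform(lo, hi))
        nodes.append(node)
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False).tolist())
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        parent.edge.length = float(rng.uniform(lo, hi))
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    for node in nodes:
        tree.seed_node.add_child(node)
    tree.is_rooted = False
    return tree


def sim_tree_distances(spec: SimSpec) -> tuple[dendropy.Tree, DistanceMatrix]:
    """Random unrooted binary tree plus its additive path-length distances."""
    rng = np.random.default_rng(spec.rng_seed + 3)
    labels = [f"T{i + 1}" for i in range(spec.n_leaves)]
    lo, hi = spec.branch_length_range
    tree = _random_binary_tree(rng, labels, lo, hi)
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    d = np.zeros((n, n))
    taxa = {t.label: t for t in tree.taxon_namespace}
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(
                taxa[labels[i]], taxa[labels[j]]
            )
    return tree, DistanceMatrix(tuple(labels), d)
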