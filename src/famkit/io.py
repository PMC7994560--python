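"""Readers and writers for the external formats the pipeline touches.

Every downstream module consumes only the domain types defined here:
protein records, gene models (ordered CDS exons), gapped alignment blocks,
RPKM expression matrices, ortholog cluster sets and motif-hit tables.
Coordinates are 1-based inclusive throughout, matching GFF3.
"""

from __future__ import annotations

import io as _io
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")
GAP_CHARS = {"-", "."}

#: canonical sample order for berry-skin expression matrices: black (B) and
#: white (W) berries at 40, 80 and 120 days after anthesis.
EXPRESSION_SAMPLES = ("B1", "B2", "B3", "W1", "W2", "W3")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class ProteinRecord:
    """A curated peptide sequence (uppercase one-letter amino acids, X allowed)."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise FormatError("protein record with empty id")
        if len(self.sequence) < 1:
            raise FormatError(f"protein record {self.id!r} has empty sequence")
        bad = set(self.sequence) - AMINO_ACIDS - {"X"}
        if bad & GAP_CHARS:
            raise FormatError(f"protein record {self.id!r} contains gap characters")
        if bad:
            raise FormatError(
                f"protein record {self.id!r} contains invalid symbols {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class GeneModel:
    """Ordered CDS exons of one gene, in transcription (5'->3') order.

    ``cds_exons`` holds 1-based inclusive genomic intervals.  On the minus
    strand the first tuple is the exon with the largest genomic coordinates.
    """

    gene_id: str
    chromosome: str
    strand: str
    cds_exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in {"+", "-"}:
            raise FormatError(f"gene {self.gene_id!r}: strand must be + or -")
        if not self.cds_exons:
            raise FormatError(f"gene {self.gene_id!r} has no CDS exons")
        for start, end in self.cds_exons:
            if end < start:
                raise FormatError(
                    f"gene {self.gene_id!r}: exon {start}-{end} has end < start"
                )
        genomic = sorted(self.cds_exons)
        for (s1, e1), (s2, e2) in zip(genomic, genomic[1:]):
            if s2 <= e1:
                raise FormatError(
                    f"gene {self.gene_id!r}: overlapping CDS exons "
                    f"{s1}-{e1} and {s2}-{e2}"
                )
        if self.total_cds_length < 3:
            raise FormatError(f"gene {self.gene_id!r}: total CDS length < 3")
        expect = genomic if self.strand == "+" else genomic[::-1]
        if list(self.cds_exons) != expect:
            raise FormatError(
                f"gene {self.gene_id!r}: exons not in transcription order"
            )

    @property
    def exon_lengths(self) -> list[int]:
        """CDS exon lengths in transcription order."""
        return [end - start + 1 for start, end in self.cds_exons]

    @property
    def total_cds_length(self) -> int:
        return sum(end - start + 1 for start, end in self.cds_exons)

    @property
    def start(self) -> int:
        """Smallest genomic coordinate (for chromosome-order naming)."""
        return min(s for s, _ in self.cds_exons)

    @property
    def n_exons(self) -> int:
        return len(self.cds_exons)


@dataclass(frozen=True)
class AlignedBlock:
    """A gapped multiple alignment: equal-length rows keyed by unique ids."""

    ids: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise FormatError("alignment ids and rows differ in count")
        if len(set(self.ids)) != len(self.ids):
            raise FormatError("duplicate ids in alignment")
        if self.rows:
            width = len(self.rows[0])
            for rid, row in zip(self.ids, self.rows):
                if len(row) != width:
                    raise FormatError(
                        f"ragged alignment: row {rid!r} has length {len(row)}, "
                        f"expected {width}"
                    )

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def row(self, rid: str) -> str:
        return self.rows[self.ids.index(rid)]

    def column(self, j: int) -> str:
        """Column ``j`` (1-based, matching residue-rule numbering)."""
        return "".join(row[j - 1] for row in self.rows)

    def subset(self, keep: Sequence[str]) -> "AlignedBlock":
        index = {rid: row for rid, row in zip(self.ids, self.rows)}
        return AlignedBlock(tuple(keep), tuple(index[r] for r in keep))


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x six berry samples (B1..B3, W1..W3) of non-negative RPKM values."""

    gene_ids: tuple[str, ...]
    values: tuple[tuple[float, ...], ...]
    sample_ids: tuple[str, ...] = EXPRESSION_SAMPLES

    def __post_init__(self) -> None:
        if tuple(self.sample_ids) != EXPRESSION_SAMPLES:
            raise FormatError(
                f"sample columns must be exactly {list(EXPRESSION_SAMPLES)}, "
                f"got {list(self.sample_ids)}"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise FormatError("duplicate gene ids in expression matrix")
        for gid, row in zip(self.gene_ids, self.values):
            if len(row) != 6:
                raise FormatError(f"gene {gid!r}: expected 6 values, got {len(row)}")
            for v in row:
                if not (v == v) or v < 0:  # NaN or negative
                    raise FormatError(f"gene {gid!r}: invalid RPKM value {v!r}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            list(self.values), index=list(self.gene_ids), columns=list(self.sample_ids)
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        missing = [c for c in EXPRESSION_SAMPLES if c not in df.columns]
        if missing:
            raise FormatError(f"expression table missing sample column(s) {missing}")
        df = df[list(EXPRESSION_SAMPLES)]
        return cls(
            tuple(str(g) for g in df.index),
            tuple(tuple(float(v) for v in row) for row in df.to_numpy()),
        )

    def row(self, gene_id: str) -> dict[str, float]:
        vals = self.values[self.gene_ids.index(gene_id)]
        return dict(zip(self.sample_ids, vals))


@dataclass(frozen=True)
class ClusterSet:
    """Parsed ortholog clusters: each member is a (species_tag, gene_id) pair."""

    clusters: tuple[frozenset[tuple[str, str]], ...]
    names: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for cluster in self.clusters:
            for member in cluster:
                if member in seen:
                    raise FormatError(
                        f"gene {member[1]!r} ({member[0]}) appears in more than "
                        "one cluster"
                    )
                seen.add(member)

    @property
    def species(self) -> set[str]:
        return {tag for cluster in self.clusters for tag, _ in cluster}


@dataclass(frozen=True)
class MotifHit:
    """One occurrence of a conserved protein motif in one gene."""

    gene_id: str
    motif_id: int
    start: int
    e_value: float = 0.0

    def __post_init__(self) -> None:
        if self.start < 1:
            raise FormatError(
                f"motif hit {self.gene_id}/motif{self.motif_id}: start < 1"
            )
        if self.motif_id < 1:
            raise FormatError(f"motif id must be >= 1, got {self.motif_id}")


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read protein FASTA into records, rejecting duplicate ids."""
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FormatError(f"duplicate FASTA id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(ProteinRecord(rec.id, str(rec.seq).upper(), desc))
    if not records and Path(path).stat().st_size > 0:
        raise FormatError(f"no FASTA records parsed from {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# Aligned FASTA

def read_alignment(path: str | Path) -> AlignedBlock:
    """Read an aligned FASTA; '.' gaps are normalized to '-'."""
    ids: list[str] = []
    rows: list[str] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in ids:
            raise FormatError(f"duplicate alignment id {rec.id!r} in {path}")
        ids.append(rec.id)
        rows.append(str(rec.seq).upper().replace(".", "-"))
    return AlignedBlock(tuple(ids), tuple(rows))


def write_alignment(block: AlignedBlock, path: str | Path) -> None:
    seqrecs = [
        SeqRecord(Seq(row), id=rid, description="")
        for rid, row in zip(block.ids, block.rows)
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3

def read_gff3(path: str | Path, feature: str = "CDS") -> list[GeneModel]:
    """Parse gene models from a GFF3 gene/mRNA/CDS hierarchy.

    When a gene carries several mRNAs the one with the longest total CDS is
    kept (keep-the-longest curation); a perfect tie between transcripts is
    resolved toward the lexicographically smallest transcript id.
    """
    import gffutils

    db = gffutils.create_db(
        str(path), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="error",
    )
    models: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by=("seqid", "start")):
        mrnas = list(db.children(gene, featuretype="mRNA"))
        if not mrnas:
            raise FormatError(f"gene {gene.id!r} has no mRNA children")
        best = None
        for mrna in sorted(mrnas, key=lambda m: m.id):
            cds = list(db.children(mrna, featuretype=feature))
            if not cds:
                continue
            total = sum(c.end - c.start + 1 for c in cds)
            if best is None or total > best[0]:
                best = (total, mrna, cds)
        if best is None:
            raise FormatError(f"gene {gene.id!r} has no {feature} features")
        _, mrna, cds = best
        intervals = sorted((c.start, c.end) for c in cds)
        if gene.strand not in {"+", "-"}:
            raise FormatError(f"gene {gene.id!r}: missing strand")
        if gene.strand == "-":
            intervals = intervals[::-1]
        models.append(
            GeneModel(gene.id, gene.seqid, gene.strand, tuple(intervals))
        )
    return models


def write_gff3(models: Iterable[GeneModel], path: str | Path) -> None:
    """Write gene models as a minimal gene/mRNA/CDS GFF3."""
    lines = ["##gff-version 3"]
    for g in models:
        lo = min(s for s, _ in g.cds_exons)
        hi = max(e for _, e in g.cds_exons)
        lines.append(
            f"{g.chromosome}\tfamkit\tgene\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id}"
        )
        lines.append(
            f"{g.chromosome}\tfamkit\tmRNA\t{lo}\t{hi}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id}.t1;Parent={g.gene_id}"
        )
        phase = 0
        for k, (start, end) in enumerate(g.cds_exons, start=1):
            lines.append(
                f"{g.chromosome}\tfamkit\tCDS\t{start}\t{end}\t.\t{g.strand}\t"
                f"{phase}\tID={g.gene_id}.cds{k};Parent={g.gene_id}.t1"
            )
            phase = (3 - ((end - start + 1 - phase) % 3)) % 3
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Expression TSV

def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a gene x sample RPKM table (TSV, first column = gene id)."""
    try:
        df = pd.read_csv(path, sep="\t", index_col=0)
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise FormatError(f"cannot parse expression table {path}: {exc}") from exc
    for col in df.columns:
        if col not in EXPRESSION_SAMPLES:
            raise FormatError(f"unknown sample column {col!r} in {path}")
        if not pd.api.types.is_numeric_dtype(df[col]):
            raise FormatError(f"non-numeric RPKM values in column {col!r} of {path}")
    return ExpressionMatrix.from_frame(df)


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    df = matrix.to_frame()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# Cluster groups

_CLUSTER_RE = re.compile(r"^(\S+):\s*(.*)$")


def read_clusters(path: str | Path) -> ClusterSet:
    """Parse OrthoMCL-style groups: ``name: tag|gene tag|gene ...`` per line."""
    clusters: list[frozenset[tuple[str, str]]] = []
    names: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        m = _CLUSTER_RE.match(line)
        if not m:
            raise FormatError(f"{path}:{lineno}: not a 'name: members' line")
        members: set[tuple[str, str]] = set()
        for token in m.group(2).split():
            if "|" not in token:
                raise FormatError(
                    f"{path}:{lineno}: member {token!r} lacks a species tag"
                )
            tag, gene = token.split("|", 1)
            members.add((tag, gene))
        names.append(m.group(1))
        clusters.append(frozenset(members))
    return ClusterSet(tuple(clusters), tuple(names))


def write_clusters(clusters: ClusterSet, path: str | Path) -> None:
    lines = []
    names = clusters.names or tuple(
        f"C{i+1}" for i in range(len(clusters.clusters))
    )
    for name, cluster in zip(names, clusters.clusters):
        members = " ".join(f"{tag}|{gene}" for tag, gene in sorted(cluster))
        lines.append(f"{name}: {members}")
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Motif hits

def read_motif_hits(path: str | Path, n_motifs: int = 20) -> list[MotifHit]:
    """Read a motif occurrence TSV with columns gene_id, motif_id, start, e_value."""
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    required = {"gene_id", "motif_id", "start"}
    if not required <= set(df.columns):
        raise FormatError(
            f"motif table {path} missing column(s) {sorted(required - set(df.columns))}"
        )
    hits = []
    for rec in df.itertuples(index=False):
        motif_id = int(rec.motif_id)
        if motif_id > n_motifs:
            raise FormatError(
                f"motif{motif_id} outside declared catalogue of {n_motifs}"
            )
        hits.append(
            MotifHit(
                str(rec.gene_id), motif_id, int(rec.start),
                float(getattr(rec, "e_value", 0.0)),
            )
        )
    return hits


def write_motif_hits(hits: Iterable[MotifHit], path: str | Path) -> None:
    # repr() is the shortest exact decimal form, so e-values round-trip
    df = pd.DataFrame(
        [(h.gene_id, h.motif_id, h.start, repr(h.e_value)) for h in hits],
        columns=["gene_id", "motif_id", "start", "e_value"],
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Newick

def write_newick(tree, path: str | Path) -> None:
    """Write a dendropy tree with internal-node support values as node labels."""
    tree.write(
        path=str(path), schema="newick", suppress_rooting=True,
        suppress_internal_node_labels=False,
    )
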