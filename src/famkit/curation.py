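"""Family curation: redundancy filtering and chromosome-order naming.

A raw candidate set (e.g. all BLASTp/HMM hits for a domain) typically contains
near-identical entries from alternative transcripts or assembly artifacts.
The curation rule keeps, among any group of near-identical sequences, only the
longest one, then names the surviving family members consecutively along the
chromosomes (``<prefix>001`` ...), with unplaced genes numbered last.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass

import numpy as np

from .io import GeneModel, ProteinRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class CurationConfig:
    """Parameters of the keep-the-longest redundancy filter and naming scheme."""

    identity_threshold: float = 0.95
    name_prefix: str = "VdbHLH"
    name_width: int = 3

    def __post_init__(self) -> None:
        if not 0.0 < self.identity_threshold <= 1.0:
            raise ValueError("identity_threshold must be in (0, 1]")


def _needleman_wunsch(a: str, b: str) -> tuple[int, int, int]:
    """Global alignment with match=1 / mismatch=0 / linear gap -1.

    Returns (identical positions, aligned gap-free columns, alignment length)
    of the optimal alignment, with a deterministic traceback preferring
    diagonal, then up, then left.  The scoring exists solely to define which
    columns are aligned; the identity fraction is matches / aligned columns,
    so a truncated but otherwise identical sequence scores 1.0.
    """
    n, m = len(a), len(b)
    GAP = -1
    score = np.zeros((n + 1, m + 1), dtype=np.int64)
    score[:, 0] = GAP * np.arange(n + 1)
    score[0, :] = GAP * np.arange(m + 1)
    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    for i in range(1, n + 1):
        match = (a_arr[i - 1] == b_arr).astype(np.int64)  # row of 0/1
        diag = score[i - 1, :-1] + match
        up = score[i - 1, 1:] + GAP
        row = score[i]
        prev = row[0]
        # left dependency forces a scalar pass over the row
        for j in range(1, m + 1):
            prev = max(diag[j - 1], up[j - 1], prev + GAP)
            row[j] = prev
    # traceback
    i, j = n, m
    matches = 0
    aligned = 0
    length = 0
    while i > 0 or j > 0:
        if i > 0 and j > 0 and score[i, j] == score[i - 1, j - 1] + (
            1 if a[i - 1] == b[j - 1] else 0
        ):
            matches += int(a[i - 1] == b[j - 1])
            aligned += 1
            i -= 1
            j -= 1
        elif i > 0 and score[i, j] == score[i - 1, j] + GAP:
            i -= 1
        else:
            j -= 1
        length += 1
    return matches, aligned, length


def pairwise_identity(a: ProteinRecord, b: ProteinRecord) -> float:
    """Global-alignment identity: identical positions / aligned columns.

    Gap columns are excluded from the denominator, so a sequence identical
    to a longer one over its whole length has identity 1.0 with it.
    """
    if a.sequence == b.sequence:
        return 1.0
    matches, aligned, _ = _needleman_wunsch(a.sequence, b.sequence)
    return matches / aligned


def filter_redundant(
    records: list[ProteinRecord], cfg: CurationConfig | None = None
) -> tuple[list[ProteinRecord], list[tuple[str, str, float]]]:
    """Greedy longest-first redundancy filter.

    Records are processed by (length desc, id asc); each record is kept unless
    it matches an already-kept record at identity >= threshold, in which case
    it is removed in favour of that (longer or equal) keeper.  Returns the
    kept records in input order and ``(removed_id, kept_id, identity)`` rows.
    """
    cfg = cfg or CurationConfig()
    if not records:
        raise ValueError("filter_redundant requires at least one record")
    order = sorted(records, key=lambda r: (-len(r), r.id))
    kept: list[ProteinRecord] = []
    removed: list[tuple[str, str, float]] = []
    for rec in order:
        hit = None
        for keeper in kept:
            ident = pairwise_identity(rec, keeper)
            if ident >= cfg.identity_threshold:
                hit = (rec.id, keeper.id, ident)
                break
        if hit is None:
            kept.append(rec)
        else:
            removed.append(hit)
    kept_ids = {r.id for r in kept}
    return [r for r in records if r.id in kept_ids], removed


_CHR_NUM_RE = re.compile(r"^(?:chr)?0*(\d+)$", re.IGNORECASE)

UNPLACED = "UNPLACED"


def _chromosome_key(chrom: str) -> tuple[int, int | str]:
    """Sort key: chr1..chrN numerically, other named scaffolds, UNPLACED last."""
    if chrom == UNPLACED:
        return (2, 0)
    m = _CHR_NUM_RE.match(chrom)
    if m:
        return (0, int(m.group(1)))
    return (1, chrom)


def assign_names(
    genes: list[GeneModel], cfg: CurationConfig | None = None
) -> dict[str, str]:
    """Chromosome-order family naming.

    Placed genes are numbered consecutively by (chromosome order, start
    coordinate ascending); unplaced genes follow, ordered by start coordinate
    from minimum to maximum.  Ties on (chromosome, start) are broken by
    gene id and logged.
    """
    cfg = cfg or CurationConfig()
    seen: dict[tuple[str, int], str] = {}
    for g in genes:
        key = (g.chromosome, g.start)
        if key in seen:
            logger.warning(
                "genes %s and %s share position %s:%d; breaking tie by id",
                seen[key], g.gene_id, g.chromosome, g.start,
            )
        seen.setdefault(key, g.gene_id)
    ranked = sorted(
        genes, key=lambda g: (_chromosome_key(g.chromosome), g.start, g.gene_id)
    )
    return {
        g.gene_id: f"{cfg.name_prefix}{i + 1:0{cfg.name_width}d}"
        for i, g in enumerate(ranked)
    }
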