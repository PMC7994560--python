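"""Conservation profiling and DNA-binding classification of the bHLH domain.

The domain alignment is a fixed-width (65 columns by default) block: the
basic region occupies columns 1-17, followed by helix 1, the loop and
helix 2.  Positional rules are stated in this alignment frame.

Binding categories follow the basic-region residue rules used throughout
the plant bHLH literature:

* fewer than six basic residues (R/K/H) in the basic region -> the protein
  is predicted not to bind DNA at all;
* His or Lys at column 9 plus Glu-13 plus Arg-17 -> G-box binder (CACGTG);
* Glu-13 plus Arg-16 -> E-box binder that is not G-box specific;
* otherwise -> non-E-box binder.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum

import pandas as pd

from .io import AlignedBlock

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class DomainAlignment:
    """An AlignedBlock restricted to the domain, with a named region map.

    ``regions`` maps region name to an inclusive 1-based column range; the
    ranges must partition 1..n_columns.
    """

    block: AlignedBlock
    regions: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {
            "basic": (1, 17),
            "helix1": (18, 32),
            "loop": (33, 47),
            "helix2": (48, 65),
        }
    )

    def __post_init__(self) -> None:
        covered: list[int] = []
        for name, (lo, hi) in self.regions.items():
            if lo > hi:
                raise ValueError(f"region {name!r}: empty range {lo}-{hi}")
            covered.extend(range(lo, hi + 1))
        if sorted(covered) != list(range(1, self.block.n_columns + 1)):
            raise ValueError(
                "region ranges must partition columns 1.."
                f"{self.block.n_columns}"
            )

    @property
    def n_columns(self) -> int:
        return self.block.n_columns

    def region_of(self, column: int) -> str:
        for name, (lo, hi) in self.regions.items():
            if lo <= column <= hi:
                return name
        raise ValueError(f"column {column} outside alignment")


class ConsensusCategory(str, Enum):
    NONE = "none"
    CONSERVED50 = "conserved50"
    CONSERVED90 = "conserved90"


@dataclass(frozen=True)
class ColumnProfile:
    column: int
    frequencies: dict[str, float]
    consensus_residue: str | None
    consensus_rate: float
    category: ConsensusCategory


@dataclass(frozen=True)
class ConservationProfile:
    columns: tuple[ColumnProfile, ...]
    thresholds: tuple[float, float] = (0.50, 0.90)

    def conserved(self, category: ConsensusCategory) -> list[ColumnProfile]:
        order = [
            ConsensusCategory.NONE,
            ConsensusCategory.CONSERVED50,
            ConsensusCategory.CONSERVED90,
        ]
        rank = order.index(category)
        return [c for c in self.columns if order.index(c.category) >= rank]

    def to_frame(self, aln: DomainAlignment | None = None) -> pd.DataFrame:
        rows = []
        for c in self.columns:
            rows.append(
                {
                    "column": c.column,
                    "consensus": c.consensus_residue or "",
                    "rate": c.consensus_rate,
                    "category": c.category.value,
                    "region": aln.region_of(c.column) if aln else "",
                }
            )
        return pd.DataFrame(rows)


def build_profile(
    aln: DomainAlignment | AlignedBlock,
    thresholds: tuple[float, float] = (0.50, 0.90),
    count_gaps: bool = False,
) -> ConservationProfile:
    """Per-column residue frequencies and consensus categories.

    A column's consensus residue is its most frequent residue (ties broken
    alphabetically); it is flagged conserved50 / conserved90 when its rate
    strictly exceeds the corresponding threshold.  Gaps are excluded from
    the denominator unless ``count_gaps`` (the sequence-logo convention).
    """
    block = aln.block if isinstance(aln, DomainAlignment) else aln
    if block.n_rows < 2:
        raise ValueError("conservation profile requires at least 2 rows")
    lo, hi = thresholds
    cols: list[ColumnProfile] = []
    for j in range(1, block.n_columns + 1):
        column = block.column(j)
        counts = Counter(column)
        if not count_gaps:
            counts.pop("-", None)
        total = sum(counts.values())
        if total == 0:
            logger.warning("column %d is all gaps", j)
            cols.append(
                ColumnProfile(j, {}, None, 0.0, ConsensusCategory.NONE)
            )
            continue
        freqs = {res: n / total for res, n in sorted(counts.items())}
        rate = max(freqs.values())
        consensus = min(r for r, f in freqs.items() if f == rate)
        if rate > hi:
            cat = ConsensusCategory.CONSERVED90
        elif rate > lo:
            cat = ConsensusCategory.CONSERVED50
        else:
            cat = ConsensusCategory.NONE
        cols.append(ColumnProfile(j, freqs, consensus, rate, cat))
    return ConservationProfile(tuple(cols), thresholds)


class BindingCategory(str, Enum):
    G_BOX = "G_BOX"
    E_BOX_NON_G = "E_BOX_NON_G"
    NON_E_BOX = "NON_E_BOX"
    NON_DNA_BINDING = "NON_DNA_BINDING"


@dataclass(frozen=True)
class BindingRuleSet:
    """Alignment columns and residue sets of the binding rules."""

    pos_hk: int = 9
    pos_e13: int = 13
    pos_r16: int = 16
    pos_r17: int = 17
    basic_residues: frozenset[str] = frozenset({"R", "K", "H"})
    min_basic_count: int = 6
    basic_region: tuple[int, int] = (1, 17)

    def __post_init__(self) -> None:
        lo, hi = self.basic_region
        for pos in (self.pos_hk, self.pos_e13, self.pos_r16, self.pos_r17):
            if not lo <= pos <= hi:
                raise ValueError(f"rule column {pos} outside basic region {lo}-{hi}")


@dataclass(frozen=True)
class BindingCall:
    member_id: str
    category: BindingCategory
    evidence: dict[int, str]
    basic_count: int


def count_basic(row: str, rules: BindingRuleSet | None = None) -> int:
    """Number of basic residues (R/K/H) among non-gap basic-region positions."""
    rules = rules or BindingRuleSet()
    lo, hi = rules.basic_region
    segment = row[lo - 1 : hi]
    return sum(1 for ch in segment if ch in rules.basic_residues)


def classify_binding(
    row: str, rules: BindingRuleSet | None = None, member_id: str = ""
) -> BindingCall:
    """Classify one gapped domain row by the basic-region residue rules.

    Decision order: (1) basic count below the minimum -> NON_DNA_BINDING;
    (2) H/K at column 9, E at 13, R at 17 -> G_BOX; (3) E at 13, R at 16 ->
    E_BOX_NON_G; (4) otherwise NON_E_BOX.  A gap at a rule column fails that
    rule's test.  A G-box call lacking Arg-16 is retained but logged, since
    a G-box site is normally a specialized E-box site.
    """
    rules = rules or BindingRuleSet()
    res = {pos: row[pos - 1] for pos in
           (rules.pos_hk, rules.pos_e13, rules.pos_r16, rules.pos_r17)}
    basic = count_basic(row, rules)
    if basic < rules.min_basic_count:
        cat = BindingCategory.NON_DNA_BINDING
    elif (
        res[rules.pos_hk] in {"H", "K"}
        and res[rules.pos_e13] == "E"
        and res[rules.pos_r17] == "R"
    ):
        cat = BindingCategory.G_BOX
        if res[rules.pos_r16] != "R":
            logger.warning(
                "%s meets the G-box rule but lacks Arg-%d",
                member_id or "row", rules.pos_r16,
            )
    elif res[rules.pos_e13] == "E" and res[rules.pos_r16] == "R":
        cat = BindingCategory.E_BOX_NON_G
    else:
        cat = BindingCategory.NON_E_BOX
    return BindingCall(member_id, cat, res, basic)


def classify_alignment(
    aln: DomainAlignment | AlignedBlock, rules: BindingRuleSet | None = None
) -> list[BindingCall]:
    """Classify every member of a domain alignment."""
    block = aln.block if isinstance(aln, DomainAlignment) else aln
    return [
        classify_binding(row, rules, member_id=rid)
        for rid, row in zip(block.ids, block.rows)
    ]


def binding_counts(calls: list[BindingCall]) -> dict[BindingCategory, int]:
    counts = Counter(c.category for c in calls)
    return {cat: counts.get(cat, 0) for cat in BindingCategory}


def plant_vs_animal_report(
    profile: ConservationProfile, reference_rates: dict[int, float]
) -> pd.DataFrame:
    """Flag columns where the profiled consensus rate exceeds a reference rate.

    ``reference_rates`` maps alignment column -> consensus rate in the
    comparison lineage (supplied by the user; e.g. animal bHLH rates).
    """
    if not reference_rates:
        raise ValueError("empty reference table")
    rows = []
    by_col = {c.column: c for c in profile.columns}
    for col, ref in sorted(reference_rates.items()):
        if col not in by_col:
            raise ValueError(f"reference column {col} outside the profile")
        c = by_col[col]
        rows.append(
            {
                "column": col,
                "consensus": c.consensus_residue or "",
                "rate": c.consensus_rate,
                "reference_rate": ref,
                "more_conserved": c.consensus_rate > ref,
            }
        )
    return pd.DataFrame(rows)
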