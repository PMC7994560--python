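"""Developmental-stage expression screen for ripening-associated candidates.

Samples are berry skins of black (B) and white (W) fruit at three stages:
40 days after anthesis (before veraison), 80 days (veraison) and 120 days
(ripening), i.e. B1/B2/B3 and W1/W2/W3.  Anthocyanin accumulates only in
the black berries from veraison onward, so candidate regulators are genes
switched on in B2/B3 while staying off in B1 and in all white samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import average, leaves_list
from scipy.spatial.distance import pdist

from .io import ExpressionMatrix


@dataclass(frozen=True)
class ScreenConfig:
    """Thresholds of the veraison-specific candidate screen (RPKM units).

    ``on_threshold``: minimum RPKM in B2 and B3 for a gene to count as
    switched on at/after veraison.  ``off_threshold``: RPKM below which a
    gene counts as off (B1 and all white samples).  ``expressed_threshold``:
    minimum RPKM in any sample for a gene to count as expressed at all.
    """

    on_threshold: float = 5.0
    off_threshold: float = 1.0
    expressed_threshold: float = 1.0
    log_transform: bool = True

    def __post_init__(self) -> None:
        if self.off_threshold > self.on_threshold:
            raise ValueError("off_threshold must be <= on_threshold")


@dataclass(frozen=True)
class CandidateReport:
    gene_id: str
    is_candidate: bool
    monotone_increase: bool
    rpkm: dict[str, float]


def count_expressed(
    matrix: ExpressionMatrix, cfg: ScreenConfig | None = None
) -> tuple[int, dict[str, bool]]:
    """Count genes with RPKM >= expressed_threshold in at least one sample."""
    cfg = cfg or ScreenConfig()
    flags = {
        gid: any(v >= cfg.expressed_threshold for v in row)
        for gid, row in zip(matrix.gene_ids, matrix.values)
    }
    return sum(flags.values()), flags


def screen_candidates(
    matrix: ExpressionMatrix, cfg: ScreenConfig | None = None
) -> list[CandidateReport]:
    """Apply the black-berry veraison screen to every gene.

    A candidate satisfies RPKM(B2) >= on and RPKM(B3) >= on and
    RPKM(B1) < off and max(W1, W2, W3) < off.  The monotone flag records
    whether expression rises with ripening (B1 <= B2 <= B3 with B3 > B1).
    """
    cfg = cfg or ScreenConfig()
    reports = []
    for gid, row in zip(matrix.gene_ids, matrix.values):
        v = dict(zip(matrix.sample_ids, row))
        is_candidate = (
            v["B2"] >= cfg.on_threshold
            and v["B3"] >= cfg.on_threshold
            and v["B1"] < cfg.off_threshold
            and max(v["W1"], v["W2"], v["W3"]) < cfg.off_threshold
        )
        monotone = v["B1"] <= v["B2"] <= v["B3"] and v["B3"] > v["B1"]
        reports.append(CandidateReport(gid, is_candidate, monotone, v))
    return reports


def candidate_ids(reports: list[CandidateReport]) -> list[str]:
    return [r.gene_id for r in reports if r.is_candidate]


def heatmap_matrix(
    matrix: ExpressionMatrix, cfg: ScreenConfig | None = None
) -> pd.DataFrame:
    """Display matrix for the expression heatmap.

    Rows are restricted to expressed genes, values log2(RPKM+1)-transformed
    when enabled, and rows ordered by average-linkage hierarchical
    clustering on Euclidean distance.
    """
    cfg = cfg or ScreenConfig()
    _, flags = count_expressed(matrix, cfg)
    df = matrix.to_frame().loc[[g for g in matrix.gene_ids if flags[g]]]
    if cfg.log_transform:
        df = np.log2(df + 1.0)
    if len(df) > 2:
        linkage = average(pdist(df.to_numpy(), metric="euclidean"))
        df = df.iloc[leaves_list(linkage)]
    return df


def log2_rpkm(value: float) -> float:
    """log2(RPKM + 1), the heatmap cell transform."""
    if value < 0:
        raise ValueError("RPKM must be non-negative")
    return math.log2(value + 1.0)
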