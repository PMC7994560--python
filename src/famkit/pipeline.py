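"""End-to-end orchestration: curate -> domain -> phylogeny -> structure ->
expression screen -> summaries, from one declarative configuration.

Every stage writes the same tables it writes when run individually; the run
manifest (versions, seed, parameter echo, per-stage status) suffices to
reproduce the run.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import curation, domain, expression, gene_structure, phylogeny, summaries
from . import io as fio

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Paths and per-stage parameters of one pipeline run."""

    out_dir: Path
    fasta: Path | None = None
    gff3: Path | None = None
    domain_alignment: Path | None = None
    full_alignment: Path | None = None
    anchors: Path | None = None
    expression: Path | None = None
    clusters: Path | None = None
    motif_hits: Path | None = None
    keep_list: Path | None = None
    identity_threshold: float = 0.95
    name_prefix: str = "VdbHLH"
    n_bootstrap: int = 1000
    support_display_min: float = 50.0
    distance_model: str = "p"
    on_threshold: float = 5.0
    off_threshold: float = 1.0
    expressed_threshold: float = 1.0
    universal_fraction: float = 0.9
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        for key in (
            "out_dir", "fasta", "gff3", "domain_alignment", "full_alignment",
            "anchors", "expression", "clusters", "motif_hits", "keep_list",
        ):
            if raw.get(key) is not None:
                raw[key] = Path(raw[key])
        if "out_dir" not in raw:
            raise ValueError("config must set out_dir")
        return cls(**raw)

    def validate(self) -> None:
        for key in (
            "fasta", "gff3", "domain_alignment", "full_alignment",
            "anchors", "expression", "clusters", "motif_hits", "keep_list",
        ):
            path = getattr(self, key)
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"{key}: {path} does not exist")


def _read_anchor_table(path: Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t")
    if not {"id", "subfamily"} <= set(df.columns):
        raise ValueError(f"anchor table {path} needs columns id, subfamily")
    return dict(zip(df["id"].astype(str), df["subfamily"].astype(str)))


def run_all(cfg: RunConfig) -> dict:
    """Run every stage whose inputs are configured; return the manifest."""
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "famkit_version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "parameters": {
            k: str(v) if isinstance(v, Path) else v
            for k, v in vars(cfg).items()
        },
        "stages": {},
    }

    assignment: dict[str, str] = {}
    naming: dict[str, str] = {}

    def stage(name: str, fn) -> None:
        try:
            result = fn()
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            _write_manifest(manifest, out)
            raise StageError(name, exc) from exc
        manifest["stages"][name] = {"status": "ok", **(result or {})}

    # --- curation -----------------------------------------------------
    if cfg.fasta is not None:
        def _curate() -> dict:
            records = fio.read_fasta(cfg.fasta)
            ccfg = curation.CurationConfig(
                identity_threshold=cfg.identity_threshold,
                name_prefix=cfg.name_prefix,
            )
            kept, removed = curation.filter_redundant(records, ccfg)
            if cfg.keep_list is not None:
                keep = set(Path(cfg.keep_list).read_text().split())
                kept = [r for r in kept if r.id in keep]
            fio.write_fasta(kept, out / "curated.fasta")
            if cfg.gff3 is not None:
                genes = fio.read_gff3(cfg.gff3)
                kept_ids = {r.id for r in kept}
                genes = [g for g in genes if g.gene_id in kept_ids]
                naming.update(curation.assign_names(genes, ccfg))
                pd.DataFrame(
                    [
                        (g.gene_id, naming[g.gene_id], g.chromosome, g.start)
                        for g in genes
                    ],
                    columns=["old_id", "new_name", "chromosome", "start"],
                ).to_csv(out / "naming.tsv", sep="\t", index=False)
            return {"n_input": len(records), "n_kept": len(kept),
                    "n_removed": len(removed)}
        stage("curate", _curate)

    # --- domain profiling & binding calls -----------------------------
    if cfg.domain_alignment is not None:
        def _domain() -> dict:
            block = fio.read_alignment(cfg.domain_alignment)
            aln = domain.DomainAlignment(block) if block.n_columns == 65 else block
            profile = domain.build_profile(aln)
            profile.to_frame(
                aln if isinstance(aln, domain.DomainAlignment) else None
            ).to_csv(out / "conservation.tsv", sep="\t", index=False)
            calls = domain.classify_alignment(aln)
            pd.DataFrame(
                [
                    {
                        "id": c.member_id,
                        "category": c.category.value,
                        "col9": c.evidence[9],
                        "col13": c.evidence[13],
                        "col16": c.evidence[16],
                        "col17": c.evidence[17],
                        "basic_count": c.basic_count,
                    }
                    for c in calls
                ]
            ).to_csv(out / "binding.tsv", sep="\t", index=False)
            counts = domain.binding_counts(calls)
            return {
                "n_members": block.n_rows,
                "n_conserved50": len(
                    profile.conserved(domain.ConsensusCategory.CONSERVED50)
                ),
                "binding_counts": {k.value: v for k, v in counts.items()},
            }
        stage("domain", _domain)

    # --- phylogeny & subfamilies --------------------------------------
    if cfg.full_alignment is not None:
        def _phylo() -> dict:
            block = fio.read_alignment(cfg.full_alignment)
            pcfg = phylogeny.PhyloConfig(
                n_bootstrap=cfg.n_bootstrap,
                support_display_min=cfg.support_display_min,
                rng_seed=cfg.seed,
                distance_model=cfg.distance_model,
            )
            tree = phylogeny.bootstrap_support(block, pcfg)
            phylogeny.render_support_labels(tree, pcfg.support_display_min)
            fio.write_newick(tree, out / "tree.nwk")
            result = {"n_taxa": block.n_rows, "n_bootstrap": cfg.n_bootstrap}
            if cfg.anchors is not None:
                anchors = _read_anchor_table(cfg.anchors)
                assignment.update(phylogeny.assign_subfamilies(tree, anchors))
                pd.DataFrame(
                    sorted(assignment.items()), columns=["id", "subfamily"]
                ).to_csv(out / "subfamilies.tsv", sep="\t", index=False)
                result["n_assigned"] = len(assignment)
                result["n_orphans"] = sum(
                    1 for v in assignment.values() if v == phylogeny.ORPHAN
                )
            return result
        stage("phylo", _phylo)

    # --- gene structure ------------------------------------------------
    if cfg.gff3 is not None:
        def _structure() -> dict:
            genes = fio.read_gff3(cfg.gff3)
            gene_structure.per_gene_table(genes).to_csv(
                out / "structure.tsv", sep="\t", index=False
            )
            summary = gene_structure.summarize_structures(
                genes, assignment if assignment else None
            )
            summary.to_frame().to_csv(
                out / "structure_summary.tsv", sep="\t", index=False
            )
            return {
                "n_genes": summary.n_genes,
                "phase_counts": summary.phase_counts,
                "symmetric_counts": summary.symmetric_counts,
                "n_intronless": summary.n_intronless,
            }
        stage("structure", _structure)

    # --- expression screen ----------------------------------------------
    if cfg.expression is not None:
        def _screen() -> dict:
            matrix = fio.read_expression(cfg.expression)
            scfg = expression.ScreenConfig(
                on_threshold=cfg.on_threshold,
                off_threshold=cfg.off_threshold,
                expressed_threshold=cfg.expressed_threshold,
            )
            n_expressed, _ = expression.count_expressed(matrix, scfg)
            reports = expression.screen_candidates(matrix, scfg)
            pd.DataFrame(
                [
                    {"gene_id": r.gene_id, "is_candidate": r.is_candidate,
                     "monotone_increase": r.monotone_increase, **r.rpkm}
                    for r in reports
                ]
            ).to_csv(out / "candidates.tsv", sep="\t", index=False)
            hm = expression.heatmap_matrix(matrix, scfg)
            hm.index.name = "gene_id"
            hm.to_csv(out / "heatmap.tsv", sep="\t")
            return {
                "n_expressed": n_expressed,
                "candidates": expression.candidate_ids(reports),
            }
        stage("screen", _screen)

    # --- summaries -------------------------------------------------------
    if cfg.clusters is not None:
        def _pairs() -> dict:
            clusters = fio.read_clusters(cfg.clusters)
            counts = summaries.count_pairs(clusters)
            counts.to_frame().to_csv(out / "pairs.tsv", sep="\t", index=False)
            return {
                "ortholog_pairs": {
                    f"{a}-{b}": n for (a, b), n in counts.ortholog_pairs.items()
                },
                "paralog_pairs": counts.paralog_pairs,
            }
        stage("pairs", _pairs)

    if cfg.motif_hits is not None and assignment:
        def _motifs() -> dict:
            hits = fio.read_motif_hits(cfg.motif_hits)
            summary = summaries.summarize_motifs(
                hits, assignment, universal_fraction=cfg.universal_fraction
            )
            summary.to_frame().to_csv(out / "motifs.tsv", sep="\t", index=False)
            return {
                "universal_motifs": list(summary.universal_motifs),
                "subfamily_specific": {
                    str(k): v for k, v in summary.subfamily_specific.items()
                },
            }
        stage("motifs", _motifs)

    _write_manifest(manifest, out)
    return manifest


def _write_manifest(manifest: dict, out: Path) -> None:
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
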