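"""End-to-end orchestration: classify -> align -> scan -> trees -> discordance.

Produces a reproducible report bundle in an output directory: architecture
TSV, aligned FASTA, triplet segmentation TSV, motif-hit TSV, two domain trees
(Newick), a discordance report (TSV + JSON) and a run manifest. All
randomness (bootstrap) is governed by the configured seed; two runs with the
same config and seed produce byte-identical outputs.
"""

from __future__ import annotations

import itertools
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__, architecture, msa, phylo, recomb, seqio

logger = logging.getLogger("svmprecomb")


@dataclass
class PipelineConfig:
    input_fasta: str | None = None
    output_dir: str = "svmprecomb_out"
    seed: int = 0
    # alignment
    match: float = 5.0
    mismatch: float = -4.0
    gap_open: float = -10.0
    gap_extend: float = -1.0
    prealigned: bool = False
    # recombination scan
    k: int = 12
    max_mismatch: int = 1
    min_separation: int = 24
    smooth: int = 9
    min_segment: int = 20
    dominance: float = 0.7
    min_support: int = 8
    anchor_support: int = 12
    anchor_dominance: float = 0.85
    triplet_min_identity: float = 60.0
    # phylogenetics
    bootstrap_reps: int = 200
    support_threshold: float = 70.0
    # domain boundaries (aa, reference numbering)
    catalytic_aa: tuple[int, int] = (1, 214)
    disintegrin_aa: tuple[int, int] = (215, 307)
    l12: int = 900
    l23: int = 1200

    def align_params(self) -> msa.AlignParams:
        return msa.AlignParams(self.match, self.mismatch, self.gap_open, self.gap_extend)


def read_config(path: str) -> PipelineConfig:
    """Parse a flat key=value config file (lines starting with # ignored)."""
    cfg = PipelineConfig()
    with open(path) as handle:
        for lineno, line in enumerate(handle, 1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise ValueError(f"{path}:{lineno}: expected key=value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if not hasattr(cfg, key):
                raise ValueError(f"{path}:{lineno}: unknown key {key!r}")
            current = getattr(cfg, key)
            if isinstance(current, bool):
                setattr(cfg, key, value.lower() in ("1", "true", "yes"))
            elif isinstance(current, int):
                setattr(cfg, key, int(value))
            elif isinstance(current, float):
                setattr(cfg, key, float(value))
            elif isinstance(current, tuple):
                parts = [int(v) for v in value.replace(",", " ").split()]
                setattr(cfg, key, tuple(parts))
            else:
                setattr(cfg, key, value)
    return cfg


@dataclass
class PipelineResult:
    architectures: list
    alignment: msa.MultipleAlignment
    segmentations: list
    motif_hits: list
    tree_catalytic: phylo.Tree | None
    tree_disintegrin: phylo.Tree | None
    discordance: phylo.DiscordanceReport | None
    output_dir: Path
    manifest: dict = field(default_factory=dict)


def _translations(records: list[seqio.SequenceRecord]) -> list[seqio.SequenceRecord]:
    out = []
    for rec in records:
        protein = seqio.translate(rec.seq, frame=0)
        stop = protein.find("*")
        if stop >= 0:
            protein = protein[:stop]
        if protein:
            out.append(seqio.SequenceRecord(rec.id, protein, "aa"))
    return out


def classify_stage(records, cfg: PipelineConfig):
    boundaries = architecture.DomainBoundaries(cfg.catalytic_aa, cfg.disintegrin_aa)
    return [
        architecture.assign_class(rec, boundaries, cfg.l12, cfg.l23) for rec in records
    ]


def align_stage(records, cfg: PipelineConfig) -> msa.MultipleAlignment:
    if cfg.prealigned:
        return msa.MultipleAlignment.from_records(records)
    return msa.progressive_msa(records, cfg.align_params())


def scan_stage(aln: msa.MultipleAlignment, cfg: PipelineConfig):
    """Shift-region scan over all triplets passing the identity pre-filter."""
    ids = list(aln.ids)
    keep_pairs = set()
    for i, j in itertools.combinations(ids, 2):
        pid = msa.percent_identity(aln, i, j)
        if pid.value >= cfg.triplet_min_identity:
            keep_pairs.add(frozenset((i, j)))
    results = []
    for a, b, c in itertools.combinations(ids, 3):
        if not (
            frozenset((a, b)) in keep_pairs
            and frozenset((a, c)) in keep_pairs
            and frozenset((b, c)) in keep_pairs
        ):
            continue
        seg, positions = recomb.scan_triplet(
            aln, a, b, c,
            min_segment=cfg.min_segment, smooth=cfg.smooth,
            dominance=cfg.dominance, min_support=cfg.min_support,
            anchor_support=cfg.anchor_support,
            anchor_dominance=cfg.anchor_dominance,
        )
        results.append((seg, positions))
    return results


def trees_stage(records, architectures, cfg: PipelineConfig):
    """Protein domain trees with bootstrap support, plus the discordance report."""
    proteins = _translations(records)
    if len(proteins) < 4:
        return None, None, None
    aa_aln = msa.progressive_msa(proteins, cfg.align_params())
    reference = max(proteins, key=lambda p: len(p.seq)).id
    boundaries = architecture.DomainBoundaries(
        cfg.catalytic_aa, cfg.disintegrin_aa, reference_id=reference
    )
    cat_aln, dis_aln = phylo.partition_domains(aa_aln, boundaries)
    if len(cat_aln) < 3 or len(dis_aln) < 3:
        return None, None, None
    tree_cat = phylo.bootstrap_support(cat_aln, cfg.bootstrap_reps, cfg.seed)
    tree_dis = phylo.bootstrap_support(dis_aln, cfg.bootstrap_reps, cfg.seed + 1)
    labels = {a.id: a.svmp_class for a in architectures}
    report = phylo.discordance_report(tree_cat, tree_dis, labels, cfg.support_threshold)
    return tree_cat, tree_dis, report


def run_pipeline(cfg: PipelineConfig, records=None) -> PipelineResult:
    """Run every stage and write the report bundle; returns in-memory results."""
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = []

    def stage(name: str):
        logger.info("[%s] running", name)
        log_lines.append(name)

    if records is None:
        if cfg.input_fasta is None:
            raise ValueError("no input: provide input_fasta or records")
        if not Path(cfg.input_fasta).exists():
            raise FileNotFoundError(f"input file not found: {cfg.input_fasta}")
        stage("read")
        records = seqio.read_fasta(cfg.input_fasta, "nt")
    if len(records) < 3:
        raise ValueError("pipeline requires >= 3 input sequences")

    stage("classify")
    architectures = classify_stage(records, cfg)
    architecture.write_architecture_table(architectures, str(out / "architecture.tsv"))

    stage("align")
    aln = align_stage(records, cfg)
    aln.write_fasta(str(out / "aligned.fasta"))

    stage("scan")
    segmentations = scan_stage(aln, cfg)
    seg_path = out / "segmentation.tsv"
    if segmentations:
        for idx, (seg, _) in enumerate(segmentations):
            recomb.write_segmentation_tsv(seg, aln, str(seg_path), append=idx > 0)
    else:
        seg_path.write_text(
            "triplet\tsegment_start_col\tsegment_end_col\tquery_start\tquery_end\t"
            "dominant_state\tpid_AB\tpid_AC\tpid_BC\n"
        )

    stage("motifs")
    hits = recomb.find_repeats_and_complements(
        records, k=cfg.k, max_mismatch=cfg.max_mismatch, min_separation=cfg.min_separation
    )
    recomb.write_motif_hits(hits, str(out / "motif_hits.tsv"))

    stage("trees")
    tree_cat, tree_dis, report = trees_stage(records, architectures, cfg)
    if tree_cat is not None:
        (out / "tree_catalytic.nwk").write_text(tree_cat.newick() + "\n")
        (out / "tree_disintegrin.nwk").write_text(tree_dis.newick() + "\n")
        phylo.write_discordance_tsv(report, str(out / "discordance.tsv"))
        (out / "discordance.json").write_text(
            json.dumps(
                {
                    "flagged": report.flagged,
                    "rf_distance": report.rf_distance,
                    "neighbor_classes": {
                        k: list(v) for k, v in report.neighbor_classes.items()
                    },
                },
                indent=2,
                sort_keys=True,
            )
            + "\n"
        )

    manifest = {
        "config": {k: v for k, v in vars(cfg).items()},
        "seed": cfg.seed,
        "version": __version__,
        "python": sys.version.split()[0],
        "stages": log_lines,
        "n_sequences": len(records),
        "n_breakpoints": sum(len(s.breakpoints) for s, _ in segmentations),
        "n_motif_hits": len(hits),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")

    return PipelineResult(
        architectures, aln, segmentations, hits, tree_cat, tree_dis, report, out, manifest
    )
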