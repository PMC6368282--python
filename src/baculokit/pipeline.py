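"""End-to-end orchestration: annotate -> hrs -> summary, with optional
distance/tree stages, a serialized run log and deterministic outputs."""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .distances_trees import (
    AlignedSeqSet,
    bootstrap_support,
    demarcation_table,
    nj_tree,
    pairwise_matrix,
    write_newick,
)
from .genome_io import GenomeRecord, gc_content, read_genome, write_gff3
from .hr_finder import cluster_hrs, find_palindromic_repeats
from .orf_annotator import (
    orf_overlaps,
    orfs_from_features,
    orientation_summary,
    scan_orfs,
    scan_promoter_motifs,
)

logger = logging.getLogger("baculokit.pipeline")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    genome_path: str | None = None  # or pass a GenomeRecord to run_pipeline
    genome_format: str = "genbank"
    outdir: str = "baculokit_out"
    seed: int = 0
    # stage toggles
    do_annotate: bool = True
    do_promoters: bool = True
    do_hrs: bool = True
    do_distances: bool = False
    # annotate
    orf_source: str = "features"  # 'features' (curated CDS table) or 'scan'
    min_codons: int = 50
    require_atg: bool = True
    reference_orf: str = "polh"  # gene label or orf_id of the polyhedrin ORF
    promoter_window: int = 120
    # hrs
    unit_len: int = 28
    max_self_mismatch: int = 8
    min_repeats: int = 5
    max_gap: int = 200
    # distances
    alignment_path: str | None = None
    bootstrap: int = 0
    threshold: float = 0.050
    focal_taxon: str | None = None

    def validate(self) -> None:
        if self.orf_source not in ("features", "scan"):
            raise ValueError(f"orf_source must be 'features' or 'scan', not {self.orf_source!r}")
        if self.min_codons < 1:
            raise ValueError("min_codons must be >= 1")
        if self.do_distances and not self.alignment_path:
            raise ValueError("distance stage enabled but no alignment_path given")


def run_pipeline(config: PipelineConfig, genome: GenomeRecord | None = None) -> dict:
    """Run the enabled stages and write per-stage outputs plus a summary.

    Returns the report dict, also written as ``report.json`` in the output
    directory.  Outputs are byte-identical for identical config and seed.
    """
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(name)s: %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    report: dict = {"baculokit_version": __version__, "config": asdict(config)}
    try:
        logger.info("config: %s", json.dumps(asdict(config), sort_keys=True))
        if genome is None:
            if not config.genome_path:
                raise ValueError("no genome given")
            genome = read_genome(config.genome_path, config.genome_format)
        summary = {
            "genome_id": genome.id,
            "length_bp": genome.length,
            "gc_percent": gc_content(genome.sequence),
        }
        if config.do_annotate:
            if config.orf_source == "features":
                orfs = orfs_from_features(genome)
                if not orfs:
                    logger.info("no CDS features; falling back to the scanner")
                    orfs = scan_orfs(genome, config.min_codons, config.require_atg)
            else:
                orfs = scan_orfs(genome, config.min_codons, config.require_atg)
            summary["n_orfs"] = len(orfs)
            ref = next(
                (o.orf_id for o in orfs if config.reference_orf in (o.orf_id, o.gene)),
                orfs[0].orf_id if orfs else None,
            )
            if ref:
                counts = orientation_summary(orfs, ref)
                summary["n_polh_sense"] = counts["polh_sense"]
                summary["n_anti_polh_sense"] = counts["anti"]
            if config.do_promoters:
                n_hits = 0
                with open(outdir / "promoters.tsv", "w") as fh:
                    fh.write("orf_id\tmotif_class\tmotif\toffset\n")
                    for o in orfs:
                        hits = scan_promoter_motifs(genome, o, config.promoter_window)
                        o.promoter_hits = hits
                        n_hits += len(hits)
                        for h in hits:
                            fh.write(f"{o.orf_id}\t{h.motif_class}\t{h.motif_seq}\t{h.offset}\n")
                summary["n_promoter_hits"] = n_hits
            overlaps = orf_overlaps(orfs, genome.length, genome.circular)
            with open(outdir / "overlaps.tsv", "w") as fh:
                fh.write("orf_a\torf_b\trelation\tsame_strand\n")
                for r in overlaps:
                    fh.write(f"{r.orf_a}\t{r.orf_b}\t{r.relation}\t{int(r.same_strand)}\n")
            from .genome_io import FeatureRecord

            feats = [
                FeatureRecord("CDS", o.start, o.end, o.strand,
                              {"ID": o.orf_id, **({"gene": o.gene} if o.gene else {})})
                for o in orfs
            ]
            write_gff3(genome, feats, outdir / "orfs.gff3")
            logger.info("annotate: %d ORFs", len(orfs))
        if config.do_hrs:
            hits = find_palindromic_repeats(genome, config.unit_len, config.max_self_mismatch)
            hrs = cluster_hrs(hits, config.min_repeats, config.max_gap)
            summary["n_hrs"] = len(hrs)
            summary["hr_repeat_counts"] = [h.n_repeats for h in hrs]
            with open(outdir / "hrs.tsv", "w") as fh:
                fh.write("hr_id\tstart\tend\tn_repeats\tconsensus\n")
                for h in hrs:
                    fh.write(f"{h.hr_id}\t{h.span[0]}\t{h.span[1]}\t{h.n_repeats}\t{h.consensus}\n")
            logger.info("hrs: %d loci", len(hrs))
        if config.do_distances:
            aln = AlignedSeqSet.from_fasta(config.alignment_path)
            dm = pairwise_matrix(aln)
            dm.write_tsv(outdir / "distances.tsv")
            focal = config.focal_taxon or aln.taxa[0]
            demarcation_table(dm, focal, config.threshold).to_csv(
                outdir / "demarcation.tsv", sep="\t", index=False
            )
            tree = (
                bootstrap_support(aln, config.bootstrap, config.seed)
                if config.bootstrap > 0
                else nj_tree(dm)
            )
            write_newick(tree, outdir / "tree.nwk")
            summary["n_taxa"] = len(aln.taxa)
            logger.info("distances: %d taxa", len(aln.taxa))
        report["summary"] = summary
        with open(outdir / "report.json", "w") as fh:
            json.dump(report, fh, indent=1, sort_keys=True)
        logger.info("done")
    finally:
        logger.removeHandler(handler)
        handler.close()
    return report
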