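"""End-to-end orchestration: profile -> nulls -> calibrate -> scan -> classify
-> cluster, with funnel logging and a content-hashed artifact manifest."""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from math import ceil
from pathlib import Path

import numpy as np

from . import conservation, context, io, motif, scan, shuffles

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    genome_fasta: str
    seed_stockholm: str
    out_dir: str
    gff: str | None = None
    #: exactly one threshold policy: a fixed bit score, or null calibration
    min_bits: float | None = None
    #: "consensus": dinucleotide shuffles of the profile consensus motif
    #: (composition-matched decoys, the default); "genome": a shuffled copy of
    #: each genome; "seeds": per-RNA shuffles of the seed sequences
    calibration_null: str = "consensus"
    calibrate_n: int = 5000
    calibrate_quantile: float = 0.999
    shuffle_mode: str = "di"
    uniform_background: bool = False
    cluster_cutoffs: tuple[float, ...] = (0.30, 0.35, 0.40, 0.45, 0.50, 0.55, 0.60)
    seed: int = 0
    constraints: motif.MotifConstraints = field(default_factory=motif.MotifConstraints)

    def validate(self) -> None:
        for label, p in (("genome", self.genome_fasta), ("seed", self.seed_stockholm)):
            if not Path(p).exists():
                raise PipelineError(f"{label} file not found: {p}")
        if self.gff is not None and not Path(self.gff).exists():
            raise PipelineError(f"gff file not found: {self.gff}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages in order; returns the artifact manifest (also written).

    Stage row counts (candidates -> curated -> thresholded -> deduped ->
    classified) are logged to allow funnel-style reporting.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()

    genomes = io.read_fasta(config.genome_fasta)
    seed_aln = io.read_stockholm(config.seed_stockholm)
    if config.uniform_background:
        background = None
    else:
        counts = np.zeros(4)
        for g in genomes:
            f = g.mononucleotide_frequencies()
            counts += np.array([f[b] for b in "ACGU"]) * g.length
        background = counts / counts.sum()
    profile = motif.build_profile(seed_aln, background=background,
                                  constraints=config.constraints)
    profile_path = out / "profile.json"
    profile.to_json(profile_path)

    nulls_path = out / "nulls.fasta"
    artifacts = {"profile": profile_path}
    if config.min_bits is not None:
        min_bits = config.min_bits
        logger.info("threshold policy: fixed min_bits=%.3f", min_bits)
    else:
        if config.calibration_null == "consensus":
            null_seqs = list(
                shuffles.consensus_null_set(profile, n=config.calibrate_n,
                                            seed=config.seed)
            )
        elif config.calibration_null == "genome":
            null_seqs = [
                shuffles.shuffle_di(g.sequence, 1, seed=config.seed,
                                    source_id=f"null:{g.id}").sequences[0]
                for g in genomes
            ]
        elif config.calibration_null == "seeds":
            seeds = seed_aln.degapped()
            per_seq = ceil(config.calibrate_n / len(seeds))
            sets = shuffles.build_negative_set(
                seeds, per_seq, mode=config.shuffle_mode, seed=config.seed
            )
            null_seqs = [s for ss in sets for s in ss.sequences][: config.calibrate_n]
            io.write_fasta(
                ((name, seq.replace("U", "T"))
                 for name, seq in shuffles.negative_set_fasta_records(sets)),
                nulls_path,
            )
            artifacts["nulls"] = nulls_path
        else:
            raise PipelineError(
                f"unknown calibration_null {config.calibration_null!r}"
            )
        min_bits = shuffles.calibrate_threshold(
            profile, null_seqs, quantile=config.calibrate_quantile,
            constraints=config.constraints,
        )
        logger.info(
            "threshold policy: calibrated q=%.4f on %s null -> %.3f bits",
            config.calibrate_quantile, config.calibration_null, min_bits,
        )

    orfs = io.read_gff3(config.gff) if config.gff else None
    all_hits = []
    stats: dict[str, int] = {}
    for g in genomes:
        hits = scan.scan_genome(g, profile, config.constraints, min_bits,
                                orfs=orfs, stats=stats)
        logger.info("genome %s: %d hits", g.id, len(hits))
        all_hits.extend(hits)
    logger.info("funnel: %s", stats)
    hits_path = out / "hits.tsv"
    io.write_hits_tsv(all_hits, hits_path)
    artifacts["hits"] = hits_path

    if orfs is not None:
        genome_by_id = {g.id: g for g in genomes}
        calls = []
        for h in all_hits:
            call = context.classify_with_rescue(h, orfs, genome_by_id[h.seqid])
            term = context.find_terminator(genome_by_id[h.seqid], h)
            if term is not None and term.overlaps_stem2:
                call = dataclasses.replace(call, terminator_overlap=True)
            calls.append(call)
        context_path = out / "context.tsv"
        io.write_hits_tsv(calls, context_path)
        tally_path = out / "category_tally.tsv"
        context.category_tally(calls).to_csv(tally_path, sep="\t", index=False)
        artifacts["context"] = context_path
        artifacts["tally"] = tally_path
        stats["classified"] = len(calls)

    if len(all_hits) >= 2:
        seqs = [(f"hit{i:04d}", h.sequence) for i, h in enumerate(all_hits)]
        reports = conservation.sweep_identity(seqs, config.cluster_cutoffs)
        rows = []
        for rep in reports:
            rows.append(
                {
                    "cutoff": rep.cutoff,
                    "n_clusters": len(rep.clusters),
                    "singletons_discarded": rep.singletons_discarded,
                    "largest_cluster": max((len(c) for c in rep.clusters), default=0),
                }
            )
        import pandas as pd

        clusters_path = out / "clusters.tsv"
        pd.DataFrame(rows).to_csv(clusters_path, sep="\t", index=False)
        artifacts["clusters"] = clusters_path

    logger.info("pipeline finished in %.1f s", time.time() - t0)
    manifest = {
        "stages": stats,
        "min_bits": min_bits,
        "seed": config.seed,
        "artifacts": {
            name: {"path": str(p), "sha256": io.sha256_of(p)}
            for name, p in artifacts.items()
        },
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
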