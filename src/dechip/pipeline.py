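"""End-to-end orchestration: assemble -> rank -> discover -> (match).

Each stage draws randomness from its own RNG stream derived from the
master seed and the stage name, so stage outputs are pure functions of
(inputs, config, seed) and re-running any stage is deterministic.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import time
from dataclasses import dataclass
from typing import List, Optional

import numpy as np

from . import assemble_dbg, assemble_profile, io_formats, motifs, quantify

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    case_path: str
    control_path: str
    outdir: str
    assembler: str = "dbg"
    assembly_params: Optional[assemble_dbg.AssemblyParams] = None
    profile_params: Optional[assemble_profile.ProfileParams] = None
    mapping_params: Optional[quantify.MappingParams] = None
    ranking: Optional[quantify.RankingConfig] = None
    motif_config: Optional[motifs.DiscoveryConfig] = None
    motif_db: Optional[str] = None
    seed: int = 0

    def __post_init__(self):
        if self.case_path == self.control_path:
            raise ValueError("case and control paths must be distinct")
        if self.assembler not in ("dbg", "profile"):
            raise ValueError(f"unknown assembler {self.assembler!r}")
        self.assembly_params = self.assembly_params or assemble_dbg.AssemblyParams()
        self.profile_params = self.profile_params or assemble_profile.ProfileParams()
        self.mapping_params = self.mapping_params or quantify.MappingParams()
        self.ranking = self.ranking or quantify.RankingConfig()
        self.motif_config = self.motif_config or motifs.DiscoveryConfig()


def stage_rng(seed: int, stage: str) -> np.random.Generator:
    """One RNG stream per stage, derived from the master seed + stage name."""
    digest = hashlib.sha256(stage.encode()).digest()
    sub = int.from_bytes(digest[:4], "big")
    return np.random.default_rng([seed, sub])


def _checksum(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and return the run manifest."""
    os.makedirs(config.outdir, exist_ok=True)
    log_path = os.path.join(config.outdir, "run.log")
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("dechip")
    root.addHandler(handler)
    manifest: dict = {
        "version": "0.1.0",
        "seed": config.seed,
        "assembler": config.assembler,
        "stages": {},
    }
    t_all = time.time()
    stage = "parse"
    try:
        t0 = time.time()
        case_reads = list(io_formats.parse_reads(config.case_path, "case"))
        manifest["inputs"] = {
            "case": {"path": str(config.case_path), "sha256_16": _checksum(config.case_path)},
        }
        manifest["stages"]["parse"] = {
            "case_reads": len(case_reads),
            "seconds": round(time.time() - t0, 2),
        }

        stage = "assemble"
        t0 = time.time()
        if config.assembler == "dbg":
            chiptigs = assemble_dbg.assemble(case_reads, config.assembly_params)
        else:
            chiptigs = assemble_profile.assemble(case_reads, config.profile_params)
        assembly_fasta = os.path.join(config.outdir, "chiptigs.fasta")
        io_formats.write_fasta(
            ((c.id, c.sequence) for c in chiptigs), assembly_fasta
        )
        manifest["stages"]["assemble"] = {
            "chiptigs": len(chiptigs),
            "seconds": round(time.time() - t0, 2),
        }

        stage = "rank"
        t0 = time.time()
        kept = quantify.length_filter(chiptigs, config.ranking)
        if not kept:
            raise ValueError("no ChIPtigs pass the length filter")
        control_reads = list(io_formats.parse_reads(config.control_path, "control"))
        manifest["inputs"]["control"] = {
            "path": str(config.control_path),
            "sha256_16": _checksum(config.control_path),
        }
        index = quantify._SeedIndex(kept, config.mapping_params.seed_length)
        case_counts, case_mapped = quantify.map_reads(
            kept, case_reads, config.mapping_params, index=index
        )
        ctrl_counts, ctrl_mapped = quantify.map_reads(
            kept, control_reads, config.mapping_params, index=index
        )
        records = quantify.compute_enrichment(kept, case_counts, ctrl_counts)
        ranked, top = quantify.rank_chiptigs(records, config.ranking)
        ranking_tsv = os.path.join(config.outdir, "ranking.tsv")
        io_formats.write_ranking_tsv(ranked, ranking_tsv)
        by_id = {c.id: c for c in kept}
        top_fasta = os.path.join(config.outdir, "top_chiptigs.fasta")
        io_formats.write_fasta(
            ((rec.chiptig_id, by_id[rec.chiptig_id].sequence) for rec in top),
            top_fasta,
        )
        manifest["stages"]["rank"] = {
            "filtered_chiptigs": len(kept),
            "control_reads": len(control_reads),
            "case_mapped": case_mapped,
            "case_unmapped": len(case_reads) - case_mapped,
            "control_mapped": ctrl_mapped,
            "control_unmapped": len(control_reads) - ctrl_mapped,
            "r": records[0].r if records else None,
            "top_m": len(top),
            "seconds": round(time.time() - t0, 2),
        }

        stage = "motifs"
        t0 = time.time()
        positives = [by_id[rec.chiptig_id].sequence for rec in top]
        found: List[motifs.Motif] = []
        if len(positives) >= 2:
            mc = config.motif_config
            mc = motifs.DiscoveryConfig(
                min_len=mc.min_len, max_len=mc.max_len, n_motifs=mc.n_motifs,
                e_threshold=mc.e_threshold,
                seed=int(stage_rng(config.seed, "motifs").integers(2 ** 31)),
            )
            found = motifs.discover_motifs(positives, mc)
        meme_path = os.path.join(config.outdir, "motifs.meme")
        io_formats.write_meme_motifs(
            [motifs.motif_to_record(m) for m in found], meme_path
        )
        manifest["stages"]["motifs"] = {
            "motifs": len(found),
            "words": [m.word for m in found],
            "seconds": round(time.time() - t0, 2),
        }

        if config.motif_db and found:
            stage = "match"
            t0 = time.time()
            match_tsv = os.path.join(config.outdir, "matches.tsv")
            with open(match_tsv, "wt") as fh:
                fh.write("query\ttarget\toffset\tstrand\tscore\tp_est\n")
                for m in found:
                    hits = motifs.compare_to_database(
                        m.pwm, config.motif_db,
                        seed=int(stage_rng(config.seed, "match").integers(2 ** 31)),
                        query_name=m.word,
                    )
                    for h in hits:
                        fh.write(
                            f"{h.query}\t{h.target}\t{h.offset}\t{h.strand}\t"
                            f"{h.score:.4f}\t{h.p_est:.4f}\n"
                        )
            manifest["stages"]["match"] = {"seconds": round(time.time() - t0, 2)}
    except Exception as exc:
        root.removeHandler(handler)
        handler.close()
        raise StageError(stage, exc) from exc
    manifest["wall_seconds"] = round(time.time() - t_all, 2)
    with open(os.path.join(config.outdir, "manifest.json"), "wt") as fh:
        json.dump(manifest, fh, indent=2)
    root.removeHandler(handler)
    handler.close()
    return manifest
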