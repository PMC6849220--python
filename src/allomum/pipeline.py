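"""End-to-end orchestration: MUMs -> one-to-one filter -> coverage -> pair ranking.

Every run is deterministic: identical inputs and configuration produce
byte-identical reports (no timestamps; fixed key ordering; SHA-256
input checksums in the provenance block make results auditable).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

from . import __version__
from .coverage import (IntervalMap, PairCoverageMatrix, CoverageReport,
                       merge_to_intervals, mums_percentage,
                       pair_coverage_matrix, rank_pairs)
from .genome_io import Genome, PathLike, parse_fasta, parse_reads
from .kmer import GenomeSizeEstimate
from .mum_engine import MumParams, find_mums, write_matches_tsv
from .synteny_filter import filter_one_to_one

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failure, labeled with the stage and the offending input."""

    def __init__(self, stage: str, subject: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed on {subject!r}: {cause}")
        self.stage = stage
        self.subject = subject
        self.__cause__ = cause


@dataclass
class PipelineConfig:
    target_path: PathLike
    candidate_paths: Optional[Sequence[PathLike]] = None
    candidate_dir: Optional[PathLike] = None
    min_length: int = 20
    uniqueness: str = "both"
    use_raw_mums: bool = False
    output_dir: PathLike = "allomum_out"
    log_level: str = "INFO"

    def resolve_candidates(self) -> List[Path]:
        if (self.candidate_paths is None) == (self.candidate_dir is None):
            raise ValueError("provide exactly one of candidate_paths / candidate_dir")
        if self.candidate_paths is not None:
            return [Path(p) for p in self.candidate_paths]
        d = Path(self.candidate_dir)
        paths = sorted(p for p in d.iterdir()
                       if p.suffix in (".fa", ".fasta", ".fna")
                       or p.name.endswith((".fa.gz", ".fasta.gz", ".fna.gz")))
        if not paths:
            raise ValueError(f"no FASTA files found in {d}")
        return paths


@dataclass
class AncestryReport:
    target: str
    singles: List[CoverageReport]
    matrix: Optional[PairCoverageMatrix]
    winner: Optional[tuple]
    provenance: dict = field(default_factory=dict)

    def to_json_dict(self) -> dict:
        pairs = None
        if self.matrix is not None:
            pairs = [
                {"pair": [a, b], "cumulative_percent": round(p, 2),
                 "sum_of_singles_percent": round(
                     self.matrix.single(a) + self.matrix.single(b), 2)}
                for a, b, p in rank_pairs(self.matrix)
            ]
        return {
            "target": self.target,
            "candidates": [s.species for s in self.singles],
            "singles": [
                {"species": s.species, "covered_bp": s.covered_bp,
                 "target_bp": s.target_bp, "percent": round(s.percent, 2)}
                for s in self.singles
            ],
            "pairs": pairs,
            "winner": list(self.winner) if self.winner else None,
            "provenance": self.provenance,
        }


def _sha256(path: PathLike) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_matrix_tsv(matrix: PairCoverageMatrix, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("species\t" + "\t".join(matrix.species) + "\n")
        for i, name in enumerate(matrix.species):
            row = "\t".join(f"{matrix.values[i, j]:.2f}"
                            for j in range(len(matrix.species)))
            fh.write(f"{name}\t{row}\n")


def run_ancestry(cfg: PipelineConfig) -> AncestryReport:
    """The full ancestry analysis; writes TSV + JSON reports to output_dir."""
    logging.basicConfig(level=cfg.log_level)
    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    cand_paths = cfg.resolve_candidates()

    try:
        target = parse_fasta(cfg.target_path)
    except Exception as exc:
        raise PipelineError("parse_target", str(cfg.target_path), exc) from exc
    log.info("target %s: %d bp in %d record(s)", target.name,
             target.total_length, len(target))

    params = MumParams(cfg.min_length, cfg.uniqueness)
    per_species: Dict[str, IntervalMap] = {}
    singles: list[CoverageReport] = []
    checksums = {"target": _sha256(cfg.target_path)}
    for path in cand_paths:
        try:
            cand = parse_fasta(path)
        except Exception as exc:
            raise PipelineError("parse_candidate", str(path), exc) from exc
        checksums[cand.name] = _sha256(path)
        try:
            matches = find_mums(target, cand, params)
        except Exception as exc:
            raise PipelineError("mums", cand.name, exc) from exc
        log.info("%s: %d raw MUM(s)", cand.name, len(matches))
        try:
            kept = matches if cfg.use_raw_mums else \
                filter_one_to_one(matches, target, cand)
        except Exception as exc:
            raise PipelineError("filter", cand.name, exc) from exc
        write_matches_tsv(kept, out_dir / f"{cand.name}.matches.tsv",
                          target, cand)
        try:
            intervals = merge_to_intervals(kept, target)
            singles.append(mums_percentage(intervals, target, cand.name))
        except Exception as exc:
            raise PipelineError("coverage", cand.name, exc) from exc
        per_species[cand.name] = intervals

    matrix = None
    winner = None
    if len(per_species) >= 2:
        try:
            matrix = pair_coverage_matrix(per_species, target)
            ranked = rank_pairs(matrix)
        except Exception as exc:
            raise PipelineError("pairs", target.name, exc) from exc
        winner = (ranked[0][0], ranked[0][1])
        _write_matrix_tsv(matrix, out_dir / "pair_coverage.tsv")
    else:
        log.warning("fewer than 2 candidates: pair ranking skipped")

    report = AncestryReport(
        target=target.name,
        singles=sorted(singles, key=lambda s: s.species),
        matrix=matrix,
        winner=winner,
        provenance={
            "tool": "allomum",
            "version": __version__,
            "parameters": {
                "min_length": cfg.min_length,
                "uniqueness": cfg.uniqueness,
                "use_raw_mums": cfg.use_raw_mums,
            },
            "input_sha256": dict(sorted(checksums.items())),
        },
    )
    with open(out_dir / "ancestry_report.json", "w") as fh:
        json.dump(report.to_json_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report


def run_gsize(reads_path: PathLike, k: int = 21, cutoff: int = 4,
              output_dir: Optional[PathLike] = None) -> GenomeSizeEstimate:
    """K-mer genome-size estimation from a FASTQ/FASTA read file.

    Writes the histogram as two-column TSV and the estimate as JSON when
    ``output_dir`` is given.
    """
    from .kmer import (count_kmers, estimate_depth, estimate_genome_size,
                       low_frequency_mass)
    try:
        reads = list(parse_reads(reads_path))
        if not reads:
            raise ValueError("no reads")
        hist = count_kmers(reads, k)
        depth = estimate_depth(hist, cutoff)
        b = low_frequency_mass(hist, cutoff)
        mean_len = sum(len(r) for r in reads) / len(reads)
        read_length = int(mean_len) if mean_len.is_integer() else mean_len
        g = estimate_genome_size(len(reads), read_length, k, b, depth)
        est = GenomeSizeEstimate(len(reads), read_length, k, b, depth, g, cutoff)
    except Exception as exc:
        raise PipelineError("gsize", str(reads_path), exc) from exc
    if output_dir is not None:
        out_dir = Path(output_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        with open(out_dir / "kmer_histogram.tsv", "w") as fh:
            fh.write("multiplicity\tdistinct_kmers\n")
            for m in sorted(hist.counts):
                fh.write(f"{m}\t{hist.counts[m]}\n")
        with open(out_dir / "genome_size.json", "w") as fh:
            json.dump(est.as_dict(), fh, indent=2, sort_keys=True)
            fh.write("\n")
    return est
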