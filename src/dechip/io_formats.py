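"""Readers and writers for the formats the pipeline touches.

FASTQ/FASTA read input (plain or gzip, auto-detected), FASTA output with
80-column wrapping, the MEME minimal motif dialect, and the tab-separated
ranking report.
"""

from __future__ import annotations

import gzip
import io
import logging
from dataclasses import dataclass
from typing import IO, Iterable, Iterator, Optional, Sequence, Tuple

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

logger = logging.getLogger(__name__)

_VALID_BASES = frozenset("ACGTN")


class ParseError(ValueError):
    """A malformed record; the message names the 1-based record index."""


class FormatError(ValueError):
    """Input that is neither FASTA nor FASTQ."""


@dataclass
class Read:
    """One sequencing read with its source label (case or control)."""

    id: str
    sequence: str
    quality: Optional[Tuple[int, ...]] = None
    source: str = "case"

    def __post_init__(self):
        if not self.sequence:
            raise ValueError(f"read {self.id!r}: empty sequence")
        if self.quality is not None and len(self.quality) != len(self.sequence):
            raise ValueError(f"read {self.id!r}: quality/sequence length mismatch")
        if self.source not in ("case", "control"):
            raise ValueError(f"read {self.id!r}: bad source {self.source!r}")


@dataclass
class MotifRecord:
    """A named PWM with the evidence that produced it."""

    name: str
    pwm: np.ndarray  # L x 4, columns over (A, C, G, T)
    nsites: int = 1
    significance: float = 1.0

    def __post_init__(self):
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4 or self.pwm.shape[0] < 1:
            raise ValueError(f"motif {self.name!r}: PWM must be L x 4 with L >= 1")
        if (self.pwm < 0).any():
            raise ValueError(f"motif {self.name!r}: negative probabilities")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError(f"motif {self.name!r}: PWM columns must sum to 1")


def _open_maybe_gzip(path) -> IO[str]:
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return io.TextIOWrapper(gzip.open(path, "rb"), encoding="ascii")
    return open(path, "rt", encoding="ascii")


def _phred(qual: str) -> Tuple[int, ...]:
    return tuple(ord(c) - 33 for c in qual)


def parse_reads(path, source: str = "case", max_n_fraction: float = 0.10) -> Iterator[Read]:
    """Stream reads from a FASTA or FASTQ file (plain or gzipped).

    The format is auto-detected from the first character ('>' FASTA,
    '@' FASTQ). Lowercase bases are uppercased; characters outside
    {A,C,G,T,N} raise :class:`ParseError`. Reads with more than
    ``max_n_fraction`` N bases are dropped (count logged at the end).
    """
    handle = _open_maybe_gzip(path)
    with handle:
        first = handle.read(1)
        handle.seek(0)
        if first == ">":
            records = ((i, s, None) for i, s in SimpleFastaParser(handle))
        elif first == "@":
            records = ((i, s, q) for i, s, q in _fastq_records(handle))
        elif first == "":
            return
        else:
            raise FormatError(f"{path}: unrecognized format (starts with {first!r})")
        n_dropped = 0
        for idx, (header, seq, qual) in enumerate(records, start=1):
            rid = header.split()[0] if header.split() else header
            seq = seq.upper()
            if not seq:
                raise ParseError(f"record {idx} ({rid!r}): empty sequence")
            bad = set(seq) - _VALID_BASES
            if bad:
                raise ParseError(
                    f"record {idx} ({rid!r}): invalid characters {sorted(bad)!r}"
                )
            if qual is not None and len(qual) != len(seq):
                raise ParseError(
                    f"record {idx} ({rid!r}): quality length {len(qual)} != "
                    f"sequence length {len(seq)}"
                )
            if seq.count("N") > max_n_fraction * len(seq):
                n_dropped += 1
                continue
            yield Read(
                id=rid,
                sequence=seq,
                quality=_phred(qual) if qual is not None else None,
                source=source,
            )
        if n_dropped:
            logger.info("parse_reads(%s): dropped %d reads with >%.0f%% N",
                        path, n_dropped, 100 * max_n_fraction)


def _fastq_records(handle):
    """FastqGeneralIterator wrapped to report the failing record index."""
    it = FastqGeneralIterator(handle)
    idx = 0
    while True:
        idx += 1
        try:
            item = next(it)
        except StopIteration:
            return
        except ValueError as exc:
            raise ParseError(f"record {idx}: {exc}") from exc
        yield item


def write_fasta(records: Iterable[Tuple[str, str]], path, width: int = 80) -> None:
    """Write (id, sequence) pairs as FASTA with 80-column wrapping."""
    seen = set()
    with open(path, "wt", encoding="ascii") as fh:
        for rid, seq in records:
            if not rid:
                raise ValueError("empty record id")
            if rid in seen:
                raise ValueError(f"duplicate record id {rid!r}")
            seen.add(rid)
            fh.write(f">{rid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_meme_motifs(
    motifs: Sequence[MotifRecord],
    path,
    background: Optional[Sequence[float]] = None,
) -> None:
    """Write motifs in MEME minimal format (consumable by the MEME suite)."""
    bg = background if background is not None else (0.25, 0.25, 0.25, 0.25)
    with open(path, "wt", encoding="ascii") as fh:
        fh.write("MEME version 4\n\n")
        fh.write("ALPHABET= ACGT\n\n")
        fh.write("strands: + -\n\n")
        fh.write("Background letter frequencies\n")
        fh.write("A %.6f C %.6f G %.6f T %.6f\n\n" % tuple(bg))
        for m in motifs:
            name = "_".join(m.name.split())
            fh.write(f"MOTIF {name}\n")
            fh.write(
                "letter-probability matrix: alength= 4 w= %d nsites= %d E= %.3e\n"
                % (m.pwm.shape[0], m.nsites, m.significance)
            )
            for row in m.pwm:
                fh.write(" ".join("%.6f" % v for v in row) + "\n")
            fh.write("\n")


def parse_meme_motifs(path) -> list[MotifRecord]:
    """Parse a MEME minimal motif file (version/alphabet lines tolerated)."""
    motifs: list[MotifRecord] = []
    with open(path, "rt", encoding="ascii") as fh:
        lines = fh.readlines()
    i = 0
    while i < len(lines):
        line = lines[i].strip()
        if line.startswith("MOTIF"):
            parts = line.split()
            name = parts[1] if len(parts) > 1 else f"motif_{len(motifs) + 1}"
            # advance to the letter-probability header
            i += 1
            while i < len(lines) and "letter-probability" not in lines[i]:
                if lines[i].strip().startswith("MOTIF"):
                    break
                i += 1
            if i >= len(lines) or "letter-probability" not in lines[i]:
                raise ParseError(f"motif {name!r}: missing letter-probability matrix")
            header = lines[i]
            w = None
            nsites = 1
            toks = header.replace("=", " = ").split()
            for j, t in enumerate(toks):
                if t == "w" and j + 2 < len(toks):
                    w = int(toks[j + 2])
                if t == "nsites" and j + 2 < len(toks):
                    nsites = int(float(toks[j + 2]))
            if w is None:
                raise ParseError(f"motif {name!r}: missing w= in matrix header")
            rows = []
            i += 1
            while i < len(lines) and len(rows) < w:
                s = lines[i].strip()
                if s:
                    rows.append([float(x) for x in s.split()[:4]])
                i += 1
            if len(rows) != w:
                raise ParseError(f"motif {name!r}: expected {w} matrix rows")
            pwm = np.array(rows, dtype=float)
            pwm = pwm / pwm.sum(axis=1, keepdims=True)
            motifs.append(MotifRecord(name=name, pwm=pwm, nsites=nsites))
        else:
            i += 1
    return motifs


RANKING_HEADER = "chiptig_id\tlength\tx1\tx0\tp_value\trank"


def write_ranking_tsv(records, path, q_values=None) -> None:
    """Write ranked enrichment records as TSV (rank-ascending).

    ``records`` need ``chiptig_id, length, x1, x0, p, rank`` attributes.
    P-values are printed in scientific notation with 6 significant digits.
    ``q_values`` (optional, parallel to the rank-sorted records) appends an
    informational q_value column.
    """
    recs = sorted(records, key=lambda r: r.rank)
    with open(path, "wt", encoding="ascii") as fh:
        header = RANKING_HEADER + ("\tq_value" if q_values is not None else "")
        fh.write(header + "\n")
        for i, r in enumerate(recs):
            row = f"{r.chiptig_id}\t{r.length}\t{r.x1}\t{r.x0}\t{r.p:.5e}\t{r.rank}"
            if q_values is not None:
                row += f"\t{q_values[i]:.5e}"
            fh.write(row + "\n")
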