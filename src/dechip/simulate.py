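"""Synthetic ChIP-seq experiments with known ground truth.

A random genome is generated, motif instances sampled from a PWM are
planted at spaced positions, and case/control read sets are drawn from a
fragment model: control fragments start uniformly; case fragments are
site-derived with probability w/(1+w) where w = enrichment_fold * n_sites
* mean fragment length / genome length, which makes the per-bp fragment
start rate inside site footprints exactly ``enrichment_fold`` times the
background rate. Reads are the first read_length bases from the fragment's
5' end on a uniformly chosen strand, so forward reads pile up upstream and
reverse reads downstream of site centers (the anti-correlated strand
geometry of bound fragments).
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from ._seqtools import revcomp
from .io_formats import Read

BASES = "ACGT"


@dataclass
class SimulationConfig:
    genome_length: int = 100_000
    gc_fraction: float = 0.5
    pwm: Optional[np.ndarray] = None  # planted motif; default set in __post_init__
    n_sites: int = 200
    min_site_spacing: int = 200
    n_case_reads: int = 50_000
    n_control_reads: int = 50_000
    enrichment_fold: float = 10.0
    fragment_length_mean: float = 150.0
    fragment_length_sd: float = 20.0
    read_length: int = 36
    error_rate: float = 0.005
    seed: int = 0

    def __post_init__(self):
        if self.pwm is None:
            self.pwm = consensus_pwm("TGACTCAG", 0.9)
        self.pwm = np.asarray(self.pwm, dtype=float)
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        if not 0.0 <= self.gc_fraction <= 1.0:
            raise ValueError("gc_fraction must be in [0,1]")
        if not 0.0 <= self.error_rate <= 1.0:
            raise ValueError("error_rate must be in [0,1]")
        if self.enrichment_fold < 1.0:
            raise ValueError("enrichment_fold must be >= 1")
        if self.read_length > self.fragment_length_mean:
            raise ValueError("read_length must be <= fragment_length_mean")
        L = self.pwm.shape[0]
        if self.n_sites * (L + self.min_site_spacing) > self.genome_length:
            raise ValueError("site placement infeasible for this genome length")


@dataclass
class SiteAnnotation:
    """A planted motif instance (0-based genome offset, half-open end)."""

    start: int
    strand: str
    instance: str

    @property
    def end(self) -> int:
        return self.start + len(self.instance)


@dataclass
class SimulationResult:
    genome: str
    sites: List[SiteAnnotation]
    case_reads: List[Read]
    control_reads: List[Read]
    config: SimulationConfig


def consensus_pwm(consensus: str, dominant: float = 0.9) -> np.ndarray:
    """PWM that puts ``dominant`` mass on each consensus base."""
    off = (1.0 - dominant) / 3.0
    pwm = np.full((len(consensus), 4), off)
    for i, b in enumerate(consensus.upper()):
        pwm[i, BASES.index(b)] = dominant
    return pwm


def pwm_consensus(pwm: np.ndarray) -> str:
    return "".join(BASES[i] for i in np.asarray(pwm).argmax(axis=1))


def generate_genome(length: int, gc_fraction: float, seed) -> str:
    """I.i.d. genome with P(G)=P(C)=gc/2 and P(A)=P(T)=(1-gc)/2."""
    if length <= 0:
        raise ValueError("length must be positive")
    rng = np.random.default_rng(seed)
    p_gc = gc_fraction / 2.0
    p_at = (1.0 - gc_fraction) / 2.0
    codes = rng.choice(4, size=length, p=[p_at, p_gc, p_gc, p_at])
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    return lut[codes].tobytes().decode("ascii")


def plant_sites(
    genome: str,
    pwm: np.ndarray,
    n_sites: int,
    min_spacing: int,
    seed,
    max_tries_per_site: int = 10_000,
) -> Tuple[str, List[SiteAnnotation]]:
    """Replace spaced genome substrings with PWM-sampled motif instances.

    Starts are drawn without replacement with every pairwise start distance
    >= min_spacing + motif length; strand is uniform and minus-strand
    instances are written reverse-complemented.
    """
    rng = np.random.default_rng(seed)
    pwm = np.asarray(pwm, dtype=float)
    L = pwm.shape[0]
    G = len(genome)
    if n_sites == 0:
        return genome, []
    gap = min_spacing + L
    cell = (G - L) // n_sites
    if cell >= gap:
        # jittered grid: one site per cell keeps sites well separated, so
        # their read footprints assemble into distinct ChIPtigs (clustered
        # sites would fuse into one long contig and defeat ground truth)
        jmax = min(cell - gap, max(1, cell // 5))
        jitter = rng.integers(0, jmax + 1, size=n_sites)
        starts = [int(i * cell + jitter[i]) for i in range(n_sites)]
    else:
        starts = []
        tries = 0
        while len(starts) < n_sites:
            tries += 1
            if tries > max_tries_per_site * n_sites:
                raise RuntimeError("could not place sites; relax spacing or count")
            s = int(rng.integers(0, G - L + 1))
            if all(abs(s - t) >= gap for t in starts):
                starts.append(s)
        starts.sort()
    g = list(genome)
    sites = []
    for s in starts:
        inst = "".join(BASES[rng.choice(4, p=pwm[i])] for i in range(L))
        strand = "+" if rng.random() < 0.5 else "-"
        written = inst if strand == "+" else revcomp(inst)
        g[s : s + L] = written
        sites.append(SiteAnnotation(start=s, strand=strand, instance=inst))
    return "".join(g), sites


def _truncated_normal(rng, mean, sd, lo, hi, size):
    out = rng.normal(mean, sd, size=size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, size=int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return np.rint(out).astype(np.int64)


def _apply_errors(codes: np.ndarray, rng, error_rate: float) -> np.ndarray:
    if error_rate <= 0:
        return codes
    flip = rng.random(codes.shape) < error_rate
    if not flip.any():
        return codes
    shift = rng.integers(1, 4, size=int(flip.sum()))
    codes = codes.copy()
    codes[flip] = (codes[flip] + shift) % 4
    return codes


def simulate_experiment(config: SimulationConfig) -> SimulationResult:
    """Generate case/control reads plus ground truth, deterministic in seed."""
    root = np.random.SeedSequence(config.seed)
    rng_genome, rng_sites, rng_case, rng_ctrl = (
        np.random.default_rng(s) for s in root.spawn(4)
    )
    genome0 = generate_genome(config.genome_length, config.gc_fraction, rng_genome)
    genome, sites = plant_sites(
        genome0, config.pwm, config.n_sites, config.min_site_spacing, rng_sites
    )
    lut = np.frombuffer(b"ACGT", dtype=np.uint8)
    gcodes = np.frombuffer(genome.encode("ascii"), dtype=np.uint8)
    gcodes = np.searchsorted(lut, gcodes)  # A,C,G,T ascii are sorted
    G = config.genome_length
    RL = config.read_length
    L = config.pwm.shape[0]
    centers = np.array([s.start + L // 2 for s in sites], dtype=np.int64)

    def draw_reads(rng, n, source, site_prob):
        frag_len = _truncated_normal(
            rng, config.fragment_length_mean, config.fragment_length_sd,
            RL, 3 * config.fragment_length_mean, n,
        )
        frag_len = np.minimum(frag_len, G)
        from_site = rng.random(n) < site_prob
        fs = np.empty(n, dtype=np.int64)
        n_bg = int((~from_site).sum())
        fs[~from_site] = rng.integers(0, G - frag_len[~from_site] + 1, size=n_bg)
        if from_site.any() and len(centers):
            which = rng.integers(0, len(centers), size=int(from_site.sum()))
            c = centers[which]
            off = rng.integers(0, frag_len[from_site], size=int(from_site.sum()))
            s = c - off  # fragment covers the site center
            s = np.clip(s, 0, G - frag_len[from_site])
            fs[from_site] = s
        fe = fs + frag_len
        fwd = rng.random(n) < 0.5
        starts = np.where(fwd, fs, fe - RL)
        mat = gcodes[starts[:, None] + np.arange(RL)]
        rev = ~fwd
        mat[rev] = 3 - mat[rev][:, ::-1]
        mat = _apply_errors(mat, rng, config.error_rate)
        blob = lut[mat].tobytes().decode("ascii")
        return [
            Read(id=f"{source}_{i}", sequence=blob[i * RL : (i + 1) * RL],
                 source=source)
            for i in range(n)
        ]

    w = (
        config.enrichment_fold
        * config.n_sites
        * config.fragment_length_mean
        / config.genome_length
    )
    p_site = w / (1.0 + w) if config.n_sites else 0.0
    case = draw_reads(rng_case, config.n_case_reads, "case", p_site)
    ctrl = draw_reads(rng_ctrl, config.n_control_reads, "control", 0.0)
    return SimulationResult(genome=genome, sites=sites, case_reads=case,
                            control_reads=ctrl, config=config)


def write_experiment(result: SimulationResult, outdir) -> dict:
    """Write FASTQ (case/control), FASTA genome, and a BED-like site TSV."""
    os.makedirs(outdir, exist_ok=True)
    paths = {
        "case": os.path.join(outdir, "case.fastq"),
        "control": os.path.join(outdir, "control.fastq"),
        "genome": os.path.join(outdir, "genome.fasta"),
        "sites": os.path.join(outdir, "sites.tsv"),
    }
    for key, reads in (("case", result.case_reads), ("control", result.control_reads)):
        with open(paths[key], "wt") as fh:
            for r in reads:
                if r.quality is not None:
                    qual = "".join(chr(q + 33) for q in r.quality)
                else:
                    qual = "I" * len(r.sequence)
                fh.write(f"@{r.id}\n{r.sequence}\n+\n{qual}\n")
    with open(paths["genome"], "wt") as fh:
        fh.write(">genome\n")
        for i in range(0, len(result.genome), 80):
            fh.write(result.genome[i : i + 80] + "\n")
    with open(paths["sites"], "wt") as fh:
        fh.write("chrom\tstart\tend\tstrand\n")
        for s in result.sites:
            fh.write(f"genome\t{s.start}\t{s.end}\t{s.strand}\n")
    return paths


def locate_in_genome(seq: str, genome: str, max_mismatches: int = 2):
    """Best ungapped placement of seq (or its revcomp) in the genome.

    Seed-and-extend with exact 16-mer seeds; returns (start, end, strand,
    mismatches) or None. Used to judge whether an assembled ChIPtig overlaps
    a planted site.
    """
    if len(seq) > len(genome):
        return None
    slen = min(16, len(seq))
    best = None
    for strand, s in (("+", seq), ("-", revcomp(seq))):
        offsets = {0, max(0, (len(s) - slen) // 2), len(s) - slen}
        tried = set()
        for off in offsets:
            seed = s[off : off + slen]
            start = genome.find(seed)
            while start != -1:
                place = start - off
                if (place, strand) not in tried and 0 <= place <= len(genome) - len(s):
                    tried.add((place, strand))
                    window = genome[place : place + len(s)]
                    mm = sum(a != b for a, b in zip(window, s))
                    if mm <= max_mismatches and (best is None or mm < best[3]):
                        best = (place, place + len(s), strand, mm)
                        if mm == 0:
                            return best
                start = genome.find(seed, start + 1)
    return best


def overlaps_any_site(
    seq: str, genome: str, sites: Sequence[SiteAnnotation], max_mismatches: int = 2
) -> bool:
    """Does this sequence map to the genome overlapping a planted site?"""
    hit = locate_in_genome(seq, genome, max_mismatches)
    if hit is None:
        return False
    start, end, _, _ = hit
    return any(s.start < end and start < s.end for s in sites)
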