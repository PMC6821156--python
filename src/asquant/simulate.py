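"""Synthetic splicing dataset generator with known ground truth.

Generates a self-contained dataset — genome FASTA, GTF annotation with
multi-isoform genes exhibiting all four event types, and two-condition
per-base coverage (bedGraph, optional BAM) — in which every event's
inclusion level (PSI) is known. Each gene carries exactly one event between
constitutive flanking exons:

* SE: inclusion transcript [E1, A, E3, E4], exclusion [E1, E3, E4];
* MXE: [E1, A, E3, E4] vs [E1, B, E3, E4] with A, B between E1 and E3;
* A5SS/A3SS: the middle exon is extended at its donor or acceptor boundary
  in one isoform (patterns chosen strand-aware so the requested type is
  produced on either strand).

Coverage model: constitutive exonic positions have mean ``depth``; the
affected region has mean ``psi * depth`` (the MXE partner exon
``(1 - psi) * depth``); introns are zero apart from an optional Poisson
noise floor. Under the default ``per_base`` model every base is an
independent Poisson draw, so the *mean* coverage of a long exon is nearly
noise-free. The ``per_region`` model instead draws one Poisson value per
region (transcript-level sampling), making the tabulated mean coverages
genuine Poisson counts — the sampling model under which the 2x2 chi-squared
comparison is calibrated.

Each event's acceptor window (-35..+5) is overwritten with draws from a
planted position-probability motif (default: AG at -2/-1, a polypyrimidine
tract over -20..-3, G-rich exon start), and 5'-UTR cassette events carry a
planted uORF inside the alternative exon. Everything is deterministic under
the seed: identical configs give byte-identical output files.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .gene_models import ASEvent, GenomicInterval, Transcript, make_event
from .quantify import CoverageTrack, write_bedgraph
from .seqcontext import ContextWindow, reverse_complement

CHROM = "chrS"
_GTF_SOURCE = "asquant_sim"
REGIONS = ("CDS", "5UTR", "3UTR")
PLANTED_UORF = "ATGGCCGCCTAA"  # 4 codons incl. start and stop
_UORF_EXON_OFFSET = 10  # transcript-sense offset of the uORF within the alt exon

TRUTH_COLUMNS = [
    "event_id",
    "etype",
    "gene_id",
    "chrom",
    "strand",
    "region",
    "psi_a",
    "psi_b",
    "depth",
    "expected_n_a",
    "expected_N_a",
    "expected_n_b",
    "expected_N_b",
    "expected_ratio_a",
    "expected_ratio_b",
    "alt_len",
    "uorf_offset",
    "uorf_len",
]


def default_acceptor_motif(window: ContextWindow | None = None) -> np.ndarray:
    """Planted per-position probabilities over A,C,G,T for the -35..+5 window.

    Uniform background at -35..-21, a strong polypyrimidine tract (C/T 0.85)
    over -20..-3, the invariant AG at -2/-1, and a G-biased exon start.
    """
    window = window or ContextWindow()
    probs = np.full((window.total, 4), 0.25)
    for idx, pos in enumerate(window.positions):
        if -20 <= pos <= -3:
            probs[idx] = (0.075, 0.425, 0.075, 0.425)  # A C G T
        elif pos == -2:
            probs[idx] = (1.0, 0.0, 0.0, 0.0)
        elif pos == -1:
            probs[idx] = (0.0, 0.0, 1.0, 0.0)
        elif pos >= 1:
            probs[idx] = (0.05, 0.05, 0.85, 0.05)
    return probs


@dataclass
class SimConfig:
    """Study conditions for the synthetic dataset.

    ``psi_a``/``psi_b`` are scalars or per-event sequences of inclusion
    levels; the defaults (0.5 vs 0.2) represent a mid-range inclusion shift
    of DeltaPSI = 0.3, giving inclusion ratios psi/(1+psi) of 1/3 vs 1/5.
    ``region_probs`` places each event in CDS / 5'-UTR / 3'-UTR with the
    frequencies seen in differential-splicing surveys (70/24/6%).
    """

    seed: int = 0
    n_se: int = 5
    n_mxe: int = 5
    n_a5ss: int = 5
    n_a3ss: int = 5
    exon_len: tuple[int, int] = (150, 250)
    intron_len: tuple[int, int] = (80, 150)
    ext_len: tuple[int, int] = (40, 80)  # A5SS/A3SS extension length
    depth: float = 50.0
    psi_a: float | Sequence[float] = 0.5
    psi_b: float | Sequence[float] = 0.2
    coverage_model: str = "per_base"  # or "per_region"
    intron_noise: float = 0.0  # Poisson rate on intronic/intergenic bases
    region_probs: tuple[float, float, float] = (0.70, 0.24, 0.06)  # CDS,5UTR,3UTR
    fixed_region: str | None = None  # force every event into one region
    plant_uorf: bool = True  # plant a uORF in 5'-UTR cassette exons
    planted_motif: np.ndarray | None = None  # (40, 4) probs; None = default
    spacing: int = 300
    make_bam: bool = False

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.coverage_model not in ("per_base", "per_region"):
            raise ValueError(f"unknown coverage_model {self.coverage_model!r}")
        if self.fixed_region is not None and self.fixed_region not in REGIONS:
            raise ValueError(f"fixed_region must be one of {REGIONS}")
        for psi in np.atleast_1d(np.asarray(self.psi_a, dtype=float)):
            if not 0 <= psi <= 1:
                raise ValueError(f"psi_a out of [0,1]: {psi}")
        for psi in np.atleast_1d(np.asarray(self.psi_b, dtype=float)):
            if not 0 <= psi <= 1:
                raise ValueError(f"psi_b out of [0,1]: {psi}")

    @property
    def n_events(self) -> int:
        return self.n_se + self.n_mxe + self.n_a5ss + self.n_a3ss


@dataclass
class _GenePlan:
    gene_id: str
    etype: str
    strand: str
    region: str
    psi_a: float
    psi_b: float
    inc_exons: list[tuple[int, int]]
    exc_exons: list[tuple[int, int]]
    affected: list[tuple[int, int]]  # genomically ordered
    cds: tuple[int, int]
    flank_up: tuple[int, int]
    flank_down: tuple[int, int]
    uorf_genomic: tuple[int, int] | None = None
    uorf_offset: int = -1  # offset within the included 5'-UTR, -1 if none


@dataclass
class SimResult:
    config: SimConfig
    outdir: str
    genome_fasta: str
    annotation_gtf: str
    coverage_a: str
    coverage_b: str
    truth_tsv: str
    bam_a: str | None
    bam_b: str | None
    events: list[ASEvent]
    transcripts: dict[str, Transcript]
    truth: pd.DataFrame


def _per_event(value, n: int) -> list[float]:
    arr = np.atleast_1d(np.asarray(value, dtype=float))
    if arr.size == 1:
        return [float(arr[0])] * n
    if arr.size != n:
        raise ValueError(f"need 1 or {n} psi values, got {arr.size}")
    return [float(v) for v in arr]


def _plan_genes(config: SimConfig, rng: np.random.Generator) -> tuple[list[_GenePlan], int]:
    """Lay out one gene per event along the chromosome."""
    etypes = (
        ["SE"] * config.n_se
        + ["MXE"] * config.n_mxe
        + ["A5SS"] * config.n_a5ss
        + ["A3SS"] * config.n_a3ss
    )
    psis_a = _per_event(config.psi_a, len(etypes))
    psis_b = _per_event(config.psi_b, len(etypes))
    plans: list[_GenePlan] = []
    cursor = 100
    exlo, exhi = config.exon_len
    inlo, inhi = config.intron_len
    extlo, exthi = config.ext_len

    def elen() -> int:
        return int(rng.integers(exlo, exhi + 1))

    def ilen() -> int:
        return int(rng.integers(max(inlo, 40), inhi + 1))

    for gi, etype in enumerate(etypes):
        strand = "+" if gi % 2 == 0 else "-"
        if config.fixed_region is not None:
            region = config.fixed_region
        else:
            region = str(rng.choice(REGIONS, p=config.region_probs))
        e1 = (cursor, cursor + elen())
        pos = e1[1] + ilen()
        affected: list[tuple[int, int]]
        if etype == "SE":
            a = (pos, pos + elen())
            pos = a[1] + ilen()
            e3 = (pos, pos + elen())
            pos = e3[1] + ilen()
            e4 = (pos, pos + elen())
            inc = [e1, a, e3, e4]
            exc = [e1, e3, e4]
            affected = [a]
            flank_up, flank_down = e1, e3
        elif etype == "MXE":
            a = (pos, pos + elen())
            pos = a[1] + ilen()
            b = (pos, pos + elen())
            pos = b[1] + ilen()
            e3 = (pos, pos + elen())
            pos = e3[1] + ilen()
            e4 = (pos, pos + elen())
            inc = [e1, a, e3, e4]
            exc = [e1, b, e3, e4]
            affected = [a, b]
            flank_up, flank_down = e1, e3
        else:
            # extension pattern chosen so the requested type holds on `strand`
            ext = int(rng.integers(extlo, exthi + 1))
            pattern_r = (etype == "A5SS") == (strand == "+")
            x = (pos, pos + elen())
            if pattern_r:
                # long form extends the exon end
                long_x = (x[0], x[1] + ext)
                short_x = x
                affected = [(x[1], x[1] + ext)]
                pos = long_x[1] + ilen()
            else:
                # long form extends the exon start: shift the short exon right
                short_x = (x[0] + ext, x[1] + ext)
                long_x = (x[0], x[1] + ext)
                affected = [(x[0], x[0] + ext)]
                pos = long_x[1] + ilen()
            e3 = (pos, pos + elen())
            pos = e3[1] + ilen()
            e4 = (pos, pos + elen())
            inc = [e1, long_x, e3, e4]
            exc = [e1, short_x, e3, e4]
            if pattern_r:
                flank_up, flank_down = short_x, e3
            else:
                flank_up, flank_down = e1, short_x
        last = inc[-1]
        if region == "CDS":
            cds = (e1[0] + 20, last[1] - 20)
        elif (region == "5UTR") == (strand == "+"):
            cds = (last[0] + 20, last[1] - 20)  # CDS in the genomically last exon
        else:
            cds = (e1[0] + 20, e1[1] - 20)
        uorf_genomic = None
        uorf_offset = -1
        if config.plant_uorf and region == "5UTR" and etype == "SE":
            a0, a1 = affected[0]
            if strand == "+":
                uorf_genomic = (a0 + _UORF_EXON_OFFSET, a0 + _UORF_EXON_OFFSET + len(PLANTED_UORF))
                upstream = e1[1] - e1[0]  # whole E1 is UTR (CDS sits in E4)
            else:
                uorf_genomic = (a1 - _UORF_EXON_OFFSET - len(PLANTED_UORF), a1 - _UORF_EXON_OFFSET)
                e3_, e4_ = inc[2], inc[3]
                upstream = (e4_[1] - e4_[0]) + (e3_[1] - e3_[0])
            uorf_offset = upstream + _UORF_EXON_OFFSET
        plans.append(
            _GenePlan(
                gene_id=f"g{gi:05d}",
                etype=etype,
                strand=strand,
                region=region,
                psi_a=psis_a[gi],
                psi_b=psis_b[gi],
                inc_exons=inc,
                exc_exons=exc,
                affected=affected,
                cds=cds,
                flank_up=flank_up,
                flank_down=flank_down,
                uorf_genomic=uorf_genomic,
                uorf_offset=uorf_offset,
            )
        )
        cursor = inc[-1][1] + config.spacing
    return plans, cursor + 100


def _plan_to_models(plan: _GenePlan) -> tuple[ASEvent, Transcript, Transcript]:
    def tx(tid: str, exons: list[tuple[int, int]]) -> Transcript:
        return Transcript(
            id=tid,
            gene_id=plan.gene_id,
            exons=[GenomicInterval(CHROM, s, e, plan.strand) for s, e in exons],
            cds_start=plan.cds[0],
            cds_end=plan.cds[1],
        )

    t_inc = tx(f"{plan.gene_id}.t1", plan.inc_exons)
    t_exc = tx(f"{plan.gene_id}.t2", plan.exc_exons)
    event = make_event(
        plan.etype,
        plan.gene_id,
        [GenomicInterval(CHROM, s, e, plan.strand) for s, e in plan.affected],
        GenomicInterval(CHROM, *plan.flank_up, plan.strand),
        GenomicInterval(CHROM, *plan.flank_down, plan.strand),
        t_inc.id,
        t_exc.id,
    )
    return event, t_inc, t_exc


def _build_genome(
    plans: list[_GenePlan],
    events: list[ASEvent],
    length: int,
    config: SimConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    bases = np.frombuffer(b"ACGT", dtype="S1")
    genome = bases[rng.integers(0, 4, size=length)].copy()
    window = ContextWindow()
    motif = config.planted_motif if config.planted_motif is not None else default_acceptor_motif(window)
    if motif.shape != (window.total, 4):
        raise ValueError(f"planted_motif must have shape {(window.total, 4)}")
    for ev in events:
        draw = np.array([rng.choice(4, p=row) for row in motif])
        seq = bases[draw]
        pos = ev.acceptor_pos
        if ev.strand == "+":
            genome[pos - window.intronic : pos + window.downstream_exonic] = seq
        else:
            rc = np.frombuffer(
                reverse_complement(seq.tobytes().decode()).encode(), dtype="S1"
            )
            genome[pos - window.downstream_exonic : pos + window.intronic] = rc.copy()
    for plan in plans:
        if plan.uorf_genomic is None:
            continue
        s, e = plan.uorf_genomic
        insert = PLANTED_UORF if plan.strand == "+" else reverse_complement(PLANTED_UORF)
        genome[s:e] = np.frombuffer(insert.encode(), dtype="S1")
    return genome


def _sample_coverage(
    plans: list[_GenePlan],
    length: int,
    config: SimConfig,
    psis: list[float],
    rng: np.random.Generator,
    label: str,
) -> CoverageTrack:
    depth = config.depth
    cov = np.zeros(length, dtype=np.int64)
    if config.intron_noise > 0:
        cov[:] = rng.poisson(config.intron_noise, size=length)
    for plan, psi in zip(plans, psis):
        union: set[tuple[int, int]] = set(map(tuple, plan.inc_exons)) | set(
            map(tuple, plan.exc_exons)
        )
        aff = plan.affected[0]
        partner = plan.affected[1] if plan.etype == "MXE" else None
        const: list[tuple[int, int]] = []
        for s, e in sorted(union):
            pieces = [(s, e)]
            for rs, re_ in plan.affected:
                nxt = []
                for ps, pe in pieces:
                    if re_ <= ps or rs >= pe:
                        nxt.append((ps, pe))
                        continue
                    if ps < rs:
                        nxt.append((ps, rs))
                    if re_ < pe:
                        nxt.append((re_, pe))
                pieces = nxt
            const.extend(pieces)
        if config.coverage_model == "per_base":
            for s, e in const:
                cov[s:e] = rng.poisson(depth, size=e - s)
            cov[aff[0] : aff[1]] = rng.poisson(psi * depth, size=aff[1] - aff[0])
            if partner is not None:
                cov[partner[0] : partner[1]] = rng.poisson(
                    (1 - psi) * depth, size=partner[1] - partner[0]
                )
        else:  # per_region: one Poisson draw per region
            v = int(rng.poisson(depth))
            for s, e in const:
                cov[s:e] = v
            cov[aff[0] : aff[1]] = int(rng.poisson(psi * depth))
            if partner is not None:
                cov[partner[0] : partner[1]] = int(rng.poisson((1 - psi) * depth))
    return CoverageTrack(depths={CHROM: cov}, library_label=label)


def _write_fasta(genome: np.ndarray, path: str, width: int = 60) -> None:
    seq = genome.tobytes().decode()
    with open(path, "w") as fh:
        fh.write(f">{CHROM}\n")
        for i in range(0, len(seq), width):
            fh.write(seq[i : i + width] + "\n")


def _gtf_attrs(gene_id: str, tx_id: str | None = None) -> str:
    if tx_id is None:
        return f'gene_id "{gene_id}";'
    return f'gene_id "{gene_id}"; transcript_id "{tx_id}";'


def write_gtf(transcripts: Sequence[Transcript], path: str) -> None:
    """Write transcripts as GTF (gene/transcript/exon/CDS lines, 1-based)."""
    by_gene: dict[str, list[Transcript]] = {}
    for tx in transcripts:
        by_gene.setdefault(tx.gene_id, []).append(tx)
    with open(path, "w") as fh:
        for gene_id in sorted(by_gene):
            txs = sorted(by_gene[gene_id], key=lambda t: t.id)
            g_lo = min(t.exons[0].start for t in txs)
            g_hi = max(t.exons[-1].end for t in txs)
            strand = txs[0].strand
            chrom = txs[0].chrom
            fh.write(
                f"{chrom}\t{_GTF_SOURCE}\tgene\t{g_lo + 1}\t{g_hi}\t.\t{strand}\t.\t"
                f"{_gtf_attrs(gene_id)}\n"
            )
            for tx in txs:
                fh.write(
                    f"{chrom}\t{_GTF_SOURCE}\ttranscript\t{tx.exons[0].start + 1}\t"
                    f"{tx.exons[-1].end}\t.\t{strand}\t.\t{_gtf_attrs(gene_id, tx.id)}\n"
                )
                for exon in tx.exons:
                    fh.write(
                        f"{chrom}\t{_GTF_SOURCE}\texon\t{exon.start + 1}\t{exon.end}"
                        f"\t.\t{strand}\t.\t{_gtf_attrs(gene_id, tx.id)}\n"
                    )
                    if tx.cds_start is not None:
                        lo = max(exon.start, tx.cds_start)
                        hi = min(exon.end, tx.cds_end)
                        if lo < hi:
                            fh.write(
                                f"{chrom}\t{_GTF_SOURCE}\tCDS\t{lo + 1}\t{hi}\t.\t"
                                f"{strand}\t0\t{_gtf_attrs(gene_id, tx.id)}\n"
                            )


def write_truth(truth: pd.DataFrame, path: str) -> None:
    """Write the ground-truth table (lossless round trip with read_truth)."""
    truth[TRUTH_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_truth(path: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: truth table lacks columns {sorted(missing)}")
    return df


def track_to_bam(track: CoverageTrack, path: str) -> None:
    """Emit a sorted, indexed BAM whose per-base depth equals the track.

    The integer coverage profile is peeled layer by layer: each maximal
    positive run in a layer becomes one fully-aligned read. Reads carry N
    base qualities only; this is a coverage carrier, not an error model.
    """
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [
            {"SN": chrom, "LN": len(arr)} for chrom, arr in sorted(track.depths.items())
        ],
    }
    tids = {chrom: i for i, chrom in enumerate(sorted(track.depths))}
    tmp = path + ".unsorted.bam"
    with pysam.AlignmentFile(tmp, "wb", header=header) as bam:
        rid = 0
        for chrom in sorted(track.depths):
            arr = track.depths[chrom].astype(np.int64).copy()
            while (arr > 0).any():
                pos = np.flatnonzero(arr > 0)
                breaks = np.flatnonzero(np.diff(pos) > 1) + 1
                for run in np.split(pos, breaks):
                    s, e = int(run[0]), int(run[-1]) + 1
                    read = pysam.AlignedSegment()
                    read.query_name = f"r{rid}"
                    read.reference_id = tids[chrom]
                    read.reference_start = s
                    read.mapping_quality = 60
                    read.cigartuples = [(0, e - s)]
                    read.query_sequence = "N" * (e - s)
                    bam.write(read)
                    rid += 1
                arr[arr > 0] -= 1
    pysam.sort("-o", path, tmp)
    os.remove(tmp)
    pysam.index(path)


def simulate_dataset(config: SimConfig, outdir: str) -> SimResult:
    """Generate the full dataset under ``outdir`` and return its handles."""
    rng = np.random.default_rng(config.seed)
    os.makedirs(outdir, exist_ok=True)
    plans, length = _plan_genes(config, rng)
    events: list[ASEvent] = []
    transcripts: dict[str, Transcript] = {}
    for plan in plans:
        ev, t_inc, t_exc = _plan_to_models(plan)
        events.append(ev)
        transcripts[t_inc.id] = t_inc
        transcripts[t_exc.id] = t_exc
    genome = _build_genome(plans, events, length, config, rng)
    psis_a = [p.psi_a for p in plans]
    psis_b = [p.psi_b for p in plans]
    track_a = _sample_coverage(plans, length, config, psis_a, rng, "a")
    track_b = _sample_coverage(plans, length, config, psis_b, rng, "b")

    rows = []
    for plan, ev in zip(plans, events):
        d = config.depth
        rows.append(
            {
                "event_id": ev.event_id,
                "etype": ev.etype,
                "gene_id": plan.gene_id,
                "chrom": CHROM,
                "strand": plan.strand,
                "region": plan.region,
                "psi_a": plan.psi_a,
                "psi_b": plan.psi_b,
                "depth": d,
                "expected_n_a": plan.psi_a * d,
                "expected_N_a": d,
                "expected_n_b": plan.psi_b * d,
                "expected_N_b": d,
                "expected_ratio_a": plan.psi_a / (1 + plan.psi_a)
                if plan.psi_a > 0 or d > 0
                else float("nan"),
                "expected_ratio_b": plan.psi_b / (1 + plan.psi_b),
                "alt_len": sum(e - s for s, e in plan.affected[:1]),
                "uorf_offset": plan.uorf_offset,
                "uorf_len": len(PLANTED_UORF) if plan.uorf_offset >= 0 else -1,
            }
        )
    truth = pd.DataFrame(rows, columns=TRUTH_COLUMNS)

    genome_fa = os.path.join(outdir, "genome.fa")
    gtf = os.path.join(outdir, "annotation.gtf")
    cov_a = os.path.join(outdir, "cov_a.bedgraph")
    cov_b = os.path.join(outdir, "cov_b.bedgraph")
    truth_tsv = os.path.join(outdir, "truth.tsv")
    _write_fasta(genome, genome_fa)
    write_gtf(sorted(transcripts.values(), key=lambda t: t.id), gtf)
    write_bedgraph(track_a, cov_a)
    write_bedgraph(track_b, cov_b)
    write_truth(truth, truth_tsv)
    bam_a = bam_b = None
    if config.make_bam:
        bam_a = os.path.join(outdir, "reads_a.bam")
        bam_b = os.path.join(outdir, "reads_b.bam")
        track_to_bam(track_a, bam_a)
        track_to_bam(track_b, bam_b)
    return SimResult(
        config=config,
        outdir=outdir,
        genome_fasta=genome_fa,
        annotation_gtf=gtf,
        coverage_a=cov_a,
        coverage_b=cov_b,
        truth_tsv=truth_tsv,
        bam_a=bam_a,
        bam_b=bam_b,
        events=events,
        transcripts=transcripts,
        truth=truth,
    )
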