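"""Coverage-based event quantification and two-condition chi-squared comparison.

For an event in one condition the statistic is a pair of mean per-base read
coverages: ``n`` over the affected exon (the genomically first exon for MXE)
and ``N`` over the remaining exons of the inclusion-form host transcript
(both exclusive exons are excluded from the rest for MXE, keeping n and N
disjoint). The inclusion ratio is ``n / (n + N)``, a proportion in [0, 1].

Two conditions are compared with a canonical 2x2 Pearson chi-squared test
(1 df, no continuity correction) on the table ``[[n_a, N_a], [n_b, N_b]]``
of rounded mean coverages. An event is called significant when the P-value
is at most ``p_max`` (default 0.1) and the absolute ratio difference exceeds
``dratio_min`` (default 0.1) — both filters, jointly.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from scipy import stats

from .gene_models import ASEvent, GenomicInterval, Transcript, classify_event_region

logger = logging.getLogger(__name__)

RATIO_DEFINITIONS = ("bounded", "raw")  # n/(n+N) vs n/N


class BedGraphError(ValueError):
    """Raised for malformed or overlapping bedGraph intervals."""


@dataclass
class CoverageTrack:
    """Dense per-base read depth, one array per chromosome."""

    depths: dict[str, np.ndarray] = field(default_factory=dict)
    library_label: str = ""
    _warned_chroms: set = field(default_factory=set, repr=False)

    def chrom_names(self) -> set[str]:
        return set(self.depths)

    def depth(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Depth over [start, end); positions beyond the track are zero."""
        arr = self.depths.get(chrom)
        if arr is None:
            if chrom not in self._warned_chroms:
                self._warned_chroms.add(chrom)
                logger.warning(
                    "chromosome %r absent from coverage track %r (have: %s)",
                    chrom,
                    self.library_label,
                    sorted(self.depths),
                )
            return np.zeros(end - start, dtype=np.int64)
        out = np.zeros(end - start, dtype=arr.dtype)
        lo, hi = max(start, 0), min(end, len(arr))
        if hi > lo:
            out[lo - start : hi - start] = arr[lo:hi]
        return out

    def mean_depth(self, intervals: Sequence[GenomicInterval]) -> tuple[float, int]:
        """(mean depth, total bases) over a set of disjoint intervals."""
        total = 0.0
        length = 0
        for iv in intervals:
            total += float(self.depth(iv.chrom, iv.start, iv.end).sum())
            length += len(iv)
        return (total / length if length else 0.0), length


def coverage_from_bedgraph(path: str, library_label: str = "") -> CoverageTrack:
    """Read a bedGraph (0-based half-open, non-overlapping) into a track.

    Overlapping intervals raise :class:`BedGraphError` naming the first
    offending line.
    """
    records: list[tuple[str, int, int, float, int]] = []
    sizes: dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise BedGraphError(f"{path}: line {lineno}: expected 4 columns")
            chrom, start, end, value = parts[0], int(parts[1]), int(parts[2]), float(parts[3])
            if not (0 <= start < end):
                raise BedGraphError(f"{path}: line {lineno}: bad interval {start}-{end}")
            if value < 0:
                raise BedGraphError(f"{path}: line {lineno}: negative depth {value}")
            records.append((chrom, start, end, value, lineno))
            sizes[chrom] = max(sizes.get(chrom, 0), end)
    integral = all(float(v).is_integer() for _, _, _, v, _ in records)
    dtype = np.int64 if integral else np.float64
    depths = {c: np.zeros(n, dtype=dtype) for c, n in sizes.items()}
    occupied = {c: np.zeros(n, dtype=bool) for c, n in sizes.items()}
    for chrom, start, end, value, lineno in records:
        if occupied[chrom][start:end].any():
            raise BedGraphError(
                f"{path}: line {lineno}: interval {chrom}:{start}-{end} "
                "overlaps a previous interval"
            )
        occupied[chrom][start:end] = True
        depths[chrom][start:end] = dtype(value)
    return CoverageTrack(depths=depths, library_label=library_label)


def write_bedgraph(track: CoverageTrack, path: str) -> None:
    """Write a track as bedGraph, merging equal-depth runs, omitting zeros."""
    with open(path, "w") as fh:
        for chrom in sorted(track.depths):
            arr = track.depths[chrom]
            if len(arr) == 0:
                continue
            change = np.flatnonzero(np.diff(arr)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [len(arr)]))
            for s, e in zip(starts, ends):
                v = arr[s]
                if v != 0:
                    val = int(v) if float(v).is_integer() else float(v)
                    fh.write(f"{chrom}\t{s}\t{e}\t{val}\n")


def coverage_from_bam(path: str, library_label: str = "") -> CoverageTrack:
    """Per-base depth from a sorted, indexed BAM.

    Each aligned base (CIGAR M/=/X) of each primary, mapped,
    non-duplicate read adds one to the depth; N gaps of split reads
    contribute nothing.
    """
    with pysam.AlignmentFile(path, "rb") as bam:
        if not bam.has_index():
            raise FileNotFoundError(
                f"{path} has no index; run `samtools index {path}` first"
            )
        depths = {
            name: np.zeros(length, dtype=np.int64)
            for name, length in zip(bam.references, bam.lengths)
        }
        for read in bam.fetch():
            if read.is_unmapped or read.is_secondary or read.is_duplicate:
                continue
            arr = depths[read.reference_name]
            for start, end in read.get_blocks():  # M/=/X blocks, N split out
                arr[start:end] += 1
    return CoverageTrack(depths=depths, library_label=library_label)


# ---------------------------------------------------------------------------
# Per-event quantification


@dataclass
class EventQuant:
    """n/N coverages and inclusion ratio for one event in one condition."""

    event_id: str
    n: float  # mean depth over the affected exon
    N: float  # mean depth over the rest of the host transcript's exons
    ratio: float  # n/(n+N) (or n/N under ratio_def="raw"); NaN when undefined
    affected_len: int
    rest_len: int
    library_label: str = ""

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ratio)


def _rest_intervals(event: ASEvent, host: Transcript) -> list[GenomicInterval]:
    """Exon union of the host transcript minus all affected intervals."""
    removed = sorted(iv.coords for iv in event.affected)
    rest: list[GenomicInterval] = []
    for exon in host.exons:
        pieces = [(exon.start, exon.end)]
        for rs, re_ in removed:
            nxt: list[tuple[int, int]] = []
            for ps, pe in pieces:
                if re_ <= ps or rs >= pe:
                    nxt.append((ps, pe))
                    continue
                if ps < rs:
                    nxt.append((ps, rs))
                if re_ < pe:
                    nxt.append((re_, pe))
            pieces = nxt
        rest.extend(
            GenomicInterval(exon.chrom, ps, pe, exon.strand) for ps, pe in pieces
        )
    return rest


def quantify_event(
    event: ASEvent,
    transcripts: Mapping[str, Transcript],
    track: CoverageTrack,
    ratio_def: str = "bounded",
) -> EventQuant | None:
    """Compute n, N and the inclusion ratio for one event on one track.

    Returns ``None`` (with a warning) when the rest-exon set is empty.
    The ratio is NaN when n + N = 0 (no coverage at all).
    """
    if ratio_def not in RATIO_DEFINITIONS:
        raise ValueError(f"ratio_def must be one of {RATIO_DEFINITIONS}")
    host = transcripts.get(event.inclusion_tx)
    if host is None:
        raise KeyError(f"host transcript missing for event {event.event_id}")
    n, affected_len = track.mean_depth([event.affected[0]])
    rest = _rest_intervals(event, host)
    if not rest:
        logger.warning(
            "event %s skipped: no rest exons in host transcript %s",
            event.event_id,
            host.id,
        )
        return None
    N, rest_len = track.mean_depth(rest)
    if ratio_def == "bounded":
        ratio = n / (n + N) if n + N > 0 else math.nan
    else:
        ratio = n / N if N > 0 else math.nan
    return EventQuant(
        event_id=event.event_id,
        n=n,
        N=N,
        ratio=ratio,
        affected_len=affected_len,
        rest_len=rest_len,
        library_label=track.library_label,
    )


# ---------------------------------------------------------------------------
# 2x2 chi-squared comparison


def chi2_2x2(a: float, b: float, c: float, d: float) -> tuple[float, float]:
    """Pearson chi-squared (1 df, no continuity correction) on [[a,b],[c,d]].

    Computed from expected counts under independence of the row/column
    margins. Any zero row or column margin carries no evidence and returns
    (0.0, 1.0).
    """
    if min(a, b, c, d) < 0:
        raise ValueError(f"negative count in table [[{a},{b}],[{c},{d}]]")
    obs = np.array([[a, b], [c, d]], dtype=float)
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    total = obs.sum()
    if rows.min() == 0 or cols.min() == 0:
        return 0.0, 1.0
    expected = np.outer(rows, cols) / total
    chi2 = float(((obs - expected) ** 2 / expected).sum())
    pvalue = float(stats.chi2.sf(chi2, df=1))
    return chi2, pvalue


@dataclass
class ComparisonThresholds:
    """The significance filters: P-value ceiling and minimum |Δratio|."""

    p_max: float = 0.1
    dratio_min: float = 0.1

    def __post_init__(self) -> None:
        if not (0 < self.p_max <= 1):
            raise ValueError(f"p_max must be in (0, 1], got {self.p_max}")
        if not (0 <= self.dratio_min < 1):
            raise ValueError(f"dratio_min must be in [0, 1), got {self.dratio_min}")


@dataclass
class EventComparison:
    event_id: str
    quant_a: EventQuant
    quant_b: EventQuant
    chi2: float
    pvalue: float
    dratio: float  # ratio_a - ratio_b; NaN when either ratio undefined
    significant: bool
    direction: str  # "a_higher" | "b_higher" | "equal" | "undefined"
    low_coverage: bool = False


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def compare_event(
    quant_a: EventQuant,
    quant_b: EventQuant,
    thresholds: ComparisonThresholds | None = None,
) -> EventComparison:
    """Chi-squared comparison of one event's quantifications in two conditions.

    Mean coverages are rounded half-up to integers for the 2x2 tabulation.
    Events with an undefined ratio in either condition are flagged
    ``low_coverage`` and never significant.
    """
    thresholds = thresholds or ComparisonThresholds()
    if quant_a.event_id != quant_b.event_id:
        raise ValueError(
            f"mismatched events: {quant_a.event_id} vs {quant_b.event_id}"
        )
    table = (
        _round_half_up(quant_a.n),
        _round_half_up(quant_a.N),
        _round_half_up(quant_b.n),
        _round_half_up(quant_b.N),
    )
    chi2, pvalue = chi2_2x2(*table)
    both_defined = quant_a.defined and quant_b.defined
    if both_defined:
        dratio = quant_a.ratio - quant_b.ratio
        significant = pvalue <= thresholds.p_max and abs(dratio) > thresholds.dratio_min
        if dratio > 0:
            direction = "a_higher"
        elif dratio < 0:
            direction = "b_higher"
        else:
            direction = "equal"
    else:
        dratio = math.nan
        significant = False
        direction = "undefined"
    return EventComparison(
        event_id=quant_a.event_id,
        quant_a=quant_a,
        quant_b=quant_b,
        chi2=chi2,
        pvalue=pvalue,
        dratio=dratio,
        significant=significant,
        direction=direction,
        low_coverage=not both_defined,
    )


RESULT_COLUMNS = [
    "event_id",
    "etype",
    "gene_id",
    "region",
    "n_a",
    "N_a",
    "ratio_a",
    "n_b",
    "N_b",
    "ratio_b",
    "chi2",
    "pvalue",
    "dratio",
    "significant",
    "direction",
]


def run_comparison(
    events: Sequence[ASEvent],
    transcripts: Mapping[str, Transcript],
    track_a: CoverageTrack,
    track_b: CoverageTrack,
    thresholds: ComparisonThresholds | None = None,
    ratio_def: str = "bounded",
    bh_correction: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Quantify and compare every event; return (results table, summary).

    Rows are ordered by event_id (deterministic). With
    ``bh_correction=True`` a ``padj`` (Benjamini–Hochberg) column is added
    and the P-value filter is applied to it instead of the raw P-value.
    Summary counts significant events per type, per direction, and the
    number of distinct genes with at least one significant event.
    """
    thresholds = thresholds or ComparisonThresholds()
    rows = []
    for event in sorted(events, key=lambda e: e.event_id):
        qa = quantify_event(event, transcripts, track_a, ratio_def)
        qb = quantify_event(event, transcripts, track_b, ratio_def)
        if qa is None or qb is None:
            continue
        comp = compare_event(qa, qb, thresholds)
        rows.append(
            {
                "event_id": event.event_id,
                "etype": event.etype,
                "gene_id": event.gene_id,
                "region": classify_event_region(event, transcripts),
                "n_a": qa.n,
                "N_a": qa.N,
                "ratio_a": qa.ratio,
                "n_b": qb.n,
                "N_b": qb.N,
                "ratio_b": qb.ratio,
                "chi2": comp.chi2,
                "pvalue": comp.pvalue,
                "dratio": comp.dratio,
                "significant": comp.significant,
                "direction": comp.direction,
            }
        )
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if bh_correction and len(df):
        df["padj"] = stats.false_discovery_control(df["pvalue"].to_numpy(), method="bh")
        df["significant"] = (
            (df["padj"] <= thresholds.p_max)
            & (df["dratio"].abs() > thresholds.dratio_min)
            & df["dratio"].notna()
        )
    sig = df[df["significant"]] if len(df) else df
    summary = {
        "n_events": int(len(df)),
        "n_significant": int(len(sig)),
        "per_etype": {t: int((sig["etype"] == t).sum()) for t in ("SE", "MXE", "A5SS", "A3SS")}
        if len(df)
        else {t: 0 for t in ("SE", "MXE", "A5SS", "A3SS")},
        "per_direction": {
            d: int((sig["direction"] == d).sum()) for d in ("a_higher", "b_higher")
        }
        if len(df)
        else {"a_higher": 0, "b_higher": 0},
        "per_region": {
            r: int((sig["region"] == r).sum())
            for r in ("5UTR", "CDS", "3UTR", "noncoding")
        }
        if len(df)
        else {r: 0 for r in ("5UTR", "CDS", "3UTR", "noncoding")},
        "n_genes_significant": int(sig["gene_id"].nunique()) if len(df) else 0,
    }
    return df, summary
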