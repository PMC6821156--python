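"""5'-UTR isoform reconstruction, uORF scanning and UTR summaries.

For events classified in the 5'-UTR, the two UTR isoform sequences are
assembled: the inclusion form splices the host transcript's exonic bases
upstream of the annotated CDS start (strand-aware, transcript orientation),
and the exclusion form removes the affected interval(s) from it — so the
length identity ``len(included) = len(excluded) + alt_exon_len`` holds by
construction even when the two isoforms differ elsewhere.

A uORF is an ATG-initiated open reading frame wholly within the 5'-UTR:
in-frame triplets are scanned from each ATG until a stop codon (TAA/TAG/TGA).
When the stop lies strictly before the CDS start the uORF is *terminated*;
ORFs that read into the main CDS are tallied separately (N-terminal
extensions, ``terminated=False``). Reported terminated uORFs must span at
least ``min_len`` nucleotides (default 9: start codon + one codon + stop).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from pyfaidx import Fasta

from .gene_models import ASEvent, GenomicInterval, Transcript, classify_event_region
from .seqcontext import reverse_complement

logger = logging.getLogger(__name__)

STOP_CODONS = ("TAA", "TAG", "TGA")
DEFAULT_MIN_UORF_LEN = 9


@dataclass
class UTRVariantPair:
    """The two 5'-UTR isoform sequences of one event."""

    event_id: str
    gene_id: str
    seq_included: str
    seq_excluded: str
    alt_exon_len: int
    alt_offset: int  # 0-based offset of the alt region within seq_included

    @property
    def utr_len_included(self) -> int:
        return len(self.seq_included)

    @property
    def utr_len_excluded(self) -> int:
        return len(self.seq_excluded)

    @property
    def alt_fraction(self) -> float:
        return self.alt_exon_len / self.utr_len_included


@dataclass(frozen=True)
class UORF:
    """One upstream open reading frame candidate."""

    start_offset: int  # 0-based offset of the ATG within the 5'-UTR
    length_nt: int  # ATG through stop inclusive (terminated), else scanned span
    terminated: bool  # stop codon found strictly before the CDS start


def utr5_intervals(tx: Transcript) -> list[GenomicInterval]:
    """Genomic exon pieces upstream (transcript sense) of the CDS start."""
    if tx.cds_start is None:
        raise ValueError(f"transcript {tx.id} has no CDS")
    out = []
    for exon in tx.exons:
        if tx.strand == "+":
            lo, hi = exon.start, min(exon.end, tx.cds_start)
        else:
            lo, hi = max(exon.start, tx.cds_end), exon.end
        if lo < hi:
            out.append(GenomicInterval(exon.chrom, lo, hi, exon.strand))
    return out


def utr5_length(tx: Transcript) -> int:
    return sum(len(iv) for iv in utr5_intervals(tx))


def _splice(intervals: Sequence[GenomicInterval], genome: Fasta, strand: str) -> str:
    parts = [str(genome[iv.chrom][iv.start : iv.end]).upper() for iv in intervals]
    seq = "".join(parts)
    return reverse_complement(seq) if strand == "-" else seq


def build_utr_variants(
    event: ASEvent,
    transcripts: Mapping[str, Transcript],
    genome: Fasta | str,
) -> UTRVariantPair:
    """Assemble inclusion/exclusion 5'-UTR sequences for a 5'-UTR event."""
    if isinstance(genome, str):
        genome = Fasta(genome)
    tx = transcripts.get(event.inclusion_tx)
    if tx is None:
        raise KeyError(f"host transcript missing for event {event.event_id}")
    if tx.cds_start is None:
        raise ValueError(f"event {event.event_id}: host {tx.id} has no CDS")
    for iv in event.affected:
        if iv.start < tx.cds_end and iv.end > tx.cds_start:
            raise ValueError(
                f"event {event.event_id}: affected exon overlaps the CDS "
                "(event is CDS-class, misrouted)"
            )
    utr = utr5_intervals(tx)
    # alt pieces actually exonic in the inclusion form (for MXE: only exon a)
    alt: list[GenomicInterval] = []
    for aff in event.affected:
        for iv in utr:
            lo, hi = max(iv.start, aff.start), min(iv.end, aff.end)
            if lo < hi:
                alt.append(GenomicInterval(iv.chrom, lo, hi, iv.strand))
    if not alt:
        raise ValueError(
            f"event {event.event_id}: affected interval not in the 5'-UTR of {tx.id}"
        )
    alt_coords = {iv.coords for iv in alt}
    kept: list[GenomicInterval] = []
    for iv in utr:
        pieces = [(iv.start, iv.end)]
        for a in alt:
            nxt = []
            for ps, pe in pieces:
                if a.end <= ps or a.start >= pe:
                    nxt.append((ps, pe))
                    continue
                if ps < a.start:
                    nxt.append((ps, a.start))
                if a.end < pe:
                    nxt.append((a.end, pe))
            pieces = nxt
        kept.extend(GenomicInterval(iv.chrom, s, e, iv.strand) for s, e in pieces)
    seq_inc = _splice(utr, genome, event.strand)
    seq_exc = _splice(kept, genome, event.strand)
    # transcript-orientation offset of the alt region within the included UTR
    if event.strand == "+":
        upstream = sum(
            min(iv.end, min(a.start for a in alt)) - iv.start
            for iv in utr
            if iv.start < min(a.start for a in alt)
        )
    else:
        upstream = sum(
            iv.end - max(iv.start, max(a.end for a in alt))
            for iv in utr
            if iv.end > max(a.end for a in alt)
        )
    alt_len = sum(len(a) for a in alt)
    return UTRVariantPair(
        event_id=event.event_id,
        gene_id=event.gene_id,
        seq_included=seq_inc,
        seq_excluded=seq_exc,
        alt_exon_len=alt_len,
        alt_offset=upstream,
    )


def find_uorfs(
    utr_seq: str,
    cds_start_offset: int | None = None,
    min_len: int = DEFAULT_MIN_UORF_LEN,
) -> list[UORF]:
    """Scan a 5'-UTR for uORFs.

    Every ATG wholly upstream of ``cds_start_offset`` (default: the sequence
    end, i.e. the sequence *is* the UTR) starts a candidate; in-frame
    triplets are read until the first stop codon. Terminated uORFs (stop
    strictly before the CDS start) are reported when at least ``min_len``
    nucleotides long; candidates whose reading frame reaches the CDS start
    (or the sequence end) without a stop are returned with
    ``terminated=False``. Overlapping uORFs are each counted from their own
    ATG.
    """
    seq = utr_seq.upper()
    cds = len(seq) if cds_start_offset is None else cds_start_offset
    out: list[UORF] = []
    for i in range(0, min(cds, len(seq)) - 2):
        if seq[i : i + 3] != "ATG":
            continue
        if i + 3 > cds:
            continue
        j = i + 3
        uorf = None
        while j + 3 <= len(seq):
            codon = seq[j : j + 3]
            if codon in STOP_CODONS:
                terminated = j + 3 <= cds
                uorf = UORF(start_offset=i, length_nt=j + 3 - i, terminated=terminated)
                break
            j += 3
        if uorf is None:
            # ran off the scanned sequence without a stop
            uorf = UORF(start_offset=i, length_nt=len(seq) - i - (len(seq) - i) % 3,
                        terminated=False)
        if uorf.terminated and uorf.length_nt < min_len:
            continue
        out.append(uorf)
    return out


def terminated_uorfs(uorfs: Iterable[UORF]) -> list[UORF]:
    return [u for u in uorfs if u.terminated]


def is_five_prime_top(seq: str, min_pyrimidines: int = 4) -> bool:
    """5'-TOP signature: a C start followed by >=4 consecutive pyrimidines."""
    seq = seq.upper()
    if len(seq) < 1 + min_pyrimidines or seq[0] != "C":
        return False
    run = 0
    for ch in seq[1:]:
        if ch in "CT":
            run += 1
            if run >= min_pyrimidines:
                return True
        else:
            break
    return run >= min_pyrimidines


def summarize_utr(
    events: Sequence[ASEvent],
    comparison: pd.DataFrame,
    transcripts: Mapping[str, Transcript],
    genome: Fasta | str,
    min_uorf_len: int = DEFAULT_MIN_UORF_LEN,
) -> tuple[dict, pd.DataFrame]:
    """Region distribution, UTR-length and uORF reconfiguration summaries.

    Returns ``(summary, per_event)`` where summary holds:

    * ``region_pct``: percent of significant events in 5UTR/CDS/3UTR
      (noncoding events excluded from the denominator),
    * ``mean_utr5_len_with_events`` / ``..._without_events``: mean 5'-UTR
      length of coding transcripts that do / do not host a catalogued event,
    * ``mean_alt_fraction``: mean alt-exon share of the included 5'-UTR,
    * ``n_genes_5utr`` / ``n_genes_uorf_change``: genes with significant
      5'-UTR events, and the subset whose uORF count or mean length differs
      between the two UTR forms,
    * ``n_five_prime_top``: 5'-UTR events whose included form carries a
      5'-TOP signature.

    ``per_event`` lists, for each significant 5'-UTR event, both UTR lengths,
    uORF counts/mean lengths per form and their deltas.
    """
    if isinstance(genome, str):
        genome = Fasta(genome)
    sig = comparison[comparison["significant"]] if len(comparison) else comparison
    sig_ids = set(sig["event_id"]) if len(sig) else set()
    by_id = {ev.event_id: ev for ev in events}

    region_counts = {"5UTR": 0, "CDS": 0, "3UTR": 0, "noncoding": 0}
    for eid in sig_ids:
        ev = by_id.get(eid)
        if ev is not None:
            region_counts[classify_event_region(ev, transcripts)] += 1
    coding_total = sum(region_counts[r] for r in ("5UTR", "CDS", "3UTR"))
    region_pct = {
        r: (100.0 * region_counts[r] / coding_total if coding_total else 0.0)
        for r in ("5UTR", "CDS", "3UTR")
    }

    hosts = {t for ev in events for t in ev.host_transcripts}
    with_ev, without_ev = [], []
    for tx in transcripts.values():
        if tx.cds_start is None:
            continue
        (with_ev if tx.id in hosts else without_ev).append(utr5_length(tx))
    mean_with = float(pd.Series(with_ev).mean()) if with_ev else math.nan
    mean_without = float(pd.Series(without_ev).mean()) if without_ev else math.nan

    rows = []
    n_top = 0
    for eid in sorted(sig_ids):
        ev = by_id.get(eid)
        if ev is None or classify_event_region(ev, transcripts) != "5UTR":
            continue
        pair = build_utr_variants(ev, transcripts, genome)
        u_inc = terminated_uorfs(find_uorfs(pair.seq_included, min_len=min_uorf_len))
        u_exc = terminated_uorfs(find_uorfs(pair.seq_excluded, min_len=min_uorf_len))
        mean_len_inc = (
            sum(u.length_nt for u in u_inc) / len(u_inc) if u_inc else 0.0
        )
        mean_len_exc = (
            sum(u.length_nt for u in u_exc) / len(u_exc) if u_exc else 0.0
        )
        if is_five_prime_top(pair.seq_included):
            n_top += 1
        rows.append(
            {
                "event_id": eid,
                "gene_id": ev.gene_id,
                "utr_len_included": pair.utr_len_included,
                "utr_len_excluded": pair.utr_len_excluded,
                "alt_exon_len": pair.alt_exon_len,
                "alt_fraction": pair.alt_fraction,
                "n_uorfs_included": len(u_inc),
                "n_uorfs_excluded": len(u_exc),
                "uorf_count_delta": len(u_inc) - len(u_exc),
                "uorf_mean_len_included": mean_len_inc,
                "uorf_mean_len_excluded": mean_len_exc,
                "uorf_mean_len_delta": mean_len_inc - mean_len_exc,
            }
        )
    per_event = pd.DataFrame(
        rows,
        columns=[
            "event_id",
            "gene_id",
            "utr_len_included",
            "utr_len_excluded",
            "alt_exon_len",
            "alt_fraction",
            "n_uorfs_included",
            "n_uorfs_excluded",
            "uorf_count_delta",
            "uorf_mean_len_included",
            "uorf_mean_len_excluded",
            "uorf_mean_len_delta",
        ],
    )
    genes_5utr = set(per_event["gene_id"]) if len(per_event) else set()
    changed = (
        per_event[(per_event["uorf_count_delta"] != 0)
                  | (per_event["uorf_mean_len_delta"] != 0)]
        if len(per_event)
        else per_event
    )
    summary = {
        "region_pct": region_pct,
        "mean_utr5_len_with_events": mean_with,
        "mean_utr5_len_without_events": mean_without,
        "mean_alt_fraction": float(per_event["alt_fraction"].mean())
        if len(per_event)
        else math.nan,
        "n_genes_5utr": len(genes_5utr),
        "n_genes_uorf_change": int(changed["gene_id"].nunique()) if len(per_event) else 0,
        "n_five_prime_top": n_top,
    }
    return summary, per_event


def write_utr_outputs(
    summary: dict,
    per_event: pd.DataFrame,
    pairs: Sequence[UTRVariantPair],
    outdir: str,
    header: str | None = None,
) -> None:
    """Write utr_variants.fasta, uorfs.tsv and utr_summary.tsv."""
    import os

    os.makedirs(outdir, exist_ok=True)
    with open(os.path.join(outdir, "utr_variants.fasta"), "w") as fh:
        for pair in pairs:
            fh.write(f">{pair.event_id}|included\n{pair.seq_included}\n")
            fh.write(f">{pair.event_id}|excluded\n{pair.seq_excluded}\n")
    with open(os.path.join(outdir, "uorfs.tsv"), "w") as fh:
        if header:
            fh.write(header if header.startswith("#") else "#" + header)
            if not header.endswith("\n"):
                fh.write("\n")
        per_event.to_csv(fh, sep="\t", index=False, float_format="%.6g")
    with open(os.path.join(outdir, "utr_summary.tsv"), "w") as fh:
        if header:
            fh.write(header if header.startswith("#") else "#" + header)
            if not header.endswith("\n"):
                fh.write("\n")
        fh.write("key\tvalue\n")
        for r, v in summary["region_pct"].items():
            fh.write(f"region_pct_{r}\t{v:.6g}\n")
        for key in (
            "mean_utr5_len_with_events",
            "mean_utr5_len_without_events",
            "mean_alt_fraction",
            "n_genes_5utr",
            "n_genes_uorf_change",
            "n_five_prime_top",
        ):
            fh.write(f"{key}\t{summary[key]:.6g}\n")
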