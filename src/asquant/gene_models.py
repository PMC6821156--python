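"""Gene/transcript models and annotation-based splicing-event enumeration.

Transcript structures are read from GTF and compared pairwise within each
gene to enumerate the four classical alternative-splicing event categories:

* **SE** (skipped / cassette exon): an internal exon of one isoform is absent
  from another while both flanking splice junctions match.
* **MXE** (mutually exclusive exons): two isoforms carry different single
  exons between identical flanking junctions, and neither exon occurs in the
  other isoform.
* **A5SS / A3SS**: two isoforms share one boundary of an exon but differ at
  the donor (5') or acceptor (3') boundary, next to a shared junction.

All internal coordinates are 0-based half-open; GTF's 1-based closed
coordinates are converted at the I/O boundary. For A5SS/A3SS the ``affected``
interval is the differential extension (the exonic stretch present only in
the long form) and the short-form exon serves as the adjacent flank, so for
every event type the affected interval(s) lie strictly between
``flank_up.end`` and ``flank_down.start``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from gffutils.feature import feature_from_line

logger = logging.getLogger(__name__)

EVENT_TYPES = ("SE", "MXE", "A5SS", "A3SS")
REGION_LABELS = ("5UTR", "CDS", "3UTR", "noncoding")


class GTFParseError(ValueError):
    """Raised when a GTF line cannot be parsed or violates the model."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A 0-based half-open genomic interval on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    @property
    def coords(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class Transcript:
    """One transcript: ordered exons plus optional genomic CDS bounds."""

    id: str
    gene_id: str
    exons: list[GenomicInterval]
    cds_start: int | None = None  # genomic (leftmost), 0-based
    cds_end: int | None = None  # genomic (rightmost), exclusive

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.id} has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) > 1 or len(strands) > 1:
            raise GTFParseError(
                f"transcript {self.id} has exons on mixed chromosomes/strands: "
                f"chroms={sorted(chroms)} strands={sorted(strands)}"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"transcript {self.id}: overlapping exons "
                    f"{a.coords} and {b.coords}"
                )
        if (self.cds_start is None) != (self.cds_end is None):
            raise ValueError(f"transcript {self.id}: partial CDS bounds")
        if self.cds_start is not None:
            lo, hi = self.exons[0].start, self.exons[-1].end
            if not (lo <= self.cds_start < self.cds_end <= hi):
                raise ValueError(
                    f"transcript {self.id}: CDS {self.cds_start}-{self.cds_end} "
                    f"outside exonic span {lo}-{hi}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def exon_coords(self) -> set[tuple[int, int]]:
        return {e.coords for e in self.exons}


@dataclass(frozen=True)
class ASEvent:
    """One catalogued alternative-splicing event.

    ``affected`` holds one interval (SE: the cassette exon; A5SS/A3SS: the
    differential extension) or two (MXE: both exclusive exons, genomically
    ordered). ``inclusion_tx`` is the transcript carrying ``affected[0]``.
    """

    event_id: str
    etype: str
    gene_id: str
    strand: str
    affected: tuple[GenomicInterval, ...]
    flank_up: GenomicInterval
    flank_down: GenomicInterval
    inclusion_tx: str
    exclusion_tx: str

    def __post_init__(self) -> None:
        if self.etype not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.etype!r}")
        for iv in self.affected:
            if not (self.flank_up.end <= iv.start and iv.end <= self.flank_down.start):
                raise ValueError(
                    f"{self.event_id}: affected {iv.coords} not between flanks"
                )

    @property
    def chrom(self) -> str:
        return self.affected[0].chrom

    @property
    def host_transcripts(self) -> tuple[str, str]:
        return (self.inclusion_tx, self.exclusion_tx)

    @property
    def acceptor_pos(self) -> int:
        """Strand-aware 5' boundary of the first affected interval.

        For SE, MXE and A3SS this is the 3'-splice-site position: the AG
        dinucleotide occupies the two intronic bases immediately upstream
        (``[pos-2, pos)`` on '+', the reverse complement of ``[pos, pos+2)``
        on '-'). For A5SS it is the donor-side extension boundary.
        """
        iv = self.affected[0]
        return iv.start if self.strand == "+" else iv.end

    @property
    def dedup_key(self) -> tuple:
        return (
            self.etype,
            tuple(iv.coords for iv in self.affected),
            self.flank_up.end,
            self.flank_down.start,
            self.strand,
        )


def _event_id(
    etype: str,
    chrom: str,
    affected: Sequence[GenomicInterval],
    flank_up: GenomicInterval,
    flank_down: GenomicInterval,
    strand: str,
) -> str:
    aff = ",".join(f"{iv.start}-{iv.end}" for iv in affected)
    return f"{etype}:{chrom}:{aff}:{flank_up.end}|{flank_down.start}:{strand}"


def make_event(
    etype: str,
    gene_id: str,
    affected: Sequence[GenomicInterval],
    flank_up: GenomicInterval,
    flank_down: GenomicInterval,
    inclusion_tx: str,
    exclusion_tx: str,
) -> ASEvent:
    """Construct an :class:`ASEvent` with its canonical stable id."""
    affected = tuple(sorted(affected, key=lambda iv: iv.start))
    strand = affected[0].strand
    return ASEvent(
        event_id=_event_id(etype, affected[0].chrom, affected, flank_up, flank_down, strand),
        etype=etype,
        gene_id=gene_id,
        strand=strand,
        affected=affected,
        flank_up=flank_up,
        flank_down=flank_down,
        inclusion_tx=inclusion_tx,
        exclusion_tx=exclusion_tx,
    )


# ---------------------------------------------------------------------------
# GTF I/O


def read_gene_models(annotation_path: str) -> dict[str, list[Transcript]]:
    """Read a GTF file into transcripts grouped by gene.

    Exon features (mandatory attributes ``gene_id``, ``transcript_id``) build
    the transcript structures; CDS features, when present, set the genomic
    CDS bounds. GTF 1-based closed coordinates become 0-based half-open.

    Raises :class:`GTFParseError` (naming the line number) on malformed
    lines, missing attributes, or transcripts with exons on mixed
    chromosomes/strands.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    genes: dict[str, str] = {}  # transcript -> gene
    cds_lo: dict[str, int] = {}
    cds_hi: dict[str, int] = {}
    n_lines = 0
    with open(annotation_path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            n_lines += 1
            fields = line.split("\t")
            if len(fields) != 9:
                raise GTFParseError(
                    f"{annotation_path}: malformed GTF line {lineno}: "
                    f"expected 9 tab-separated fields, got {len(fields)}"
                )
            if fields[2] not in ("exon", "CDS"):
                continue
            if not (fields[3].isdigit() and fields[4].isdigit()):
                raise GTFParseError(
                    f"{annotation_path}: malformed GTF line {lineno}: "
                    f"non-numeric coordinates {fields[3]!r}/{fields[4]!r}"
                )
            try:
                feat = feature_from_line(line)
            except Exception as exc:  # gffutils raises assorted types
                raise GTFParseError(
                    f"{annotation_path}: malformed GTF line {lineno}: {exc}"
                ) from exc
            try:
                gene_id = feat.attributes["gene_id"][0]
                tx_id = feat.attributes["transcript_id"][0]
            except KeyError as exc:
                raise GTFParseError(
                    f"{annotation_path}: line {lineno} lacks mandatory "
                    f"attribute {exc}"
                ) from exc
            start, end = feat.start - 1, feat.end  # to 0-based half-open
            if feat.strand not in ("+", "-"):
                raise GTFParseError(
                    f"{annotation_path}: line {lineno}: strand {feat.strand!r} "
                    "must be + or -"
                )
            prev_gene = genes.setdefault(tx_id, gene_id)
            if prev_gene != gene_id:
                raise GTFParseError(
                    f"{annotation_path}: line {lineno}: transcript {tx_id} "
                    f"assigned to both {prev_gene} and {gene_id}"
                )
            if feat.featuretype == "exon":
                exons.setdefault(tx_id, []).append(
                    GenomicInterval(feat.seqid, start, end, feat.strand)
                )
            else:
                cds_lo[tx_id] = min(cds_lo.get(tx_id, start), start)
                cds_hi[tx_id] = max(cds_hi.get(tx_id, end), end)
    if n_lines == 0:
        logger.warning("%s: no GTF records found (empty annotation)", annotation_path)
        return {}
    by_gene: dict[str, list[Transcript]] = {}
    for tx_id, tx_exons in sorted(exons.items()):
        tx = Transcript(
            id=tx_id,
            gene_id=genes[tx_id],
            exons=tx_exons,
            cds_start=cds_lo.get(tx_id),
            cds_end=cds_hi.get(tx_id),
        )
        by_gene.setdefault(tx.gene_id, []).append(tx)
    return by_gene


# ---------------------------------------------------------------------------
# Event enumeration


def _se_events(t1: Transcript, t2: Transcript, out: list[ASEvent]) -> None:
    """SE: exon of t1 absent from t2 with both flank junctions matched."""
    t2_coords = t2.exon_coords
    pairs2 = list(zip(t2.exons, t2.exons[1:]))
    for u, e, d in zip(t1.exons, t1.exons[1:], t1.exons[2:]):
        if e.coords in t2_coords:
            continue
        for u2, d2 in pairs2:
            if u.end == u2.end and d.start == d2.start:
                out.append(make_event("SE", t1.gene_id, [e], u, d, t1.id, t2.id))


def _mxe_events(t1: Transcript, t2: Transcript, out: list[ASEvent]) -> None:
    """MXE: different middle exons between identical flank junctions."""
    t1_coords = t1.exon_coords
    t2_coords = t2.exon_coords
    for u, a, d in zip(t1.exons, t1.exons[1:], t1.exons[2:]):
        if a.coords in t2_coords:
            continue
        for u2, b, d2 in zip(t2.exons, t2.exons[1:], t2.exons[2:]):
            if (
                u.end == u2.end
                and d.start == d2.start
                and b.coords not in t1_coords
                and not a.overlaps(b)
            ):
                inc, exc = (t1.id, t2.id) if a.start <= b.start else (t2.id, t1.id)
                out.append(make_event("MXE", t1.gene_id, [a, b], u, d, inc, exc))


def _alt_ss_events(t1: Transcript, t2: Transcript, out: list[ASEvent]) -> None:
    """A5SS/A3SS: exons sharing one boundary, differing at the other.

    Pattern R — shared start, longer end, followed by a shared-junction
    downstream exon: a donor-side extension on '+', an acceptor-side
    extension on '-'. Pattern L is the genomic mirror.
    """
    strand = t1.strand
    for i1, e1 in enumerate(t1.exons):
        for i2, e2 in enumerate(t2.exons):
            if e1.chrom != e2.chrom:
                continue
            # pattern R: same start, e1 longer at the end
            if e1.start == e2.start and e1.end > e2.end:
                if i1 + 1 < len(t1.exons) and i2 + 1 < len(t2.exons):
                    n1, n2 = t1.exons[i1 + 1], t2.exons[i2 + 1]
                    if n1.start == n2.start and e1.end < n1.start:
                        etype = "A5SS" if strand == "+" else "A3SS"
                        aff = GenomicInterval(e1.chrom, e2.end, e1.end, strand)
                        short = GenomicInterval(e1.chrom, e2.start, e2.end, strand)
                        out.append(
                            make_event(etype, t1.gene_id, [aff], short, n1, t1.id, t2.id)
                        )
            # pattern L: same end, e1 longer at the start
            if e1.end == e2.end and e1.start < e2.start:
                if i1 > 0 and i2 > 0:
                    p1, p2 = t1.exons[i1 - 1], t2.exons[i2 - 1]
                    if p1.end == p2.end and p1.end < e1.start:
                        etype = "A3SS" if strand == "+" else "A5SS"
                        aff = GenomicInterval(e1.chrom, e1.start, e2.start, strand)
                        short = GenomicInterval(e1.chrom, e2.start, e2.end, strand)
                        out.append(
                            make_event(etype, t1.gene_id, [aff], p1, short, t1.id, t2.id)
                        )


def enumerate_as_events(transcripts: Sequence[Transcript]) -> list[ASEvent]:
    """Enumerate SE/MXE/A5SS/A3SS events among the transcripts of one gene.

    Every unordered transcript pair is tested in both roles; duplicate
    events (same type, affected coordinates, flank junctions and strand)
    are collapsed, keeping the lexicographically smallest
    (inclusion, exclusion) transcript pair as representative. The result is
    sorted by event_id.
    """
    candidates: list[ASEvent] = []
    for i, t1 in enumerate(transcripts):
        for t2 in transcripts[i + 1 :]:
            if t1.chrom != t2.chrom or t1.strand != t2.strand:
                continue
            for a, b in ((t1, t2), (t2, t1)):
                _se_events(a, b, candidates)
                _alt_ss_events(a, b, candidates)
            _mxe_events(t1, t2, candidates)
    best: dict[tuple, ASEvent] = {}
    for ev in candidates:
        key = ev.dedup_key
        cur = best.get(key)
        if cur is None or ev.host_transcripts < cur.host_transcripts:
            best[key] = ev
    return sorted(best.values(), key=lambda e: e.event_id)


def classify_event_region(
    event: ASEvent, transcripts: Mapping[str, Transcript]
) -> str:
    """Classify an event as 5UTR, CDS, 3UTR or noncoding.

    Uses the inclusion-form host transcript's CDS bounds, strand-aware (on
    '-' the 5'-UTR lies genomically downstream of the CDS). Any affected
    interval overlapping the CDS — including boundary overlaps — yields CDS.
    """
    tx = transcripts.get(event.inclusion_tx)
    if tx is None:
        raise KeyError(f"host transcript missing for event {event.event_id}")
    if tx.cds_start is None:
        return "noncoding"
    lo, hi = tx.cds_start, tx.cds_end
    if any(iv.start < hi and iv.end > lo for iv in event.affected):
        return "CDS"
    if all(iv.end <= lo for iv in event.affected):
        return "5UTR" if event.strand == "+" else "3UTR"
    if all(iv.start >= hi for iv in event.affected):
        return "3UTR" if event.strand == "+" else "5UTR"
    return "CDS"  # affected intervals straddle the CDS without overlap (MXE)


# ---------------------------------------------------------------------------
# Event I/O (BED6 + TSV sidecar)

_TSV_COLUMNS = (
    "event_id",
    "etype",
    "gene_id",
    "chrom",
    "strand",
    "affected",
    "flank_up",
    "flank_down",
    "inclusion_tx",
    "exclusion_tx",
    "acceptor_pos",
)


def write_events_bed(events: Iterable[ASEvent], path: str) -> None:
    """Write events as BED6 (one line per affected interval span)."""
    with open(path, "w") as fh:
        for ev in events:
            start = min(iv.start for iv in ev.affected)
            end = max(iv.end for iv in ev.affected)
            fh.write(f"{ev.chrom}\t{start}\t{end}\t{ev.event_id}\t0\t{ev.strand}\n")


def write_events_tsv(events: Iterable[ASEvent], path: str, header: str | None = None) -> None:
    with open(path, "w") as fh:
        if header:
            fh.write(header if header.startswith("#") else "#" + header)
            if not header.endswith("\n"):
                fh.write("\n")
        fh.write("\t".join(_TSV_COLUMNS) + "\n")
        for ev in events:
            aff = ",".join(f"{iv.start}-{iv.end}" for iv in ev.affected)
            fh.write(
                "\t".join(
                    [
                        ev.event_id,
                        ev.etype,
                        ev.gene_id,
                        ev.chrom,
                        ev.strand,
                        aff,
                        f"{ev.flank_up.start}-{ev.flank_up.end}",
                        f"{ev.flank_down.start}-{ev.flank_down.end}",
                        ev.inclusion_tx,
                        ev.exclusion_tx,
                        str(ev.acceptor_pos),
                    ]
                )
                + "\n"
            )


def read_events_tsv(path: str) -> list[ASEvent]:
    """Re-read an event TSV written by :func:`write_events_tsv`."""
    events: list[ASEvent] = []
    with open(path) as fh:
        header: list[str] | None = None
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            if header is None:
                header = line.split("\t")
                continue
            rec = dict(zip(header, line.split("\t")))
            strand = rec["strand"]
            chrom = rec["chrom"]

            def iv(spec: str) -> GenomicInterval:
                s, e = spec.split("-")
                return GenomicInterval(chrom, int(s), int(e), strand)

            events.append(
                ASEvent(
                    event_id=rec["event_id"],
                    etype=rec["etype"],
                    gene_id=rec["gene_id"],
                    strand=strand,
                    affected=tuple(iv(a) for a in rec["affected"].split(",")),
                    flank_up=iv(rec["flank_up"]),
                    flank_down=iv(rec["flank_down"]),
                    inclusion_tx=rec["inclusion_tx"],
                    exclusion_tx=rec["exclusion_tx"],
                )
            )
    return events
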