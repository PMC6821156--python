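"""3'-splice-site sequence context: frequency and certainty matrices.

For each event a strand-aware window around the acceptor is extracted:
positions -35..-1 are intronic (with the AG dinucleotide at -2, -1) and
+1..+5 are the first exonic bases; there is no position 0. Column-wise
nucleotide fractions give the frequency matrix; each frequency maps to a
"certainty" in bits,

    certainty = clamp(log10(100 * freq / 2.4), 0, 1.5)

i.e. the base-10 log of the percent frequency over a 2.4% background floor,
clamped to [0, 1.5]. A conventional information content (2 + log2 freq,
clamped at 0) is computed alongside for comparability. The per-position
C+T fraction profiles the polypyrimidine tract upstream of the acceptor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from pyfaidx import Fasta

from .gene_models import ASEvent

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")
_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ContextWindow:
    """Acceptor window geometry: intronic bases before the AG, the AG, and
    the first exonic bases. Defaults give the 40-base -35..+5 window."""

    upstream: int = 33  # intronic bases before the AG (positions -35..-3)
    downstream_exonic: int = 5  # exonic bases (+1..+5)

    def __post_init__(self) -> None:
        if self.upstream < 1 or self.downstream_exonic < 1:
            raise ValueError("window must have >=1 upstream and downstream base")

    @property
    def intronic(self) -> int:
        return self.upstream + 2  # includes the AG at -2, -1

    @property
    def total(self) -> int:
        return self.intronic + self.downstream_exonic

    @property
    def positions(self) -> list[int]:
        """Position labels -upstream-2..-1, +1..+downstream (no 0)."""
        return list(range(-self.intronic, 0)) + list(
            range(1, self.downstream_exonic + 1)
        )


@dataclass
class ContextSequences:
    """Extracted acceptor windows plus extraction diagnostics."""

    sequences: list[str]
    non_ag: int = 0  # windows without AG at -2,-1 (kept)
    skipped: int = 0  # events skipped (window out of contig bounds)


def extract_acceptor_context(
    events: Iterable[ASEvent],
    genome: Fasta | str,
    window: ContextWindow | None = None,
) -> ContextSequences:
    """Extract uppercased acceptor windows for a set of events.

    The window is anchored so that -2, -1 are the intronic AG immediately
    preceding the (strand-aware) start of the affected exon; minus-strand
    windows are reverse-complemented. Events whose window would run off the
    contig are skipped with a warning; windows lacking the canonical AG are
    kept but counted (annotations contain non-canonical acceptors).
    """
    window = window or ContextWindow()
    if isinstance(genome, str):
        genome = Fasta(genome)
    out = ContextSequences(sequences=[])
    for ev in events:
        pos = ev.acceptor_pos
        contig = genome[ev.chrom]
        if ev.strand == "+":
            lo, hi = pos - window.intronic, pos + window.downstream_exonic
        else:
            lo, hi = pos - window.downstream_exonic, pos + window.intronic
        if lo < 0 or hi > len(contig):
            logger.warning(
                "event %s: window %s:%d-%d exceeds contig bounds, skipped",
                ev.event_id,
                ev.chrom,
                lo,
                hi,
            )
            out.skipped += 1
            continue
        seq = str(contig[lo:hi]).upper()
        if ev.strand == "-":
            seq = reverse_complement(seq)
        if seq[window.upstream : window.upstream + 2] != "AG":
            out.non_ag += 1
        out.sequences.append(seq)
    if out.non_ag:
        logger.info("%d/%d windows lack the canonical AG at -2,-1",
                    out.non_ag, len(out.sequences))
    return out


def certainty(freq, background_percent: float = 2.4):
    """Certainty in bits: clamp(log10(100*freq / background), 0, 1.5).

    Monotone non-decreasing in freq; 0 at or below the 2.4% background,
    1.5 at the ceiling (freq = 1 gives log10(41.7) = 1.62, clamped).
    Accepts scalars or arrays.
    """
    f = np.asarray(freq, dtype=float)
    with np.errstate(divide="ignore"):
        bits = np.log10(100.0 * f / background_percent)
    bits = np.clip(np.where(f > 0, bits, 0.0), 0.0, 1.5)
    return float(bits) if np.isscalar(freq) else bits


@dataclass
class ContextMatrix:
    """Per-position nucleotide frequencies and certainty bits."""

    positions: list[int]
    freq: pd.DataFrame  # rows A/C/G/T x position columns, columns sum to 1
    certainty: pd.DataFrame  # bits in [0, 1.5]
    info: pd.DataFrame  # conventional information content, max(0, 2+log2 f)
    n_sequences: int
    background_percent: float = 2.4


def frequency_matrix(
    sequences: Sequence[str],
    window: ContextWindow | None = None,
    background_percent: float = 2.4,
) -> ContextMatrix:
    """Column-wise nucleotide fractions over equal-length sequences.

    Ambiguous bases (anything outside ACGT) are excluded from the
    per-column denominator. Raises ValueError on empty input or ragged
    lengths.
    """
    if not sequences:
        raise ValueError("frequency_matrix: empty sequence set")
    length = len(sequences[0])
    if any(len(s) != length for s in sequences):
        raise ValueError("frequency_matrix: sequences have unequal lengths")
    if window is not None and window.total != length:
        raise ValueError(
            f"window of {window.total} positions does not match "
            f"sequence length {length}"
        )
    positions = (
        window.positions
        if window is not None
        else _default_positions(length)
    )
    arr = np.frombuffer("".join(sequences).encode(), dtype="S1").reshape(
        len(sequences), length
    )
    counts = np.stack([(arr == nt.encode()).sum(axis=0) for nt in NUCLEOTIDES])
    denom = counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(denom > 0, counts / np.where(denom > 0, denom, 1), 0.0)
    freq_df = pd.DataFrame(freq, index=list(NUCLEOTIDES), columns=positions)
    cert_df = pd.DataFrame(
        certainty(freq, background_percent), index=list(NUCLEOTIDES), columns=positions
    )
    with np.errstate(divide="ignore"):
        info = np.maximum(0.0, 2.0 + np.where(freq > 0, np.log2(np.maximum(freq, 1e-300)), -np.inf))
    info_df = pd.DataFrame(info, index=list(NUCLEOTIDES), columns=positions)
    return ContextMatrix(
        positions=list(positions),
        freq=freq_df,
        certainty=cert_df,
        info=info_df,
        n_sequences=len(sequences),
        background_percent=background_percent,
    )


def _default_positions(length: int) -> list[int]:
    """Default labels when no window is given: the last 5 bases exonic if the
    length matches the canonical 40-mer, else 1..length."""
    if length > 5:
        return list(range(-(length - 5), 0)) + list(range(1, 6))
    return list(range(1, length + 1))


def pyrimidine_profile(matrix: ContextMatrix) -> pd.Series:
    """Per-position C+T fraction (the polypyrimidine-tract profile)."""
    return matrix.freq.loc["C"] + matrix.freq.loc["T"]


def polypyrimidine_mean(
    matrix: ContextMatrix, lo: int = -20, hi: int = -3
) -> float:
    """Mean C+T fraction over positions lo..hi (default -20..-3), the span
    where U2AF2-bound polypyrimidine tracts concentrate."""
    prof = pyrimidine_profile(matrix)
    cols = [p for p in matrix.positions if lo <= p <= hi]
    return float(prof[cols].mean())


def write_matrix_tsv(matrix: ContextMatrix, path: str, kind: str = "freq",
                     header: str | None = None) -> None:
    """Write the freq / certainty / info matrix as TSV (rows A/C/G/T)."""
    df = getattr(matrix, kind)
    with open(path, "w") as fh:
        if header:
            fh.write(header if header.startswith("#") else "#" + header)
            if not header.endswith("\n"):
                fh.write("\n")
        fh.write(f"# n_sequences={matrix.n_sequences} "
                 f"background_percent={matrix.background_percent}\n")
        df.to_csv(fh, sep="\t", index_label="nt", float_format="%.6g")


def plot_logo(matrix: ContextMatrix, path: str, kind: str = "certainty") -> None:
    """Stacked-bar logo of per-position certainty (or info) values.

    Requires matplotlib (install the ``plot`` extra).
    """
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError("plot_logo requires matplotlib (pip install asquant[plot])") from exc
    values = getattr(matrix, kind)
    colors = {"A": "#33a02c", "C": "#1f78b4", "G": "#ff7f00", "T": "#e31a1c"}
    fig, ax = plt.subplots(figsize=(10, 3))
    x = np.arange(len(matrix.positions))
    bottom = np.zeros(len(matrix.positions))
    for nt in NUCLEOTIDES:
        h = values.loc[nt].to_numpy()
        ax.bar(x, h, bottom=bottom, color=colors[nt], label=nt, width=0.85)
        bottom += h
    ax.set_xticks(x[::5])
    ax.set_xticklabels([matrix.positions[i] for i in range(0, len(x), 5)])
    ax.set_xlabel("position relative to the 3'-splice-site AG")
    ax.set_ylabel(f"{kind} (bits)")
    ax.legend(ncol=4, fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
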