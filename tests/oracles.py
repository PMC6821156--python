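"""Independent brute-force oracles used to cross-check the implementation.

These deliberately use naive mechanics (exhaustive index loops, regex
scanning, closed-form algebra) distinct from the package's code paths.
"""

from __future__ import annotations

import re

import numpy as np


def chi2_closed_form(a: float, b: float, c: float, d: float) -> float:
    """Pearson 2x2 statistic via the determinant identity
    T(ad-bc)^2 / ((a+b)(c+d)(a+c)(b+d))."""
    T = a + b + c + d
    den = (a + b) * (c + d) * (a + c) * (b + d)
    if den == 0:
        return 0.0
    return T * (a * d - b * c) ** 2 / den


def chi2_pvalue_erfc(chi2: float) -> float:
    """Upper tail of chi-squared with 1 df: p = erfc(sqrt(x/2))."""
    from scipy.special import erfc

    return float(erfc(np.sqrt(chi2 / 2.0)))


def chi2_pvalue_quad(chi2: float) -> float:
    """Numeric integration of the 1-df chi-squared density over [x, inf)."""
    from scipy.integrate import quad

    if chi2 <= 0:
        return 1.0
    pdf = lambda t: np.exp(-t / 2.0) / np.sqrt(2.0 * np.pi * t)
    val, _ = quad(pdf, chi2, np.inf, epsabs=1e-12, epsrel=1e-12)
    return float(val)


# ---------------------------------------------------------------------------
# brute-force alternative-splicing event enumeration


def _exon_in(exon: tuple[int, int], exons: list[tuple[int, int]]) -> bool:
    return any(e == exon for e in exons)


def brute_force_events(transcript_exons: dict[str, list[tuple[int, int]]],
                       strand: str) -> set[tuple]:
    """Enumerate event keys (etype, affected coords, flank junctions, strand)
    by exhaustively testing every exon / exon pair of every ordered
    transcript pair against the four definitions."""
    keys: set[tuple] = set()
    items = sorted(transcript_exons.items())
    for t1_id, ex1 in items:
        for t2_id, ex2 in items:
            if t1_id == t2_id:
                continue
            n1, n2 = len(ex1), len(ex2)
            # SE: (u, e, d) consecutive in T1, e absent from T2,
            # some consecutive (u2, d2) in T2 with matching junctions
            for i in range(n1):
                for j in range(n1):
                    for k in range(n1):
                        if not (j == i + 1 and k == j + 1):
                            continue
                        u, e, d = ex1[i], ex1[j], ex1[k]
                        if _exon_in(e, ex2):
                            continue
                        for p in range(n2):
                            for q in range(n2):
                                if q != p + 1:
                                    continue
                                if ex2[p][1] == u[1] and ex2[q][0] == d[0]:
                                    keys.add(("SE", (e,), u[1], d[0], strand))
            # MXE: consecutive (u,a,d) in T1 and (u2,b,d2) in T2, matching
            # junctions, a not in T2, b not in T1, a and b non-overlapping
            for i in range(n1 - 2):
                u, a, d = ex1[i], ex1[i + 1], ex1[i + 2]
                if _exon_in(a, ex2):
                    continue
                for p in range(n2 - 2):
                    u2, b, d2 = ex2[p], ex2[p + 1], ex2[p + 2]
                    if u2[1] != u[1] or d2[0] != d[0]:
                        continue
                    if _exon_in(b, ex1):
                        continue
                    if a[0] < b[1] and b[0] < a[1]:  # overlap
                        continue
                    pair = tuple(sorted((a, b)))
                    keys.add(("MXE", pair, u[1], d[0], strand))
            # alt splice sites: exons sharing one boundary, differing at the
            # other, beside a shared junction
            for i in range(n1):
                for p in range(n2):
                    e1, e2 = ex1[i], ex2[p]
                    if e1[0] == e2[0] and e1[1] > e2[1]:
                        if i + 1 < n1 and p + 1 < n2:
                            if ex1[i + 1][0] == ex2[p + 1][0] and e1[1] < ex1[i + 1][0]:
                                etype = "A5SS" if strand == "+" else "A3SS"
                                keys.add((etype, ((e2[1], e1[1]),), e2[1],
                                          ex1[i + 1][0], strand))
                    if e1[1] == e2[1] and e1[0] < e2[0]:
                        if i > 0 and p > 0:
                            if ex1[i - 1][1] == ex2[p - 1][1] and ex1[i - 1][1] < e1[0]:
                                etype = "A3SS" if strand == "+" else "A5SS"
                                keys.add((etype, ((e1[0], e2[0]),),
                                          ex1[i - 1][1], e2[0], strand))
    return keys


def random_toy_gene(rng: np.random.Generator,
                    max_transcripts: int = 4) -> tuple[dict[str, list[tuple[int, int]]], str]:
    """A random multi-isoform toy gene: a master exon chain plus transcripts
    formed by dropping exons and jittering boundaries into the introns."""
    n_exons = int(rng.integers(3, 7))
    cursor = int(rng.integers(0, 50))
    master: list[tuple[int, int]] = []
    for _ in range(n_exons):
        length = int(rng.integers(20, 80))
        master.append((cursor, cursor + length))
        cursor += length + int(rng.integers(30, 90))  # intron >= 30
    strand = "+" if rng.random() < 0.5 else "-"
    n_tx = int(rng.integers(2, max_transcripts + 1))
    transcripts: dict[str, list[tuple[int, int]]] = {}
    for t in range(n_tx):
        keep = [i for i in range(n_exons) if rng.random() > 0.25 or i in (0, n_exons - 1)]
        if len(keep) < 2:
            keep = [0, n_exons - 1]
        exons = []
        for i in keep:
            s, e = master[i]
            if rng.random() < 0.3:  # jitter one boundary into the intron
                if rng.random() < 0.5 and i > 0:
                    s -= int(rng.integers(1, 15))
                elif i < n_exons - 1:
                    e += int(rng.integers(1, 15))
            exons.append((s, e))
        transcripts[f"t{t}"] = exons
    return transcripts, strand


# ---------------------------------------------------------------------------
# brute-force uORF scanner

_UORF_RE = re.compile(r"ATG(?:...)*?(?:TAA|TAG|TGA)", re.S)


def uorf_oracle(seq: str, cds: int | None = None, min_len: int = 9) -> list[tuple[int, int, bool]]:
    """Regex-based uORF scan returning (start, length_nt, terminated)."""
    seq = seq.upper()
    cds = len(seq) if cds is None else cds
    out = []
    for i in range(len(seq) - 2):
        if seq[i : i + 3] != "ATG" or i + 3 > cds:
            continue
        m = _UORF_RE.match(seq, i)
        if m:
            length = m.end() - i
            terminated = m.end() <= cds
            if terminated and length < min_len:
                continue
            out.append((i, length, terminated))
        else:
            out.append((i, (len(seq) - i) // 3 * 3, False))
    return out
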