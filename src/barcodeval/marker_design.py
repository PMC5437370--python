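"""Primer-window selection over a pairwise-aligned genomic region.

Candidate amplicons are bounded by primer windows that are identical in
both genomes (conserved flanks) and must bracket at least one variant
column. Constraints follow common wet-lab practice for universal plastid
primers: primer length 18-24 nt, melting temperature 50-65 degrees C,
product length 400-1100 bp.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .genome_compare import revcomp


@dataclass
class PrimerParams:
    min_primer: int = 18
    max_primer: int = 24
    tm_min: float = 50.0
    tm_max: float = 65.0
    min_product: int = 400
    max_product: int = 1100


@dataclass
class PrimerPair:
    """Forward/reverse primers (both written 5'->3') and their product."""

    fwd: str
    rev: str
    tm_fwd: float
    tm_rev: float
    product: tuple[int, int]  # interval on the reference region, half-open
    region_label: str = ""


@dataclass
class CandidateMarker:
    primer_pair: PrimerPair
    n_variant_sites: int
    conserved_flanks: bool = True


def melting_temperature(seq: str, method: str = "auto") -> float:
    """Primer melting temperature in degrees C.

    ``wallace``: 2(A+T) + 4(G+C). ``gc``: 64.9 + 41(GC - 16.4)/len.
    ``auto`` uses the Wallace rule up to 20 nt and the GC formula above
    (standard short-oligo practice).
    """
    if len(seq) < 8:
        raise ValueError("primer too short for a Tm estimate")
    if set(seq) - set("ACGT"):
        raise ValueError(f"ambiguity codes in primer: {seq}")
    if method == "auto":
        method = "wallace" if len(seq) <= 20 else "gc"
    at = seq.count("A") + seq.count("T")
    gc = seq.count("G") + seq.count("C")
    if method == "wallace":
        return 2.0 * at + 4.0 * gc
    if method == "gc":
        return 64.9 + 41.0 * (gc - 16.4) / len(seq)
    raise ValueError(f"unknown Tm method {method!r}")


def classify_columns(ref_aligned: str, alt_aligned: str) -> list[str]:
    """Per-column classification: 'conserved', 'snp', or 'gap'."""
    if len(ref_aligned) != len(alt_aligned):
        raise ValueError("aligned region strings differ in length")
    out = []
    for a, b in zip(ref_aligned, alt_aligned):
        if a == "-" or b == "-":
            out.append("gap")
        elif a == b:
            out.append("conserved")
        else:
            out.append("snp")
    return out


def _valid_window(seq: str, end: int, params: PrimerParams,
                  conserved: list[bool]) -> Optional[tuple[int, int, float]]:
    """Rightmost valid primer window ending at ``end`` (exclusive).

    Returns (start, end, tm) for the shortest acceptable length, or None.
    """
    for length in range(params.min_primer, params.max_primer + 1):
        start = end - length
        if start < 0:
            return None
        if not all(conserved[start:end]):
            return None
        window = seq[start:end]
        if "N" in window:
            return None
        tm = melting_temperature(window)
        if params.tm_min <= tm <= params.tm_max:
            return (start, end, tm)
    return None


def pick_primer_windows(ref_aligned: str, alt_aligned: str,
                        params: Optional[PrimerParams] = None,
                        region_label: str = "region",
                        ref_offset: int = 0) -> list[CandidateMarker]:
    """Greedy left-to-right tiling of candidate amplicons.

    Both inputs are the same aligned region (gaps allowed). Windows must be
    identical in both genomes and gap-free; each emitted product brackets at
    least one variant (SNP or gap) column. Products are reported on
    ungapped reference coordinates shifted by ``ref_offset``.
    """
    params = params or PrimerParams()
    cols = classify_columns(ref_aligned, alt_aligned)
    # ungapped reference sequence and column -> ref-position map
    ref_pos = []
    ref_seq_chars = []
    p = 0
    for c, ch in enumerate(ref_aligned):
        ref_pos.append(p)
        if ch != "-":
            ref_seq_chars.append(ch)
            p += 1
    ref_seq = "".join(ref_seq_chars)
    n = len(ref_seq)
    # conserved mask on reference coordinates (gap columns are variants and
    # consume no reference position when the gap is in the reference)
    conserved = [True] * n
    variant_ref_pos: list[int] = []
    for c, kind in enumerate(cols):
        if kind == "conserved":
            continue
        rp = min(ref_pos[c], n - 1)
        conserved[rp] = False
        variant_ref_pos.append(rp)
    variant_ref_pos = sorted(set(variant_ref_pos))
    if not variant_ref_pos:
        return []

    candidates: list[CandidateMarker] = []
    cursor = 0
    vi = 0
    while vi < len(variant_ref_pos):
        v = variant_ref_pos[vi]
        if v < cursor:
            vi += 1
            continue
        pair = _bracket_variant(ref_seq, conserved, v, cursor, params)
        if pair is None:
            vi += 1
            continue
        fstart, fend, tm_f, rstart, rend, tm_r = pair
        product = (fstart, rend)
        inside = [u for u in variant_ref_pos if fend <= u < rstart]
        rev = revcomp(ref_seq[rstart:rend])
        candidates.append(CandidateMarker(
            primer_pair=PrimerPair(
                fwd=ref_seq[fstart:fend],
                rev=rev,
                tm_fwd=tm_f,
                tm_rev=tm_r,
                product=(product[0] + ref_offset, product[1] + ref_offset),
                region_label=f"{region_label}_{len(candidates) + 1}",
            ),
            n_variant_sites=len(inside),
        ))
        cursor = rend
        while vi < len(variant_ref_pos) and variant_ref_pos[vi] < rend:
            vi += 1
    return candidates


def _bracket_variant(ref_seq: str, conserved: list[bool], v: int, cursor: int,
                     params: PrimerParams):
    """Find the closest valid (forward, reverse) window pair around ``v``.

    Searches forward-window end positions from just left of the variant
    leftwards, and reverse-window start positions from just right of it
    rightwards, accepting the first pair whose product length fits.
    """
    n = len(ref_seq)
    for fend in range(v, max(cursor + params.min_primer, params.min_primer) - 1, -1):
        fwd = _valid_window(ref_seq, fend, params, conserved)
        if fwd is None:
            continue
        fstart, fend, tm_f = fwd
        if fstart < cursor:
            continue
        for rstart in range(v + 1, n - params.min_primer + 1):
            rend_limit = fstart + params.max_product
            if rstart + params.min_primer > rend_limit:
                break
            rev = _valid_window_right(ref_seq, rstart, params, conserved)
            if rev is None:
                continue
            rstart2, rend, tm_r = rev
            product_len = rend - fstart
            if product_len < params.min_product:
                continue
            if product_len > params.max_product:
                break
            return fstart, fend, tm_f, rstart2, rend, tm_r
        # no reverse partner for this forward window; try the next one
    return None


def _valid_window_right(seq: str, start: int, params: PrimerParams,
                        conserved: list[bool]) -> Optional[tuple[int, int, float]]:
    """Leftmost valid primer window starting at ``start``."""
    for length in range(params.min_primer, params.max_primer + 1):
        end = start + length
        if end > len(seq):
            return None
        if not all(conserved[start:end]):
            return None
        window = seq[start:end]
        if "N" in window:
            return None
        tm = melting_temperature(revcomp(window))
        if params.tm_min <= tm <= params.tm_max:
            return (start, end, tm)
    return None
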