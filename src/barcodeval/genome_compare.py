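"""Plastome structure and pairwise comparison.

Locates the quadripartite LSC/IRa/SSC/IRb structure of a circular plastid
genome, summarizes it (lengths, GC content, repeat counts), scans for short
dispersed repeats, and counts SNPs and gap events between the single-copy
regions of two genomes using an anchor-chain plus per-segment global
alignment strategy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import edlib

from .io_formats import GenomeRecord

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHV", "TGCANYRSWMKVHDB")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class NoInvertedRepeatError(ValueError):
    """No inverted repeat of the required length was found."""


class DivergentGenomesError(ValueError):
    """Anchoring covered too little of the reference; genomes too divergent."""


@dataclass
class QuadripartiteMap:
    """LSC/IRa/SSC/IRb intervals (0-based half-open) on a genome record."""

    lsc: tuple[int, int]
    ira: tuple[int, int]
    ssc: tuple[int, int]
    irb: tuple[int, int]
    source: str = "computed"  # computed | annotated

    def validate(self, genome: GenomeRecord, max_ir_mismatch: float = 0.01) -> None:
        n = len(genome.seq)
        ira_len = _interval_len(self.ira, n)
        irb_len = _interval_len(self.irb, n)
        if ira_len != irb_len:
            raise ValueError(f"IR copies differ in length: {ira_len} vs {irb_len}")
        lsc_len = _interval_len(self.lsc, n)
        ssc_len = _interval_len(self.ssc, n)
        if lsc_len <= ssc_len:
            raise ValueError("LSC not longer than SSC")
        if lsc_len + ssc_len + 2 * ira_len != n:
            raise ValueError("quadripartite intervals do not cover the genome")
        ira_seq = _extract(genome.seq, self.ira)
        irb_seq = _extract(genome.seq, self.irb)
        mismatches = sum(a != b for a, b in zip(ira_seq, revcomp(irb_seq)))
        if mismatches > max_ir_mismatch * ira_len:
            raise ValueError(
                f"IR copies disagree at {mismatches}/{ira_len} positions"
            )

    def region_lengths(self, genome: GenomeRecord) -> dict[str, int]:
        n = len(genome.seq)
        return {
            "lsc": _interval_len(self.lsc, n),
            "ira": _interval_len(self.ira, n),
            "ssc": _interval_len(self.ssc, n),
            "irb": _interval_len(self.irb, n),
        }


@dataclass
class GenomeSummary:
    """Table-style genome summary: lengths, GC percent, repeat count."""

    total_bp: int
    lsc_bp: int
    ssc_bp: int
    ir_bp: int
    gc_percent: float
    n_repeats: int


@dataclass
class RepeatHit:
    """A maximal exact repeated pair of length 8-50 bp (default bounds)."""

    kind: str  # forward | palindromic
    pos1: int
    pos2: int
    length: int
    unit: str


@dataclass
class VariantSummary:
    """SNP and gap-event counts between homologous single-copy regions."""

    snp_count: int
    gap_event_count: int
    anchored_fraction: float


def _interval_len(iv: tuple[int, int], n: int) -> int:
    start, end = iv
    return end - start if end >= start else n - start + end


def _extract(seq: str, iv: tuple[int, int]) -> str:
    start, end = iv
    return seq[start:end] if end >= start else seq[start:] + seq[:end]


def locate_inverted_repeats(genome: GenomeRecord, min_ir_len: int = 1000,
                            seed_k: int = 20,
                            source_preference: str = "computed") -> QuadripartiteMap:
    """Find the quadripartite structure via the maximal inverted-repeat pair.

    Seeds shared k-mers between the sequence and its reverse complement,
    extends each seed pair outward with zero mismatches, and keeps the
    longest resulting pair of disjoint reverse-complement segments of at
    least ``min_ir_len``. Ties are broken toward the smallest IRa start.

    With ``source_preference="annotated"`` and repeat_region annotations
    present, the annotated intervals are used instead (and validated).
    """
    n = len(genome.seq)
    if n <= 4 * min_ir_len:
        raise ValueError("genome too short for the requested minimum IR length")

    if source_preference == "annotated":
        irs = [(s, e) for (ft, s, e, _st, _lb) in genome.annotations
               if ft == "repeat_region" and e - s >= min_ir_len]
        if len(irs) == 2:
            irs.sort()
            qmap = _map_from_irs(genome, irs[0], irs[1], source="annotated")
            qmap.validate(genome)
            return qmap

    seq = genome.seq
    rc = revcomp(seq)
    # k-mer index of the reverse complement; a shared k-mer at seq position i
    # and rc position j corresponds to an inverted copy at n - j - k on seq.
    index: dict[str, list[int]] = {}
    for j in range(0, n - seed_k + 1, seed_k):
        index.setdefault(rc[j:j + seed_k], []).append(j)

    best: Optional[tuple[int, int, int]] = None  # (length, start1, start2)
    seen_pairs: set[tuple[int, int]] = set()
    for i in range(n - seed_k + 1):
        hits = index.get(seq[i:i + seed_k])
        if not hits:
            continue
        for j in hits:
            # extend (i, j) on (seq, rc) maximally with 0 mismatches
            a, b = i, j
            while a > 0 and b > 0 and seq[a - 1] == rc[b - 1]:
                a -= 1
                b -= 1
            e1, e2 = i + seed_k, j + seed_k
            while e1 < n and e2 < n and seq[e1] == rc[e2]:
                e1 += 1
                e2 += 1
            length = e1 - a
            if length < min_ir_len:
                continue
            start_on_seq2 = n - (b + length)  # rc interval mapped back to seq
            s1, s2 = sorted((a, start_on_seq2))
            if (s1, s2) in seen_pairs:
                continue
            seen_pairs.add((s1, s2))
            if s2 < s1 + length:  # overlapping copies: not a true IR pair
                continue
            cand = (length, s1, s2)
            if best is None or (cand[0], -cand[1]) > (best[0], -best[1]):
                best = cand
    if best is None:
        raise NoInvertedRepeatError(
            f"no inverted repeat of length >= {min_ir_len} found"
        )
    length, s1, s2 = best
    return _map_from_irs(genome, (s1, s1 + length), (s2, s2 + length))


def _map_from_irs(genome: GenomeRecord, ir1: tuple[int, int],
                  ir2: tuple[int, int], source: str = "computed") -> QuadripartiteMap:
    """Assign LSC/SSC to the two single-copy arcs between the IR copies."""
    n = len(genome.seq)
    arc_a = (ir1[1], ir2[0])            # between IR1 end and IR2 start
    arc_b = (ir2[1] % n, ir1[0])        # wraps around the origin
    len_a = _interval_len(arc_a, n)
    len_b = _interval_len(arc_b, n)
    if len_a >= len_b:
        lsc, ssc = arc_a, arc_b
    else:
        lsc, ssc = arc_b, arc_a
    return QuadripartiteMap(lsc=lsc, ira=ir1, ssc=ssc, irb=ir2, source=source)


def genome_summary(genome: GenomeRecord, qmap: QuadripartiteMap,
                   repeats: list[RepeatHit]) -> GenomeSummary:
    """Summary statistics for one genome given its quadripartite map."""
    qmap.validate(genome)
    lengths = qmap.region_lengths(genome)
    counts = {b: genome.seq.count(b) for b in "ACGT"}
    denom = sum(counts.values())
    gc = 100.0 * (counts["G"] + counts["C"]) / denom if denom else 0.0
    return GenomeSummary(
        total_bp=len(genome.seq),
        lsc_bp=lengths["lsc"],
        ssc_bp=lengths["ssc"],
        ir_bp=lengths["ira"],
        gc_percent=round(gc, 2),
        n_repeats=len(repeats),
    )


def _is_mononucleotide(unit: str) -> bool:
    return len(set(unit)) == 1


def find_repeats(genome: GenomeRecord, min_len: int = 8, max_len: int = 50,
                 include_palindromic: bool = True,
                 exclude: Optional[list[tuple[int, int]]] = None) -> list[RepeatHit]:
    """All maximal exact repeated pairs with length in [min_len, max_len].

    Mononucleotide units are excluded, as are hits overlapping any interval
    in ``exclude`` (typically the IR copies, whose mutual repeat is trivial).
    Results are deduplicated by (unit, sorted positions) and sorted by
    length descending, then by first position.
    """
    if min_len < 2:
        raise ValueError("min_len must be >= 2")
    seq = genome.seq
    n = len(seq)
    hits: dict[tuple[str, str, int, int], RepeatHit] = {}

    def _excluded(pos: int, length: int) -> bool:
        if not exclude:
            return False
        return any(pos < e and pos + length > s for s, e in exclude)

    def _record(kind: str, a: int, b: int, length: int, unit: str) -> None:
        if not (min_len <= length <= max_len):
            return
        if _is_mononucleotide(unit):
            return
        if _excluded(a, length) or _excluded(b, length):
            return
        p1, p2 = sorted((a, b))
        hits.setdefault((kind, unit, p1, p2),
                        RepeatHit(kind, p1, p2, length, seq[p1:p1 + length]))

    # forward repeats: seed on min_len-mers of the sequence against itself
    index: dict[str, list[int]] = {}
    for i in range(n - min_len + 1):
        index.setdefault(seq[i:i + min_len], []).append(i)
    for positions in index.values():
        if len(positions) < 2:
            continue
        for ai in range(len(positions)):
            for bi in range(ai + 1, len(positions)):
                a, b = positions[ai], positions[bi]
                # maximal extension of the pair
                sa, sb = a, b
                while sa > 0 and sb > 0 and seq[sa - 1] == seq[sb - 1]:
                    sa -= 1
                    sb -= 1
                ea, eb = a + min_len, b + min_len
                while ea < n and eb < n and seq[ea] == seq[eb]:
                    ea += 1
                    eb += 1
                if sa == sb:
                    continue
                _record("forward", sa, sb, ea - sa, seq[sa:ea])

    if include_palindromic:
        rc = revcomp(seq)
        rc_index: dict[str, list[int]] = {}
        for j in range(n - min_len + 1):
            rc_index.setdefault(rc[j:j + min_len], []).append(j)
        for i in range(n - min_len + 1):
            for j in rc_index.get(seq[i:i + min_len], ()):
                a, b = i, j
                while a > 0 and b > 0 and seq[a - 1] == rc[b - 1]:
                    a -= 1
                    b -= 1
                e1, e2 = i + min_len, j + min_len
                while e1 < n and e2 < n and seq[e1] == rc[e2]:
                    e1 += 1
                    e2 += 1
                length = e1 - a
                other = n - (b + length)  # rc copy mapped back to seq coords
                if other == a:
                    continue  # self-reverse-complement palindrome center
                _record("palindromic", a, other, length, seq[a:e1])

    out = sorted(hits.values(), key=lambda h: (-h.length, h.pos1, h.pos2))
    return out


def _anchor_chain(a: str, b: str, k: int) -> list[tuple[int, int]]:
    """Longest collinear chain of k-mers unique to and shared by both strings."""

    def _unique_kmers(s: str) -> dict[str, int]:
        seen: dict[str, int] = {}
        dup: set[str] = set()
        for i in range(len(s) - k + 1):
            kmer = s[i:i + k]
            if kmer in seen:
                dup.add(kmer)
            else:
                seen[kmer] = i
        for kmer in dup:
            del seen[kmer]
        return seen

    ka = _unique_kmers(a)
    kb = _unique_kmers(b)
    shared = [(ka[m], kb[m]) for m in ka.keys() & kb.keys()]
    shared.sort()
    if not shared:
        return []
    # longest strictly increasing subsequence in the second coordinate
    import bisect

    tails: list[int] = []
    tails_idx: list[int] = []
    prev = [-1] * len(shared)
    for idx, (_pa, pb) in enumerate(shared):
        pos = bisect.bisect_left(tails, pb)
        if pos == len(tails):
            tails.append(pb)
            tails_idx.append(idx)
        else:
            tails[pos] = pb
            tails_idx[pos] = idx
        prev[idx] = tails_idx[pos - 1] if pos > 0 else -1
    chain = []
    cur = tails_idx[-1]
    while cur != -1:
        chain.append(shared[cur])
        cur = prev[cur]
    chain.reverse()
    # drop anchors overlapping their predecessor so segments stay disjoint
    filtered = [chain[0]]
    for pa, pb in chain[1:]:
        la, lb = filtered[-1]
        if pa >= la + k and pb >= lb + k:
            filtered.append((pa, pb))
    return filtered


def _align_segment(a: str, b: str) -> tuple[int, int]:
    """(mismatch columns, gap events) of a global pairwise alignment."""
    if not a and not b:
        return 0, 0
    if not a or not b:
        return 0, 1
    res = edlib.align(a, b, mode="NW", task="path")
    snps = 0
    gap_events = 0
    prev_gap = False
    import re

    for count, op in re.findall(r"(\d+)([=XID])", res["cigar"]):
        if op == "X":
            snps += int(count)
            prev_gap = False
        elif op in "ID":
            if not prev_gap:
                gap_events += 1
            prev_gap = True
        else:
            prev_gap = False
    return snps, gap_events


def compare_single_copy_regions(region_a: str, region_b: str,
                                k: int = 20) -> VariantSummary:
    """Count SNPs and gap events between two homologous single-copy regions.

    An anchor chain of unique shared k-mers fixes the collinear backbone;
    the inter-anchor (and flanking) segments are globally aligned and their
    mismatch columns and maximal gap runs counted. One contiguous run of
    gap columns counts as a single gap event regardless of length.

    Raises DivergentGenomesError when the anchor chain spans less than half
    of the reference region.
    """
    chain = _anchor_chain(region_a, region_b, k)
    if chain:
        anchored = (chain[-1][0] + k) - chain[0][0]
        anchored_fraction = anchored / len(region_a)
    else:
        anchored_fraction = 0.0
    if anchored_fraction < 0.5:
        raise DivergentGenomesError(
            f"anchor chain covers only {anchored_fraction:.2f} of the reference"
        )
    snps = 0
    gaps = 0
    # head segment before the first anchor
    sa, sb = chain[0]
    s, g = _align_segment(region_a[:sa], region_b[:sb])
    snps += s
    gaps += g
    for (pa, pb), (qa, qb) in zip(chain, chain[1:]):
        s, g = _align_segment(region_a[pa + k:qa], region_b[pb + k:qb])
        snps += s
        gaps += g
    la, lb = chain[-1]
    s, g = _align_segment(region_a[la + k:], region_b[lb + k:])
    snps += s
    gaps += g
    return VariantSummary(snp_count=snps, gap_event_count=gaps,
                          anchored_fraction=anchored_fraction)


def compare_genomes(genome_a: GenomeRecord, genome_b: GenomeRecord,
                    map_a: QuadripartiteMap, map_b: QuadripartiteMap,
                    k: int = 20) -> dict[str, VariantSummary]:
    """LSC-vs-LSC and SSC-vs-SSC variant summaries with IRs removed."""
    out = {}
    for region in ("lsc", "ssc"):
        seg_a = _extract(genome_a.seq, getattr(map_a, region))
        seg_b = _extract(genome_b.seq, getattr(map_b, region))
        out[region] = compare_single_copy_regions(seg_a, seg_b, k=k)
    return out
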