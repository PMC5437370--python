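"""Nucleotide diversity, indel-polymorphism diversity, marker screening.

These are the statistics used to screen candidate plastid markers: per
species nucleotide diversity (pi, the mean pairwise p-distance among
conspecific sequences) with a universality threshold, and for markers whose
variation lives in repeats/indels, a multiallelic deletion-insertion
polymorphism (DIP) diversity h = n/(n-1) * (1 - sum p_i^2).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .distance_barcoding import p_distance_pair
from .io_formats import MarkerAlignment, SpeciesMap
from .matrix_prep import _gap_spans


@dataclass
class DiversityResult:
    per_species_pi: dict[str, float]
    mean_pi: float  # unweighted mean over species with >= 2 individuals


@dataclass
class DipResult:
    per_locus_h: dict[tuple[int, int], float]
    mean_dip: Optional[float]  # None when no indel locus exists


def nucleotide_diversity(aln: MarkerAlignment, ids: Sequence[str]) -> float:
    """Mean pairwise p-distance (pairwise deletion) among ``ids``."""
    if len(ids) < 2:
        raise ValueError("nucleotide diversity needs at least two sequences")
    rows = [aln.row(i) for i in ids]
    total = 0.0
    n_pairs = 0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            d = p_distance_pair(rows[i], rows[j])
            if not math.isnan(d):
                total += d
                n_pairs += 1
    if n_pairs == 0:
        return float("nan")
    return total / n_pairs


def per_species_diversity(aln: MarkerAlignment,
                          species_map: SpeciesMap) -> DiversityResult:
    """Per-species pi and its unweighted mean over multi-individual species."""
    per: dict[str, float] = {}
    present = set(aln.ids)
    for sp in species_map.species():
        inds = [i for i in species_map.individuals_of(sp) if i in present]
        if len(inds) >= 2:
            per[sp] = nucleotide_diversity(aln, inds)
    usable = [v for v in per.values() if not math.isnan(v)]
    mean = sum(usable) / len(usable) if usable else float("nan")
    return DiversityResult(per_species_pi=per, mean_pi=mean)


def _indel_loci(rows: dict[str, str]) -> dict[tuple[int, int], dict[str, tuple]]:
    """Group overlapping gap spans into loci; allele = span signature.

    Each locus is the union interval of a connected component of
    overlapping gap spans; an individual's allele at the locus is the tuple
    of its own gap spans falling inside the locus (empty tuple = no gap).
    """
    all_spans = sorted({sp for r in rows.values() for sp in _gap_spans(r)})
    if not all_spans:
        return {}
    loci: list[tuple[int, int]] = []
    cur_s, cur_e = all_spans[0]
    for s, e in all_spans[1:]:
        if s < cur_e:
            cur_e = max(cur_e, e)
        else:
            loci.append((cur_s, cur_e))
            cur_s, cur_e = s, e
    loci.append((cur_s, cur_e))
    out: dict[tuple[int, int], dict[str, tuple]] = {}
    for locus in loci:
        ls, le = locus
        alleles = {}
        for ind, row in rows.items():
            alleles[ind] = tuple(sp for sp in _gap_spans(row)
                                 if sp[0] < le and sp[1] > ls)
        out[locus] = alleles
    return out


def dip_statistic(aln: MarkerAlignment, ids: Sequence[str]) -> DipResult:
    """Multiallelic indel diversity per locus: h = n/(n-1) (1 - sum p_i^2).

    Loci are connected components of overlapping gap spans among ``ids``;
    alleles are the distinct gap configurations at the locus.
    """
    rows = {i: aln.row(i) for i in ids}
    loci = _indel_loci(rows)
    per: dict[tuple[int, int], float] = {}
    n = len(ids)
    for locus, alleles in loci.items():
        counts: dict[tuple, int] = {}
        for allele in alleles.values():
            counts[allele] = counts.get(allele, 0) + 1
        het = 1.0 - sum((c / n) ** 2 for c in counts.values())
        per[locus] = (n / (n - 1)) * het if n > 1 else 0.0
    mean = sum(per.values()) / len(per) if per else None
    return DipResult(per_locus_h=per, mean_dip=mean)


@dataclass
class MarkerScreenInput:
    diversity: DiversityResult
    amplification_success: float  # observed wet-lab input, never computed


def screen_markers(per_marker: dict[str, MarkerScreenInput],
                   pi_threshold: float = 0.0005,
                   success_threshold: float = 0.8
                   ) -> tuple[list[str], dict[str, str]]:
    """Select phylogeography-suitable markers.

    A marker passes when its mean per-species pi exceeds ``pi_threshold``
    and its amplification success (an observed input) is at least
    ``success_threshold``. Returns the selected marker ids and a per-marker
    note explaining each decision.
    """
    selected = []
    notes = {}
    for marker, rec in per_marker.items():
        pi = rec.diversity.mean_pi
        if math.isnan(pi):
            notes[marker] = "rejected: pi not estimable"
            continue
        if pi <= pi_threshold:
            notes[marker] = f"rejected: mean pi {pi:.4g} <= {pi_threshold}"
        elif rec.amplification_success < success_threshold:
            notes[marker] = (
                f"rejected: amplification success "
                f"{rec.amplification_success:.2f} < {success_threshold}"
            )
        else:
            notes[marker] = f"selected: mean pi {pi:.4g}"
            selected.append(marker)
    return selected, notes
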