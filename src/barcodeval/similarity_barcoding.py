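"""Similarity-based barcoding: leave-self-out top-hit classification.

Each individual queries a reference set of aligned sequences; similarity is
the identity fraction over pairwise-shared unambiguous columns (1 minus the
p-distance). A species is identified when every one of its individuals has
its best hit (excluding itself) among conspecifics only; any heterospecific
sequence tied at the top fails the query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field


import numpy as np

from .distance_barcoding import encode_alignment
from .io_formats import MarkerAlignment, SpeciesMap


@dataclass
class TopHitQuery:
    individual: str
    hits: list[tuple[str, float]]  # sorted by score desc, then id asc
    top_conspecific: bool
    tie: bool
    unclassifiable: bool = False


@dataclass
class TopHitResult:
    queries: dict[str, TopHitQuery] = field(default_factory=dict)


def top_hit_classify(query_aln: MarkerAlignment, ref_aln: MarkerAlignment,
                     species_map: SpeciesMap) -> TopHitResult:
    """Rank reference hits for every query individual by identity fraction.

    Query and reference alignments must share a coordinate system (the same
    marker or the same concatenation). The query itself is excluded from
    its own hit list.
    """
    if query_aln.length != ref_aln.length:
        raise ValueError("query and reference alignments have different "
                         "column counts; coordinate systems incompatible")
    q_enc = encode_alignment(query_aln)
    r_enc = encode_alignment(ref_aln)
    q_valid = q_enc >= 0
    r_valid = r_enc >= 0
    result = TopHitResult()
    for qi, qid in enumerate(query_aln.ids):
        both = q_valid[qi] & r_valid
        matches = (q_enc[qi] == r_enc) & both
        shared = both.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            sims = np.where(shared > 0,
                            matches.sum(axis=1) / np.maximum(shared, 1),
                            np.nan)
        hits = [(rid, float(sims[ri]))
                for ri, rid in enumerate(ref_aln.ids)
                if rid != qid and not math.isnan(sims[ri])]
        hits.sort(key=lambda h: (-h[1], h[0]))
        if not hits:
            result.queries[qid] = TopHitQuery(qid, [], False, False,
                                              unclassifiable=True)
            continue
        top_score = hits[0][1]
        top_ids = [rid for rid, s in hits if s == top_score]
        tie = len(top_ids) > 1
        q_species = species_map.species_of(qid)
        top_conspecific = all(
            species_map.species_of(rid) == q_species for rid in top_ids
        )
        result.queries[qid] = TopHitQuery(qid, hits, top_conspecific, tie)
    return result


def score_top_hits(result: TopHitResult, species_map: SpeciesMap,
                   min_individuals: int = 2) -> tuple[float, list[str]]:
    """Identification rate over eligible species.

    A species is identified when every individual's top hit is exclusively
    conspecific. Eligible species have at least ``min_individuals``
    individuals among the queries (with self-exclusion a singleton can
    never match a conspecific, so singletons are excluded by default).
    Rate is a percentage.
    """
    queried = set(result.queries)
    eligible = species_map.eligible_species(min_individuals,
                                            restrict_to=queried)
    identified = []
    for sp in eligible:
        inds = [i for i in species_map.individuals_of(sp) if i in queried]
        if inds and all(result.queries[i].top_conspecific for i in inds):
            identified.append(sp)
    rate = 100.0 * len(identified) / len(eligible) if eligible else 0.0
    return rate, identified
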