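"""Marker-combination enumeration and the four-method discrimination grid.

For every non-empty subset of the available markers the four barcoding
methods are run on the concatenated matrix and their identification rates
collected into a DiscriminationReport. Distance matrices are computed once
per combination and shared between the distance- and tree-based methods.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from itertools import combinations as _combos
from typing import Optional, Sequence

from . import character_barcoding as cb
from . import distance_barcoding as db
from . import similarity_barcoding as sb
from . import tree_barcoding as tb
from .io_formats import MarkerAlignment, SpeciesMap
from .matrix_prep import code_indels

logger = logging.getLogger(__name__)

METHODS = ("distance", "similarity", "character", "tree")


@dataclass
class EvalConfig:
    seed: int = 17
    methods: tuple[str, ...] = METHODS
    code_indels: bool = True
    #: distance-method denominator counts every species (singletons too);
    #: the other methods require multiple individuals per species
    distance_min_individuals: int = 1
    other_min_individuals: int = 2
    #: floor for the partition prior when no intraspecific variation exists
    min_prior: float = 1e-4
    abgd_steps: int = 100
    strict_intersection: bool = False


@dataclass
class ReportRow:
    method: str
    marker_set: tuple[str, ...]
    n_identified: int
    n_eligible: int
    rate: float  # percent
    identified_species: list[str]
    status: str = "ok"


@dataclass
class DiscriminationReport:
    rows: list[ReportRow] = field(default_factory=list)

    def sorted_rows(self) -> list[ReportRow]:
        return sorted(
            self.rows,
            key=lambda r: (r.method, len(r.marker_set), r.marker_set),
        )

    def rate(self, method: str, marker_set: Sequence[str]) -> float:
        key = tuple(sorted(marker_set))
        for r in self.rows:
            if r.method == method and tuple(sorted(r.marker_set)) == key:
                return r.rate
        raise KeyError((method, key))


def enumerate_combinations(markers: Sequence[str]
                           ) -> list[tuple[str, ...]]:
    """All non-empty subsets, ordered by size then lexicographically."""
    markers = list(markers)
    if not markers:
        raise ValueError("empty marker list")
    if len(markers) > 12:
        raise ValueError("more than 12 markers makes 2^n evaluation "
                         "impractical; subset first")
    out: list[tuple[str, ...]] = []
    for size in range(1, len(markers) + 1):
        for c in _combos(sorted(markers), size):
            out.append(c)
    return out


def concatenate(alignments: dict[str, MarkerAlignment],
                subset: Sequence[str],
                strict_intersection: bool = False) -> MarkerAlignment:
    """Concatenate per-marker blocks over the union of individuals.

    Individuals missing a marker are filled with '?' across that block
    (pairwise deletion absorbs the missing data downstream); with
    ``strict_intersection`` only individuals present in every marker are
    kept. Individuals present in no marker of the subset are dropped.
    """
    if not subset:
        raise ValueError("empty marker subset")
    subset = list(subset)
    for m in subset:
        if m not in alignments:
            raise KeyError(f"marker {m!r} not among loaded alignments")
    if strict_intersection:
        ids = [i for i in alignments[subset[0]].ids
               if all(i in a.ids for a in (alignments[m] for m in subset))]
    else:
        seen: dict[str, None] = {}
        for m in subset:
            for i in alignments[m].ids:
                seen.setdefault(i)
        ids = list(seen)
    dropped = []
    kept = []
    for i in ids:
        if any(i in alignments[m].ids for m in subset):
            kept.append(i)
        else:
            dropped.append(i)
    if dropped:
        logger.warning("dropping individuals absent from every marker: %s",
                       dropped)
    rows = []
    for i in kept:
        parts = []
        for m in subset:
            aln = alignments[m]
            if i in aln.ids:
                parts.append(aln.row(i))
            else:
                parts.append("?" * aln.length)
        rows.append("".join(parts))
    marker_id = "+".join(subset)
    return MarkerAlignment(marker_id, kept, rows)


def _run_distance(aln: MarkerAlignment, dm: db.DistanceMatrix,
                  smap: SpeciesMap, cfg: EvalConfig
                  ) -> tuple[float, list[str], int]:
    pairs = db._conspecific_pairs(dm.ids, smap)
    intra = [dm.d[i, j] for i, j in pairs]
    intra = [v for v in intra if v == v]  # drop NaN
    prior = max(max(intra) if intra else 0.0, cfg.min_prior)
    part = db.abgd_partition(dm, prior_P=prior, n_steps=cfg.abgd_steps,
                             species_map=smap)
    eligible = smap.eligible_species(cfg.distance_min_individuals,
                                     restrict_to=set(dm.ids))
    identified = [sp for sp in part.delimited_species if sp in eligible]
    rate = 100.0 * len(identified) / len(eligible) if eligible else 0.0
    return rate, identified, len(eligible)


def evaluate_all(alignments: dict[str, MarkerAlignment],
                 species_map: SpeciesMap,
                 methods: Optional[Sequence[str]] = None,
                 config: Optional[EvalConfig] = None,
                 combinations: Optional[Sequence[Sequence[str]]] = None
                 ) -> DiscriminationReport:
    """Run the requested methods over marker combinations.

    Failures on a single (method, combination) cell are recorded in the
    report row's status and the evaluation continues.
    """
    cfg = config or EvalConfig()
    methods = tuple(methods or cfg.methods)
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    if cfg.code_indels:
        prepared = {m: code_indels(a, species_map)[0]
                    for m, a in alignments.items()}
    else:
        prepared = dict(alignments)
    if combinations is None:
        combinations = enumerate_combinations(list(prepared))
    report = DiscriminationReport()
    for subset in combinations:
        subset = tuple(subset)
        t0 = time.perf_counter()
        cat = concatenate(prepared, subset,
                          strict_intersection=cfg.strict_intersection)
        dm = None
        if {"distance", "tree"} & set(methods):
            dm = db.p_distance_matrix(cat)
        for method in methods:
            try:
                if method == "distance":
                    rate, identified, n_eligible = _run_distance(
                        cat, dm, species_map, cfg)
                elif method == "similarity":
                    hits = sb.top_hit_classify(cat, cat, species_map)
                    rate, identified = sb.score_top_hits(
                        hits, species_map, cfg.other_min_individuals)
                    n_eligible = len(species_map.eligible_species(
                        cfg.other_min_individuals, restrict_to=set(cat.ids)))
                elif method == "character":
                    formulas = cb.induce_formulas(cat, species_map)
                    assignments = cb.classify(formulas, cat)
                    rate, identified = cb.score_classification(
                        assignments, species_map, cfg.other_min_individuals)
                    n_eligible = len(species_map.eligible_species(
                        cfg.other_min_individuals, restrict_to=set(cat.ids)))
                else:  # tree
                    tree = tb.nj_tree(dm)
                    rate, identified, _single = tb.score_tree(
                        tree, species_map, cfg.other_min_individuals)
                    n_eligible = len(species_map.eligible_species(
                        cfg.other_min_individuals, restrict_to=set(cat.ids)))
                report.rows.append(ReportRow(
                    method=method, marker_set=subset,
                    n_identified=len(identified), n_eligible=n_eligible,
                    rate=rate, identified_species=sorted(identified),
                ))
            except (ValueError, KeyError) as exc:
                logger.warning("method %s failed on %s: %s", method, subset,
                               exc)
                report.rows.append(ReportRow(
                    method=method, marker_set=subset, n_identified=0,
                    n_eligible=0, rate=0.0, identified_species=[],
                    status=f"error: {exc}",
                ))
        logger.info("combination %s evaluated in %.2fs", subset,
                    time.perf_counter() - t0)
    return report
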