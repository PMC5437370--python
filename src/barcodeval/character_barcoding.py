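"""Character-based barcoding: induce per-species logic formulas over
(position, state) literals and classify by exclusive satisfaction.

Each species receives a formula in disjunctive normal form. When pure
single-position diagnostics exist they are used directly; otherwise a
greedy set-cover style search grows conjunctions literal by literal under
an asymmetric cost that makes covering a heterospecific individual far more
expensive than excluding a conspecific one (false positives expensive,
false negatives cheap). Training equals testing on the full matrix: the
reference database is verified against itself.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional

from .io_formats import MarkerAlignment, SpeciesMap
from .matrix_prep import STATES, find_diagnostic_characters


@dataclass
class DiagnosticFormula:
    species: str
    dnf: list[list[tuple[int, str]]]  # disjunction of conjunctions
    train_coverage: float
    train_exclusion: float

    @property
    def imperfect(self) -> bool:
        return self.train_exclusion < 1.0 or self.train_coverage < 1.0


def _literal_satisfied(row: str, column: int, state: str) -> bool:
    """Ambiguity codes never satisfy a literal."""
    return row[column] == state


def _conjunction_satisfied(row: str, conj: list[tuple[int, str]]) -> bool:
    return all(_literal_satisfied(row, c, s) for c, s in conj)


def dnf_satisfied(row: str, dnf: list[list[tuple[int, str]]]) -> bool:
    return any(_conjunction_satisfied(row, conj) for conj in dnf)


def induce_formulas(aln: MarkerAlignment, species_map: SpeciesMap,
                    max_literals: int = 3, max_disjuncts: int = 5,
                    pos_weight: float = 50.0, neg_weight: float = 800.0
                    ) -> list[DiagnosticFormula]:
    """Induce one DNF formula per species present in the alignment.

    Species with single-position diagnostics get one single-literal
    disjunct per diagnostic (up to ``max_disjuncts``); the rest get greedy
    conjunctions choosing at each step the literal minimizing
    pos_weight * (conspecifics newly excluded) + neg_weight *
    (heterospecifics still covered), stopping when no heterospecific
    remains covered or ``max_literals`` is reached.
    """
    present = set(aln.ids)
    row_of = dict(zip(aln.ids, aln.rows))
    diagnostics = find_diagnostic_characters(aln, species_map)
    formulas = []
    for sp in species_map.species():
        pos_ids = [i for i in species_map.individuals_of(sp) if i in present]
        if not pos_ids:
            raise ValueError(f"species {sp!r} absent from alignment")
        neg_ids = [i for i in aln.ids if i not in set(pos_ids)]
        diag = diagnostics.get(sp, [])
        if diag:
            dnf = [[lit] for lit in diag[:max_disjuncts]]
        else:
            dnf = _greedy_dnf(aln, row_of, pos_ids, neg_ids, max_literals,
                              max_disjuncts, pos_weight, neg_weight)
        covered = sum(dnf_satisfied(row_of[i], dnf) for i in pos_ids)
        leaked = sum(dnf_satisfied(row_of[i], dnf) for i in neg_ids)
        formulas.append(DiagnosticFormula(
            species=sp,
            dnf=dnf,
            train_coverage=covered / len(pos_ids),
            train_exclusion=1.0 - (leaked / len(neg_ids) if neg_ids else 0.0),
        ))
    return formulas


def _candidate_literals(aln: MarkerAlignment, row_of: dict[str, str],
                        pos_ids: list[str]) -> list[tuple[int, str]]:
    """Literals worth considering: states some conspecific actually has."""
    literals = []
    for c in range(aln.length):
        states = {row_of[i][c] for i in pos_ids} & STATES
        for s in sorted(states):
            literals.append((c, s))
    return literals


def _greedy_dnf(aln: MarkerAlignment, row_of: dict[str, str],
                pos_ids: list[str], neg_ids: list[str], max_literals: int,
                max_disjuncts: int, pos_weight: float, neg_weight: float
                ) -> list[list[tuple[int, str]]]:
    literals = _candidate_literals(aln, row_of, pos_ids)
    dnf: list[list[tuple[int, str]]] = []
    uncovered = list(pos_ids)
    for _ in range(max_disjuncts):
        if not uncovered:
            break
        conj: list[tuple[int, str]] = []
        pos_in = list(uncovered)
        neg_in = list(neg_ids)
        while len(conj) < max_literals and neg_in:
            best = None
            for lit in literals:
                if lit in conj:
                    continue
                c, s = lit
                new_pos = [i for i in pos_in if row_of[i][c] == s]
                if not new_pos:
                    continue  # literal kills every remaining positive
                new_neg = [i for i in neg_in if row_of[i][c] == s]
                cost = (pos_weight * (len(pos_in) - len(new_pos))
                        + neg_weight * len(new_neg))
                key = (cost, len(new_neg), c, s)
                if best is None or key < best[0]:
                    best = (key, lit, new_pos, new_neg)
            if best is None:
                break
            _, lit, pos_in, neg_in = best
            conj.append(lit)
        if not conj:
            break
        dnf.append(conj)
        uncovered = [i for i in uncovered
                     if not _conjunction_satisfied(row_of[i], conj)]
    if not dnf:
        # degenerate fall-back: single most-common literal, likely imperfect
        literals = _candidate_literals(aln, row_of, pos_ids)
        if literals:
            dnf = [[literals[0]]]
    return dnf


def exhaustive_dnf(aln: MarkerAlignment, pos_rows: list[str],
                   neg_rows: list[str], max_literals: int = 2
                   ) -> Optional[list[tuple[int, str]]]:
    """Smallest perfect single conjunction by exhaustive search.

    Test oracle for the greedy search on tiny matrices: returns the first
    (in lexicographic order) conjunction of at most ``max_literals``
    literals covering every positive row and no negative row, or None.
    """
    columns = range(aln.length)
    for k in range(1, max_literals + 1):
        for cols in combinations(columns, k):
            state_sets = []
            for c in cols:
                states = {r[c] for r in pos_rows}
                if len(states) != 1 or not states <= STATES:
                    break
                state_sets.append((c, next(iter(states))))
            else:
                conj = state_sets
                if all(all(r[c] == s for c, s in conj) for r in pos_rows) \
                        and not any(all(r[c] == s for c, s in conj)
                                    for r in neg_rows):
                    return conj
    return None


def classify(formulas: list[DiagnosticFormula], aln: MarkerAlignment
             ) -> dict[str, Optional[str]]:
    """Assign each individual the unique species whose formula it satisfies.

    Zero or multiple satisfied formulas leave the individual unassigned.
    """
    row_of = dict(zip(aln.ids, aln.rows))
    out: dict[str, Optional[str]] = {}
    for ind, row in row_of.items():
        satisfied = [f.species for f in formulas if dnf_satisfied(row, f.dnf)]
        out[ind] = satisfied[0] if len(satisfied) == 1 else None
    return out


def score_classification(assignments: dict[str, Optional[str]],
                         species_map: SpeciesMap,
                         min_individuals: int = 2) -> tuple[float, list[str]]:
    """Percentage of eligible species whose individuals are all assigned
    correctly."""
    assigned = set(assignments)
    eligible = species_map.eligible_species(min_individuals,
                                            restrict_to=assigned)
    identified = []
    for sp in eligible:
        inds = [i for i in species_map.individuals_of(sp) if i in assigned]
        if inds and all(assignments[i] == sp for i in inds):
            identified.append(sp)
    rate = 100.0 * len(identified) / len(eligible) if eligible else 0.0
    return rate, identified
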