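"""Alignment cleaning, simple indel coding, ITS screening, site statistics.

Indel coding follows the simple indel coding (SIC) scheme: every distinct
maximal gap span becomes one binary presence/absence character appended to
the matrix, with '?' scored for rows whose own gap strictly contains the
span (their state at that character is unknowable). Ambiguity codes are
never counted as character states, so heterozygous calls cannot create or
destroy a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .io_formats import IUPAC_SETS, MarkerAlignment, SpeciesMap

#: Unambiguous nucleotide states used for variability and diagnostics.
STATES = frozenset("ACGT")


@dataclass
class CleanPolicy:
    """Column-removal policy for raw alignments.

    max_ambiguous: maximum tolerated fraction of N/? cells per column
        (0 drops any column containing an ambiguous cell).
    polyAT_min: minimum run length for a mononucleotide A or T stretch to
        count as a poly-A/T structure.
    polyAT_frac: fraction of rows that must carry the stretch for the
        columns to be removed.
    """

    max_ambiguous: float = 0.0
    polyAT_min: int = 8
    polyAT_frac: float = 0.5


@dataclass
class IndelCharacter:
    """One simple-indel-coding character: a distinct maximal gap span."""

    span: tuple[int, int]
    presence: dict[str, Optional[bool]]  # id -> True/False/None ('?')
    diagnostic_for: Optional[str] = None


@dataclass
class SiteStats:
    aligned_length: int
    n_variable: int
    n_informative: int
    n_indels: int
    n_diagnostic_indels: int


def clean_alignment(aln: MarkerAlignment,
                    policy: Optional[CleanPolicy] = None
                    ) -> tuple[MarkerAlignment, list[int]]:
    """Drop ambiguous columns and poly-A/T blocks.

    Returns the cleaned alignment and a provenance list mapping each kept
    column to its original coordinate.
    """
    policy = policy or CleanPolicy()
    n, L = aln.n, aln.length
    drop = [False] * L
    for c in range(L):
        ambiguous = sum(1 for r in aln.rows if r[c] in "N?")
        if ambiguous / n > policy.max_ambiguous:
            drop[c] = True
    # poly-A/T: per row, flag positions inside mononucleotide runs of A or T
    run_votes = [0] * L
    for row in aln.rows:
        c = 0
        while c < L:
            ch = row[c]
            if ch in "AT":
                j = c
                while j < L and row[j] == ch:
                    j += 1
                if j - c >= policy.polyAT_min:
                    for p in range(c, j):
                        run_votes[p] += 1
                c = j
            else:
                c += 1
    for c in range(L):
        if run_votes[c] / n >= policy.polyAT_frac:
            drop[c] = True
    kept = [c for c in range(L) if not drop[c]]
    if not kept:
        raise ValueError("cleaning removed every column of the alignment")
    rows = ["".join(r[c] for c in kept) for r in aln.rows]
    return MarkerAlignment(aln.marker_id, list(aln.ids), rows), kept


def _gap_spans(row: str) -> list[tuple[int, int]]:
    spans = []
    c = 0
    L = len(row)
    while c < L:
        if row[c] == "-":
            j = c
            while j < L and row[j] == "-":
                j += 1
            spans.append((c, j))
            c = j
        else:
            c += 1
    return spans


def code_indels(aln: MarkerAlignment,
                species_map: Optional[SpeciesMap] = None
                ) -> tuple[MarkerAlignment, list[IndelCharacter]]:
    """Simple indel coding: append one binary column per distinct gap span.

    Presence is encoded as 'T', absence as 'A', and '?' where a row's own
    gap strictly contains the span. Original gap columns are retained.
    When a species map is given, each character unique to exactly the
    individuals of one species is marked diagnostic for it.
    """
    per_row_spans = {ind: _gap_spans(row)
                     for ind, row in zip(aln.ids, aln.rows)}
    distinct: list[tuple[int, int]] = sorted(
        {sp for spans in per_row_spans.values() for sp in spans}
    )
    characters: list[IndelCharacter] = []
    extra_cols: list[str] = []
    for span in distinct:
        presence: dict[str, Optional[bool]] = {}
        col_chars = []
        for ind in aln.ids:
            spans = per_row_spans[ind]
            if span in spans:
                presence[ind] = True
                col_chars.append("T")
            elif any(s < span[0] and span[1] <= e or
                     s <= span[0] and span[1] < e
                     for s, e in spans):
                presence[ind] = None  # strictly containing gap
                col_chars.append("?")
            else:
                presence[ind] = False
                col_chars.append("A")
        ch = IndelCharacter(span=span, presence=presence)
        if species_map is not None:
            carriers = {i for i, p in presence.items() if p is True}
            for sp in species_map.species():
                inds = set(species_map.individuals_of(sp)) & set(aln.ids)
                if inds and carriers == inds:
                    ch.diagnostic_for = sp
                    break
        characters.append(ch)
        extra_cols.append("".join(col_chars))
    if not characters:
        return aln, []
    rows = [row + "".join(extra_cols[k][i] for k in range(len(extra_cols)))
            for i, row in enumerate(aln.rows)]
    return MarkerAlignment(aln.marker_id, list(aln.ids), rows), characters


@dataclass
class ItsChecks:
    """Screens applied to putative ITS orthologues (pseudogene filtering)."""

    gc_min: float = 45.0
    gc_max: float = 70.0
    motifs_5_8s: list[str] = field(default_factory=list)


def _iupac_match(pattern: str, text: str) -> bool:
    """IUPAC-aware substring search: pattern codes match compatible bases."""
    m, n = len(pattern), len(text)
    for start in range(n - m + 1):
        ok = True
        for p, t in zip(pattern, text[start:start + m]):
            if not (IUPAC_SETS.get(t, frozenset()) &
                    IUPAC_SETS.get(p, frozenset())):
                ok = False
                break
        if ok:
            return True
    return False


def screen_its(aln: MarkerAlignment,
               checks: Optional[ItsChecks] = None) -> dict[str, bool]:
    """Per-individual pass/fail flags for ITS orthology screening.

    A row fails when its GC content (over unambiguous bases) falls outside
    the configured bounds, or when any configured conserved 5.8S motif is
    absent (IUPAC-aware match). An empty motif list passes vacuously.
    """
    checks = checks or ItsChecks()
    flags: dict[str, bool] = {}
    for ind, row in zip(aln.ids, aln.rows):
        bases = [c for c in row if c in STATES]
        if not bases:
            flags[ind] = False
            continue
        gc = 100.0 * sum(c in "GC" for c in bases) / len(bases)
        ok = checks.gc_min <= gc <= checks.gc_max
        if ok:
            ungapped = row.replace("-", "").replace("?", "")
            for motif in checks.motifs_5_8s:
                if not _iupac_match(motif, ungapped):
                    ok = False
                    break
        flags[ind] = ok
    return flags


def site_stats(aln: MarkerAlignment, species_map: SpeciesMap) -> SiteStats:
    """Variable/informative site counts plus indel character counts.

    A column is variable when it shows >= 2 unambiguous nucleotide states;
    parsimony-informative when >= 2 states each occur in >= 2 individuals.
    Gaps and ambiguity codes are not states.
    """
    n_variable = 0
    n_informative = 0
    for c in range(aln.length):
        counts: dict[str, int] = {}
        for r in aln.rows:
            if r[c] in STATES:
                counts[r[c]] = counts.get(r[c], 0) + 1
        if len(counts) >= 2:
            n_variable += 1
            if sum(1 for v in counts.values() if v >= 2) >= 2:
                n_informative += 1
    _, characters = code_indels(aln, species_map)
    n_diag = sum(1 for ch in characters if ch.diagnostic_for is not None)
    return SiteStats(
        aligned_length=aln.length,
        n_variable=n_variable,
        n_informative=n_informative,
        n_indels=len(characters),
        n_diagnostic_indels=n_diag,
    )


def find_diagnostic_characters(aln: MarkerAlignment, species_map: SpeciesMap
                               ) -> dict[str, list[tuple[int, str]]]:
    """Species-specific (column, state) pairs.

    (c, state) is diagnostic for species s iff every individual of s holds
    ``state`` at column c and no individual of any other species does.
    Ambiguity codes neither supply nor match a state (conservative: a
    heterozygote overlapping the state blocks the diagnostic).
    """
    ids_present = set(aln.ids)
    by_species = {
        sp: [i for i in species_map.individuals_of(sp) if i in ids_present]
        for sp in species_map.species()
    }
    by_species = {sp: inds for sp, inds in by_species.items() if inds}
    row_of = dict(zip(aln.ids, aln.rows))
    out: dict[str, list[tuple[int, str]]] = {sp: [] for sp in by_species}
    for c in range(aln.length):
        col = {ind: row_of[ind][c] for ind in aln.ids}
        for sp, inds in by_species.items():
            states = {col[i] for i in inds}
            if len(states) != 1:
                continue
            state = next(iter(states))
            if state not in STATES:
                continue
            blocked = False
            for other_sp, other_inds in by_species.items():
                if other_sp == sp:
                    continue
                for i in other_inds:
                    ch = col[i]
                    if ch == state:
                        blocked = True
                        break
                    # ambiguity overlapping the state blocks conservatively
                    if ch in IUPAC_SETS and state in IUPAC_SETS[ch] and ch not in STATES:
                        blocked = True
                        break
                if blocked:
                    break
            if not blocked:
                out[sp].append((c, state))
    return out
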