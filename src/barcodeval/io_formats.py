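"""Readers and writers for the external formats the pipeline touches.

Sequence parsing is delegated to Biopython; this module adds the domain
containers (genome records, marker alignments, species maps) and the
validation contracts the downstream analyses rely on: uppercase sequences,
equal-length alignment rows, unique identifiers, 0-based half-open
coordinates.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping, Optional, Sequence

from Bio import SeqIO

if TYPE_CHECKING:  # pragma: no cover
    from .evaluation import DiscriminationReport
    from .tree_barcoding import NJTree

logger = logging.getLogger(__name__)

#: IUPAC single-letter nucleotide codes accepted in alignments.
IUPAC_CODES = set("ACGTRYSWKMBDHVN")

#: Mapping of each IUPAC code to the set of bases it may stand for.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"), "C": frozenset("C"), "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"), "Y": frozenset("CT"), "S": frozenset("CG"),
    "W": frozenset("AT"), "K": frozenset("GT"), "M": frozenset("AC"),
    "B": frozenset("CGT"), "D": frozenset("AGT"), "H": frozenset("ACT"),
    "V": frozenset("ACG"), "N": frozenset("ACGT"),
}


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class GenomeRecord:
    """A single (typically circular plastid) genome sequence.

    Annotations are ``(feature_type, start, end, strand, label)`` tuples in
    0-based half-open coordinates; GenBank 1-based closed intervals are
    converted on read.
    """

    id: str
    seq: str
    circular: bool = True
    annotations: list[tuple[str, int, int, int, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.seq:
            raise ValueError("genome sequence is empty")
        self.seq = self.seq.upper().replace("U", "T")
        for ftype, start, end, strand, label in self.annotations:
            if not (0 <= start < end <= len(self.seq)):
                raise ValueError(
                    f"annotation {ftype}:{label} interval [{start},{end}) "
                    f"outside genome of length {len(self.seq)}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class MarkerAlignment:
    """An aligned matrix of individual sequences for one marker.

    Rows are equal-length strings over A/C/G/T, '-', '?', and IUPAC
    ambiguity codes; row order is meaningful and preserved from input.
    """

    marker_id: str
    ids: list[str]
    rows: list[str]

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows differ in length")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ValueError(f"duplicate individual ids: {dupes}")
        if self.rows:
            lengths = {len(r) for r in self.rows}
            if len(lengths) > 1:
                bad = [i for i, r in zip(self.ids, self.rows)
                       if len(r) != len(self.rows[0])]
                raise ValueError(f"ragged alignment rows for ids: {bad}")
            if len(self.rows[0]) == 0:
                raise ValueError("alignment has zero columns")

    @property
    def length(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    @property
    def n(self) -> int:
        return len(self.ids)

    def row(self, individual: str) -> str:
        return self.rows[self.ids.index(individual)]

    def subset(self, ids: Sequence[str]) -> "MarkerAlignment":
        """Alignment restricted to ``ids``, in the given order."""
        idx = {i: k for k, i in enumerate(self.ids)}
        return MarkerAlignment(
            self.marker_id, list(ids), [self.rows[idx[i]] for i in ids]
        )

    def columns(self) -> list[str]:
        return ["".join(r[c] for r in self.rows) for c in range(self.length)]


@dataclass
class SpeciesMap:
    """Binding of individual ids to species, and optionally section/group."""

    entries: dict[str, tuple[str, Optional[str], Optional[str]]]

    def __post_init__(self) -> None:
        for ind, (sp, _sec, _grp) in self.entries.items():
            if not sp:
                raise ValueError(f"empty species name for individual {ind!r}")

    def species_of(self, individual: str) -> str:
        return self.entries[individual][0]

    def section_of(self, individual: str) -> Optional[str]:
        return self.entries[individual][1]

    def group_of(self, individual: str) -> Optional[str]:
        return self.entries[individual][2]

    def species(self) -> list[str]:
        """Distinct species names, in first-appearance order."""
        seen: dict[str, None] = {}
        for sp, _, _ in self.entries.values():
            seen.setdefault(sp)
        return list(seen)

    def individuals_of(self, species: str) -> list[str]:
        return [i for i, (sp, _, _) in self.entries.items() if sp == species]

    def eligible_species(self, min_individuals: int = 2,
                         restrict_to: Optional[Iterable[str]] = None) -> list[str]:
        """Species represented by at least ``min_individuals`` individuals."""
        pool = set(restrict_to) if restrict_to is not None else None
        out = []
        for sp in self.species():
            inds = self.individuals_of(sp)
            if pool is not None:
                inds = [i for i in inds if i in pool]
            if len(inds) >= min_individuals:
                out.append(sp)
        return out


def read_genbank(path: str | Path) -> GenomeRecord:
    """Read a GenBank flat file or single-record FASTA into a GenomeRecord.

    GenBank feature intervals are converted to 0-based half-open; the
    LOCUS-declared length is checked against the sequence.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("LOCUS"):
        try:
            rec = SeqIO.read(str(path), "genbank")
        except ValueError as exc:
            raise FormatError(f"malformed GenBank record in {path}: {exc}") from exc
        annotations = []
        for feat in rec.features:
            if feat.type == "source":
                continue
            label = str(
                feat.qualifiers.get("gene",
                                    feat.qualifiers.get("note", [""]))[0]
            )
            annotations.append(
                (feat.type, int(feat.location.start), int(feat.location.end),
                 feat.location.strand or 1, label)
            )
        circular = rec.annotations.get("topology", "circular") == "circular"
        declared = len(rec.seq)
        genome = GenomeRecord(rec.id, str(rec.seq), circular, annotations)
        if len(genome.seq) != declared:
            raise FormatError(
                f"LOCUS length {declared} != sequence length {len(genome.seq)}"
            )
        return genome
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no FASTA record found in {path}")
    if len(records) > 1:
        raise FormatError(
            f"expected a single FASTA record in {path}, found {len(records)}"
        )
    rec = records[0]
    return GenomeRecord(rec.id, str(rec.seq), circular=True)


def read_fasta_alignment(path: str | Path, marker_id: str) -> MarkerAlignment:
    """Read an aligned FASTA into a MarkerAlignment.

    Row order preserves file order; U is converted to T and '.' to '-'.
    Ragged lengths and duplicate ids are errors.
    """
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"no records in {path}")
    ids = [r.id for r in records]
    rows = [str(r.seq).upper().replace("U", "T").replace(".", "-")
            for r in records]
    bad = [c for row in rows for c in set(row) if c not in IUPAC_CODES | {"-", "?"}]
    if bad:
        raise FormatError(f"unexpected characters in {path}: {sorted(set(bad))}")
    return MarkerAlignment(marker_id, ids, rows)


def write_fasta_alignment(aln: MarkerAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for ind, row in zip(aln.ids, aln.rows):
            fh.write(f">{ind}\n{row}\n")


def read_species_map(path: str | Path) -> SpeciesMap:
    """Read a TSV with header columns individual/species[/section/group]."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        cols = {name: k for k, name in enumerate(header)}
        for required in ("individual", "species"):
            if required not in cols:
                raise FormatError(f"species map missing column {required!r}")
        known = {"individual", "species", "section", "group"}
        unknown = [c for c in header if c not in known]
        if unknown:
            logger.warning("ignoring unknown species-map columns: %s", unknown)
        entries: dict[str, tuple[str, Optional[str], Optional[str]]] = {}
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            ind = fields[cols["individual"]].strip()
            sp = fields[cols["species"]].strip()
            if not sp:
                raise FormatError(f"empty species at line {lineno} of {path}")
            if ind in entries:
                raise FormatError(
                    f"individual {ind!r} appears twice (line {lineno} of {path})"
                )

            def _opt(name: str) -> Optional[str]:
                if name in cols and len(fields) > cols[name]:
                    val = fields[cols[name]].strip()
                    return val or None
                return None

            entries[ind] = (sp, _opt("section"), _opt("group"))
    return SpeciesMap(entries)


def write_species_map(smap: SpeciesMap, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("individual\tspecies\tsection\tgroup\n")
        for ind, (sp, sec, grp) in smap.entries.items():
            fh.write(f"{ind}\t{sp}\t{sec or ''}\t{grp or ''}\n")


def write_newick(tree: "NJTree", path: str | Path,
                 escape: str = "underscore") -> None:
    """Write a tree as Newick with branch lengths and integer support labels.

    ``escape`` controls how leaf names containing whitespace are rendered:
    ``underscore`` replaces spaces, ``quote`` wraps the name in single quotes.
    """
    if escape not in ("underscore", "quote"):
        raise ValueError(f"unknown escape mode {escape!r}")
    with open(path, "w") as fh:
        fh.write(tree.to_newick(escape=escape) + "\n")


def write_report(report: "DiscriminationReport", path: str | Path,
                 format: str = "tsv") -> None:
    """Write a discrimination report as TSV or JSON.

    One row per (method, combination); rows ordered by method, then
    combination size, then lexicographically.
    """
    rows = report.sorted_rows()
    if format == "tsv":
        with open(path, "w") as fh:
            fh.write("method\tmarkers\tn_identified\tn_eligible\trate\t"
                     "identified_species\tstatus\n")
            for r in rows:
                fh.write(
                    f"{r.method}\t{'+'.join(r.marker_set)}\t{r.n_identified}\t"
                    f"{r.n_eligible}\t{r.rate:.6f}\t"
                    f"{';'.join(r.identified_species)}\t{r.status}\n"
                )
    elif format == "json":
        payload = [
            {
                "method": r.method,
                "markers": list(r.marker_set),
                "n_identified": r.n_identified,
                "n_eligible": r.n_eligible,
                "rate": r.rate,
                "identified": list(r.identified_species),
                "status": r.status,
            }
            for r in rows
        ]
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)
    else:
        raise ValueError(f"unknown report format {format!r}")


def read_report_tsv(path: str | Path) -> list[dict]:
    """Read back a TSV report (used for round-trip checks)."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        for line in fh:
            fields = line.rstrip("\n").split("\t")
            rec = dict(zip(header, fields))
            rec["markers"] = tuple(rec["markers"].split("+"))
            rec["n_identified"] = int(rec["n_identified"])
            rec["n_eligible"] = int(rec["n_eligible"])
            rec["rate"] = float(rec["rate"])
            rec["identified_species"] = (
                rec["identified_species"].split(";")
                if rec["identified_species"] else []
            )
            out.append(rec)
    return out
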