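"""Seeded generator of multi-species, multi-marker barcode datasets.

The generator emulates the statistical structure a barcoding study sees:
a star phylogeny of K species, per-species consensus sequences derived
from a common ancestor by Jukes-Cantor-like substitutions at rate
``d_inter`` per site, individuals derived from their consensus at rate
``d_intra``, planted species-diagnostic columns (mutation-masked so they
stay diagnostic), species-specific deletions, optional whole-haplotype
sharing across species for plastid markers (mimicking chloroplast capture
through hybridization or incomplete lineage sorting), and IUPAC
heterozygous sites on nuclear markers.

Everything is reproducible from a single integer seed, and every planted
feature is recorded in a TruthRecord so tests can verify recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field


import numpy as np

from .io_formats import MarkerAlignment, SpeciesMap

_BASES = np.array(list("ACGT"))
_HET_CODE = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("CG"): "S",
    frozenset("AT"): "W", frozenset("GT"): "K", frozenset("AC"): "M",
}


@dataclass
class MarkerSpec:
    marker_id: str
    length: int
    inheritance: str  # plastid | nuclear


@dataclass
class SyntheticConfig:
    n_species: int = 10
    n_individuals: int | list[int] = 5
    markers: list[MarkerSpec] = field(default_factory=lambda: [
        MarkerSpec("pm1", 600, "plastid"),
        MarkerSpec("pm2", 600, "plastid"),
        MarkerSpec("nm1", 600, "nuclear"),
    ])
    d_intra: float = 0.003
    d_inter: float = 0.05
    p_diag: float = 1.0
    indel_rate: float = 0.2   # per (species, marker) chance of a deletion
    indel_len: tuple[int, int] = (3, 10)
    p_share: float = 0.0      # plastid haplotype capture probability
    p_het: float = 0.0        # per-site heterozygosity on nuclear markers
    seed: int = 0
    two_clade: bool = False   # split species into two groups a la
                              # deciduous/evergreen lineages

    def validate(self) -> None:
        for name in ("d_intra", "d_inter", "p_diag", "indel_rate",
                     "p_share", "p_het"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.d_intra > 0.5:
            raise ValueError("d_intra > 0.5 is not a meaningful rate")
        if self.n_species < 2:
            raise ValueError("need at least 2 species")
        for m in self.markers:
            if m.length < 50:
                raise ValueError(f"marker {m.marker_id} shorter than 50 bp")
            if m.inheritance not in ("plastid", "nuclear"):
                raise ValueError(f"unknown inheritance {m.inheritance!r}")

    def individuals_per_species(self) -> list[int]:
        if isinstance(self.n_individuals, int):
            return [self.n_individuals] * self.n_species
        if len(self.n_individuals) != self.n_species:
            raise ValueError("per-species individual list has wrong length")
        return list(self.n_individuals)


@dataclass
class TruthRecord:
    species_of: dict[str, str]
    diagnostics: dict[tuple[str, str], tuple[int, str]]  # (marker, sp) -> (col, state)
    shared_haplotypes: list[tuple[str, str, str]]  # (marker, individual, donor sp)
    indel_spans: dict[tuple[str, str], tuple[int, int]]  # (marker, sp) -> span


def _preset_clean(**overrides) -> SyntheticConfig:
    return SyntheticConfig(**overrides)


def _preset_hybrid(**overrides) -> SyntheticConfig:
    overrides.setdefault("p_share", 0.3)
    return SyntheticConfig(**overrides)


def _preset_gapless(**overrides) -> SyntheticConfig:
    overrides.setdefault("d_intra", 0.02)
    overrides.setdefault("d_inter", 0.03)
    overrides.setdefault("p_diag", 0.2)
    return SyntheticConfig(**overrides)


PRESETS = {
    "clean": _preset_clean,
    "hybrid": _preset_hybrid,
    "gapless": _preset_gapless,
}


def preset_config(name: str, seed: int = 0, **overrides) -> SyntheticConfig:
    if name not in PRESETS:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    overrides["seed"] = seed
    return PRESETS[name](**overrides)


def expected_pairwise_distance(config: SyntheticConfig,
                               relation: str) -> float:
    """Closed-form expected p-distance under the two-step mutation model.

    Each mutation step replaces a site with probability q by one of the
    three alternative bases uniformly. Composing steps with probabilities
    q1 then q2 changes a site with probability
    (1-q1) q2 + q1 (1 - q2/3). Two lineages whose end states each differ
    from the shared start with probability c disagree with probability
    2 c (1-c) + (2/3) c^2 (given both changed, they collide 1/3 of the
    time by symmetry).
    """
    m, D = config.d_intra, config.d_inter
    if relation == "intra":
        c = m
    elif relation == "inter":
        c = (1.0 - D) * m + D * (1.0 - m / 3.0)
    else:
        raise ValueError("relation must be 'intra' or 'inter'")
    return 2.0 * c * (1.0 - c) + (2.0 / 3.0) * c * c


def _mutate(seq: np.ndarray, rate: float, mask: np.ndarray,
            rng: np.random.Generator) -> np.ndarray:
    """Mutate unmasked sites with probability ``rate``, uniform over the
    three alternative bases."""
    out = seq.copy()
    hit = (rng.random(seq.size) < rate) & ~mask
    idx = np.nonzero(hit)[0]
    if idx.size:
        shift = rng.integers(1, 4, size=idx.size)
        out[idx] = (out[idx] + shift) % 4
    return out


def simulate_dataset(config: SyntheticConfig
                     ) -> tuple[dict[str, MarkerAlignment], SpeciesMap,
                                TruthRecord]:
    """Generate aligned marker matrices, a species map, and ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_per = config.individuals_per_species()
    species = [f"sp{k + 1:02d}" for k in range(config.n_species)]
    individuals: list[tuple[str, str]] = []  # (id, species)
    for sp, n_ind in zip(species, n_per):
        for k in range(n_ind):
            individuals.append((f"{sp}_i{k + 1}", sp))

    half = (config.n_species + 1) // 2
    group_of = {sp: ("cladeA" if k < half else "cladeB") if config.two_clade
                else None
                for k, sp in enumerate(species)}
    smap = SpeciesMap({
        ind: (sp, None, group_of[sp]) for ind, sp in individuals
    })
    truth = TruthRecord(species_of=dict(individuals), diagnostics={},
                        shared_haplotypes=[], indel_spans={})

    alignments: dict[str, MarkerAlignment] = {}
    for marker in config.markers:
        L = marker.length
        ancestor = rng.integers(0, 4, size=L)
        mask = np.zeros(L, dtype=bool)  # mutation-masked columns

        # reserve one diagnostic column per species (distinct columns)
        diag_cols: dict[str, tuple[int, int]] = {}
        reserved = rng.choice(L, size=config.n_species, replace=False)
        for sp, col in zip(species, reserved):
            if rng.random() < config.p_diag:
                state = (ancestor[col] + 1 + rng.integers(0, 3)) % 4
                if state == ancestor[col]:
                    state = (state + 1) % 4
                diag_cols[sp] = (int(col), int(state))
                mask[col] = True
                truth.diagnostics[(marker.marker_id, sp)] = (
                    int(col), str(_BASES[state])
                )

        consensus: dict[str, np.ndarray] = {}
        for sp in species:
            cons = _mutate(ancestor, config.d_inter, mask, rng)
            if sp in diag_cols:
                col, state = diag_cols[sp]
                cons[col] = state
            consensus[sp] = cons

        # species-specific deletions at distinct coordinates
        spans: dict[str, tuple[int, int]] = {}
        used = np.zeros(L, dtype=bool)
        for sp in species:
            if rng.random() >= config.indel_rate:
                continue
            length = int(rng.integers(config.indel_len[0],
                                      config.indel_len[1] + 1))
            for _attempt in range(20):
                start = int(rng.integers(0, L - length))
                window = slice(start, start + length)
                if not used[window].any() and not mask[window].any():
                    spans[sp] = (start, start + length)
                    used[window] = True
                    truth.indel_spans[(marker.marker_id, sp)] = spans[sp]
                    break

        ids, rows = [], []
        for ind, sp in individuals:
            source_sp = sp
            if (marker.inheritance == "plastid"
                    and config.p_share > 0
                    and rng.random() < config.p_share):
                donors = [s for s in species if s != sp]
                source_sp = donors[int(rng.integers(0, len(donors)))]
                truth.shared_haplotypes.append(
                    (marker.marker_id, ind, source_sp)
                )
            hap = _mutate(consensus[source_sp], config.d_intra, mask, rng)
            chars = _BASES[hap].copy()
            if marker.inheritance == "nuclear" and config.p_het > 0:
                het_sites = np.nonzero((rng.random(L) < config.p_het)
                                       & ~mask)[0]
                for c in het_sites:
                    own = chars[c]
                    other = str(_BASES[(hap[c] + 1 + rng.integers(0, 3)) % 4])
                    if other == own:
                        other = str(_BASES[(hap[c] + 1) % 4])
                    chars[c] = _HET_CODE[frozenset((own, other))]
            if source_sp in spans:
                s, e = spans[source_sp]
                chars[s:e] = "-"
            ids.append(ind)
            rows.append("".join(chars))
        alignments[marker.marker_id] = MarkerAlignment(marker.marker_id,
                                                       ids, rows)
    return alignments, smap, truth
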