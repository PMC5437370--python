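"""Distance-based barcoding: p-distances, barcode-gap assessment,
threshold partitioning, and intra- vs inter-specific divergence tests.

The partitioning step is a deterministic re-implementation of the barcode
gap discovery idea: given a prior maximum intraspecific divergence, the
threshold is placed at the widest gap in the ranked pairwise distances
above the prior, individuals are clustered by single linkage at that
threshold, and clusters are recursively re-split with geometrically shrunk
priors until stable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .io_formats import MarkerAlignment, SpeciesMap

_CODE = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _CODE[_b] = _i


@dataclass
class DistanceMatrix:
    """Symmetric pairwise p-distance matrix with pairwise deletion.

    ``d`` holds NaN where two sequences share no unambiguously compared
    column; ``shared_sites`` the per-pair count of compared columns.
    """

    ids: list[str]
    d: np.ndarray
    shared_sites: np.ndarray

    def pair(self, a: str, b: str) -> float:
        return float(self.d[self.ids.index(a), self.ids.index(b)])

    def submatrix(self, ids: Sequence[str]) -> "DistanceMatrix":
        idx = np.array([self.ids.index(i) for i in ids])
        return DistanceMatrix(list(ids), self.d[np.ix_(idx, idx)],
                              self.shared_sites[np.ix_(idx, idx)])

    def finite_pair_values(self) -> np.ndarray:
        iu = np.triu_indices(len(self.ids), k=1)
        vals = self.d[iu]
        return vals[~np.isnan(vals)]


@dataclass
class GapAssessment:
    ranked: np.ndarray
    d_intra_max: float
    se: float
    gap_found: bool
    gap_interval: Optional[tuple[float, float]]


@dataclass
class PartitionResult:
    groups: list[frozenset[str]]
    prior_P: float
    delimited_species: list[str]


@dataclass
class DivergenceTestResult:
    t_stat: float
    t_p: float
    w_stat: float
    w_p: float
    mode: str


def encode_alignment(aln: MarkerAlignment) -> np.ndarray:
    """(n, L) int8 matrix: A/C/G/T -> 0..3, everything else -> -1."""
    buf = np.frombuffer(
        "".join(aln.rows).encode("ascii"), dtype=np.uint8
    ).reshape(aln.n, aln.length)
    return _CODE[buf]


def p_distance_pair(row_a: str, row_b: str) -> float:
    """p-distance between two aligned rows under pairwise deletion."""
    a = _CODE[np.frombuffer(row_a.encode("ascii"), dtype=np.uint8)]
    b = _CODE[np.frombuffer(row_b.encode("ascii"), dtype=np.uint8)]
    mask = (a >= 0) & (b >= 0)
    shared = int(mask.sum())
    if shared == 0:
        return float("nan")
    return float((a[mask] != b[mask]).sum()) / shared


def p_distance_matrix(aln: MarkerAlignment) -> DistanceMatrix:
    """All-pairs p-distance with pairwise deletion.

    Only columns where both rows carry an unambiguous A/C/G/T are compared;
    gaps, '?' and IUPAC ambiguity codes are deleted pairwise. Appended
    indel-coded binary columns, when present, participate like ordinary
    sites (they are A/T encoded).
    """
    enc = encode_alignment(aln)
    n = enc.shape[0]
    valid = enc >= 0
    d = np.zeros((n, n))
    shared = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        both = valid[i] & valid[i + 1:]
        mism = (enc[i] != enc[i + 1:]) & both
        s = both.sum(axis=1)
        m = mism.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            row_d = np.where(s > 0, m / np.maximum(s, 1), np.nan)
        d[i, i + 1:] = row_d
        d[i + 1:, i] = row_d
        shared[i, i + 1:] = s
        shared[i + 1:, i] = s
    return DistanceMatrix(list(aln.ids), d, shared)


def _conspecific_pairs(ids: Sequence[str], species_map: SpeciesMap
                       ) -> list[tuple[int, int]]:
    pairs = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if (species_map.species_of(ids[i])
                    == species_map.species_of(ids[j])):
                pairs.append((i, j))
    return pairs


def max_intraspecific(dm: DistanceMatrix, species_map: SpeciesMap,
                      aln: MarkerAlignment, n_boot: int = 1000,
                      seed: int = 0) -> tuple[float, float]:
    """Maximum conspecific p-distance and its column-bootstrap SE.

    The statistic is recomputed on ``n_boot`` alignments obtained by
    resampling columns with replacement; the SE is the standard deviation
    of the replicate statistics.
    """
    pairs = _conspecific_pairs(dm.ids, species_map)
    if not pairs:
        raise ValueError("no conspecific pair available")
    vals = [dm.d[i, j] for i, j in pairs if not math.isnan(dm.d[i, j])]
    if not vals:
        raise ValueError("all conspecific pairs lack shared sites")
    d_max = float(max(vals))

    enc = encode_alignment(aln)
    valid = enc >= 0
    # per-pair mismatch and validity vectors over columns
    mism = np.stack([((enc[i] != enc[j]) & valid[i] & valid[j])
                     for i, j in pairs]).astype(np.float64)
    both = np.stack([(valid[i] & valid[j]) for i, j in pairs]
                    ).astype(np.float64)
    L = enc.shape[1]
    rng = np.random.default_rng(seed)
    reps = np.empty(n_boot)
    for r in range(n_boot):
        idx = rng.integers(0, L, size=L)
        m = mism[:, idx].sum(axis=1)
        s = both[:, idx].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            dd = np.where(s > 0, m / np.maximum(s, 1), np.nan)
        reps[r] = np.nanmax(dd) if not np.all(np.isnan(dd)) else np.nan
    se = float(np.nanstd(reps))
    return d_max, se


def barcode_gap_assess(dm: DistanceMatrix, species_map: SpeciesMap,
                       gap_factor: float = 2.0,
                       d_intra_max: Optional[float] = None,
                       se: float = 0.0) -> GapAssessment:
    """Look for a sudden increase in ranked distances near the maximum
    intraspecific divergence.

    A gap is reported when the widest consecutive step in the ranked list
    straddles the maximum intraspecific distance and exceeds ``gap_factor``
    times the typical step. A barcode gap is the dominant discontinuity of
    the ranked-distance curve, positioned at the intra/inter boundary;
    large steps elsewhere (e.g. in the sparse extreme tail) are ordinary
    order-statistic spacing, not a gap. p-distances tie on a
    1/shared-sites grid, so the typical step is the median of the strictly
    positive consecutive differences.
    """
    ranked = np.sort(dm.finite_pair_values())
    if d_intra_max is None:
        pairs = _conspecific_pairs(dm.ids, species_map)
        intra = [dm.d[i, j] for i, j in pairs if not math.isnan(dm.d[i, j])]
        if not intra:
            raise ValueError("no conspecific pair for gap assessment")
        d_intra_max = float(max(intra))
    diffs = np.diff(ranked)
    gap_found = False
    gap_interval = None
    if diffs.size:
        straddle = (ranked[:-1] <= d_intra_max) & (ranked[1:] > d_intra_max)
        positive = diffs[diffs > 0]
        med = float(np.median(positive)) if positive.size else 0.0
        k = int(np.argmax(diffs))
        if (med > 0 and straddle[k] and diffs[k] > gap_factor * med):
            gap_found = True
            gap_interval = (float(ranked[k]), float(ranked[k + 1]))
    return GapAssessment(ranked=ranked, d_intra_max=d_intra_max, se=se,
                         gap_found=gap_found, gap_interval=gap_interval)


def cluster_at_threshold(dm: DistanceMatrix, threshold: float
                         ) -> list[frozenset[str]]:
    """Single-linkage components linking pairs with d <= threshold.

    NaN distances never link. Monotone: raising the threshold can only
    merge components.
    """
    n = len(dm.ids)
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            dij = dm.d[i, j]
            if not math.isnan(dij) and dij <= threshold:
                parent[find(i)] = find(j)
    comps: dict[int, set[str]] = {}
    for i in range(n):
        comps.setdefault(find(i), set()).add(dm.ids[i])
    return [frozenset(c) for c in comps.values()]


def _threshold_from_prior(values: np.ndarray, prior_P: float
                          ) -> tuple[float, float]:
    """(threshold, gap width) from the widest gap reaching above the prior.

    The ranked distance list is scanned for consecutive pairs whose upper
    member lies strictly above the prior; the threshold is the lower bound
    of the widest such gap (the prior itself acts as lower bound when every
    distance lies above it). Returns (prior, 0) when nothing lies above.
    """
    ranked = np.sort(values)
    above_mask = ranked > prior_P
    if not above_mask.any():
        return prior_P, 0.0
    first_above = int(np.argmax(above_mask))
    candidates: list[tuple[float, float]] = []  # (width, lower bound)
    if first_above == 0:
        candidates.append((float(ranked[0] - prior_P), prior_P))
    for k in range(max(first_above - 1, 0), ranked.size - 1):
        if ranked[k + 1] > prior_P:
            candidates.append((float(ranked[k + 1] - ranked[k]),
                               float(ranked[k])))
    width, T = max(candidates, key=lambda c: (c[0], -c[1]))
    return T, width


def abgd_partition(dm: DistanceMatrix, prior_P: float, n_steps: int = 100,
                   recursive: bool = True,
                   species_map: Optional[SpeciesMap] = None
                   ) -> PartitionResult:
    """Partition individuals into candidate species groups.

    The linkage threshold is the lower bound of the widest gap among ranked
    pairwise distances strictly above the prior maximum intraspecific
    divergence (falling back to the prior itself when no distance exceeds
    it). With ``recursive=True`` each resulting group is re-examined with
    ``n_steps`` geometrically spaced priors in [P/10, P] until the
    partition stabilizes. A split is only accepted when the selected gap is
    wider than the top-level prior: a discontinuity narrower than the
    assumed maximum intraspecific divergence is noise, not a barcode gap.

    A species is delimited when its individuals form exactly one group with
    no individuals of any other species.
    """
    if prior_P <= 0:
        raise ValueError("prior_P must be positive")
    min_gap_width = prior_P

    def _split(sub: DistanceMatrix, priors: Sequence[float]
               ) -> list[frozenset[str]]:
        values = sub.finite_pair_values()
        if values.size == 0 or len(sub.ids) == 1:
            return [frozenset(sub.ids)]
        for P in priors:  # largest prior first
            T, width = _threshold_from_prior(values, P)
            if width <= min_gap_width:
                continue
            comps = cluster_at_threshold(sub, T)
            if len(comps) > 1:
                out: list[frozenset[str]] = []
                for comp in comps:
                    if len(comp) == 1:
                        out.append(comp)
                    else:
                        out.extend(_split(sub.submatrix(sorted(comp)), priors))
                return out
        return [frozenset(sub.ids)]

    if recursive:
        priors = list(np.geomspace(prior_P, prior_P / 10.0, n_steps))
    else:
        priors = [prior_P]
    groups = _split(dm, priors)
    groups.sort(key=lambda g: sorted(g)[0])

    delimited: list[str] = []
    if species_map is not None:
        for sp in species_map.species():
            inds = frozenset(i for i in species_map.individuals_of(sp)
                             if i in set(dm.ids))
            if inds and inds in groups:
                delimited.append(sp)
    return PartitionResult(groups=groups, prior_P=prior_P,
                           delimited_species=delimited)


def intra_inter_tests(dm: DistanceMatrix, species_map: SpeciesMap,
                      grouping: str = "all",
                      mode: str = "pooled") -> DivergenceTestResult:
    """Welch t-test and Wilcoxon rank-sum of intra- vs inter-specific
    divergences.

    ``grouping`` restricts the pairs considered: "section"/"group" keeps
    only pairs within the same section/group. ``pooled`` compares all
    intraspecific against all interspecific pairwise distances;
    ``per_species`` compares per-species maximum intraspecific distance
    against per-species minimum interspecific distance.

    The Wilcoxon statistic is reported as the rank sum W of the
    intraspecific sample (normal approximation, tie-corrected).
    """
    ids = dm.ids
    n = len(ids)

    def _same_grouping(a: str, b: str) -> bool:
        if grouping == "all":
            return True
        if grouping == "section":
            return (species_map.section_of(a) is not None
                    and species_map.section_of(a) == species_map.section_of(b))
        if grouping == "group":
            return (species_map.group_of(a) is not None
                    and species_map.group_of(a) == species_map.group_of(b))
        raise ValueError(f"unknown grouping {grouping!r}")

    intra, inter = [], []
    inter_by_sp: dict[str, list[float]] = {}
    intra_by_sp: dict[str, list[float]] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dij = dm.d[i, j]
            if math.isnan(dij) or not _same_grouping(ids[i], ids[j]):
                continue
            sp_i = species_map.species_of(ids[i])
            sp_j = species_map.species_of(ids[j])
            if sp_i == sp_j:
                intra.append(dij)
                intra_by_sp.setdefault(sp_i, []).append(dij)
            else:
                inter.append(dij)
                inter_by_sp.setdefault(sp_i, []).append(dij)
                inter_by_sp.setdefault(sp_j, []).append(dij)
    if mode == "pooled":
        x, y = intra, inter
    elif mode == "per_species":
        x = [max(v) for sp, v in intra_by_sp.items()]
        y = [min(v) for sp, v in inter_by_sp.items()
             if sp in intra_by_sp]
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if not x or not y:
        raise ValueError(
            f"empty intra or inter distance set under grouping={grouping!r}"
        )
    t_stat, t_p = stats.ttest_ind(x, y, equal_var=False)
    u_stat, w_p = stats.mannwhitneyu(x, y, alternative="two-sided",
                                     method="asymptotic")
    n_x = len(x)
    w_stat = float(u_stat) + n_x * (n_x + 1) / 2.0  # rank sum of sample x
    return DivergenceTestResult(t_stat=float(t_stat), t_p=float(t_p),
                                w_stat=w_stat, w_p=float(w_p), mode=mode)
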