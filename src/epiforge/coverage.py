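"""HLA population coverage and minimal-epitope optimization.

Given a map from epitopes to the HLA alleles they bind (the post-filtration
pairs) and per-population allele frequencies, an individual's "hits" are the
number of distinct epitope/HLA combinations their genotype can present.
Under Hardy-Weinberg equilibrium each locus draws two alleles independently
with the population frequencies (unlisted residual mass acts as a null
allele); a homozygote (a, a) presents the h(a) combinations of allele `a`
once, a heterozygote (a, b) presents h(a) + h(b). Loci are independent, so
the population hit distribution is the convolution of the per-locus
distributions. From it:

    coverage     = P(at least one hit) = 1 - P(0)
    average hit  = E[hits]
    PC90         = interpolated minimum number of combinations recognized by
                   90% of the population: with survival S(n) = P(hits >= n)
                   and n the largest count with S(n) >= 0.9,
                   PC90 = n + (S(n) - 0.9) / (S(n) - S(n+1))

Optimization keeps a minimum-cardinality subset of epitopes whose allele
union is unchanged, so coverage is exactly preserved while the average hit
drops.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .predictors import COVERAGE_UNSUPPORTED_CLASS_II, parse_allele

EpitopeAlleleMap = dict[str, frozenset[str]]

_SUM_TOL = 1e-9


class AlleleFrequencyTable:
    """population -> locus -> {allele name: frequency}.

    Frequencies are per-locus allele frequencies in [0, 1]; each locus may
    sum to less than 1, the residual being unlisted alleles (which can never
    be hit). Allele names are canonicalized on load.
    """

    def __init__(self, data: Mapping[str, Mapping[str, Mapping[str, float]]]):
        self._data: dict[str, dict[str, dict[str, float]]] = {}
        for pop, loci in data.items():
            self._data[pop] = {}
            for locus, freqs in loci.items():
                clean = {}
                for allele, f in freqs.items():
                    f = float(f)
                    if f < 0:
                        raise ValueError(
                            f"negative frequency for {allele} in {pop}/{locus}"
                        )
                    clean[parse_allele(allele).name] = f
                total = sum(clean.values())
                if total > 1.0 + _SUM_TOL:
                    raise ValueError(
                        f"{pop}/{locus}: allele frequencies sum to {total:.6f} > 1"
                    )
                self._data[pop][locus] = clean

    @classmethod
    def from_csv(cls, path: str | Path) -> "AlleleFrequencyTable":
        """Load from a CSV with columns ``population,locus,allele,frequency``."""
        df = pd.read_csv(path)
        data: dict[str, dict[str, dict[str, float]]] = {}
        for _, row in df.iterrows():
            data.setdefault(str(row["population"]), {}).setdefault(
                str(row["locus"]), {}
            )[str(row["allele"])] = float(row["frequency"])
        return cls(data)

    @property
    def populations(self) -> list[str]:
        return sorted(self._data)

    def loci(self, population: str) -> dict[str, dict[str, float]]:
        if population not in self._data:
            raise KeyError(f"unknown population {population!r}")
        return self._data[population]


@dataclass(frozen=True)
class CoverageReport:
    population: str
    coverage: float
    average_hit: float
    pc90: float
    hit_distribution: tuple[float, ...]
    unmatched_alleles: tuple[str, ...] = field(default=())


def _locus_hit_distribution(
    freqs: Mapping[str, float], hits_per_allele: Mapping[str, int]
) -> np.ndarray:
    """Diploid hit distribution at one locus.

    Enumerates ordered pairs of chromosome draws; the residual frequency
    mass is a null allele with zero hits.
    """
    alleles = sorted(freqs)
    f = np.array([freqs[a] for a in alleles], dtype=float)
    h = np.array([hits_per_allele.get(a, 0) for a in alleles], dtype=int)
    residual = 1.0 - float(f.sum())
    alleles_f = np.append(f, max(residual, 0.0))
    alleles_h = np.append(h, 0)
    max_hits = int(alleles_h.max() * 2) if len(alleles_h) else 0
    dist = np.zeros(max_hits + 1)
    for i, fi in enumerate(alleles_f):
        for j, fj in enumerate(alleles_f):
            n = alleles_h[i] if i == j else alleles_h[i] + alleles_h[j]
            dist[n] += fi * fj
    return dist


def pc90_from_distribution(dist: Sequence[float], quantile: float = 0.90) -> float:
    """Interpolated minimum hit count recognized by ``quantile`` of the
    population."""
    dist = np.asarray(dist, dtype=float)
    # S[n] = P(hits >= n); S[0] = 1
    survival = np.concatenate([[1.0], 1.0 - np.cumsum(dist)[:-1], [0.0]])
    survival = np.clip(survival, 0.0, 1.0)
    n = int(np.max(np.nonzero(survival >= quantile)[0]))
    s_n, s_next = survival[n], survival[n + 1]
    if s_n == s_next:  # degenerate plateau; no interpolation possible
        return float(n)
    return float(n + (s_n - quantile) / (s_n - s_next))


def compute_coverage(
    epitope_map: EpitopeAlleleMap,
    freqs: AlleleFrequencyTable,
    population: str,
) -> CoverageReport:
    """Coverage statistics of an epitope/HLA map in one population.

    Map alleles absent from every locus of the population's frequency table
    are reported in ``unmatched_alleles`` (they cannot contribute hits).
    An empty map yields coverage 0 and average hit 0.
    """
    loci = freqs.loci(population)
    hits_per_allele: dict[str, int] = {}
    for peptide, alleles in epitope_map.items():
        if not alleles:
            raise ValueError(f"epitope {peptide!r} has an empty allele set")
        for allele in alleles:
            name = parse_allele(allele).name
            hits_per_allele[name] = hits_per_allele.get(name, 0) + 1
    known = {a for freqs_ in loci.values() for a in freqs_}
    unmatched = tuple(sorted(set(hits_per_allele) - known))

    dist = np.array([1.0])
    for locus in sorted(loci):
        dist = np.convolve(dist, _locus_hit_distribution(loci[locus], hits_per_allele))
    total = dist.sum()
    if total > 0:
        dist = dist / total  # guard rounding; mass is conserved analytically
    coverage = float(1.0 - dist[0])
    average = float(np.arange(len(dist)) @ dist)
    return CoverageReport(
        population=population,
        coverage=coverage,
        average_hit=average,
        pc90=pc90_from_distribution(dist),
        hit_distribution=tuple(float(p) for p in dist),
        unmatched_alleles=unmatched,
    )


def exclude_unsupported_alleles(
    epitope_map: EpitopeAlleleMap,
    unsupported: Iterable[str] | None = None,
) -> tuple[EpitopeAlleleMap, list[tuple[str, str]]]:
    """Drop pairs whose allele the coverage data cannot account for.

    Default list: the packaged Class II alleles missing from the coverage
    tool's data set. Epitopes left with no alleles are dropped entirely.
    Returns the reduced map and a log of every removed (peptide, allele).
    """
    if unsupported is None:
        names = {a.name for a in COVERAGE_UNSUPPORTED_CLASS_II}
    else:
        names = {parse_allele(a).name for a in unsupported}
    reduced: EpitopeAlleleMap = {}
    log: list[tuple[str, str]] = []
    for peptide in sorted(epitope_map):
        kept = set()
        for allele in sorted(epitope_map[peptide]):
            canon = parse_allele(allele).name
            if canon in names:
                log.append((peptide, canon))
            else:
                kept.add(canon)
        if kept:
            reduced[peptide] = frozenset(kept)
    return reduced, log


def optimize_epitope_set(
    epitope_map: EpitopeAlleleMap,
    scores: Mapping[str, float] | None = None,
    exact_limit: int = 20,
) -> tuple[EpitopeAlleleMap, dict]:
    """Minimum epitope subset preserving the full allele union (set cover).

    Coverage in every population is unchanged because the allele union — the
    only thing coverage of "at least one hit" depends on — is preserved,
    while redundant epitopes are removed, reducing the average hit.

    Up to ``exact_limit`` epitopes the search is exhaustive (smallest
    cardinality, ties broken by higher total score then lexicographic
    peptides); above it a greedy largest-gain heuristic with the same
    tie-breaks is used. The mode is recorded in the returned info dict.
    """
    if not epitope_map:
        raise ValueError("cannot optimize an empty epitope map")
    scores = scores or {}
    peptides = sorted(epitope_map)
    universe = sorted(set().union(*epitope_map.values()))
    bit = {a: 1 << i for i, a in enumerate(universe)}
    masks = {
        p: sum(bit[a] for a in epitope_map[p]) for p in peptides
    }
    full = (1 << len(universe)) - 1

    def choose(subset: tuple[str, ...]) -> tuple[float, tuple[str, ...]]:
        return (-sum(scores.get(p, 0.0) for p in subset), subset)

    if len(peptides) <= exact_limit:
        mode = "exact"
        best: tuple[str, ...] | None = None
        for k in range(1, len(peptides) + 1):
            covers = [
                combo
                for combo in itertools.combinations(peptides, k)
                if _union(masks, combo) == full
            ]
            if covers:
                best = min(covers, key=choose)
                break
        assert best is not None  # the full set always covers
    else:
        mode = "greedy"
        chosen: list[str] = []
        covered = 0
        while covered != full:
            # largest uncovered-allele gain; ties by higher score, then name
            cand = min(
                peptides,
                key=lambda p: (
                    -bin(masks[p] & ~covered).count("1"),
                    -scores.get(p, 0.0),
                    p,
                ),
            )
            chosen.append(cand)
            covered |= masks[cand]
        best = tuple(sorted(chosen))
    reduced = {p: epitope_map[p] for p in best}
    info = {
        "mode": mode,
        "n_input": len(peptides),
        "n_retained": len(best),
        "retained": list(best),
        "n_alleles": len(universe),
    }
    return reduced, info


def _union(masks: Mapping[str, int], combo: Iterable[str]) -> int:
    m = 0
    for p in combo:
        m |= masks[p]
    return m


def coverage_table(
    epitope_map: EpitopeAlleleMap,
    freqs: AlleleFrequencyTable,
    populations: Iterable[str] | None = None,
) -> pd.DataFrame:
    """One coverage row per population: coverage %, average hit, PC90."""
    pops = list(populations) if populations is not None else freqs.populations
    rows = []
    for pop in pops:
        rep = compute_coverage(epitope_map, freqs, pop)
        rows.append(
            {
                "population": pop,
                "coverage_pct": 100.0 * rep.coverage,
                "average_hit": rep.average_hit,
                "pc90": rep.pc90,
            }
        )
    return pd.DataFrame(rows)
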