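"""Population coverage against a brute-force genotype-enumeration oracle,
PC90 interpolation, unsupported-allele exclusion, and set-cover optimization."""

import itertools

import numpy as np
import pandas as pd
import pytest

from epiforge.coverage import (
    AlleleFrequencyTable,
    compute_coverage,
    coverage_table,
    exclude_unsupported_alleles,
    optimize_epitope_set,
    pc90_from_distribution,
)


def brute_force_hit_distribution(loci, hits_per_allele):
    """Oracle: enumerate every diploid genotype across loci explicitly.

    ``loci`` maps locus -> {allele: freq}. The residual mass at each locus
    is a null allele with zero hits. Returns P(total hits = n) as a dict.
    """
    per_locus = []
    for freqs in loci.values():
        alleles = list(freqs) + ["<null>"]
        probs = list(freqs.values()) + [1.0 - sum(freqs.values())]
        genotypes = {}
        for (a, pa), (b, pb) in itertools.product(zip(alleles, probs), repeat=2):
            ha = hits_per_allele.get(a, 0)
            hb = hits_per_allele.get(b, 0)
            n = ha if a == b else ha + hb
            genotypes[n] = genotypes.get(n, 0.0) + pa * pb
        per_locus.append(genotypes)
    total = {0: 1.0}
    for genotypes in per_locus:
        new = {}
        for n1, p1 in total.items():
            for n2, p2 in genotypes.items():
                new[n1 + n2] = new.get(n1 + n2, 0.0) + p1 * p2
        total = new
    return total


def _freq_table(loci, population="World"):
    return AlleleFrequencyTable({population: loci})


ALLELE_NAMES = [
    "HLA-A*01:01", "HLA-A*02:01", "HLA-A*03:01",
    "HLA-B*07:02", "HLA-B*08:01", "HLA-B*15:01",
    "HLA-DRB1*01:01", "HLA-DRB1*03:01", "HLA-DRB1*04:01",
]


class TestComputeCoverage:
    def test_single_locus_single_allele_closed_form(self):
        freqs = _freq_table({"A": {"HLA-A*02:01": 0.5}})
        rep = compute_coverage({"PEPTIDE": frozenset(["HLA-A*02:01"])}, freqs, "World")
        assert rep.coverage == pytest.approx(0.75)  # 1 - (1 - 0.5)^2
        assert rep.average_hit == pytest.approx(2 * 0.5 * 0.5 * 1 + 0.25 * 1)

    def test_empty_map_means_zero_coverage(self):
        freqs = _freq_table({"A": {"HLA-A*02:01": 0.5}})
        rep = compute_coverage({}, freqs, "World")
        assert rep.coverage == 0.0
        assert rep.average_hit == 0.0

    def test_homozygote_counts_hits_once(self):
        # one allele at frequency 1: every individual is homozygous
        freqs = _freq_table({"A": {"HLA-A*02:01": 1.0}})
        emap = {
            "PEPA": frozenset(["HLA-A*02:01"]),
            "PEPB": frozenset(["HLA-A*02:01"]),
        }
        rep = compute_coverage(emap, freqs, "World")
        assert rep.average_hit == pytest.approx(2.0)  # h(a)=2, once, not 4
        assert rep.hit_distribution[2] == pytest.approx(1.0)

    def test_distribution_properties(self, rng):
        freqs, emap = _random_instance(rng)
        rep = compute_coverage(emap, freqs, "World")
        assert sum(rep.hit_distribution) == pytest.approx(1.0, abs=1e-9)
        assert rep.coverage == pytest.approx(1 - rep.hit_distribution[0], abs=1e-12)
        mean = sum(n * p for n, p in enumerate(rep.hit_distribution))
        assert rep.average_hit == pytest.approx(mean, abs=1e-9)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            freqs_raw, emap = _random_instance(rng, return_raw=True)
            hits = {}
            for alleles in emap.values():
                for a in alleles:
                    hits[a] = hits.get(a, 0) + 1
            oracle = brute_force_hit_distribution(freqs_raw, hits)
            rep = compute_coverage(emap, _freq_table(freqs_raw), "World")
            for n, p in enumerate(rep.hit_distribution):
                assert p == pytest.approx(oracle.get(n, 0.0), abs=1e-9)

    def test_adding_an_epitope_never_decreases_coverage(self, rng):
        freqs_raw, emap = _random_instance(rng, return_raw=True)
        table = _freq_table(freqs_raw)
        base = compute_coverage(emap, table, "World")
        emap2 = dict(emap)
        emap2["ZZZNEWPEP"] = frozenset([ALLELE_NAMES[0]])
        more = compute_coverage(emap2, table, "World")
        assert more.coverage >= base.coverage - 1e-12
        assert more.average_hit >= base.average_hit - 1e-12

    def test_unmatched_alleles_reported(self):
        freqs = _freq_table({"A": {"HLA-A*02:01": 0.5}})
        rep = compute_coverage(
            {"PEP": frozenset(["HLA-A*02:01", "HLA-B*57:01"])}, freqs, "World"
        )
        assert rep.unmatched_alleles == ("HLA-B*57:01",)

    def test_unknown_population_rejected(self):
        freqs = _freq_table({"A": {"HLA-A*02:01": 0.5}})
        with pytest.raises(KeyError):
            compute_coverage({"P": frozenset(["HLA-A*02:01"])}, freqs, "Mars")


def _random_instance(rng, return_raw=False):
    """<=3 loci, <=3 alleles per locus, small epitope maps."""
    loci_names = ["A", "B", "DR"][: rng.integers(1, 4)]
    pool = {
        "A": ALLELE_NAMES[0:3], "B": ALLELE_NAMES[3:6], "DR": ALLELE_NAMES[6:9],
    }
    freqs_raw = {}
    usable = []
    for locus in loci_names:
        k = int(rng.integers(1, 4))
        alleles = list(rng.choice(pool[locus], size=k, replace=False))
        props = rng.dirichlet(np.ones(k + 1))  # last = residual mass
        freqs_raw[locus] = {a: float(p) for a, p in zip(alleles, props[:-1])}
        usable.extend(alleles)
    emap = {}
    for i in range(int(rng.integers(1, 5))):
        k = int(rng.integers(1, min(3, len(usable)) + 1))
        emap[f"PEP{i}"] = frozenset(rng.choice(usable, size=k, replace=False))
    if return_raw:
        return freqs_raw, emap
    return _freq_table(freqs_raw), emap


class TestPC90:
    def test_printed_class_ii_pair(self):
        """Single-hit coverage 0.8181 interpolates to PC90 ~ 0.55."""
        dist = [1 - 0.8181, 0.8181]
        assert pc90_from_distribution(dist) == pytest.approx(0.1 / 0.1819, abs=1e-4)
        assert round(pc90_from_distribution(dist), 2) == 0.55

    def test_high_coverage_interpolates_above_one(self):
        dist = [0.02, 0.03, 0.95]  # S(2) = 0.95 >= 0.9
        pc90 = pc90_from_distribution(dist)
        assert pc90 == pytest.approx(2 + (0.95 - 0.9) / 0.95)

    def test_survival_definition(self, rng):
        dist = rng.dirichlet(np.ones(6))
        pc90 = pc90_from_distribution(dist)
        survival = [sum(dist[n:]) for n in range(len(dist) + 1)]
        n = int(pc90)
        assert survival[n] >= 0.9 - 1e-12
        if n + 1 < len(survival):
            assert survival[n + 1] <= 0.9 + 1e-12


class TestExcludeUnsupportedAlleles:
    def test_packaged_class_ii_list(self):
        emap = {
            "PEPA": frozenset(["HLA-DRB5*01:01", "HLA-DRB1*03:01"]),
            "PEPB": frozenset(["HLA-DRB5*01:01"]),
        }
        reduced, log = exclude_unsupported_alleles(emap)
        assert reduced == {"PEPA": frozenset(["HLA-DRB1*03:01"])}
        assert ("PEPA", "HLA-DRB5*01:01") in log
        assert ("PEPB", "HLA-DRB5*01:01") in log

    def test_custom_list(self):
        emap = {"PEP": frozenset(["HLA-A*02:01", "HLA-A*01:01"])}
        reduced, log = exclude_unsupported_alleles(emap, ["HLA-A*01:01"])
        assert reduced["PEP"] == frozenset(["HLA-A*02:01"])
        assert log == [("PEP", "HLA-A*01:01")]


def brute_force_min_cover(emap):
    """Oracle: smallest subset whose allele union equals the full union."""
    peptides = sorted(emap)
    universe = frozenset().union(*emap.values())
    for k in range(1, len(peptides) + 1):
        covers = [
            combo
            for combo in itertools.combinations(peptides, k)
            if frozenset().union(*(emap[p] for p in combo)) == universe
        ]
        if covers:
            return k, covers
    raise AssertionError("unreachable")


class TestOptimizeEpitopeSet:
    def test_redundant_epitopes_removed(self):
        emap = {
            "E1": frozenset(["HLA-A*01:01", "HLA-A*02:01"]),
            "E2": frozenset(["HLA-A*01:01"]),
            "E3": frozenset(["HLA-A*02:01"]),
        }
        reduced, info = optimize_epitope_set(emap)
        assert set(reduced) == {"E1"}
        assert info["mode"] == "exact"

    def test_disjoint_single_alleles_all_retained(self):
        emap = {f"E{i}": frozenset([ALLELE_NAMES[i]]) for i in range(4)}
        reduced, _ = optimize_epitope_set(emap)
        assert set(reduced) == set(emap)

    def test_duplicate_allele_sets_keep_one(self):
        emap = {
            "AAA": frozenset(["HLA-A*01:01"]),
            "BBB": frozenset(["HLA-A*01:01"]),
        }
        reduced, _ = optimize_epitope_set(emap)
        assert len(reduced) == 1

    def test_score_tie_break_prefers_higher_score(self):
        emap = {
            "AAA": frozenset(["HLA-A*01:01"]),
            "BBB": frozenset(["HLA-A*01:01"]),
        }
        reduced, _ = optimize_epitope_set(emap, scores={"AAA": 0.1, "BBB": 0.9})
        assert set(reduced) == {"BBB"}

    def test_matches_exhaustive_minimum_cover(self, rng):
        for _ in range(40):
            n = int(rng.integers(2, 9))
            emap = {}
            for i in range(n):
                k = int(rng.integers(1, 4))
                emap[f"P{i}"] = frozenset(
                    rng.choice(ALLELE_NAMES[:6], size=k, replace=False)
                )
            reduced, info = optimize_epitope_set(emap)
            k_min, covers = brute_force_min_cover(emap)
            assert info["n_retained"] == k_min
            assert tuple(sorted(reduced)) in {tuple(sorted(c)) for c in covers}
            # allele union preserved
            assert frozenset().union(*reduced.values()) == frozenset().union(
                *emap.values()
            )

    def test_greedy_mode_above_exact_limit_preserves_union(self, rng):
        emap = {}
        for i in range(30):
            k = int(rng.integers(1, 4))
            emap[f"P{i:02d}"] = frozenset(
                rng.choice(ALLELE_NAMES, size=k, replace=False)
            )
        reduced, info = optimize_epitope_set(emap, exact_limit=20)
        assert info["mode"] == "greedy"
        assert frozenset().union(*reduced.values()) == frozenset().union(
            *emap.values()
        )

    def test_coverage_invariant_under_optimization(self, rng):
        for _ in range(10):
            freqs_raw, emap = _random_instance(rng, return_raw=True)
            table = _freq_table(freqs_raw)
            reduced, _ = optimize_epitope_set(emap)
            before = compute_coverage(emap, table, "World").coverage
            after = compute_coverage(reduced, table, "World").coverage
            assert after == pytest.approx(before, abs=1e-9)


class TestFrequencyTable:
    def test_csv_roundtrip(self, tmp_path):
        df = pd.DataFrame(
            [
                {"population": "World", "locus": "A",
                 "allele": "HLA-A*02:01", "frequency": 0.3},
                {"population": "World", "locus": "A",
                 "allele": "HLA-A*01:01", "frequency": 0.2},
            ]
        )
        path = tmp_path / "freq.csv"
        df.to_csv(path, index=False)
        table = AlleleFrequencyTable.from_csv(path)
        assert table.populations == ["World"]
        assert table.loci("World")["A"]["HLA-A*02:01"] == 0.3

    def test_overfull_locus_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            AlleleFrequencyTable(
                {"World": {"A": {"HLA-A*02:01": 0.7, "HLA-A*01:01": 0.5}}}
            )

    def test_negative_frequency_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            AlleleFrequencyTable({"World": {"A": {"HLA-A*02:01": -0.1}}})

    def test_coverage_table_layout(self):
        freqs = _freq_table({"A": {"HLA-A*02:01": 0.5}})
        out = coverage_table({"PEP": frozenset(["HLA-A*02:01"])}, freqs)
        assert list(out.columns) == [
            "population", "coverage_pct", "average_hit", "pc90",
        ]
        assert out.loc[0, "coverage_pct"] == pytest.approx(75.0)
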