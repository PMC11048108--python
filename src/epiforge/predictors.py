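"""Predicted epitope features behind a uniform backend contract.

In the original workflow binding affinity, immunogenicity, antigenicity,
allergenicity, toxicity and IFN-gamma release come from external web
predictors. Core code never touches the network: backends implement a small
contract, and two are shipped — a deterministic mock (for tests, fixtures and
offline runs) and a precomputed-table backend that replays feature CSVs a
user exported from the real tools.
"""

from __future__ import annotations

import hashlib
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .sequence_mutation import EpitopeCandidate

#: Feature names understood by the contract.
PAIR_FEATURES = ("binding_affinity",)  # vary per (peptide, allele)
EPITOPE_FEATURES = (
    "immunogenicity",
    "antigenicity",
    "allergenicity",
    "toxicity",
    "ifn_gamma",
)
ALL_FEATURES = PAIR_FEATURES + EPITOPE_FEATURES

BINDING_LABELS = ("STRONG", "NORMAL", "WEAK", "N/A")


class PredictionError(KeyError):
    """Missing or unsupported (peptide, allele, feature) request."""


@dataclass(frozen=True)
class HlaAllele:
    """A normalized HLA allele name with its locus and MHC class."""

    name: str
    locus: str  # A, B, DR, DQ, DP
    mhc_class: str  # "I" or "II"

    def __str__(self) -> str:
        return self.name


_CHAIN_RE = re.compile(
    r"^(HLA-)?(A|B|C|DRB[1-9]|DQA1|DQB1|DPA1|DPB1)\*?(\d+):(\d+)$"
)


def _parse_chain(chain: str) -> tuple[str, str]:
    """Return (gene, 'gene*gg:pp') from one chain in any accepted dialect."""
    m = _CHAIN_RE.match(chain.strip())
    if m is None:
        raise ValueError(f"unrecognized HLA chain {chain!r}")
    gene, g1, g2 = m.group(2), m.group(3), m.group(4)
    return gene, f"{gene}*{g1}:{g2}"


def parse_allele(name: str) -> HlaAllele:
    """Normalize an allele name to its canonical reference-set spelling.

    Accepts ``HLA-A*02:01``, ``HLA-A02:01``, ``A*02:01`` and, for
    paired-chain Class II alleles, either chain optionally carrying its own
    ``HLA-`` prefix (``HLA-DQA1*05:01/HLA-DQB1*03:01``).
    """
    parts = name.strip().split("/")
    chains = [_parse_chain(p) for p in parts]
    genes = [g for g, _ in chains]
    canon = "HLA-" + "/".join(c for _, c in chains)
    first = genes[0]
    if first in ("A", "B"):
        if len(chains) != 1:
            raise ValueError(f"Class I allele cannot be paired: {name!r}")
        return HlaAllele(canon, first, "I")
    if first.startswith("DR"):
        if len(chains) != 1:
            raise ValueError(f"DR alleles are single-chain: {name!r}")
        return HlaAllele(canon, "DR", "II")
    if first.startswith("DQ") or first.startswith("DP"):
        if len(chains) != 2:
            raise ValueError(f"DQ/DP alleles are alpha/beta pairs: {name!r}")
        return HlaAllele(canon, first[:2], "II")
    raise ValueError(f"unknown HLA locus in {name!r}")


def _alleles(names: str) -> tuple[HlaAllele, ...]:
    return tuple(parse_allele(n) for n in names.split(", "))


#: 27-allele Class I reference set (HLA-A/B) used for 9/10-mer predictions.
CLASS_I_REFERENCE = _alleles(
    "HLA-A*30:01, HLA-B*40:01, HLA-A*11:01, HLA-A*68:02, HLA-A*02:06, "
    "HLA-A*31:01, HLA-A*02:03, HLA-B*44:03, HLA-A*02:01, HLA-A*01:01, "
    "HLA-A*33:01, HLA-A*23:01, HLA-B*35:01, HLA-B*08:01, HLA-B*15:01, "
    "HLA-B*07:02, HLA-B*53:01, HLA-A*26:01, HLA-A*68:01, HLA-B*57:01, "
    "HLA-A*30:02, HLA-A*24:02, HLA-B*51:01, HLA-B*44:02, HLA-A*32:01, "
    "HLA-A*03:01, HLA-B*58:01"
)

#: 27-allele Class II reference set (DR single-chain, DQ/DP paired) for 15-mers.
CLASS_II_REFERENCE = _alleles(
    "HLA-DRB4*01:01, HLA-DQA1*01:01/DQB1*05:01, HLA-DRB1*03:01, "
    "HLA-DQA1*01:02/DQB1*06:02, HLA-DRB1*13:02, HLA-DRB1*04:05, "
    "HLA-DQA1*05:01/DQB1*02:01, HLA-DRB1*15:01, HLA-DRB1*04:01, "
    "HLA-DRB3*02:02, HLA-DPA1*03:01/DPB1*04:02, HLA-DRB1*07:01, "
    "HLA-DQA1*05:01/DQB1*03:01, HLA-DRB1*12:01, HLA-DRB5*01:01, "
    "HLA-DRB1*08:02, HLA-DPA1*02:01/DPB1*01:01, HLA-DQA1*03:01/DQB1*03:02, "
    "HLA-DRB1*11:01, HLA-DRB1*09:01, HLA-DPA1*02:01/DPB1*05:01, "
    "HLA-DRB1*01:01, HLA-DPA1*02:01/DPB1*14:01, HLA-DPA1*01:03/DPB1*04:01, "
    "HLA-DRB3*01:01, HLA-DPA1*01:03/DPB1*02:01, HLA-DQA1*04:01/DQB1*04:02"
)

#: Class II alleles the downstream population-coverage data set does not
#: carry frequencies for; pairs restricted to these are excluded before
#: coverage analysis. This is every non-DRB1 allele of the reference set.
COVERAGE_UNSUPPORTED_CLASS_II = tuple(
    a for a in CLASS_II_REFERENCE if not a.name.startswith("HLA-DRB1")
)


def reference_set(mhc_class: str) -> tuple[HlaAllele, ...]:
    if mhc_class == "I":
        return CLASS_I_REFERENCE
    if mhc_class == "II":
        return CLASS_II_REFERENCE
    raise ValueError(f"unknown MHC class {mhc_class!r}")


def label_binding_affinity(ba_nM: float) -> str:
    """Bin an IC50 (nM) into STRONG / NORMAL / WEAK / N/A.

    <=50 nM STRONG; (50, 500] NORMAL; (500, 5000] WEAK; >5000 N/A — upper
    bounds inclusive.
    """
    if not ba_nM > 0:
        raise ValueError(f"binding affinity must be positive, got {ba_nM}")
    if ba_nM <= 50:
        return "STRONG"
    if ba_nM <= 500:
        return "NORMAL"
    if ba_nM <= 5000:
        return "WEAK"
    return "N/A"


class MockBackend:
    """Deterministic stand-in for the external predictors.

    Every value is a pure function of ``(seed, peptide, allele, feature)``:
    a stable blake2b hash mapped to uniform [0, 1) and transformed onto each
    tool's documented output scale. Per-epitope features omit the allele from
    the hash key so they are constant across alleles, as the contract
    requires.

    Output scales:

    - binding affinity: log-uniform over [10, 50000] nM
    - immunogenicity: Class I uniform [-0.3, 0.4]; Class II uniform [0, 100]
      (lower = more immunogenic, inverted later during normalization)
    - antigenicity: uniform [-1, 2]
    - allergenicity: uniform [0, 1] (lower = less allergenic)
    - toxicity: "Toxin" with probability ``toxic_rate``, else "Non-Toxin"
    - IFN-gamma: "Positive" with probability ``ifn_positive_rate``
    """

    supported_lengths = (9, 10, 15)
    supported_features = ALL_FEATURES

    def __init__(
        self,
        seed: int = 0,
        toxic_rate: float = 0.1,
        ifn_positive_rate: float = 0.5,
    ) -> None:
        self.seed = int(seed)
        self.toxic_rate = float(toxic_rate)
        self.ifn_positive_rate = float(ifn_positive_rate)

    def _u(self, *key: object) -> float:
        msg = ":".join(str(k) for k in key).encode()
        digest = hashlib.blake2b(msg, digest_size=8).digest()
        return int.from_bytes(digest, "big") / 2**64

    def value(self, peptide: str, allele: HlaAllele, feature: str) -> float | str:
        if feature == "binding_affinity":
            u = self._u(self.seed, peptide, allele.name, feature)
            return math.exp(math.log(10.0) + u * (math.log(50000.0) - math.log(10.0)))
        u = self._u(self.seed, peptide, feature)
        if feature == "immunogenicity":
            if allele.mhc_class == "I":
                return -0.3 + u * 0.7
            return u * 100.0
        if feature == "antigenicity":
            return -1.0 + u * 3.0
        if feature == "allergenicity":
            return u
        if feature == "toxicity":
            return "Toxin" if u < self.toxic_rate else "Non-Toxin"
        if feature == "ifn_gamma":
            return "Positive" if u < self.ifn_positive_rate else "Negative"
        raise PredictionError(f"unsupported feature {feature!r}")


class TableBackend:
    """Replays precomputed feature values from a long-format table.

    Expected columns: ``peptide, allele, feature, value``. Per-epitope
    features may use ``*`` in the allele column to mean "all alleles".
    """

    supported_lengths = (9, 10, 15)

    def __init__(self, table: pd.DataFrame) -> None:
        required = {"peptide", "allele", "feature", "value"}
        missing = required - set(table.columns)
        if missing:
            raise ValueError(f"feature table missing columns {sorted(missing)}")
        self._map: dict[tuple[str, str, str], object] = {}
        for _, row in table.iterrows():
            allele = str(row["allele"]).strip()
            if allele != "*":
                allele = parse_allele(allele).name
            key = (str(row["peptide"]).strip(), allele, str(row["feature"]).strip())
            self._map[key] = row["value"]
        self.supported_features = tuple(
            sorted({k[2] for k in self._map}, key=ALL_FEATURES.index)
        )

    @classmethod
    def from_csv(cls, path: str | Path) -> "TableBackend":
        return cls(pd.read_csv(path))

    def value(self, peptide: str, allele: HlaAllele, feature: str) -> float | str:
        for key in ((peptide, allele.name, feature), (peptide, "*", feature)):
            if key in self._map:
                return self._map[key]
        raise PredictionError(
            f"no precomputed {feature!r} for peptide {peptide!r} / allele "
            f"{allele.name!r}"
        )


def predict(
    backend,
    epitopes: Sequence[EpitopeCandidate],
    alleles: Sequence[HlaAllele],
    features: Iterable[str] = ALL_FEATURES,
) -> pd.DataFrame:
    """Complete feature table over the (epitope, allele) cross product.

    One row per pair, wide columns per requested feature (binding affinity as
    ``binding_affinity_nM``). Raises :class:`PredictionError` if the backend
    cannot supply a requested feature, length or pair.
    """
    features = list(features)
    unsupported = set(features) - set(backend.supported_features)
    if unsupported:
        raise PredictionError(
            f"backend does not support feature(s) {sorted(unsupported)}"
        )
    rows = []
    for ep in epitopes:
        if ep.length not in backend.supported_lengths:
            raise PredictionError(
                f"backend does not support {ep.length}-mer peptides"
            )
        ref = {a.name for a in reference_set(ep.mhc_class)}
        for allele in alleles:
            if allele.mhc_class != ep.mhc_class:
                continue
            if allele.name not in ref:
                raise PredictionError(
                    f"allele {allele.name} not in the Class {ep.mhc_class} "
                    "reference set"
                )
            row = {
                "peptide": ep.peptide,
                "mutation": ep.mutation.token,
                "mhc_class": ep.mhc_class,
                "start": ep.start,
                "allele": allele.name,
            }
            for feat in features:
                col = "binding_affinity_nM" if feat == "binding_affinity" else feat
                row[col] = backend.value(ep.peptide, allele, feat)
            rows.append(row)
    df = pd.DataFrame(rows)
    if not df.empty and "binding_affinity_nM" in df.columns:
        df["binding_label"] = df["binding_affinity_nM"].map(label_binding_affinity)
    return df
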