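"""Synthetic data generation: proteins, mutation lists, training tables and
allele-frequency tables.

Everything here is deterministic in its seed and mirrors the statistical
shape of the real inputs without copying any external database:

- tool scores (immunogenicity/antigenicity/allergenicity) are drawn bimodal,
  clustered near the extremes, as classifier-style predictors produce;
- training-set binding affinities are a 50:50 binder / non-binder mixture
  (log-uniform over 10-500 nM and 2000-50000 nM respectively), as data sets
  assembled from positive and negative assay results are;
- allele frequencies are Dirichlet-distributed per locus with a residual
  mass of unlisted alleles.
"""

from __future__ import annotations

import importlib.resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from ._proptables import AMINO_ACIDS
from .predictors import HlaAllele, reference_set
from .scoring import apply_normalization, fit_normalization
from .sequence_mutation import PointMutation, ProteinRecord, read_mutations_csv


def packaged_mutation_csv_path():
    """Path to the packaged PIK3CA-study mutation list (mutation,cancer_type)."""
    return importlib.resources.files("epiforge.data") / "pik3ca_mutations.csv"


def load_packaged_mutations() -> list[PointMutation]:
    """The 49 distinct PIK3CA point mutations with their cancer annotations."""
    with importlib.resources.as_file(packaged_mutation_csv_path()) as p:
        return read_mutations_csv(p)


def synthetic_protein(
    seed: int,
    length: int = 1100,
    mutations: Sequence[PointMutation] = (),
    protein_id: str = "synthetic-protein",
) -> ProteinRecord:
    """A random protein constrained to carry each mutation's wild-type residue.

    Synthetic stand-in for a real oncogene product: residues are drawn
    uniformly from the 20-letter alphabet, then position ``p`` is overwritten
    with the wild-type residue of every mutation at ``p`` so that
    ``apply_mutation`` succeeds. Raises if two mutations demand different
    wild-type residues at the same position.
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(AMINO_ACIDS), size=length))
    required: dict[int, str] = {}
    for mut in mutations:
        if mut.position > length:
            raise ValueError(
                f"{mut.token} beyond synthetic length {length}"
            )
        prev = required.setdefault(mut.position, mut.wt_residue)
        if prev != mut.wt_residue:
            raise ValueError(
                f"conflicting wild-type residues at position {mut.position}"
            )
    for pos, res in required.items():
        seq[pos - 1] = res
    return ProteinRecord(id=protein_id, sequence="".join(seq))


def _bimodal_scores(rng: np.random.Generator, n: int) -> np.ndarray:
    lo = rng.uniform(0.0, 0.1, n)
    hi = rng.uniform(0.9, 1.0, n)
    return np.where(rng.uniform(0, 1, n) < 0.5, lo, hi)


def _mixture_affinity(rng: np.random.Generator, n: int) -> np.ndarray:
    binder = np.exp(rng.uniform(np.log(10.0), np.log(500.0), n))
    non = np.exp(rng.uniform(np.log(2000.0), np.log(50000.0), n))
    return np.where(rng.uniform(0, 1, n) < 0.5, binder, non)


def random_peptides(
    rng: np.random.Generator, n: int, length: int
) -> list[str]:
    letters = list(AMINO_ACIDS)
    return ["".join(rng.choice(letters, size=length)) for _ in range(n)]


def synthetic_training_table(
    family: str,
    mhc_class: str,
    n: int,
    true_weights: Sequence[float],
    seed: int = 0,
    noise_sd: float = 0.0,
) -> pd.DataFrame:
    """A training table whose outcome follows known weights.

    ``true_weights`` = (b0, b1, b2, b3, b4) act on the *normalized* feature
    scale (alpha, gamma, delta, epsilon), i.e. the scale ``fit_model`` fits
    on, so a fit on the returned table estimates exactly these numbers.
    Logistic tables sample a Bernoulli outcome from the inverse-logit of the
    linear predictor (the label noise is the Bernoulli draw itself); linear
    tables set ``potential`` to the affine value plus Gaussian noise of
    ``noise_sd`` (zero noise makes the fit exact).
    """
    if len(true_weights) != 5:
        raise ValueError("expected five weights (b0..b4)")
    rng = np.random.default_rng(seed)
    length = 15 if mhc_class == "II" else 9
    ref = reference_set(mhc_class)
    table = pd.DataFrame(
        {
            "peptide": random_peptides(rng, n, length),
            "allele": [ref[i].name for i in rng.integers(0, len(ref), n)],
            "immunogenicity": _bimodal_scores(rng, n),
            "antigenicity": _bimodal_scores(rng, n),
            "allergenicity": _bimodal_scores(rng, n),
            "binding_affinity_nM": _mixture_affinity(rng, n),
        }
    )
    params = fit_normalization(table, mhc_class)
    fv = apply_normalization(params, table)
    b0, b1, b2, b3, b4 = true_weights
    eta = (
        b0
        + b1 * fv["alpha"].to_numpy()
        + b2 * fv["gamma"].to_numpy()
        + b3 * fv["delta"].to_numpy()
        + b4 * fv["epsilon"].to_numpy()
    )
    if family == "logistic":
        p = 1.0 / (1.0 + np.exp(-eta))
        table["outcome"] = (rng.uniform(0, 1, n) < p).astype(int)
    elif family == "linear":
        table["potential"] = eta + rng.normal(0.0, noise_sd, n)
    else:
        raise ValueError(f"unknown family {family!r}")
    return table


def synthetic_frequency_table(
    seed: int,
    populations: Iterable[str] = ("World",),
    mhc_class: str = "I",
    listed_fraction: float = 0.85,
) -> pd.DataFrame:
    """Per-population allele frequencies over the reference-set alleles.

    Each locus's listed alleles receive Dirichlet(1) proportions of
    ``listed_fraction`` total mass; the remainder models unlisted alleles,
    so per-locus sums stay below 1 as real frequency tables do. Returns a
    long CSV-shaped frame: ``population,locus,allele,frequency``.
    """
    rng = np.random.default_rng(seed)
    by_locus: dict[str, list[HlaAllele]] = {}
    for a in reference_set(mhc_class):
        by_locus.setdefault(a.locus, []).append(a)
    rows = []
    for pop in populations:
        for locus in sorted(by_locus):
            alleles = by_locus[locus]
            props = rng.dirichlet(np.ones(len(alleles)))
            for allele, p in zip(alleles, props):
                rows.append(
                    {
                        "population": pop,
                        "locus": locus,
                        "allele": allele.name,
                        "frequency": float(listed_fraction * p),
                    }
                )
    return pd.DataFrame(rows)


def random_epitope_allele_map(
    rng: np.random.Generator,
    n_epitopes: int,
    alleles: Sequence[str],
    max_alleles_per_epitope: int = 4,
) -> dict[str, frozenset[str]]:
    """Random epitope -> allele-set map for coverage/set-cover exercises."""
    peptides = random_peptides(rng, n_epitopes, 9)
    out = {}
    for pep in peptides:
        k = int(rng.integers(1, max_alleles_per_epitope + 1))
        chosen = rng.choice(len(alleles), size=min(k, len(alleles)), replace=False)
        out[pep] = frozenset(alleles[i] for i in chosen)
    return out
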