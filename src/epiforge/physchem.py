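"""ProtParam-style physicochemical descriptors, computed natively.

Five descriptors are used downstream: the instability index and N-end-rule
half-life feed the safety/stability filter, while the aliphatic index, GRAVY
and isoelectric point are reported for experimental planning but never
filtered on.
"""

from __future__ import annotations

from dataclasses import dataclass

from ._proptables import (
    ALIPHATIC_COEFF,
    AMINO_ACIDS,
    DIPEPTIDE_INSTABILITY,
    HALF_LIFE_MAMMALIAN_H,
    KYTE_DOOLITTLE,
    PKA_CTERM_BY_RESIDUE,
    PKA_NEGATIVE,
    PKA_NTERM_BY_RESIDUE,
    PKA_POSITIVE,
)

_STANDARD = set(AMINO_ACIDS)


@dataclass(frozen=True)
class PhyschemProfile:
    instability_index: float
    half_life_hours: float
    aliphatic_index: float
    gravy: float
    isoelectric_point: float


def _check(peptide: str, min_len: int = 1) -> str:
    peptide = peptide.upper()
    if len(peptide) < min_len:
        raise ValueError(f"peptide shorter than {min_len} residues")
    bad = set(peptide) - _STANDARD
    if bad:
        raise ValueError(f"non-standard residue(s) {sorted(bad)}")
    return peptide


def instability_index(peptide: str) -> float:
    """Guruprasad dipeptide-weight instability index.

    ``(10 / L) * sum(DIWV(p[i], p[i+1]))`` over consecutive dipeptides.
    Values below 40 predict a stable peptide.
    """
    peptide = _check(peptide, min_len=2)
    total = sum(
        DIPEPTIDE_INSTABILITY[a][b] for a, b in zip(peptide, peptide[1:])
    )
    return (10.0 / len(peptide)) * total


def gravy(peptide: str) -> float:
    """Grand average of hydropathy: mean Kyte-Doolittle value per residue."""
    peptide = _check(peptide)
    return sum(KYTE_DOOLITTLE[a] for a in peptide) / len(peptide)


def aliphatic_index(peptide: str) -> float:
    """Ikai aliphatic index: X_Ala + 2.9 X_Val + 3.9 (X_Ile + X_Leu),
    with X the mole percent of each residue."""
    peptide = _check(peptide)
    n = len(peptide)
    return sum(
        100.0 * peptide.count(res) / n * coeff
        for res, coeff in ALIPHATIC_COEFF.items()
    )


def net_charge(peptide: str, ph: float) -> float:
    """Net charge at ``ph`` under the packaged Bjellqvist pKa set (termini,
    with residue-specific terminal pKas, plus the ionizable side chains
    D, E, C, Y, H, K, R), Henderson-Hasselbalch."""
    peptide = _check(peptide)
    pos = {"Nterm": 1}
    neg = {"Cterm": 1}
    for res in peptide:
        if res in PKA_POSITIVE:
            pos[res] = pos.get(res, 0) + 1
        elif res in PKA_NEGATIVE:
            neg[res] = neg.get(res, 0) + 1
    pos_pka = dict(PKA_POSITIVE)
    neg_pka = dict(PKA_NEGATIVE)
    pos_pka["Nterm"] = PKA_NTERM_BY_RESIDUE.get(peptide[0], pos_pka["Nterm"])
    neg_pka["Cterm"] = PKA_CTERM_BY_RESIDUE.get(peptide[-1], neg_pka["Cterm"])
    charge = 0.0
    for group, count in pos.items():
        charge += count / (1.0 + 10.0 ** (ph - pos_pka[group]))
    for group, count in neg.items():
        charge -= count / (1.0 + 10.0 ** (neg_pka[group] - ph))
    return charge


def isoelectric_point(peptide: str, tol: float = 1e-4) -> float:
    """pH at which the peptide's net charge is zero, by bisection on [0, 14].

    Net charge is strictly decreasing in pH, so bisection converges; the
    bracket is tightened until ``|net_charge| < tol``.
    """
    peptide = _check(peptide)
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        q = net_charge(peptide, mid)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return mid


def half_life(peptide: str) -> float:
    """Mammalian (reticulocyte) N-end-rule half-life in hours.

    A pure lookup on the N-terminal residue; the downstream stability
    filter keeps peptides with half-life above 1 h.
    """
    peptide = _check(peptide)
    return HALF_LIFE_MAMMALIAN_H[peptide[0]]


def profile(peptide: str) -> PhyschemProfile:
    """All five descriptors for one peptide."""
    return PhyschemProfile(
        instability_index=instability_index(peptide),
        half_life_hours=half_life(peptide),
        aliphatic_index=aliphatic_index(peptide),
        gravy=gravy(peptide),
        isoelectric_point=isoelectric_point(peptide),
    )
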