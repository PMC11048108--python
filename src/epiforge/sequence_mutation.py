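"""Protein sequences, missense mutations, and mutation-spanning epitope windows.

Coordinates are 1-based and intervals are closed, matching the conventional
``<WT><pos><MUT>`` mutation notation (e.g. ``E542K`` means the wild-type
glutamate at residue 542 is replaced by lysine).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from ._proptables import AMINO_ACIDS

_STANDARD = set(AMINO_ACIDS)
_MUTATION_RE = re.compile(r"^([A-Za-z])(\d+)([A-Za-z])$")

#: Peptide window lengths presented by each MHC class.
CLASS_I_LENGTHS = (9, 10)
CLASS_II_LENGTHS = (15,)


class MutationError(ValueError):
    """Malformed mutation token or a mutation inconsistent with its protein."""


@dataclass(frozen=True)
class ProteinRecord:
    """A protein identified by ``id`` with an uppercase 20-letter sequence."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        object.__setattr__(self, "sequence", seq)
        if not seq:
            raise ValueError("empty protein sequence")
        bad = set(seq) - _STANDARD
        if bad:
            raise ValueError(f"non-standard residue(s) {sorted(bad)} in {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class PointMutation:
    """A single missense substitution, 1-based.

    ``cancer_types`` carries the cancer subtypes a mutation is annotated with
    in the input list; it does not affect any computation, only report
    grouping.
    """

    wt_residue: str
    position: int
    mut_residue: str
    cancer_types: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "cancer_types", frozenset(self.cancer_types))
        for res in (self.wt_residue, self.mut_residue):
            if res not in _STANDARD:
                raise MutationError(f"non-standard residue {res!r}")
        if self.wt_residue == self.mut_residue:
            raise MutationError(
                f"{self.token}: identity substitution is not a mutation"
            )
        if self.position < 1:
            raise MutationError(f"{self.token}: position must be >= 1")

    @property
    def token(self) -> str:
        return f"{self.wt_residue}{self.position}{self.mut_residue}"


@dataclass(frozen=True)
class EpitopeCandidate:
    """A peptide window on the mutant protein that spans the mutated residue."""

    peptide: str
    mhc_class: str  # "I" or "II"
    start: int  # 1-based on the mutant protein
    mutation: PointMutation

    @property
    def length(self) -> int:
        return len(self.peptide)

    @property
    def end(self) -> int:
        """1-based inclusive end coordinate."""
        return self.start + self.length - 1

    @property
    def mutation_offset(self) -> int:
        """1-based position of the mutated residue within the peptide."""
        return self.mutation.position - self.start + 1


def parse_mutation(token: str, cancer_types: Iterable[str] = ()) -> PointMutation:
    """Parse ``<WT><pos><MUT>`` notation such as ``"E542K"``.

    Raises :class:`MutationError` on malformed tokens, non-standard residues,
    or identity substitutions.
    """
    m = _MUTATION_RE.match(token.strip())
    if m is None:
        raise MutationError(f"malformed mutation token {token!r}")
    wt, pos, mut = m.group(1).upper(), int(m.group(2)), m.group(3).upper()
    return PointMutation(wt, pos, mut, frozenset(cancer_types))


def apply_mutation(protein: ProteinRecord, mut: PointMutation) -> ProteinRecord:
    """Return the mutant protein; verifies the wild-type residue first.

    A wild-type mismatch usually signals the wrong isoform or a stale
    sequence, so it is an error rather than a silent overwrite.
    """
    if not 1 <= mut.position <= len(protein):
        raise MutationError(
            f"{mut.token}: position out of range for {protein.id!r} "
            f"(length {len(protein)})"
        )
    found = protein.sequence[mut.position - 1]
    if found != mut.wt_residue:
        raise MutationError(
            f"{mut.token}: expected {mut.wt_residue} at position {mut.position} "
            f"of {protein.id!r}, found {found}"
        )
    seq = (
        protein.sequence[: mut.position - 1]
        + mut.mut_residue
        + protein.sequence[mut.position :]
    )
    return replace(protein, id=f"{protein.id}_{mut.token}", sequence=seq)


def enumerate_epitopes(
    mutant: ProteinRecord,
    mut: PointMutation,
    lengths: Iterable[int],
    mhc_class_for_length: dict[int, str] | None = None,
) -> list[EpitopeCandidate]:
    """All exact-length windows of ``mutant`` whose span contains the mutation.

    Windows that would run past a terminus are dropped (predictors need
    exact-length peptides), so a mutation within ``L - 1`` residues of an end
    yields fewer than ``L`` windows. Order is deterministic: ascending start,
    then ascending length. Duplicate peptides from sequence repeats are kept
    as distinct candidates (they have distinct coordinates).
    """
    lengths = sorted(set(lengths))
    if not lengths:
        raise ValueError("empty set of window lengths")
    if mhc_class_for_length is None:
        mhc_class_for_length = {9: "I", 10: "I", 15: "II"}
    n = len(mutant)
    out: list[EpitopeCandidate] = []
    for start in range(1, n + 1):
        for length in lengths:
            end = start + length - 1
            if end > n:
                continue
            if not (start <= mut.position <= end):
                continue
            out.append(
                EpitopeCandidate(
                    peptide=mutant.sequence[start - 1 : end],
                    mhc_class=mhc_class_for_length.get(length, "I"),
                    start=start,
                    mutation=mut,
                )
            )
    return out


def read_fasta(path: str | Path, record_id: str | None = None) -> ProteinRecord:
    """Read one record from a FASTA file (first record unless ``record_id``)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    if record_id is None:
        rec = records[0]
    else:
        by_id = {r.id: r for r in records}
        if record_id not in by_id:
            raise KeyError(f"record {record_id!r} not in {path}")
        rec = by_id[record_id]
    return ProteinRecord(id=rec.id, sequence=str(rec.seq))


def write_fasta(protein: ProteinRecord, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f">{protein.id}\n")
        for i in range(0, len(protein.sequence), 60):
            fh.write(protein.sequence[i : i + 60] + "\n")


def read_mutations_csv(path: str | Path) -> list[PointMutation]:
    """Read a mutation list CSV with columns ``mutation,cancer_type``.

    One row per mutation-cancer pair; rows sharing a mutation token are
    merged into a single :class:`PointMutation` with the union of cancer
    types. Order of first appearance is preserved.
    """
    import pandas as pd

    df = pd.read_csv(path)
    if "mutation" not in df.columns:
        raise ValueError(f"{path}: expected a 'mutation' column")
    groups: dict[str, set[str]] = {}
    for _, row in df.iterrows():
        tok = str(row["mutation"]).strip()
        groups.setdefault(tok, set())
        if "cancer_type" in df.columns and not pd.isna(row["cancer_type"]):
            groups[tok].add(str(row["cancer_type"]).strip())
    return [parse_mutation(tok, sorted(cts)) for tok, cts in groups.items()]


def enumerate_for_classes(
    wild_type: ProteinRecord,
    mutations: Sequence[PointMutation],
    mhc_classes: Iterable[str] = ("I", "II"),
) -> list[EpitopeCandidate]:
    """Apply each mutation and enumerate candidate windows for the requested
    MHC classes (9/10-mers for Class I, 15-mers for Class II)."""
    classes = set(mhc_classes)
    lengths: list[int] = []
    if "I" in classes:
        lengths += list(CLASS_I_LENGTHS)
    if "II" in classes:
        lengths += list(CLASS_II_LENGTHS)
    if not lengths:
        raise ValueError("at least one MHC class required")
    out: list[EpitopeCandidate] = []
    for mut in mutations:
        mutant = apply_mutation(wild_type, mut)
        out.extend(enumerate_epitopes(mutant, mut, lengths))
    return out
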