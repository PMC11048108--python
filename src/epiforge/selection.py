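"""Ranking and individual-variable filtration of scored epitope/HLA pairs.

The unit of selection is the epitope/HLA pair. Pairs are ranked per point
mutation (and per MHC class, since the two classes use different scoring
functions), the top ``k`` survive, and the survivors are then filtered on
safety/stability criteria:

    instability index < 40, half-life > 1 h, non-toxic, and — for Class II
    only — predicted IFN-gamma release positive.

Aliphatic index, GRAVY and isoelectric point are reported but never
filtered. Thresholds are strict: a pair at exactly 40 / exactly 1 h is
excluded. Because filtration runs after the top-k cut, a mutation can end
with zero surviving pairs.
"""

from __future__ import annotations

import pandas as pd

GROUP_KEYS = ["mutation", "mhc_class"]
#: total tie-break order: best probability, then strongest binder, then name
_SORT = ["probability", "binding_affinity_nM", "peptide", "allele"]
_ASC = [False, True, True, True]


def rank_top_k(scored: pd.DataFrame, k: int = 20) -> pd.DataFrame:
    """Keep the ``k`` highest-probability pairs per (mutation, MHC class).

    Ties are broken by lower binding affinity, then lexicographic peptide,
    then allele name — a total order, so the result is identical for any
    input row ordering. Ranks are assigned 1..k within each group.
    """
    required = set(GROUP_KEYS + _SORT)
    missing = required - set(scored.columns)
    if missing:
        raise ValueError(f"scored table missing columns {sorted(missing)}")
    if scored.empty:
        out = scored.copy()
        out["rank"] = pd.Series(dtype=int)
        return out
    df = scored.sort_values(
        GROUP_KEYS + _SORT,
        ascending=[True, True] + _ASC,
        kind="mergesort",
    )
    df = df.groupby(GROUP_KEYS, sort=True).head(k).copy()
    df["rank"] = df.groupby(GROUP_KEYS, sort=True).cumcount() + 1
    return df.reset_index(drop=True)


_FILTER_COLS = ["instability_index", "half_life_hours", "toxicity"]


def filter_epitopes(ranked: pd.DataFrame, mhc_class: str | None = None) -> pd.DataFrame:
    """Apply the exclusion criteria to ranked pairs, preserving rank order.

    ``mhc_class`` restricts the table to one class first; with the default
    ``None`` each row is filtered under its own class's rules (the IFN-gamma
    requirement applies only to Class II rows). Idempotent, and always a
    subset of its input.
    """
    df = ranked if mhc_class is None else ranked[ranked["mhc_class"] == mhc_class]
    missing = set(_FILTER_COLS) - set(df.columns)
    if missing:
        raise ValueError(f"missing filtration annotation(s) {sorted(missing)}")
    if (df["mhc_class"] == "II").any() and "ifn_gamma" not in df.columns:
        raise ValueError("Class II rows require an 'ifn_gamma' annotation")
    keep = (
        (df["instability_index"] < 40.0)
        & (df["half_life_hours"] > 1.0)
        & (df["toxicity"] == "Non-Toxin")
    )
    if "ifn_gamma" in df.columns:
        keep &= (df["mhc_class"] != "II") | (df["ifn_gamma"] == "Positive")
    return df[keep].copy()


def collapse_to_peptides(pairs: pd.DataFrame) -> pd.DataFrame:
    """Per-peptide report view: one row per (mutation, class, peptide) with
    its allele list and best (lowest) rank."""
    if pairs.empty:
        return pairs.copy()
    return (
        pairs.groupby(GROUP_KEYS + ["peptide"], sort=True)
        .agg(
            alleles=("allele", lambda s: ", ".join(sorted(s))),
            n_alleles=("allele", "nunique"),
            best_rank=("rank", "min"),
            probability=("probability", "max"),
        )
        .reset_index()
    )
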