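"""End-to-end pipeline: enumerate -> predict -> score -> rank -> filter ->
coverage -> optimize -> report.

The pipeline is the headless equivalent of the original GUI workflow. All
randomness flows from the single config seed; with a fixed seed and the same
inputs the CSV outputs are byte-identical between runs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__
from .coverage import (
    AlleleFrequencyTable,
    compute_coverage,
    coverage_table,
    exclude_unsupported_alleles,
    optimize_epitope_set,
)
from .physchem import profile
from .predictors import (
    ALL_FEATURES,
    MockBackend,
    TableBackend,
    predict,
    reference_set,
)
from .scoring import (
    PUBLISHED_MODELS,
    ScoringModel,
    apply_normalization,
    fit_normalization,
    score,
)
from .selection import filter_epitopes, rank_top_k
from .sequence_mutation import (
    PointMutation,
    ProteinRecord,
    enumerate_for_classes,
    read_fasta,
    read_mutations_csv,
)

logger = logging.getLogger("epiforge")


@dataclass
class PipelineConfig:
    """Everything a pipeline run depends on.

    ``protein`` may be a :class:`ProteinRecord`, a raw sequence string, or a
    FASTA path. ``mutations`` may be a list of :class:`PointMutation` or a
    mutations CSV path. ``models`` maps MHC class to a :class:`ScoringModel`
    (default: the published logistic weights for each class, with
    normalization fitted on the collected candidate features).
    """

    protein: ProteinRecord | str | Path
    mutations: Sequence[PointMutation] | str | Path
    mhc_classes: tuple[str, ...] = ("I", "II")
    features: tuple[str, ...] = ALL_FEATURES
    backend: object | None = None  # default: MockBackend(seed)
    seed: int = 0
    models: Mapping[str, ScoringModel] | None = None
    top_k: int = 20
    drop_na_pairs: bool = True  # drop binding label "N/A" (>5000 nM)
    apply_filters: bool = True
    frequency_table: AlleleFrequencyTable | str | Path | None = None
    populations: tuple[str, ...] | None = None
    output_dir: str | Path | None = None

    def __post_init__(self) -> None:
        if not self.mhc_classes:
            raise ValueError("at least one MHC class required")


@dataclass
class PipelineResult:
    candidates: pd.DataFrame
    scored: pd.DataFrame
    ranked: pd.DataFrame
    filtered: pd.DataFrame
    epitope_maps: dict[str, dict[str, frozenset[str]]]
    optimized_maps: dict[str, dict[str, frozenset[str]]]
    optimization_logs: dict[str, dict]
    coverage_filtered: pd.DataFrame | None
    coverage_optimized: pd.DataFrame | None
    exclusion_log: list[tuple[str, str]]
    manifest: dict


def _resolve_protein(spec: ProteinRecord | str | Path) -> ProteinRecord:
    if isinstance(spec, ProteinRecord):
        return spec
    text = str(spec)
    if set(text.upper()) <= set("ACDEFGHIKLMNPQRSTVWY") and not Path(text).exists():
        return ProteinRecord(id="input-sequence", sequence=text)
    return read_fasta(text)


def _resolve_mutations(spec) -> list[PointMutation]:
    if isinstance(spec, (str, Path)):
        return read_mutations_csv(spec)
    return list(spec)


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Execute the full pipeline and (optionally) write the report bundle."""
    protein = _resolve_protein(config.protein)
    mutations = _resolve_mutations(config.mutations)
    backend = config.backend or MockBackend(seed=config.seed)
    models = dict(config.models or {})
    for cls in config.mhc_classes:
        models.setdefault(
            cls, PUBLISHED_MODELS[f"published-class{1 if cls == 'I' else 2}-logistic"]
        )
    counts: dict[str, int] = {"mutations": len(mutations)}
    warnings_log: list[str] = []

    # 1. enumerate mutation-spanning candidates
    candidates = enumerate_for_classes(protein, mutations, config.mhc_classes)
    counts["candidate_windows"] = len(candidates)
    logger.info("enumerated %d candidate windows", len(candidates))

    # 2. predict features over the reference-set cross product
    frames = []
    for cls in config.mhc_classes:
        eps = [c for c in candidates if c.mhc_class == cls]
        if not eps:
            continue
        frames.append(predict(backend, eps, list(reference_set(cls)), config.features))
    pairs = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=["peptide", "mutation", "mhc_class", "allele"])
    )
    counts["predicted_pairs"] = len(pairs)

    # 3. drop non-binder pairs (binding label N/A, >5000 nM)
    if config.drop_na_pairs and "binding_label" in pairs.columns and len(pairs):
        before = len(pairs)
        pairs = pairs[pairs["binding_label"] != "N/A"].reset_index(drop=True)
        counts["binder_pairs"] = len(pairs)
        logger.info("dropped %d non-binder pairs (>5000 nM)", before - len(pairs))

    # 4. score per class (normalization fitted on the collected features)
    scored_frames = []
    for cls in config.mhc_classes:
        sub = pairs[pairs["mhc_class"] == cls].copy()
        if sub.empty:
            continue
        model = models[cls]
        if model.normalization is not None:
            params = model.normalization
        else:
            params = fit_normalization(sub, cls)
        fv = apply_normalization(params, sub)
        sub[["alpha", "gamma", "delta", "epsilon"]] = fv
        sub["probability"] = score(model, fv)
        scored_frames.append(sub)
    scored = (
        pd.concat(scored_frames, ignore_index=True) if scored_frames else pairs.copy()
    )
    counts["scored_pairs"] = len(scored)

    # 5. rank top-k per (mutation, class)
    ranked = rank_top_k(scored, k=config.top_k) if len(scored) else scored
    counts["ranked_pairs"] = len(ranked)

    # 6. physchem annotation + safety filtration
    if len(ranked):
        profiles = {p: profile(p) for p in ranked["peptide"].unique()}
        for attr in (
            "instability_index",
            "half_life_hours",
            "aliphatic_index",
            "gravy",
            "isoelectric_point",
        ):
            ranked[attr] = ranked["peptide"].map(
                lambda p, a=attr: getattr(profiles[p], a)
            )
    filtered = filter_epitopes(ranked) if config.apply_filters and len(ranked) else ranked
    counts["filtered_pairs"] = len(filtered)
    mutations_with = (
        filtered.groupby("mhc_class")["mutation"].nunique().to_dict()
        if len(filtered)
        else {}
    )
    counts.update(
        {f"mutations_with_class_{k}_epitopes": int(v) for k, v in mutations_with.items()}
    )

    # 7. epitope/allele maps; Class II coverage-unsupported exclusion
    epitope_maps: dict[str, dict[str, frozenset[str]]] = {}
    exclusion_log: list[tuple[str, str]] = []
    for cls in config.mhc_classes:
        sub = filtered[filtered["mhc_class"] == cls] if len(filtered) else filtered
        if len(sub) == 0:
            continue
        emap = {
            pep: frozenset(grp["allele"])
            for pep, grp in sub.groupby("peptide", sort=True)
        }
        if cls == "II":
            emap, log = exclude_unsupported_alleles(emap)
            exclusion_log.extend(log)
        if emap:
            epitope_maps[cls] = emap
    counts["excluded_unsupported_pairs"] = len(exclusion_log)

    # 8. optimize each class's map (minimum epitopes, same allele union)
    optimized_maps: dict[str, dict[str, frozenset[str]]] = {}
    optimization_logs: dict[str, dict] = {}
    for cls, emap in epitope_maps.items():
        scores_by_pep = (
            filtered[filtered["mhc_class"] == cls]
            .groupby("peptide")["probability"]
            .max()
            .to_dict()
        )
        optimized_maps[cls], optimization_logs[cls] = optimize_epitope_set(
            emap, scores=scores_by_pep
        )

    # 9. population coverage, filtered and optimized
    cov_filtered = cov_optimized = None
    freqs = config.frequency_table
    if isinstance(freqs, (str, Path)):
        freqs = AlleleFrequencyTable.from_csv(freqs)
    if freqs is not None and epitope_maps:
        rows_f, rows_o = [], []
        pops = list(config.populations or freqs.populations)
        for cls, emap in epitope_maps.items():
            tf = coverage_table(emap, freqs, pops)
            tf.insert(0, "mhc_class", cls)
            rows_f.append(tf)
            to = coverage_table(optimized_maps[cls], freqs, pops)
            to.insert(0, "mhc_class", cls)
            rows_o.append(to)
        cov_filtered = pd.concat(rows_f, ignore_index=True)
        cov_optimized = pd.concat(rows_o, ignore_index=True)

    manifest = {
        "version": __version__,
        "seed": config.seed,
        "mhc_classes": list(config.mhc_classes),
        "top_k": config.top_k,
        "protein_id": protein.id,
        "protein_length": len(protein),
        "backend": type(backend).__name__,
        "models": {cls: models[cls].name or "fitted" for cls in config.mhc_classes},
        "counts": counts,
        "optimization": optimization_logs,
        "warnings": warnings_log,
        "outputs": {},
    }

    result = PipelineResult(
        candidates=pd.DataFrame(
            [
                {
                    "peptide": c.peptide,
                    "mutation": c.mutation.token,
                    "mhc_class": c.mhc_class,
                    "start": c.start,
                    "length": c.length,
                }
                for c in candidates
            ]
        ),
        scored=scored,
        ranked=ranked,
        filtered=filtered,
        epitope_maps=epitope_maps,
        optimized_maps=optimized_maps,
        optimization_logs=optimization_logs,
        coverage_filtered=cov_filtered,
        coverage_optimized=cov_optimized,
        exclusion_log=exclusion_log,
        manifest=manifest,
    )
    if config.output_dir is not None:
        write_outputs(result, config, Path(config.output_dir))
    return result


def _cancer_types_of(mutations: Sequence[PointMutation]) -> dict[str, list[str]]:
    return {m.token: sorted(m.cancer_types) for m in mutations}


def write_outputs(
    result: PipelineResult, config: PipelineConfig, outdir: Path
) -> None:
    """Write CSV mirrors, xlsx workbooks, coverage reports and the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    mutations = _resolve_mutations(config.mutations)
    cancer_of = _cancer_types_of(mutations)

    def save_csv(df: pd.DataFrame, name: str) -> None:
        path = outdir / name
        df.to_csv(path, index=False)
        result.manifest["outputs"][name] = _digest(path)

    final = result.filtered.copy()
    if len(final):
        final["cancer_types"] = final["mutation"].map(
            lambda m: "; ".join(cancer_of.get(m, []))
        )
    save_csv(result.candidates, "candidates.csv")
    save_csv(result.ranked, "ranked_pairs.csv")
    save_csv(final, "final_epitopes.csv")
    if result.coverage_filtered is not None:
        save_csv(result.coverage_filtered, "coverage_filtered.csv")
        save_csv(result.coverage_optimized, "coverage_optimized.csv")
    if result.exclusion_log:
        save_csv(
            pd.DataFrame(result.exclusion_log, columns=["peptide", "allele"]),
            "excluded_unsupported_pairs.csv",
        )

    # xlsx workbook: one sheet per cancer type plus a per-mutation summary
    xlsx = outdir / "final_epitopes.xlsx"
    with pd.ExcelWriter(xlsx, engine="openpyxl") as writer:
        if len(final):
            all_cancers = sorted({c for cts in cancer_of.values() for c in cts})
            for cancer in all_cancers:
                toks = [t for t, cts in cancer_of.items() if cancer in cts]
                sheet = final[final["mutation"].isin(toks)]
                name = cancer[:31].replace("/", "-")
                sheet.to_excel(writer, sheet_name=name or "epitopes", index=False)
        else:
            final.to_excel(writer, sheet_name="epitopes", index=False)
    result.manifest["outputs"]["final_epitopes.xlsx"] = _digest(xlsx)

    opt_rows = [
        {"mhc_class": cls, **log} for cls, log in result.optimization_logs.items()
    ]
    (outdir / "optimization_log.json").write_text(
        json.dumps(opt_rows, indent=2, default=list) + "\n"
    )
    (outdir / "manifest.json").write_text(
        json.dumps(result.manifest, indent=2, sort_keys=True) + "\n"
    )
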