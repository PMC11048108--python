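"""Immunogenicity scoring: training-data cleaning, feature normalization,
linear and probabilistic-logistic scoring functions, fitting and CV.

The score of an epitope is a function of four predicted features:

    alpha   immunogenicity   (z-score then min-max to [0, 1])
    gamma   antigenicity     (z-score then min-max to [0, 1])
    delta   allergenicity    (z-score then min-max, then inverted: 1 - x)
    epsilon ln(binding affinity in nM), no further rescaling

Class II immunogenicity is also inverted because its source tool scores
more-immunogenic peptides lower. The logistic family models the log-odds
``pi* = b0 + b1*alpha + b2*gamma + b3*delta + b4*epsilon`` of a positive
T-cell response and reports the inverse-logit probability; the linear family
reports the affine value as-is (an unclamped "potential").

Published fitted weights for both families and both MHC classes ship as
named constant models so scoring works without retraining.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression
from sklearn.metrics import r2_score, roc_auc_score
from sklearn.model_selection import KFold, ShuffleSplit

from ._proptables import AMINO_ACIDS
from .predictors import reference_set, parse_allele

_STANDARD = set(AMINO_ACIDS)

#: raw feature column -> scored-feature name
RAW_FEATURES = {
    "immunogenicity": "alpha",
    "antigenicity": "gamma",
    "allergenicity": "delta",
    "binding_affinity_nM": "epsilon",
}
MINMAX_FEATURES = ("immunogenicity", "antigenicity", "allergenicity")


class DegenerateFitError(ValueError):
    """Training data cannot identify the model (constant outcome, singular
    design, ...)."""


def clean_training_data(raw: pd.DataFrame, mhc_class: str) -> pd.DataFrame:
    """Apply the training-set cleaning rules.

    Class I keeps only 9/10-mers; Class II truncates longer peptides to
    their first 15 residues and keeps exact 15-mers. Peptides with
    non-standard letters and rows whose MHC restriction is outside the
    27-allele reference set are dropped. Input row order is preserved for
    the survivors (deterministic output).
    """
    df = raw.copy()
    df["peptide"] = df["peptide"].astype(str).str.strip().str.upper()
    if mhc_class == "II":
        df["peptide"] = df["peptide"].str.slice(0, 15)
        keep_len = df["peptide"].str.len() == 15
    elif mhc_class == "I":
        keep_len = df["peptide"].str.len().isin((9, 10))
    else:
        raise ValueError(f"unknown MHC class {mhc_class!r}")
    standard = df["peptide"].map(lambda p: set(p) <= _STANDARD)
    ref = {a.name for a in reference_set(mhc_class)}

    def in_ref(name: object) -> bool:
        try:
            return parse_allele(str(name)).name in ref
        except ValueError:
            return False

    keep_allele = df["allele"].map(in_ref)
    out = df[keep_len & standard & keep_allele].reset_index(drop=True)
    out["allele"] = out["allele"].map(lambda a: parse_allele(str(a)).name)
    return out


def potential_from_assays(
    tested: int, responded: int, prior: tuple[float, float] = (1.0, 1.0)
) -> float:
    """Immunogenic potential from T-cell assay counts.

    Posterior mean of a Beta-binomial model with a Beta(a, b) prior
    (uniform Beta(1, 1) by default): ``(responded + a) / (tested + a + b)``.
    Strictly inside (0, 1) and monotone in ``responded``.
    """
    a, b = prior
    if tested < 1:
        raise ValueError("tested must be >= 1")
    if not 0 <= responded <= tested:
        raise ValueError("responded must lie in [0, tested]")
    return (responded + a) / (tested + a + b)


@dataclass(frozen=True)
class NormalizationParams:
    """z-score + min-max parameters fitted on a training table.

    ``stats`` maps each min-maxed raw feature to (mean, sd, post-z min,
    post-z max); ``inverted`` lists features mapped through ``1 - x`` after
    min-max (allergenicity always; immunogenicity for Class II). Binding
    affinity is transformed as ``ln(nM)`` with no further rescaling.
    """

    mhc_class: str
    stats: Mapping[str, tuple[float, float, float, float]]
    inverted: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "mhc_class": self.mhc_class,
            "stats": {k: list(v) for k, v in self.stats.items()},
            "inverted": list(self.inverted),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationParams":
        return cls(
            mhc_class=d["mhc_class"],
            stats={k: tuple(v) for k, v in d["stats"].items()},
            inverted=tuple(d["inverted"]),
        )


def fit_normalization(table: pd.DataFrame, mhc_class: str) -> NormalizationParams:
    """Fit normalization parameters on a raw feature table.

    A zero-variance feature column is flagged (it will normalize to a
    constant 0.5) with a warning rather than failing.
    """
    if table.empty:
        raise ValueError("cannot fit normalization on an empty table")
    stats: dict[str, tuple[float, float, float, float]] = {}
    for feat in MINMAX_FEATURES:
        col = table[feat].astype(float).to_numpy()
        mean = float(np.mean(col))
        sd = float(np.std(col, ddof=0))
        if sd == 0.0:
            warnings.warn(
                f"feature {feat!r} has zero variance; it will normalize to 0.5",
                RuntimeWarning,
            )
            stats[feat] = (mean, 0.0, 0.0, 0.0)
            continue
        z = (col - mean) / sd
        stats[feat] = (mean, sd, float(z.min()), float(z.max()))
    inverted = ["allergenicity"]
    if mhc_class == "II":
        inverted.append("immunogenicity")
    return NormalizationParams(mhc_class, stats, tuple(inverted))


def apply_normalization(
    params: NormalizationParams, raw: pd.DataFrame, clip: bool = True
) -> pd.DataFrame:
    """Map raw feature columns onto (alpha, gamma, delta, epsilon).

    New data may fall outside the training min-max range; by default the
    three min-maxed features are clipped back to [0, 1].
    """
    out = pd.DataFrame(index=raw.index)
    for feat, name in RAW_FEATURES.items():
        if feat == "binding_affinity_nM":
            ba = raw[feat].astype(float)
            if (ba <= 0).any():
                raise ValueError("binding affinities must be positive")
            out[name] = np.log(ba)
            continue
        mean, sd, zmin, zmax = params.stats[feat]
        col = raw[feat].astype(float)
        if sd == 0.0:
            vals = pd.Series(0.5, index=raw.index)
        else:
            z = (col - mean) / sd
            span = zmax - zmin
            vals = (z - zmin) / span if span > 0 else pd.Series(0.5, index=raw.index)
            if clip:
                vals = vals.clip(0.0, 1.0)
        if feat in params.inverted:
            vals = 1.0 - vals
        out[name] = vals
    return out


@dataclass(frozen=True)
class ScoringModel:
    """A fitted or published scoring function.

    ``weights`` is (b0, b1, b2, b3, b4) over (intercept, alpha, gamma,
    delta, epsilon).
    """

    family: str  # "linear" or "logistic"
    mhc_class: str
    weights: tuple[float, float, float, float, float]
    normalization: NormalizationParams | None = None
    name: str = field(default="", compare=False)

    def __post_init__(self) -> None:
        if self.family not in ("linear", "logistic"):
            raise ValueError(f"unknown model family {self.family!r}")
        if len(self.weights) != 5:
            raise ValueError("a scoring model has exactly five weights")

    def linear_predictor(self, fv: pd.DataFrame) -> np.ndarray:
        b0, b1, b2, b3, b4 = self.weights
        return (
            b0
            + b1 * fv["alpha"].to_numpy(dtype=float)
            + b2 * fv["gamma"].to_numpy(dtype=float)
            + b3 * fv["delta"].to_numpy(dtype=float)
            + b4 * fv["epsilon"].to_numpy(dtype=float)
        )

    def to_json(self, path: str | Path | None = None) -> str:
        doc = {
            "family": self.family,
            "mhc_class": self.mhc_class,
            "weights": list(self.weights),
            "normalization": (
                self.normalization.to_dict() if self.normalization else None
            ),
            "name": self.name,
        }
        text = json.dumps(doc, indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ScoringModel":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        doc = json.loads(text)
        norm = doc.get("normalization")
        return cls(
            family=doc["family"],
            mhc_class=doc["mhc_class"],
            weights=tuple(doc["weights"]),
            normalization=NormalizationParams.from_dict(norm) if norm else None,
            name=doc.get("name", ""),
        )


def score(model: ScoringModel, fv: pd.DataFrame) -> np.ndarray:
    """Score normalized feature vectors.

    Logistic models return the inverse-logit probability, strictly inside
    (0, 1); linear models return the unclamped affine value.
    """
    missing = {"alpha", "gamma", "delta", "epsilon"} - set(fv.columns)
    if missing:
        raise ValueError(f"feature vector missing columns {sorted(missing)}")
    eta = model.linear_predictor(fv)
    if model.family == "linear":
        return eta
    with np.errstate(over="ignore"):
        return 1.0 / (1.0 + np.exp(-eta))


#: Published fitted weights (intercept, alpha, gamma, delta, epsilon).
PUBLISHED_MODELS: dict[str, ScoringModel] = {
    m.name: m
    for m in (
        ScoringModel(
            "logistic", "I", (2.311, 0.893, 0.197, -3.426, -0.479),
            name="published-class1-logistic",
        ),
        ScoringModel(
            "logistic", "II", (0.654, -0.010, 0.381, 0.831, -0.096),
            name="published-class2-logistic",
        ),
        ScoringModel(
            "linear", "I", (0.335, 0.142, 0.457, -0.072, -0.005),
            name="published-class1-linear",
        ),
        ScoringModel(
            "linear", "II", (0.681, 0.149, -0.016, 0.134, -0.029),
            name="published-class2-linear",
        ),
    )
}


def _design(fv: pd.DataFrame) -> np.ndarray:
    return fv[["alpha", "gamma", "delta", "epsilon"]].to_numpy(dtype=float)


def fit_model(
    family: str, mhc_class: str, table: pd.DataFrame, name: str = ""
) -> ScoringModel:
    """Fit a scoring model on a cleaned training table.

    ``table`` must carry the raw feature columns plus ``outcome`` (binary,
    logistic family) or ``potential`` (in [0, 1], linear family). The
    normalization is fitted on the same table and persisted with the model.
    Logistic fits are unregularized maximum likelihood; a warning is issued
    on (near-)perfect separation, where weights are not identifiable.
    """
    params = fit_normalization(table, mhc_class)
    fv = apply_normalization(params, table)
    X = _design(fv)
    if family == "logistic":
        y = table["outcome"].astype(int).to_numpy()
        if len(np.unique(y)) < 2:
            raise DegenerateFitError("outcome column is constant")
        # C=inf -> unregularized maximum likelihood
        clf = LogisticRegression(C=np.inf, solver="lbfgs", max_iter=5000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            clf.fit(X, y)
        weights = (float(clf.intercept_[0]), *map(float, clf.coef_[0]))
        if np.all((clf.predict_proba(X)[:, 1] > 0.5) == y.astype(bool)):
            warnings.warn(
                "training data may be perfectly separated; logistic weights "
                "are poorly identified",
                RuntimeWarning,
            )
    elif family == "linear":
        y = table["potential"].astype(float).to_numpy()
        if float(np.std(y)) == 0.0:
            raise DegenerateFitError("potential column is constant")
        reg = LinearRegression()
        reg.fit(X, y)
        weights = (float(reg.intercept_), *map(float, reg.coef_))
    else:
        raise ValueError(f"unknown model family {family!r}")
    return ScoringModel(family, mhc_class, weights, params, name=name)


def evaluate_cv(
    family: str,
    mhc_class: str,
    table: pd.DataFrame,
    repeats: int = 5,
    test_fraction: float = 0.30,
    seed: int = 0,
    scheme: str = "shuffle",
) -> dict[str, float]:
    """Cross-validated performance of a scoring-function family.

    Default scheme: ``repeats`` independent random 70:30 train/test splits
    (means reported). ``scheme="kfold"`` gives plain k-fold with
    ``repeats`` folds instead. Logistic models report mean accuracy at the
    0.5 probability threshold and mean rank-based (tie-corrected) AUC;
    linear models report mean test R-squared. A test split containing a
    single outcome class is redrawn.
    """
    if len(table) < 20:
        raise ValueError("need at least 20 rows for cross-validation")
    if scheme == "shuffle":
        splitter = ShuffleSplit(
            n_splits=repeats, test_size=test_fraction, random_state=seed
        )
    elif scheme == "kfold":
        splitter = KFold(n_splits=repeats, shuffle=True, random_state=seed)
    else:
        raise ValueError(f"unknown CV scheme {scheme!r}")

    idx = np.arange(len(table))
    splits = list(splitter.split(idx))
    if family == "logistic":
        y_all = table["outcome"].astype(int).to_numpy()
        rng = np.random.default_rng(seed + 1)
        fixed = []
        for tr, te in splits:
            tries = 0
            while len(np.unique(y_all[te])) < 2 or len(np.unique(y_all[tr])) < 2:
                perm = rng.permutation(idx)
                cut = len(te)
                te, tr = perm[:cut], perm[cut:]
                tries += 1
                if tries > 100:
                    raise DegenerateFitError(
                        "could not draw a two-class train/test split"
                    )
            fixed.append((tr, te))
        splits = fixed

    accs, aucs, r2s = [], [], []
    for tr, te in splits:
        train, test = table.iloc[tr], table.iloc[te]
        model = fit_model(family, mhc_class, train)
        # no clipping here: test folds legitimately extend past the training
        # min-max range, and clipping would bias the evaluation
        fv_test = apply_normalization(model.normalization, test, clip=False)
        pred = score(model, fv_test)
        if family == "logistic":
            y = test["outcome"].astype(int).to_numpy()
            accs.append(float(np.mean((pred > 0.5).astype(int) == y)))
            aucs.append(float(roc_auc_score(y, pred)))
        else:
            y = test["potential"].astype(float).to_numpy()
            r2s.append(float(r2_score(y, pred)))
    if family == "logistic":
        return {
            "accuracy": float(np.mean(accs)),
            "auc": float(np.mean(aucs)),
            "accuracy_per_split": accs,
            "auc_per_split": aucs,
        }
    return {"r2": float(np.mean(r2s)), "r2_per_split": r2s}
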