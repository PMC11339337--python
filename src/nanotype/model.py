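"""Composite PLS→SVM classifier.

The model fits a bank of binary partial-least-squares regressions — one per
unordered class pair and one per class-versus-rest contrast, each at every
component count n in an inclusive range (default 5..11) — on log-transformed,
standardized gene expression. Every sample is projected through every fitted
PLS; the concatenated latent scores form the feature vector of a support
vector machine that emits calibrated probabilities over all classes.

Stacking many shallow projections makes the classifier robust to the sparse,
heterogeneous expression profiles produced by low-coverage sequencing, where
a single linear model tends to overfit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import joblib
import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.svm import SVC

from .config import RunConfig
from .matrix import ExpressionMatrix

REST = "rest"


@dataclass(frozen=True)
class Contrast:
    """A binary sub-problem: class-vs-class or class-vs-rest."""

    kind: str  # "pair" | "ovr"
    positive: str
    negative: str  # other class, or "rest"

    @property
    def key(self) -> str:
        return f"{self.negative}|{self.positive}" if self.kind == "pair" else f"{self.positive}|{REST}"


def build_contrasts(classes: Sequence[str]) -> List[Contrast]:
    """All C(C-1)/2 pairs (in class order) followed by C one-vs-rest contrasts."""
    classes = list(classes)
    out: List[Contrast] = []
    for i, a in enumerate(classes):
        for b in classes[i + 1 :]:
            out.append(Contrast(kind="pair", positive=b, negative=a))
    for c in classes:
        out.append(Contrast(kind="ovr", positive=c, negative=REST))
    return out


def confidence_tier(probability: float) -> str:
    if probability > 0.8:
        return "high"
    if probability > 0.6:
        return "medium"
    if probability > 0.5:
        return "low"
    return "unconfident"


@dataclass
class PredictionResult:
    """Class-probability vector for one sample, with the called class and its
    confidence tier (high > 0.8, medium > 0.6, low > 0.5, else unconfident)."""

    sample_id: str
    probabilities: Dict[str, float]
    called_class: str
    probability: float
    tier: str

    def to_dict(self) -> dict:
        return {
            "sample_id": self.sample_id,
            "probabilities": self.probabilities,
            "called_class": self.called_class,
            "probability": self.probability,
            "tier": self.tier,
        }


@dataclass
class CompositeModel:
    """The fitted bank of PLS projections plus the stacking SVM."""

    classes: Tuple[str, ...]
    gene_set: Tuple[str, ...]
    transform: str
    component_range: Tuple[int, int]
    contrasts: Tuple[Contrast, ...]
    pls_bank: Dict[Tuple[str, int], PLSRegression]
    svm: SVC
    feature_mean: np.ndarray
    feature_std: np.ndarray
    config: RunConfig

    @property
    def feature_dim(self) -> int:
        """Total stacked-score dimension consumed by the SVM."""
        return sum(p.n_components for p in self.pls_bank.values())

    def _design(self, X: np.ndarray) -> np.ndarray:
        """Transform and standardize raw TPM with stored training statistics."""
        if self.transform == "log2p1":
            X = np.log2(X + 1.0)
        return (X - self.feature_mean) / self.feature_std

    def score_features(self, X_std: np.ndarray) -> np.ndarray:
        """Project standardized samples through every PLS in the bank,
        concatenated contrast-major then by ascending component count."""
        lo, hi = self.component_range
        blocks = [
            self.pls_bank[(c.key, n)].transform(X_std)
            for c in self.contrasts
            for n in range(lo, hi + 1)
        ]
        return np.hstack(blocks)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "CompositeModel":
        model = joblib.load(path)
        if not isinstance(model, CompositeModel):
            raise ValueError(f"{path} does not contain a CompositeModel")
        return model


def _fit_pls(X: np.ndarray, y: np.ndarray, n_components: int) -> PLSRegression:
    pls = PLSRegression(n_components=n_components, scale=False)
    with warnings.catch_warnings():
        # near-perfect contrasts exhaust the Y residual before the last
        # component; harmless here
        warnings.simplefilter("ignore")
        pls.fit(X, y.reshape(-1, 1).astype(float))
    return pls


def fit_composite(
    m: ExpressionMatrix,
    component_range: Optional[Tuple[int, int]] = None,
    config: Optional[RunConfig] = None,
) -> CompositeModel:
    """Fit the composite model on a (filtered) cohort matrix.

    Responses are coded {0,1} per contrast; pairwise contrasts are fitted on
    the two classes' samples only, one-vs-rest contrasts on all samples. The
    per-contrast component count is capped at (contrast samples − 1) and at
    the gene count so small classes never exceed the PLS rank limit. The SVM
    is trained on every sample's concatenated score vector — samples outside
    a pairwise contrast are still projected through that contrast's loadings.
    """
    config = config or RunConfig()
    lo, hi = component_range or config.component_range
    if not (1 <= lo <= hi):
        raise ValueError(f"invalid component range [{lo}, {hi}]")

    classes = tuple(sorted(m.labels.unique()))
    if len(classes) < 2:
        raise ValueError(f"need >= 2 classes, got {classes}")
    counts = m.labels.value_counts()
    small = [c for c in classes if counts[c] < 2]
    if small:
        raise ValueError(f"classes with fewer than 2 samples: {small}")
    if m.n_genes < lo:
        raise ValueError(f"{m.n_genes} genes is fewer than the minimum component count {lo}")

    X_raw = m.values.to_numpy(dtype=float)
    X = np.log2(X_raw + 1.0) if config.transform == "log2p1" else X_raw
    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    X_std = (X - mean) / std

    labels = m.labels.to_numpy()
    contrasts = tuple(build_contrasts(classes))
    pls_bank: Dict[Tuple[str, int], PLSRegression] = {}
    for contrast in contrasts:
        if contrast.kind == "pair":
            mask = np.isin(labels, [contrast.positive, contrast.negative])
        else:
            mask = np.ones(len(labels), dtype=bool)
        Xc = X_std[mask]
        yc = (labels[mask] == contrast.positive).astype(float)
        for n in range(lo, hi + 1):
            n_eff = max(1, min(n, Xc.shape[0] - 1, Xc.shape[1]))
            pls_bank[(contrast.key, n)] = _fit_pls(Xc, yc, n_eff)

    model = CompositeModel(
        classes=classes,
        gene_set=tuple(m.genes),
        transform=config.transform,
        component_range=(lo, hi),
        contrasts=contrasts,
        pls_bank=pls_bank,
        svm=SVC(kernel=config.svm_kernel, probability=True, random_state=config.seed),
        feature_mean=mean,
        feature_std=std,
        config=config,
    )
    scores = model.score_features(X_std)
    with warnings.catch_warnings():
        # sklearn deprecation chatter for SVC(probability=True); the Platt-style
        # calibration it performs is exactly what we want here
        warnings.simplefilter("ignore", FutureWarning)
        model.svm.fit(scores, labels)
    return model


def _profile_vector(model: CompositeModel, profile: Union[Mapping[str, float], pd.Series]) -> np.ndarray:
    if isinstance(profile, pd.Series):
        vec = profile.reindex(model.gene_set).fillna(0.0).to_numpy(dtype=float)
    else:
        vec = np.array([float(profile.get(g, 0.0)) for g in model.gene_set])
    if not np.isfinite(vec).all() or (vec < 0).any():
        raise ValueError("profile values must be finite and non-negative")
    return vec


def predict(
    model: CompositeModel,
    profile: Union[Mapping[str, float], pd.Series],
    sample_id: str = "sample",
) -> PredictionResult:
    """Classify one gene-TPM profile.

    The profile is restricted/expanded to the model's gene set (missing genes
    contribute 0), pushed through the stored transform and standardization,
    projected through every PLS, and scored by the SVM. Argmax ties break by
    class order, deterministically.
    """
    vec = _profile_vector(model, profile)
    X_std = model._design(vec.reshape(1, -1))
    scores = model.score_features(X_std)
    raw = model.svm.predict_proba(scores)[0]
    by_class = dict(zip(model.svm.classes_, raw))
    probs = np.array([by_class[c] for c in model.classes])
    total = probs.sum()
    if total > 0:
        probs = probs / total
    idx = int(np.argmax(probs))  # first max wins -> tie-break by class order
    return PredictionResult(
        sample_id=sample_id,
        probabilities={c: float(p) for c, p in zip(model.classes, probs)},
        called_class=model.classes[idx],
        probability=float(probs[idx]),
        tier=confidence_tier(float(probs[idx])),
    )


def fit_binary_subtype(
    m: ExpressionMatrix, scheme: str, config: Optional[RunConfig] = None
) -> CompositeModel:
    """Fit a two-class composite model on a subtype labeling scheme (e.g.
    FOXO1 fusion status) within one tumor type; samples with no subtype label
    are dropped."""
    if scheme not in m.subtype_labels:
        raise ValueError(f"matrix has no subtype scheme {scheme!r}")
    labels = m.subtype_labels[scheme]
    keep = labels.notna()
    if keep.sum() < 4:
        raise ValueError(f"too few labeled samples for scheme {scheme!r}")
    sub = m.subset_samples(list(labels.index[keep])).with_labels(labels[keep])
    if len(sub.classes) != 2:
        raise ValueError(
            f"scheme {scheme!r} must have exactly 2 observed labels, got {sub.classes}"
        )
    return fit_composite(sub, config=config)


def top_coefficient_genes(
    model: CompositeModel, contrast: Union[str, Contrast], k: Optional[int] = None
) -> List[str]:
    """Rank genes by |regression coefficient| of the largest-component PLS for
    one contrast (descending; ties keep gene order). Useful for inspecting
    which genes drive a class distinction."""
    key = contrast.key if isinstance(contrast, Contrast) else contrast
    hi = model.component_range[1]
    if (key, hi) not in model.pls_bank:
        known = sorted({c.key for c in model.contrasts})
        raise KeyError(f"unknown contrast {key!r}; known: {known}")
    coef = np.ravel(model.pls_bank[(key, hi)].coef_)
    order = np.argsort(-np.abs(coef), kind="stable")
    if k is None:
        k = len(order)
    return [model.gene_set[i] for i in order[: max(0, k)]]
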