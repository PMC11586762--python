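"""Continental ancestry assignment: projection of cohort genotypes onto
reference principal components and random-forest classification.

Per-sample coordinates are sum_v w_v * (g_v - 2 f_v) / sqrt(2 f_v (1-f_v))
over the non-missing loadings variants, divided by the fraction of loadings
variants used so that missingness does not shrink projections toward the
origin.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split

from .types import MISSING, AncestryLabel, CohortGenotypeMatrix, CONTINENTAL_ANCESTRIES

logger = logging.getLogger(__name__)

__all__ = ["PCProjection", "AncestryModel", "project_onto_pcs", "fit_ancestry_classifier", "assign_ancestry"]

MIN_GROUP_SIZE = 10  # groups below this are excluded from burden testing


@dataclass
class PCProjection:
    sample_id: str
    coordinates: np.ndarray | None  # None when below the genotyped-fraction floor
    fraction_used: float


@dataclass
class AncestryModel:
    classifier: RandomForestClassifier
    prob_threshold: float = 0.9
    holdout_accuracy: float | None = None

    @property
    def classes(self) -> list[AncestryLabel]:
        return [AncestryLabel(c) for c in self.classifier.classes_]


def project_onto_pcs(
    genotypes: CohortGenotypeMatrix,
    loadings: pd.DataFrame,
    min_fraction: float = 0.8,
) -> list[PCProjection]:
    """Project each sample onto the reference principal components.

    ``loadings`` is indexed by VariantKey with columns f, w_1..w_k.
    Samples genotyped at fewer than ``min_fraction`` of the loadings
    variants are flagged with absent coordinates.
    """
    weight_cols = [c for c in loadings.columns if c.startswith("w_")]
    avail = [k for k in loadings.index if k in genotypes._index]
    if not avail:
        raise ValueError("no loadings variants present in the cohort")
    rows = np.array([genotypes.variant_index(k) for k in avail])
    f = loadings.loc[avail, "f"].to_numpy(dtype=float)
    w = loadings.loc[avail, weight_cols].to_numpy(dtype=float)  # (m, k)
    denom = np.sqrt(2.0 * f * (1.0 - f))
    dos = genotypes.dosage[rows, :].astype(float)  # (m, n)
    observed = dos != MISSING
    z = np.where(observed, (dos - 2.0 * f[:, None]) / denom[:, None], 0.0)
    coords = w.T @ z  # (k, n)
    frac_used = observed.sum(axis=0) / len(loadings)
    out = []
    for j, sample in enumerate(genotypes.samples):
        if frac_used[j] < min_fraction:
            out.append(PCProjection(sample, None, float(frac_used[j])))
        else:
            out.append(
                PCProjection(sample, coords[:, j] / frac_used[j], float(frac_used[j]))
            )
    return out


def fit_ancestry_classifier(
    reference_projections: list[PCProjection],
    labels: dict[str, AncestryLabel],
    seed: int = 0,
    n_estimators: int = 500,
    prob_threshold: float = 0.9,
    min_class_size: int = 20,
) -> AncestryModel:
    """Fit a random forest on labelled reference projections."""
    X, y = [], []
    for proj in reference_projections:
        if proj.coordinates is None:
            continue
        X.append(proj.coordinates)
        y.append(labels[proj.sample_id].value)
    X = np.asarray(X)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need at least 2 labelled classes")
    small = [f"{c} (n={n})" for c, n in zip(classes, counts) if n < min_class_size]
    if small:
        raise ValueError(f"classes below the {min_class_size}-sample floor: {small}")
    bad = set(classes) - {a.value for a in CONTINENTAL_ANCESTRIES}
    if bad:
        raise ValueError(f"labels outside the continental set: {sorted(bad)}")
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=0.2, random_state=seed, stratify=y
    )
    clf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    clf.fit(X_tr, y_tr)
    acc = float(clf.score(X_te, y_te))
    logger.info("ancestry classifier held-out accuracy: %.3f", acc)
    clf.fit(X, y)  # refit on everything for deployment
    return AncestryModel(classifier=clf, prob_threshold=prob_threshold, holdout_accuracy=acc)


def assign_ancestry(
    projections: list[PCProjection],
    model: AncestryModel,
    min_group_size: int = MIN_GROUP_SIZE,
) -> dict[str, AncestryLabel]:
    """Assign each sample the argmax class when its probability clears the
    threshold, else UNKNOWN; groups smaller than ``min_group_size`` are
    downgraded to UNKNOWN for burden testing."""
    assignments: dict[str, AncestryLabel] = {}
    valid = [p for p in projections if p.coordinates is not None]
    for p in projections:
        if p.coordinates is None:
            assignments[p.sample_id] = AncestryLabel.UNKNOWN
    if valid:
        X = np.asarray([p.coordinates for p in valid])
        probs = model.classifier.predict_proba(X)
        classes = model.classifier.classes_
        for p, row in zip(valid, probs):
            i = int(np.argmax(row))
            if row[i] >= model.prob_threshold:
                assignments[p.sample_id] = AncestryLabel(classes[i])
            else:
                assignments[p.sample_id] = AncestryLabel.UNKNOWN
    sizes: dict[AncestryLabel, int] = {}
    for lbl in assignments.values():
        sizes[lbl] = sizes.get(lbl, 0) + 1
    for sample, lbl in assignments.items():
        if lbl != AncestryLabel.UNKNOWN and sizes[lbl] < min_group_size:
            assignments[sample] = AncestryLabel.UNKNOWN
    return assignments
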