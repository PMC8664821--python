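"""Lifestyle classification from gene-family copy numbers.

A random-forest classifier is trained on raw per-genome orthogroup copy
numbers (tree ensembles are scale-invariant, so no standardization).
Accuracy is estimated by leave-one-out cross-validation with a full
refit per fold; the fitted model then emits lifestyle probability
vectors for reconstructed ancestral genomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .ancestral import AncestralReconstruction
from .datamodel import GeneFamilyMatrix, LifestyleMap


@dataclass
class ClassifierReport:
    """Fitted model plus the leave-one-out cross-validation record."""

    model: RandomForestClassifier
    cv_accuracy: float
    fold_predictions: pd.DataFrame   # genome -> true label, predicted label
    family_ids: list[str]
    seed: int


def train_lifestyle_classifier(matrix: GeneFamilyMatrix,
                               lifestyles: LifestyleMap,
                               exclude: list[str] | None = None,
                               seed: int = 0,
                               n_trees: int = 100) -> ClassifierReport:
    """Fit the ensemble and estimate accuracy by leave-one-out CV.

    ``exclude`` removes genomes (e.g. the isolates whose lifestyle is the
    question) from training and from the CV folds.  Classes with a single
    member make their fold trivially unpredictable; the fold is kept and
    a warning emitted.
    """
    labels = lifestyles.labels.drop(index=exclude or [], errors="ignore")
    genomes = [g for g in matrix.genome_ids if g in labels.index]
    if len(pd.unique(labels[genomes])) < 2:
        raise ValueError("need >= 2 lifestyles after exclusion")
    x = matrix.counts.loc[genomes].to_numpy(float)
    y = labels[genomes].to_numpy()
    singletons = pd.Series(y).value_counts()
    lonely = singletons[singletons == 1]
    if len(lonely):
        warnings.warn(
            f"lifestyles with a single genome make their LOOCV fold "
            f"degenerate: {sorted(lonely.index)}", stacklevel=2)

    preds = []
    for i in range(len(genomes)):
        mask = np.ones(len(genomes), dtype=bool)
        mask[i] = False
        clf = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
        clf.fit(x[mask], y[mask])
        preds.append(clf.predict(x[i:i + 1])[0])
    fold = pd.DataFrame({"true": y, "predicted": preds},
                        index=pd.Index(genomes, name="genome_id"))
    accuracy = float((fold["true"] == fold["predicted"]).mean())

    final = RandomForestClassifier(n_estimators=n_trees, random_state=seed)
    final.fit(x, y)
    return ClassifierReport(model=final, cv_accuracy=accuracy,
                            fold_predictions=fold,
                            family_ids=matrix.family_ids, seed=seed)


def predict_node_lifestyles(report: ClassifierReport,
                            recon: AncestralReconstruction,
                            nodes: list[str] | None = None) -> pd.DataFrame:
    """Lifestyle probability vectors for reconstructed ancestral genomes.

    Probabilities are the ensemble vote fractions on the Wagner integer
    copy-number profiles; each row sums to 1.
    """
    states = recon.states
    if list(states.columns) != report.family_ids:
        raise ValueError("reconstruction family set does not match classifier")
    if nodes is not None:
        states = states.loc[nodes]
    probs = report.model.predict_proba(states.to_numpy(float))
    return pd.DataFrame(probs, index=states.index,
                        columns=report.model.classes_)
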