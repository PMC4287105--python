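"""BIC classification of differentially expressed probes into sub-models.

Four candidate fixed-effect structures, all with the random sow intercept:

1. age + genotype + age:genotype
2. age + genotype (additive)
3. age only
4. genotype only

Each probe is fitted by ML under all four and assigned to the sub-model
with the smallest BIC, ``BIC = -2 loglik + k log(n)`` with ``n`` the number
of fetuses and ``k`` the fixed-effect rank plus the two variance
components.  Exact ties go to the most parsimonious sub-model.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .io import ExpressionMatrix, validate_design
from .mixedlm import (
    ADDITIVE_TERMS,
    AGE_TERMS,
    FULL_TERMS,
    GENOTYPE_TERMS,
    MixedFitResult,
    MixedModelEngine,
    fit_mixed,
)

SUBMODEL_TERMS = {1: FULL_TERMS, 2: ADDITIVE_TERMS, 3: AGE_TERMS, 4: GENOTYPE_TERMS}


def bic(fit: MixedFitResult | float, n: int | None = None, n_params: int | None = None) -> float:
    """BIC of an ML fit: ``-2 loglik + n_params log(n)``."""
    if isinstance(fit, MixedFitResult):
        return -2.0 * fit.loglik_ml + fit.n_params * np.log(fit.n)
    return -2.0 * float(fit) + int(n_params) * np.log(int(n))


def fit_submodels(y, design: pd.DataFrame) -> dict[int, MixedFitResult]:
    """ML fits of one probe under all four sub-models."""
    engine = design if isinstance(design, MixedModelEngine) else MixedModelEngine(design)
    return {m: fit_mixed(y, engine, terms) for m, terms in SUBMODEL_TERMS.items()}


class SubmodelClassifier(BaseEstimator):
    """Assign each probe to its BIC-best sub-model.

    Attributes
    ----------
    results_ : DataFrame indexed by probe with ``bic_1`` .. ``bic_4``,
        ``label`` and ``delta_bic`` (gap to the runner-up).
    labels_ : per-probe sub-model labels (1-4).
    proportions_ : fraction of probes per label.
    """

    def fit(self, X, design: pd.DataFrame, y=None):
        design = validate_design(design)
        if isinstance(X, ExpressionMatrix):
            X = X.X
        if isinstance(X, pd.DataFrame):
            if set(design["sample_id"]) <= set(X.index):
                X = X.loc[design["sample_id"]]
            probe_ids = list(X.columns)
            Y = X.to_numpy(dtype=float).T
        else:
            X = np.asarray(X, dtype=float)
            probe_ids = [f"p{i}" for i in range(X.shape[1])]
            Y = X.T
        engine = MixedModelEngine(design)
        n = engine.struct.n

        bics = {}
        ranks = {}
        for m, terms in SUBMODEL_TERMS.items():
            fit = engine.fit(Y, terms)
            k = fit["rank"] + 2
            ranks[m] = fit["rank"]
            bics[m] = -2.0 * fit["loglik"] + k * np.log(n)

        res = pd.DataFrame(
            {f"bic_{m}": bics[m] for m in (1, 2, 3, 4)},
            index=pd.Index(probe_ids, name="probe_id"),
        )
        # argmin with ties broken toward fewest parameters (then lower label)
        order = sorted((ranks[m], m) for m in (1, 2, 3, 4))
        stack = np.column_stack([bics[m] for _, m in order])
        arg = np.argmin(stack, axis=1)  # first occurrence = most parsimonious
        labels = np.array([m for _, m in order])[arg]
        sorted_bics = np.sort(np.column_stack([bics[m] for m in (1, 2, 3, 4)]), axis=1)
        res["label"] = labels
        res["delta_bic"] = sorted_bics[:, 1] - sorted_bics[:, 0]

        self.results_ = res
        self.labels_ = pd.Series(labels, index=res.index, name="label")
        self.proportions_ = self.labels_.value_counts(normalize=True).reindex(
            [1, 2, 3, 4], fill_value=0.0
        )
        return self

    def predict(self, X=None) -> pd.Series:
        return self.labels_


def classify(X, design: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """BIC sub-model labels for a probe set; returns (table, proportions)."""
    clf = SubmodelClassifier().fit(X, design)
    return clf.results_, clf.proportions_
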