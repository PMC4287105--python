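"""Parent-of-origin expression effects from the reciprocal cross.

Because LW and MS sows were each inseminated with mixed LW+MS semen, the
four fetal genotypes map onto a 2 x 2 maternal x paternal grid, which
separates the two parental contributions.  The full model per probe is

    age + maternal + paternal + age:maternal + age:paternal
        + maternal:paternal  (+ random sow)

and two whitened F-tests each drop exactly one age x parent interaction:
dropping age:maternal tests for maternal-genome influence on the age
trajectory, dropping age:paternal for paternal-genome influence.  BH
correction is applied across probes per test; a probe significant on both
sides is reported as "both" rather than silently assigned to one list.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .dge import adjust_pvalues
from .io import ExpressionMatrix, validate_design
from .mixedlm import PARENTAL_TERMS, MixedFitResult, MixedModelEngine, fit_mixed

_REDUCED = {
    "maternal": tuple(t for t in PARENTAL_TERMS if t != "age:maternal"),
    "paternal": tuple(t for t in PARENTAL_TERMS if t != "age:paternal"),
}


def _check_parental_cells(design: pd.DataFrame) -> None:
    cells = set(zip(design["maternal_genotype"], design["paternal_genotype"]))
    for mg in ("LW", "MS"):
        for pg in ("LW", "MS"):
            if (mg, pg) not in cells:
                raise ValueError(
                    f"parental model not identifiable: no fetuses with maternal={mg}, "
                    f"paternal={pg} in the design"
                )


def fit_parental(y, design: pd.DataFrame) -> MixedFitResult:
    """ML fit of the parental-genotype model for one probe."""
    design = validate_design(design)
    _check_parental_cells(design)
    return fit_mixed(y, design, PARENTAL_TERMS)


class ParentalEffectTester(BaseEstimator):
    """Test age x maternal and age x paternal interactions for every probe.

    Parameters
    ----------
    q_threshold : float
        BH q-value threshold for calling a probe maternally or paternally
        influenced (both tests use it independently).
    gamma_mode : {"consensus", "per_probe"}
        Whitening variance ratio, as in
        :class:`~maturix.dge.MixedDifferentialExpression`.

    Attributes
    ----------
    results_ : DataFrame with ``F_maternal``, ``p_maternal``, ``q_maternal``,
        the paternal triple, and ``call`` in {maternal, paternal, both, none}.
    """

    def __init__(self, q_threshold: float = 0.01, gamma_mode: str = "consensus"):
        self.q_threshold = q_threshold
        self.gamma_mode = gamma_mode

    def fit(self, X, design: pd.DataFrame, y=None):
        design = validate_design(design)
        _check_parental_cells(design)
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

        testable = Y.var(axis=1) > 1e-12
        Yt = Y[testable]
        full = engine.fit(Yt, PARENTAL_TERMS)
        if self.gamma_mode == "consensus":
            gamma = engine.consensus_gamma(Yt, PARENTAL_TERMS)
            self.consensus_gamma_ = gamma
        else:
            gamma = full["gamma"]
            self.consensus_gamma_ = None

        res = pd.DataFrame(index=pd.Index(probe_ids, name="probe_id"))
        for side in ("maternal", "paternal"):
            tab = engine.ftest(Yt, PARENTAL_TERMS, _REDUCED[side], gamma)
            F = np.full(len(probe_ids), np.nan)
            p = np.full(len(probe_ids), np.nan)
            F[testable] = tab["F"].to_numpy()
            p[testable] = tab["p_raw"].to_numpy()
            res[f"F_{side}"] = F
            res[f"p_{side}"] = p
            res[f"q_{side}"] = adjust_pvalues(p, "bh")

        mat = res["q_maternal"] < self.q_threshold
        pat = res["q_paternal"] < self.q_threshold
        res["call"] = np.select(
            [mat & pat, mat, pat], ["both", "maternal", "paternal"], default="none"
        )
        res.loc[~pd.Series(testable, index=res.index), "call"] = "none"
        self.results_ = res
        self.full_fit_ = full
        return self


def test_parental_interactions(X, design: pd.DataFrame, q_threshold: float = 0.01,
                               gamma_mode: str = "consensus") -> pd.DataFrame:
    """Functional wrapper over :class:`ParentalEffectTester`."""
    return ParentalEffectTester(q_threshold=q_threshold, gamma_mode=gamma_mode).fit(
        X, design
    ).results_


test_parental_interactions.__test__ = False  # not a pytest case despite the name
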