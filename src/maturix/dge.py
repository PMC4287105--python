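"""Differential expression over the 2-age x 4-genotype design.

Each probe is tested by comparing the full mixed model
(age + genotype + age:genotype, random sow) against the null reduced model
(intercept + random sow) with a whitened F-test, followed by Bonferroni or
Benjamini-Hochberg correction across the tested probes.  Log2 fold changes
between gestational ages are computed from model-estimated cell means, per
genotype and averaged over genotypes.
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from statsmodels.stats.multitest import multipletests

from .io import AGES, GENOTYPES, ExpressionMatrix, validate_design
from .mixedlm import FULL_TERMS, MixedModelEngine

logger = logging.getLogger(__name__)

FC_COLUMNS = ["log2fc_age_overall"] + [f"log2fc_age_{g}" for g in GENOTYPES]


def adjust_pvalues(p, method: str = "bonferroni") -> np.ndarray:
    """Multiple-testing adjustment: ``bonferroni`` (capped) or ``bh`` step-up."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p.copy()
    ok = ~np.isnan(p)
    out = np.full_like(p, np.nan)
    if method == "bonferroni":
        out[ok] = np.minimum(p[ok] * ok.sum(), 1.0)
    elif method == "bh":
        out[ok] = multipletests(p[ok], method="fdr_bh")[1]
    else:
        raise ValueError(f"unknown correction method: {method!r}")
    return out


def call_deps(results: pd.DataFrame, alpha: float = 0.01, method: str = "bonferroni") -> list[str]:
    """Probe ids whose adjusted p-value is below ``alpha``, input order kept."""
    col = {"bonferroni": "p_bonferroni", "bh": "q_bh"}[method]
    if results.empty:
        return []
    mask = results[col] < alpha
    return list(results.index[mask.fillna(False)])


class MixedDifferentialExpression(BaseEstimator):
    """Per-probe mixed-model F-tests with multiple-testing control.

    Parameters
    ----------
    alpha : float
        Adjusted-p threshold for calling a probe differentially expressed.
    correction : {"bonferroni", "bh"}
        Which adjusted p-value the DEP call uses (both are computed).
    gamma_mode : {"consensus", "per_probe"}
        Whitening variance ratio for the F-test: a single pooled-REML
        consensus across probes (calibrated; default) or each probe's own
        ML estimate.

    Attributes
    ----------
    results_ : DataFrame indexed by probe with columns ``F``, ``df_num``,
        ``df_den``, ``p_raw``, ``p_bonferroni``, ``q_bh``, the fold-change
        columns, and ``status`` ("ok" or "not_testable").
    deps_ : list of probe ids called differentially expressed.
    consensus_gamma_ : the pooled sow/residual variance ratio (consensus mode).
    """

    def __init__(self, alpha: float = 0.01, correction: str = "bonferroni",
                 gamma_mode: str = "consensus"):
        self.alpha = alpha
        self.correction = correction
        self.gamma_mode = gamma_mode

    def fit(self, X, design: pd.DataFrame, y=None):
        """Fit and test every probe.

        ``X`` is samples x probes (DataFrame columns are probe ids) or an
        :class:`~maturix.io.ExpressionMatrix`; rows must align with the
        design table's sample order (aligned by sample id when available).
        """
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.correction not in ("bonferroni", "bh"):
            raise ValueError(f"unknown correction: {self.correction!r}")
        if self.gamma_mode not in ("consensus", "per_probe"):
            raise ValueError(f"unknown gamma_mode: {self.gamma_mode!r}")
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
        self.engine_ = engine

        variances = Y.var(axis=1)
        testable = variances > 1e-12
        n_skipped = int((~testable).sum())
        if n_skipped:
            logger.info("skipping %d zero-variance probe(s) as not testable", n_skipped)

        full = engine.fit(Y[testable], FULL_TERMS)
        if self.gamma_mode == "consensus":
            gamma = engine.consensus_gamma(Y[testable], FULL_TERMS)
            self.consensus_gamma_ = gamma
        else:
            gamma = full["gamma"]
            self.consensus_gamma_ = None
        ftab = engine.ftest(Y[testable], FULL_TERMS, (), gamma)

        res = pd.DataFrame(index=pd.Index(probe_ids, name="probe_id"))
        for col in ("F", "df_num", "df_den", "p_raw"):
            res[col] = np.nan
        res.loc[np.array(probe_ids)[testable], ["F", "df_num", "df_den", "p_raw"]] = (
            ftab[["F", "df_num", "df_den", "p_raw"]].to_numpy()
        )
        res["p_bonferroni"] = adjust_pvalues(res["p_raw"].to_numpy(), "bonferroni")
        res["q_bh"] = adjust_pvalues(res["p_raw"].to_numpy(), "bh")

        fc = log2_fold_changes_table(engine, full)
        for col in FC_COLUMNS:
            res[col] = np.nan
        res.loc[np.array(probe_ids)[testable], FC_COLUMNS] = fc.to_numpy()
        res["status"] = np.where(testable, "ok", "not_testable")
        res.loc[res.index[testable][full["degenerate"]], "status"] = "not_testable"

        self.results_ = res
        self.full_fit_ = full
        self.n_tested_ = int(testable.sum())
        self.deps_ = call_deps(res, self.alpha, self.correction)
        return self

    def transform(self, X=None) -> pd.DataFrame:
        return self.results_


def log2_fold_changes_table(engine: MixedModelEngine, fitres: dict,
                            terms=FULL_TERMS) -> pd.DataFrame:
    """Age fold changes (d110 minus d90, log2) from model cell means.

    Per-genotype value: estimated cell mean at d110 minus at d90 for that
    genotype; overall value: unweighted mean over the genotypes observed in
    the design.  Positive values mean up-regulation at d110.
    """
    cells = engine.cell_means(fitres, terms)
    out = {}
    per_g = []
    for g in GENOTYPES:
        val = cells[("d110", g)] - cells[("d90", g)]
        out[f"log2fc_age_{g}"] = val
        per_g.append(val)
    stacked = np.column_stack(per_g)
    with np.errstate(invalid="ignore"):
        out["log2fc_age_overall"] = np.nanmean(stacked, axis=1)
    df = pd.DataFrame(out)
    return df[FC_COLUMNS]


def log2_fold_changes(fit, design: pd.DataFrame):
    """Single-probe fold changes from a full-model :class:`MixedFitResult`.

    Returns ``(overall, per_genotype)`` where ``per_genotype`` maps each
    fetal genotype to its d110-minus-d90 estimate (NaN when the genotype is
    absent from the design).
    """
    engine = design if isinstance(design, MixedModelEngine) else MixedModelEngine(design)
    fitres = {"beta": fit.beta.to_numpy()[None, :]}
    tab = log2_fold_changes_table(engine, fitres, fit.terms)
    per_g = {g: float(tab[f"log2fc_age_{g}"].iloc[0]) for g in GENOTYPES}
    return float(tab["log2fc_age_overall"].iloc[0]), per_g
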