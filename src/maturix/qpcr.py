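"""Pfaffl relative qPCR quantification with per-gene efficiency estimation.

Amplification efficiency ``E`` (fold of product per cycle, 2 for perfect
doubling) is estimated from a serial-dilution standard curve by least
squares of Ct on log10 relative concentration: ``E = 10^(-1/slope)``.  The
Pfaffl ratio corrects the classical 2^(-ddCt) method for gene-specific
efficiencies:

    ratio = E_target^(dCt_target) / E_ref^(dCt_ref),

with each dCt the calibrator Ct minus the sample Ct.  The calibrator is
the gene's mean Ct over all samples unless another is supplied.  qPCR
ratios are log2-transformed before Pearson correlation with (log2)
microarray expression.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class EfficiencyEstimate:
    gene: str
    E: float
    slope: float
    r_squared: float


def estimate_efficiency(concentration, ct, gene: str = "") -> EfficiencyEstimate:
    """Standard-curve efficiency from (relative concentration, Ct) pairs."""
    conc = np.asarray(concentration, dtype=float)
    ct = np.asarray(ct, dtype=float)
    if np.any(conc <= 0):
        raise ValueError("concentrations must be positive")
    if len(np.unique(conc)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    fit = stats.linregress(np.log10(conc), ct)
    if fit.slope >= 0:
        raise ValueError(f"non-amplifying standard curve (slope {fit.slope:.3f} >= 0)")
    return EfficiencyEstimate(
        gene=gene,
        E=float(10.0 ** (-1.0 / fit.slope)),
        slope=float(fit.slope),
        r_squared=float(fit.rvalue**2),
    )


def pfaffl_ratio(ct_target_calibrator, ct_target_sample, ct_ref_calibrator,
                 ct_ref_sample, e_target: float, e_ref: float) -> float:
    """Efficiency-corrected relative expression against a reference gene.

    Theoretical efficiencies lie in (1, 2]; standard-curve estimates can
    overshoot 2 slightly under Ct noise, so values up to 2.5 are accepted.
    """
    for e in (e_target, e_ref):
        if not 1.0 < e <= 2.5:
            raise ValueError(f"efficiency must lie in (1, 2] (estimates tolerated to 2.5), got {e}")
    return float(
        e_target ** (ct_target_calibrator - ct_target_sample)
        / e_ref ** (ct_ref_calibrator - ct_ref_sample)
    )


def average_replicates(ct_table: pd.DataFrame) -> pd.DataFrame:
    """Mean Ct per (gene, sample) over technical replicates."""
    return ct_table.groupby(["gene", "sample_id"], as_index=False)["Ct"].mean()


def relative_expression(ct_table: pd.DataFrame, efficiencies: dict[str, float],
                        reference_gene: str) -> pd.DataFrame:
    """Per-sample Pfaffl ratios for every non-reference gene.

    ``ct_table`` columns: gene, sample_id, (replicate,) Ct.  Technical
    replicates are averaged on the Ct scale first; the calibrator is each
    gene's mean Ct across samples.
    """
    avg = average_replicates(ct_table)
    wide = avg.pivot(index="sample_id", columns="gene", values="Ct")
    if reference_gene not in wide.columns:
        raise ValueError(f"reference gene {reference_gene!r} absent from Ct table")
    calib = wide.mean(axis=0)
    e_ref = efficiencies[reference_gene]
    rows = {}
    for gene in wide.columns:
        if gene == reference_gene:
            continue
        e_t = efficiencies[gene]
        rows[gene] = [
            pfaffl_ratio(calib[gene], wide.at[s, gene], calib[reference_gene],
                         wide.at[s, reference_gene], e_t, e_ref)
            for s in wide.index
        ]
    return pd.DataFrame(rows, index=wide.index)


def validate_against_microarray(qpcr_ratios, microarray_log2) -> tuple[float, float, int]:
    """Pearson correlation of log2 qPCR ratios with microarray log2 values.

    Returns ``(r, two-sided p, n)`` for the paired samples.
    """
    q = np.asarray(qpcr_ratios, dtype=float)
    m = np.asarray(microarray_log2, dtype=float)
    if q.shape != m.shape:
        raise ValueError("paired vectors must have equal length")
    if len(q) < 3:
        raise ValueError("need at least 3 paired samples")
    r, p = stats.pearsonr(np.log2(q), m)
    return float(r), float(p), int(len(q))
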