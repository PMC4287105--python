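"""Synthetic data with the statistical structure of the piglet-maturity study.

The generator emulates the experimental design: 18 sows (9 Large White, 9
Meishan dams), each sampled by caesarean at one gestational age (d90 or
d110) and each litter containing both a purebred and a crossbred fetus, for
~61 fetuses over 8 age x genotype conditions.  Expression is simulated on
the log2 scale per probe as

    y = mu_g + fixed-effect pattern + S_sow + eps,

with the sow intercept shared by littermates (sd ``sigma_sow``) and iid
residuals (sd ``sigma_resid``).  Gene classes plant every structure the
downstream stages look for: nulls, the four fixed-effect sub-models,
age x maternal and age x paternal interaction genes, and four co-expression
blocks driven by a shared latent factor calibrated to a target within-block
correlation (blocks 1-3 up-regulated at d90 with an LW interaction, block 4
up at d110 with an MS interaction, mirroring the biology the network stage
is meant to recover).  A truth table aligned with the probe ids records the
planted class of every gene for recovery testing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, validate_design

GENE_CLASSES = (
    "null",
    "submodel1",
    "submodel2",
    "submodel3",
    "submodel4",
    "maternal_interaction",
    "paternal_interaction",
    "network_block_1",
    "network_block_2",
    "network_block_3",
    "network_block_4",
)

_DEFAULT_N_GENES = {
    "null": 200,
    "submodel1": 50,
    "submodel2": 50,
    "submodel3": 50,
    "submodel4": 50,
    "maternal_interaction": 25,
    "paternal_interaction": 25,
    "network_block_1": 25,
    "network_block_2": 25,
    "network_block_3": 25,
    "network_block_4": 25,
}

#: genotype main-effect pattern in units of the effect size
_GENOTYPE_PATTERN = {"LW": 0.0, "MS": 1.0, "LWMS": 0.5, "MSLW": 0.5}


@dataclass
class SimulationConfig:
    """Knobs of the generator; defaults reproduce the study conditions."""

    seed: int = 0
    n_sows_per_maternal_genotype: int = 9
    fetuses_per_sow: tuple[int, int] = (3, 4)
    sigma_sow: float = 0.3
    sigma_resid: float = 0.5
    effect_size: float = 1.0
    block_within_correlation: float = 0.99
    block_factor_noise_sd: float = 0.4
    baseline_mean: float = 8.0
    baseline_sd: float = 1.0
    fraction_unannotated: float = 0.1
    n_genes: dict[str, int] = field(default_factory=lambda: dict(_DEFAULT_N_GENES))

    def __post_init__(self) -> None:
        if self.sigma_sow < 0 or self.sigma_resid <= 0:
            raise ValueError("standard deviations must be positive (sigma_sow may be 0)")
        if self.fetuses_per_sow[0] < 2:
            raise ValueError(
                "fetuses_per_sow must be >= 2: each litter needs a purebred and a crossbred"
            )
        if not 0.0 < self.block_within_correlation < 1.0:
            raise ValueError("block_within_correlation must lie in (0, 1)")
        unknown = set(self.n_genes) - set(GENE_CLASSES)
        if unknown:
            raise ValueError(f"unknown gene class(es): {sorted(unknown)}")
        if any(v < 0 for v in self.n_genes.values()):
            raise ValueError("gene counts must be non-negative")
        for cls in GENE_CLASSES:
            self.n_genes.setdefault(cls, 0)


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([cfg.seed, stream])


def simulate_design(cfg: SimulationConfig) -> pd.DataFrame:
    """Sample table of the reciprocal-cross design.

    Each sow carries one litter sampled at one age; ages are split between
    the sows of each dam breed so that all 8 age x genotype cells are
    populated; each litter contains its purebred and its crossbred genotype
    at least once, remaining slots drawn at random.
    """
    rng = _rng(cfg, 1)
    rows = []
    sid = 0
    for mat in ("LW", "MS"):
        n = cfg.n_sows_per_maternal_genotype
        n90 = (n + 1) // 2 if mat == "LW" else n // 2
        ages = ["d90"] * n90 + ["d110"] * (n - n90)
        pure = mat
        cross = "MSLW" if mat == "LW" else "LWMS"
        for s, age in enumerate(ages, start=1):
            sow = f"{mat}_sow{s}"
            lo, hi = cfg.fetuses_per_sow
            n_fet = int(rng.integers(lo, hi + 1))
            genotypes = [pure, cross] + [
                pure if rng.random() < 0.5 else cross for _ in range(n_fet - 2)
            ]
            for g in genotypes:
                rows.append(
                    {"sample_id": f"s{sid:03d}", "sow_id": sow, "age": age,
                     "fetal_genotype": g}
                )
                sid += 1
    return validate_design(pd.DataFrame(rows))


def _class_pattern(cls: str, design: pd.DataFrame, e: float) -> np.ndarray:
    """Per-sample fixed-effect pattern (log2 units) for one gene class."""
    d110 = (design["age"] == "d110").to_numpy(float)
    geno = design["fetal_genotype"].map(_GENOTYPE_PATTERN).to_numpy(float)
    ms = (design["fetal_genotype"] == "MS").to_numpy(float)
    lw = (design["fetal_genotype"] == "LW").to_numpy(float)
    mg_ms = (design["maternal_genotype"] == "MS").to_numpy(float)
    pg_ms = (design["paternal_genotype"] == "MS").to_numpy(float)
    if cls == "null":
        return np.zeros(len(design))
    if cls == "submodel3":
        return e * d110
    if cls == "submodel4":
        return e * geno
    if cls == "submodel2":
        return e * d110 + e * geno
    if cls == "submodel1":
        # genotype-dependent age response (no age effect in LW, 2e in MS, e
        # in the crossbreds) plus a genotype main effect; the age fold
        # change averaged over genotypes is exactly e
        return e * geno + 2.0 * e * d110 * geno
    if cls == "maternal_interaction":
        # age response only in fetuses of MS dams: marginal fold change e
        return 2.0 * e * d110 * mg_ms
    if cls == "paternal_interaction":
        return 2.0 * e * d110 * pg_ms
    if cls.startswith("network_block"):
        # blocks 1-3 fall by d110 (most in MS), block 4 rises by d110 (most
        # in MS): genotype-dependent age slopes of mean magnitude e
        b = int(cls.rsplit("_", 1)[1])
        sign = 1.0 if b == 4 else -1.0
        return sign * 2.0 * e * d110 * geno
    raise ValueError(f"unknown gene class {cls!r}")


def true_overall_log2fc(cls: str, e: float) -> float:
    """Planted d110-minus-d90 fold change averaged over the four genotypes."""
    probe = pd.DataFrame(
        {
            "sample_id": [f"x{i}" for i in range(8)],
            "sow_id": ["a"] * 4 + ["b"] * 4,
            "age": ["d90"] * 4 + ["d110"] * 4,
            "fetal_genotype": list(_GENOTYPE_PATTERN) * 2,
        }
    )
    # one litter per age violates the maternal-consistency rule, so derive
    # parental columns directly rather than via validate_design
    probe["maternal_genotype"] = probe["fetal_genotype"].map(
        {"LW": "LW", "MS": "MS", "LWMS": "MS", "MSLW": "LW"}
    )
    probe["paternal_genotype"] = probe["fetal_genotype"].map(
        {"LW": "LW", "MS": "MS", "LWMS": "LW", "MSLW": "MS"}
    )
    pat = _class_pattern(cls, probe, e)
    return float(pat[4:].mean() - pat[:4].mean())


def simulate_expression(cfg: SimulationConfig, design: pd.DataFrame):
    """Expression matrix plus per-probe truth table.

    Returns ``(ExpressionMatrix, truth)`` where ``truth`` is indexed by
    probe id with columns ``gene``, ``class``, ``block``, ``role`` and
    ``true_log2fc_age_overall``.
    """
    rng = _rng(cfg, 2)
    n = len(design)
    probes, genes, classes, blocks, roles, values, truefc = [], [], [], [], [], [], []
    pid = 0

    sow_levels = sorted(design["sow_id"].unique())
    sow_idx = design["sow_id"].map({s: i for i, s in enumerate(sow_levels)}).to_numpy()
    e = cfg.effect_size

    def add_probe(cls, block, role, y, fc):
        nonlocal pid
        probes.append(f"P{pid:05d}")
        genes.append(f"G{pid:05d}")
        classes.append(cls)
        blocks.append(block)
        roles.append(role)
        values.append(y)
        truefc.append(fc)
        pid += 1

    for cls in GENE_CLASSES:
        count = cfg.n_genes.get(cls, 0)
        if count == 0:
            continue
        if cls.startswith("network_block"):
            pattern = _class_pattern(cls, design, e)
            factor = pattern + rng.normal(0.0, cfg.block_factor_noise_sd, n)
            rho = cfg.block_within_correlation
            var_f = float(factor.var())
            child_sd = np.sqrt(var_f * (1.0 - rho) / rho)
            fc = true_overall_log2fc(cls, e)
            block = cls.rsplit("_", 1)[1]
            for g in range(count):
                mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd)
                role = "hub" if g == 0 else "child"
                noise = 0.0 if g == 0 else rng.normal(0.0, child_sd, n)
                add_probe(cls, block, role, mu + factor + noise, fc)
        else:
            pattern = _class_pattern(cls, design, e)
            fc = true_overall_log2fc(cls, e)
            for g in range(count):
                mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd)
                sow_eff = rng.normal(0.0, cfg.sigma_sow, len(sow_levels))[sow_idx]
                y = mu + pattern + sow_eff + rng.normal(0.0, cfg.sigma_resid, n)
                add_probe(cls, "", "", y, fc)

    value_df = pd.DataFrame(
        np.vstack(values), index=probes, columns=list(design["sample_id"])
    )
    annotated = rng.random(len(probes)) >= cfg.fraction_unannotated
    annotation = pd.Series(
        [g for g, a in zip(genes, annotated) if a],
        index=[p for p, a in zip(probes, annotated) if a],
        name="gene_symbol",
    )
    truth = pd.DataFrame(
        {
            "gene": [g if a else "unannotated" for g, a in zip(genes, annotated)],
            "class": classes,
            "block": blocks,
            "role": roles,
            "true_log2fc_age_overall": truefc,
        },
        index=pd.Index(probes, name="probe_id"),
    )
    return ExpressionMatrix(values=value_df, annotation=annotation), truth


def simulate_genesets(cfg: SimulationConfig, truth: pd.DataFrame,
                      n_decoys: int = 10, set_size: int = 30,
                      planted_overlap: int = 25):
    """GMT-style gene sets with one set planted in up-at-d110 genes.

    The planted set takes ``planted_overlap`` annotated genes from classes
    whose true fold change is positive (sub-model 1 and block 4) and pads
    with random genes; decoys are uniform draws from the annotated universe.
    Returns ``(sets, planted_name)``.
    """
    rng = _rng(cfg, 3)
    annotated = truth[truth["gene"] != "unannotated"]
    universe = list(annotated["gene"])
    up = list(
        annotated.loc[
            (annotated["true_log2fc_age_overall"] > 0)
            & annotated["class"].isin(["submodel1", "network_block_4"]),
            "gene",
        ]
    )
    sets: dict[str, list[str]] = {}
    if universe:
        take = min(planted_overlap, len(up))
        members = list(rng.choice(up, size=take, replace=False)) if take else []
        rest = [g for g in universe if g not in set(members)]
        pad = min(set_size - take, len(rest))
        members += list(rng.choice(rest, size=pad, replace=False)) if pad > 0 else []
        sets["planted_up_d110"] = sorted(members)
        for i in range(n_decoys):
            size = min(set_size, len(universe))
            sets[f"decoy_{i:02d}"] = sorted(rng.choice(universe, size=size, replace=False))
    return sets, "planted_up_d110"


def simulate_qpcr(cfg: SimulationConfig, truth: pd.DataFrame,
                  expr: ExpressionMatrix, n_genes: int = 10,
                  noise_sd: float = 0.2, n_replicates: int = 2,
                  reference_gene: str = "HPRT"):
    """Ct tables for a qPCR validation of simulated genes.

    For each assayed gene ``Ct = intercept - log_E(2^y) + noise`` with a
    per-gene efficiency E ~ U(1.8, 2], so Ct falls by exactly one cycle per
    doubling of expression when E = 2.  A stable reference gene at the
    baseline mean is included, plus a 4-point standard curve at relative
    concentrations (1, 1/2, 1/4, 1/8).  Returns
    ``(ct_table, dilution_table, true_efficiencies, assayed_genes)``.
    """
    rng = _rng(cfg, 4)
    effectful = truth[
        (truth["gene"] != "unannotated") & (truth["class"] != "null") & (truth["block"] == "")
    ]
    chosen = list(effectful.index[:n_genes])
    gene_names = {p: truth.at[p, "gene"] for p in chosen}
    eff = {reference_gene: float(rng.uniform(1.8, 2.0))}
    for p in chosen:
        eff[gene_names[p]] = float(rng.uniform(1.8, 2.0))

    samples = expr.sample_ids
    ct_rows, dil_rows = [], []

    def ct_of(y_log2, E, intercept=32.0):
        return intercept - y_log2 * np.log(2.0) / np.log(E)

    for p in chosen:
        g = gene_names[p]
        y = expr.values.loc[p].to_numpy()
        for s, yv in zip(samples, y):
            for rep in range(1, n_replicates + 1):
                ct_rows.append(
                    {"gene": g, "sample_id": s, "replicate": rep,
                     "Ct": ct_of(yv, eff[g]) + rng.normal(0, noise_sd)}
                )
        pool = float(np.mean(y))
        for conc in (1.0, 0.5, 0.25, 0.125):
            dil_rows.append(
                {"gene": g, "concentration": conc,
                 "Ct": ct_of(pool + np.log2(conc), eff[g]) + rng.normal(0, noise_sd)}
            )
    for s in samples:
        for rep in range(1, n_replicates + 1):
            ct_rows.append(
                {"gene": reference_gene, "sample_id": s, "replicate": rep,
                 "Ct": ct_of(cfg.baseline_mean, eff[reference_gene]) + rng.normal(0, noise_sd)}
            )
    for conc in (1.0, 0.5, 0.25, 0.125):
        dil_rows.append(
            {"gene": reference_gene, "concentration": conc,
             "Ct": ct_of(cfg.baseline_mean + np.log2(conc), eff[reference_gene])
                   + rng.normal(0, noise_sd)}
        )
    return (
        pd.DataFrame(ct_rows),
        pd.DataFrame(dil_rows),
        eff,
        {gene_names[p]: p for p in chosen},
    )
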