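"""Replicate simulation study: bias, type I error, power, MRT, and RE.

For each replicate the cohort trait is residualized on age/sex/smoking; every
requested design then selects its sample from the residual distribution
(afresh per replicate, with sub-seeds derived from the master seed so that
adding a design never perturbs another design's draws) and every requested
model is fit on that sample.  Under the probability designs (D5_1/D5_2) the
forward linear model uses IPW weights and the design-based sandwich variance;
the reverse GLMs condition on the trait and are always unweighted.

Summaries per (design, model, target): mean coefficient, empirical SD of the
coefficients, mean estimated SE, rejection rate at the nominal level (type I
error for a null trait, power for an alternative trait), MRT (mean over
replicates of |full-cohort statistic| / |design statistic|), and RE (100 x
ratio of the full-cohort coefficient's empirical variance to the design's).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import fit_glm_reverse, fit_linear
from .cohort import Cohort, make_cohort
from .designs import DESIGN_IDS, make_selection
from .trait_prep import median_distance, residualize
from .variants import filter_and_classify, minor_allele_dosage, rare_variant_score

__all__ = [
    "SimulationConfig",
    "run_simulation",
    "rejection_rate",
    "mrt",
    "relative_efficiency",
    "summarize",
    "plot_statistic_scatter",
]

MODELS = ("linear", "poisson_rev", "logistic_rev")
TARGETS = ("rare_score", "common")


@dataclass
class SimulationConfig:
    """Dimensions and settings of one replicate study."""

    n: int = 321
    n_replicates: int = 200
    alpha: float = 0.05
    designs: tuple[str, ...] = DESIGN_IDS
    models: tuple[str, ...] = MODELS
    targets: tuple[str, ...] = TARGETS
    trait_kind: str = "null"  # null -> type I error; alternative -> power
    fraction: float = 0.5
    floor: float = 0.1
    master_seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates")
        for d in self.designs:
            if d not in DESIGN_IDS:
                raise ValueError(f"unknown design {d!r}")
        for m in self.models:
            if m not in MODELS:
                raise ValueError(f"unknown model {m!r}")


def _fit_cell(model, target, sel, y, score, common, carrier, design_id):
    """Fit one (model, target) on one design's sample; None when inapplicable."""
    idx = sel.indices
    ys = y[idx]
    weighted = design_id.startswith("D5")
    if model == "linear":
        x = score[idx] if target == "rare_score" else common[idx]
        if weighted:
            return fit_linear(ys, x, weights=sel.w[idx],
                              variance_mode="design_sandwich", design_id=design_id)
        return fit_linear(ys, x, design_id=design_id)
    if model == "poisson_rev":
        if target != "rare_score":
            return None
        return fit_glm_reverse(score[idx], ys, "poisson", design_id=design_id)
    if model == "logistic_rev":
        if target != "common":
            return None
        return fit_glm_reverse(carrier[idx], ys, "binomial", design_id=design_id)
    raise ValueError(f"unknown model {model!r}")


def run_simulation(config: SimulationConfig, cohort: Cohort | None = None) -> pd.DataFrame:
    """Run the full replicate study; returns one row per fitted cell.

    Columns: replicate, design, model, target, coefficient, se, statistic,
    p_value, n_used, converged.  Cells whose fit raises are recorded with NaN
    estimates and ``converged=False`` rather than aborting the study.
    Deterministic given ``config.master_seed``.
    """
    if cohort is None:
        cohort = make_cohort(n=config.n, trait_kind=config.trait_kind,
                             n_replicates=config.n_replicates,
                             seed=config.master_seed)
    if cohort.n_replicates < config.n_replicates:
        raise ValueError("cohort holds fewer trait replicates than requested")

    panel = filter_and_classify(pd.DataFrame(cohort.genotypes,
                                             columns=cohort.snp_ids))
    geno_df = pd.DataFrame(cohort.genotypes, columns=cohort.snp_ids)
    score = rare_variant_score(geno_df, panel)
    if panel.common_snp is not None:
        common = minor_allele_dosage(geno_df[panel.common_snp].to_numpy())
    else:
        common = None
    carrier = None if common is None else (common >= 1).astype(float)

    rows = []
    for r in range(config.n_replicates):
        y = residualize(cohort.traits[:, r], cohort.covariates)
        rt = median_distance(y)
        for d_idx, design in enumerate(config.designs):
            seed = np.random.SeedSequence(
                (config.master_seed, r, DESIGN_IDS.index(design)))
            sel = make_selection(design, rt, seed=np.random.default_rng(seed),
                                 fraction=config.fraction, floor=config.floor)
            for target in config.targets:
                if target == "common" and common is None:
                    continue
                for model in config.models:
                    try:
                        fit = _fit_cell(model, target, sel, y, score, common,
                                        carrier, design)
                    except Exception:
                        fit = "error"
                    if fit is None:
                        continue
                    if fit == "error":
                        rows.append(dict(replicate=r, design=design, model=model,
                                         target=target, coefficient=np.nan,
                                         se=np.nan, statistic=np.nan,
                                         p_value=np.nan, n_used=sel.n_sampled,
                                         converged=False))
                        continue
                    rows.append(dict(replicate=r, design=design,
                                     model=fit.model, target=target,
                                     coefficient=fit.coefficient, se=fit.se,
                                     statistic=fit.statistic,
                                     p_value=fit.p_value, n_used=fit.n_used,
                                     converged=fit.converged))
    return pd.DataFrame(rows)


def rejection_rate(p_values, alpha: float) -> float:
    """Share of replicates with p < alpha (strict); NaN cells are dropped."""
    p = pd.Series(p_values).dropna().to_numpy()
    if p.size == 0:
        return float("nan")
    return float((p < alpha).mean())


def mrt(stats_d1, stats_alt) -> float:
    """Mean over replicates of |full-cohort statistic| / |design statistic|.

    Pairs with |design statistic| < 1e-12 (or either value missing) are
    skipped.  Returns NaN when no valid pairs remain.
    """
    a = np.asarray(stats_d1, dtype=float)
    b = np.asarray(stats_alt, dtype=float)
    if a.shape != b.shape:
        raise ValueError("statistic vectors must be paired by replicate")
    ok = np.isfinite(a) & np.isfinite(b) & (np.abs(b) >= 1e-12)
    if not ok.any():
        return float("nan")
    return float(np.mean(np.abs(a[ok]) / np.abs(b[ok])))


def relative_efficiency(coefs_d1, coefs_alt) -> float:
    """100 x var(full-cohort coefficients) / var(design coefficients).

    Sample variances with divisor R-1 over non-missing replicates.  Returns
    NaN when the alternative design's variance is zero.
    """
    a = pd.Series(coefs_d1).dropna().to_numpy()
    b = pd.Series(coefs_alt).dropna().to_numpy()
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least 2 coefficients per design")
    vb = b.var(ddof=1)
    if vb == 0.0:
        return float("nan")
    return float(100.0 * (a.var(ddof=1) / vb))


def summarize(results: pd.DataFrame, config: SimulationConfig) -> pd.DataFrame:
    """Per-(design, model, target) summary of a replicate study.

    Non-converged fits are excluded (their count is reported in
    ``n_excluded``).  MRT and RE compare each design against the full cohort
    (D1) for the same model and target; they are NaN when D1 was not run.
    """
    res = results.copy()
    res.loc[~res["converged"].astype(bool), ["coefficient", "se", "statistic",
                                             "p_value"]] = np.nan
    rows = []
    grouped = res.groupby(["design", "model", "target"], sort=False)
    d1 = {}
    for (design, model, target), g in grouped:
        if design == "D1":
            d1[(model, target)] = g.set_index("replicate")
    for (design, model, target), g in grouped:
        coefs = g["coefficient"]
        base_model = "linear" if model == "ipw_linear" else model
        base = d1.get((base_model, target))
        row = dict(
            design=design, model=model, target=target,
            mean_coefficient=coefs.mean(),
            empirical_sd=coefs.std(ddof=1),
            mean_se=g["se"].mean(),
            rejection_rate=rejection_rate(g["p_value"], config.alpha),
            n_fits=int(g["converged"].astype(bool).sum()),
            n_excluded=int((~g["converged"].astype(bool)).sum()),
            mrt=np.nan, re=np.nan,
        )
        if base is not None:
            paired = g.set_index("replicate")
            common_idx = base.index.intersection(paired.index)
            row["mrt"] = mrt(base.loc[common_idx, "statistic"],
                             paired.loc[common_idx, "statistic"])
            if coefs.dropna().size >= 2:
                row["re"] = relative_efficiency(base["coefficient"],
                                                paired["coefficient"])
        rows.append(row)
    return pd.DataFrame(rows)


def plot_statistic_scatter(results: pd.DataFrame, model: str, target: str,
                           path) -> None:
    """Pairwise scatter of full-cohort vs alternative-design test statistics."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = results[(results["target"] == target)
                  & (results["model"].str.replace("ipw_", "") == model.replace("ipw_", ""))]
    base = sub[sub["design"] == "D1"].set_index("replicate")["statistic"]
    alts = [d for d in sub["design"].unique() if d != "D1"]
    fig, axes = plt.subplots(1, max(len(alts), 1),
                             figsize=(3 * max(len(alts), 1), 3), squeeze=False)
    for ax, d in zip(axes[0], alts):
        alt = sub[sub["design"] == d].set_index("replicate")["statistic"]
        idx = base.index.intersection(alt.index)
        ax.scatter(base.loc[idx], alt.loc[idx], s=6)
        lim = [min(base.min(), alt.min()), max(base.max(), alt.max())]
        ax.plot(lim, lim, lw=0.5, color="gray")
        ax.set_title(d)
        ax.set_xlabel("D1 statistic")
    axes[0][0].set_ylabel(f"{model} statistic")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
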