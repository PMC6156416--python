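"""Leave-one-out validation of phylogenetic trait prediction.

For each measured species the species is removed, the model is refit on
the remainder, the species' value is predicted with its 95% prediction
interval, and two aggregates are reported:

* ``coverage_pct`` — percentage of species whose observed value falls
  inside the interval (nominally 95);
* ``median_dev_sd`` — median |observed - predicted| expressed as a
  proportion of the sample standard deviation (n - 1 divisor) of all
  measured values for the trait.

Two predictors are validated: the phylogenetic-signal-only imputer
(:func:`jackknife_phylo`) and the PGLS regression predictor with
Garland-Ives prediction intervals (:func:`jackknife_regression`, using
species with complete life-history covariates). By default lambda and
sigma^2 are re-estimated in every leave-one-out iteration (true
leave-one-out); ``refit=False`` reuses the full-sample estimates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ancestral import PhylogeneticImputer
from .errors import FitError
from .pgls import PGLS
from .traits import TraitTable
from .tree import Phylogeny

__all__ = [
    "ValidationReport",
    "jackknife_phylo",
    "jackknife_regression",
    "compare_methods",
    "compare_across_traits",
]


@dataclass
class ValidationReport:
    """Per-species jackknife results and their aggregates."""

    table: pd.DataFrame  #: observed, predicted, ci_low, ci_high, inside, abs_dev
    coverage_pct: float
    median_dev_sd: float
    n: int
    sd: float  #: sample SD of the measured values (n - 1 divisor)


def _aggregate(rows: list[dict], sd: float) -> ValidationReport:
    table = pd.DataFrame(rows).set_index("species")
    coverage = 100.0 * float(table["inside"].mean())
    med = float(table["abs_dev"].median()) / sd
    return ValidationReport(table, coverage, med, len(table), sd)


def jackknife_phylo(
    tree: Phylogeny,
    table,
    column: str | None = None,
    refit: bool = True,
    lam="ml",
    t_mode: str = "path",
) -> ValidationReport:
    """Jackknife the phylogenetic-signal-only prediction of one trait.

    ``table`` may be a TraitTable (with ``column``) or a species-indexed
    Series. Requires at least 5 measured species on the tree.
    """
    if isinstance(table, TraitTable):
        values = table.column(column).dropna()
    else:
        values = pd.Series(table).dropna()
    on_tree = [t for t in tree.tip_labels if t in set(values.index)]
    if len(on_tree) < 5:
        raise FitError(f"jackknife needs >= 5 measured species, have {len(on_tree)}")
    values = values.loc[on_tree]
    sd = float(values.std(ddof=1))

    full_imp = None
    if not refit:
        full_imp = PhylogeneticImputer(tree=tree, lam=lam, t_mode=t_mode).fit(values)

    rows = []
    for sp in on_tree:
        rest = values.drop(sp)
        if refit:
            imp = PhylogeneticImputer(tree=tree, lam=lam, t_mode=t_mode).fit(rest)
        else:
            imp = PhylogeneticImputer(
                tree=tree, lam=full_imp.lambda_, t_mode=t_mode
            ).fit(rest)
            imp.sigma2_ = full_imp.sigma2_
        pred = imp._predict_one(sp)
        if not refit:
            half = 1.96 * np.sqrt(pred.t * full_imp.sigma2_)
            pred.var = pred.t * full_imp.sigma2_
            pred.ci_low, pred.ci_high = pred.predicted - half, pred.predicted + half
        obs = float(values.loc[sp])
        rows.append(
            {
                "species": sp,
                "observed": obs,
                "predicted": pred.predicted,
                "ci_low": pred.ci_low,
                "ci_high": pred.ci_high,
                "inside": bool(pred.ci_low <= obs <= pred.ci_high),
                "abs_dev": abs(obs - pred.predicted),
            }
        )
    return _aggregate(rows, sd)


def jackknife_regression(
    tree: Phylogeny,
    table: TraitTable,
    outcome: str,
    predictors,
    log_outcome: bool = False,
    lam="ml",
    refit: bool = True,
) -> ValidationReport:
    """Jackknife the PGLS/Garland-Ives regression prediction of one trait.

    Restricted to species with the outcome and every predictor observed.
    Each left-out species is predicted by the GLS BLUP (regression part
    plus phylogenetically weighted residual) with prediction variance
    including coefficient uncertainty.
    """
    predictors = list(predictors)
    if log_outcome:
        table = table.transform(outcome, "log")
    sub = table.df[[outcome] + predictors].dropna()
    on_tree = [t for t in tree.tip_labels if t in set(sub.index)]
    if len(on_tree) < 5:
        raise FitError(f"jackknife needs >= 5 complete cases, have {len(on_tree)}")
    sub = sub.loc[on_tree]
    y = sub[outcome]
    sd = float(y.std(ddof=1))

    lam_fixed = lam
    if not refit:
        m = PGLS(tree=tree, lam=lam).fit(sub[predictors], y.to_numpy(), species=on_tree)
        lam_fixed = m.lambda_

    rows = []
    for sp in on_tree:
        rest = sub.drop(index=sp)
        model = PGLS(tree=tree, lam=lam if refit else lam_fixed).fit(
            rest[predictors], rest[outcome].to_numpy(), species=list(rest.index)
        )
        out = model.predict(
            sub.loc[[sp], predictors], species=[sp], interval=True, full_tree=tree
        )
        obs = float(y.loc[sp])
        rows.append(
            {
                "species": sp,
                "observed": obs,
                "predicted": float(out["predicted"].iloc[0]),
                "ci_low": float(out["ci_low"].iloc[0]),
                "ci_high": float(out["ci_high"].iloc[0]),
                "inside": bool(out["ci_low"].iloc[0] <= obs <= out["ci_high"].iloc[0]),
                "abs_dev": abs(obs - float(out["predicted"].iloc[0])),
            }
        )
    return _aggregate(rows, sd)


def compare_methods(report_a: ValidationReport, report_b: ValidationReport,
                    labels=("phylo", "regression")) -> pd.DataFrame:
    """Side-by-side coverage and median deviation of two reports."""
    df = pd.DataFrame(
        {
            labels[0]: [report_a.coverage_pct, report_a.median_dev_sd, report_a.n],
            labels[1]: [report_b.coverage_pct, report_b.median_dev_sd, report_b.n],
        },
        index=["coverage_pct", "median_dev_sd", "n"],
    )
    df["difference"] = df[labels[0]] - df[labels[1]]
    return df


def compare_across_traits(reports: dict) -> pd.DataFrame:
    """Stack {trait: ValidationReport} into a table with a mean row."""
    df = pd.DataFrame(
        {
            t: {"coverage_pct": r.coverage_pct, "median_dev_sd": r.median_dev_sd, "n": r.n}
            for t, r in reports.items()
        }
    ).T
    df.loc["mean"] = [df["coverage_pct"].mean(), df["median_dev_sd"].mean(), df["n"].mean()]
    return df
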