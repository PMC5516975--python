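"""Repeated k-fold cross-validation of genomic prediction accuracy.

Individuals are randomly partitioned into k near-equal folds; each fold is
predicted in turn with its phenotypes masked, the model being trained on the
remaining folds.  The whole partition is redrawn for each repeat.

The headline criterion is the average over folds and repeats of Pearson's
correlation r between validation GEBVs and corrected phenotypes, divided by
the square root of the trait heritability (r / sqrt(h2)), with h2 estimated
once on the full data by G-matrix REML; the reported dispersion is the
standard deviation of the per-fold correlations on the same scale.  Because
breeding values have no absolute origin, GEBVs predicted from different
training sets carry arbitrary offsets; correlations are therefore always
computed within a validation set, and the per-individual GEBVs returned for
inspection are centered within each fold before averaging over repeats.
When simulation truth is available the correlation with the true breeding
values is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .gblup import GMatrix, VarianceComponents, gblup_predict, reml_h2, vanraden_G
from .genoio import GenotypeMatrix
from .mcmc import METHODS, PriorSpec
from .parchain import ChainPlan, gebv_from_effects, plan_chains, run_parallel

__all__ = ["FoldPlan", "AccuracyResult", "make_folds", "cross_validate", "comparison_report"]


@dataclass(frozen=True)
class FoldPlan:
    """One repeat's random partition into k folds."""

    k: int
    assignments: np.ndarray  # fold index per individual, values in 0..k-1
    repeat_id: int
    seed: int


@dataclass
class AccuracyResult:
    """Cross-validated accuracy of one method on one trait."""

    trait: str
    method: str
    r: float  # mean over folds x repeats of cor(validation GEBV, corrected phenotype)
    h2: float
    accuracy: float  # r / sqrt(h2)
    dispersion: float  # SD of per-fold-per-repeat correlations / sqrt(h2)
    fold_correlations: np.ndarray = field(default_factory=lambda: np.empty(0))
    r_tbv: Optional[float] = None  # cor(averaged GEBV, TBV), simulation only
    gebv: Optional[np.ndarray] = None
    error: Optional[str] = None


def make_folds(
    individual_ids: Sequence, k: int, repeats: int = 1, seed: int = 0
) -> list[FoldPlan]:
    """Random near-equal k-fold partitions, one per repeat, deterministic in seed."""
    n = len(individual_ids)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > n:
        raise ValueError(f"k={k} folds but only {n} individuals")
    rng = np.random.default_rng(seed)
    plans = []
    for rep in range(repeats):
        perm = rng.permutation(n)
        assign = np.empty(n, dtype=int)
        # fold sizes differ by at most one
        sizes = np.full(k, n // k)
        sizes[: n % k] += 1
        start = 0
        for f, s in enumerate(sizes):
            assign[perm[start : start + s]] = f
            start += s
        plans.append(FoldPlan(k=k, assignments=assign, repeat_id=rep, seed=seed))
    return plans


def _bayes_fold_gebv(
    method: str,
    G: GenotypeMatrix,
    y: np.ndarray,
    train: np.ndarray,
    val: np.ndarray,
    total_iter: int,
    burn_in: int,
    n_chains: int,
    seed: int,
    prior: PriorSpec | None,
    n_jobs: int,
) -> np.ndarray:
    Gtr = G.subset_individuals(train)
    plan = plan_chains(total_iter, burn_in, n_chains, seed)
    pooled = run_parallel(method, Gtr, y[train], plan, prior=prior, n_jobs=n_jobs)
    Gval = G.subset_individuals(val)
    return gebv_from_effects(Gval, pooled.pooled_effects, effect_marker_ids=Gtr.marker_ids)


def cross_validate(
    method: str,
    genotypes: GenotypeMatrix,
    y_corrected: np.ndarray,
    k: int = 5,
    repeats: int = 10,
    total_iter: int = 50_000,
    burn_in: int = 5_000,
    n_chains: int = 1,
    seed: int = 0,
    prior: PriorSpec | None = None,
    h2: float | None = None,
    vc: VarianceComponents | None = None,
    tbv: np.ndarray | None = None,
    trait: str = "trait",
    fold_plans: list[FoldPlan] | None = None,
    n_jobs: int = 1,
) -> AccuracyResult:
    """Repeated k-fold cross-validation of one prediction method.

    For every repeat each individual is predicted exactly once, from the fold
    where it was held out with phenotype masked.  The headline r is the mean
    of the per-fold, per-repeat validation correlations; ``gebv`` holds the
    fold-centered GEBVs averaged over repeats.  ``h2`` (for the accuracy
    scaling) defaults to a single G-matrix REML estimate on the full data,
    shared by all methods on the trait.
    ``fold_plans`` may be supplied to compare methods or chain counts on an
    identical partition.
    """
    if method != "gblup" and method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    y = np.asarray(y_corrected, dtype=float)
    n = genotypes.n_individuals
    if y.size != n:
        raise ValueError("phenotype length does not match genotypes")
    if fold_plans is None:
        fold_plans = make_folds(genotypes.individual_ids, k, repeats, seed)
    G_rel: GMatrix | None = None
    if h2 is None or method == "gblup":
        G_rel = vanraden_G(genotypes)
    if vc is None and method == "gblup":
        vc = reml_h2(y, G_rel)
    if h2 is None:
        h2 = (vc or reml_h2(y, G_rel)).heritability
    if h2 <= 0:
        raise ValueError("h2 must be positive to scale accuracies")

    gebv_by_rep = np.zeros((len(fold_plans), n))
    fold_r: list[float] = []
    for rep, plan in enumerate(fold_plans):
        for f in range(plan.k):
            val = np.flatnonzero(plan.assignments == f)
            train = np.flatnonzero(plan.assignments != f)
            if method == "gblup":
                ghat = gblup_predict(y[train], G_rel, train, vc)
                gebv_val = ghat[val]
            else:
                fold_seed = int(
                    np.random.SeedSequence([seed, rep, f]).generate_state(1, np.uint32)[0]
                ) & 0x7FFFFFFF
                gebv_val = _bayes_fold_gebv(
                    method, genotypes, y, train, val, total_iter, burn_in,
                    n_chains, fold_seed, prior, n_jobs,
                )
            gebv_by_rep[rep, val] = gebv_val - gebv_val.mean()  # fold-centered
            if np.std(gebv_val) > 0 and np.std(y[val]) > 0:
                fold_r.append(float(np.corrcoef(gebv_val, y[val])[0, 1]))
            else:
                fold_r.append(np.nan)

    gebv_avg = gebv_by_rep.mean(axis=0)
    fold_r_arr = np.asarray(fold_r)
    valid = fold_r_arr[~np.isnan(fold_r_arr)]
    err = None
    if valid.size == 0:
        r = float("nan")
        err = "constant GEBV vector; correlation undefined"
    else:
        r = float(valid.mean())
    disp = float(np.std(valid, ddof=1) / np.sqrt(h2)) if valid.size > 1 else 0.0
    r_tbv = None
    if tbv is not None and np.std(gebv_avg) > 0:
        r_tbv = float(np.corrcoef(gebv_avg, np.asarray(tbv, float))[0, 1])
    return AccuracyResult(
        trait=trait,
        method=method,
        r=r,
        h2=float(h2),
        accuracy=r / np.sqrt(h2),
        dispersion=disp,
        fold_correlations=fold_r_arr,
        r_tbv=r_tbv,
        gebv=gebv_avg,
        error=err,
    )


def comparison_report(results: Sequence[AccuracyResult], digits: int = 3) -> pd.DataFrame:
    """Tidy trait x method table of r(SD) and accuracy(SD) plus a per-method mean row.

    Values are formatted to ``digits`` decimals as ``value(SD)``; the final
    ``mean`` row averages the trait rows method by method.  When simulation
    truth was supplied (``r_tbv``), a correlation-with-TBV column is added
    per method.
    """
    if not results:
        raise ValueError("no results to report")
    methods = list(dict.fromkeys(r.method for r in results))
    traits = list(dict.fromkeys(r.trait for r in results))
    by = {(r.trait, r.method): r for r in results}
    with_tbv = any(r.r_tbv is not None for r in results)

    def fmt(v: float, s: float) -> str:
        return f"{v:.{digits}f}({s:.{digits}f})"

    rows = []
    for t in traits:
        row: dict[str, object] = {"trait": t}
        for m in methods:
            res = by.get((t, m))
            if res is None:
                row[f"r_{m}"] = ""
                row[f"acc_{m}"] = ""
                if with_tbv:
                    row[f"rtbv_{m}"] = ""
            else:
                r_sd = res.dispersion * np.sqrt(res.h2)  # SD on the r scale
                row[f"r_{m}"] = fmt(res.r, r_sd)
                row[f"acc_{m}"] = fmt(res.accuracy, res.dispersion)
                if with_tbv:
                    row[f"rtbv_{m}"] = (
                        f"{res.r_tbv:.{digits}f}" if res.r_tbv is not None else ""
                    )
        rows.append(row)
    mean_row: dict[str, object] = {"trait": "mean"}
    for m in methods:
        rs = [by[(t, m)] for t in traits if (t, m) in by]
        if with_tbv:
            tb = [x.r_tbv for x in rs if x.r_tbv is not None]
            mean_row[f"rtbv_{m}"] = f"{np.mean(tb):.{digits}f}" if tb else ""
        if rs:
            mean_row[f"r_{m}"] = fmt(
                float(np.mean([x.r for x in rs])),
                float(np.mean([x.dispersion * np.sqrt(x.h2) for x in rs])),
            )
            mean_row[f"acc_{m}"] = fmt(
                float(np.mean([x.accuracy for x in rs])),
                float(np.mean([x.dispersion for x in rs])),
            )
        else:
            mean_row[f"r_{m}"] = ""
            mean_row[f"acc_{m}"] = ""
    rows.append(mean_row)
    return pd.DataFrame(rows)
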