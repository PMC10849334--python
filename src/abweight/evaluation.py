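"""Leave-one-family-out evaluation, metrics, and relative efficiencies.

Each family serves once as the test set: its phenotypes are masked, the
(weighted or unweighted) GRM is built on all lines, the multi-kernel
GBLUP is fit per trait, and MSE / Pearson correlation / NRMSE are
computed on the held-out family's observations pooled across
environments, then averaged across traits.  Relative efficiency compares
the two methods per family — GBLUP/AB ratios for the error metrics (MSE,
NRMSE) and the AB/GBLUP ratio for the correlation, so values above 1
always favor the weighted method.  The across-family (AF) row holds the
arithmetic mean of the per-family metrics and the arithmetic mean of the
per-family relative efficiencies (not the ratio of AF metrics).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .adversarial import ab_weights
from .boruta import BorutaConfig
from .data import Dataset
from .gblup import MCMCSettings, ModelSpec, fit_predict
from .grm import WeightVector, compute_grm, compute_weighted_grm

logger = logging.getLogger(__name__)

METRIC_COLUMNS = [
    "MSE_GBLUP",
    "COR_GBLUP",
    "NRMSE_GBLUP",
    "MSE_AB",
    "COR_AB",
    "NRMSE_AB",
]
RE_COLUMNS = ["RE_MSE", "RE_COR", "RE_NRMSE"]


def mse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Mean squared deviation between observed and predicted values."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.shape != predicted.shape or observed.size < 1:
        raise ValueError("observed and predicted must have equal nonzero length")
    return float(np.mean((observed - predicted) ** 2))


def pearson_cor(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Sample Pearson correlation; NaN if length < 3 or a vector is constant."""
    observed = np.asarray(observed, float)
    predicted = np.asarray(predicted, float)
    if observed.shape != predicted.shape:
        raise ValueError("observed and predicted must have equal length")
    if observed.size < 3 or observed.std() == 0 or predicted.std() == 0:
        return float("nan")
    return float(np.corrcoef(observed, predicted)[0, 1])


def nrmse(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Root-MSE divided by the mean of the observed values.

    Meaningful only for positive-mean responses; otherwise NaN with a
    warning (the normalization would flip sign or blow up).
    """
    observed = np.asarray(observed, float)
    mean_obs = float(np.mean(observed))
    if mean_obs <= 0:
        warnings.warn(
            "NRMSE undefined for non-positive observed mean; returning NaN",
            RuntimeWarning,
            stacklevel=2,
        )
        return float("nan")
    return float(np.sqrt(mse(observed, predicted)) / mean_obs)


def relative_efficiency(metric_gblup: float, metric_ab: float, kind: str) -> float:
    """RE of the weighted method vs plain GBLUP for one metric.

    Error metrics (``mse``, ``nrmse``) use GBLUP/AB, the correlation uses
    AB/GBLUP; either way RE > 1 means the weighted method wins.
    """
    if kind in ("mse", "nrmse"):
        num, den = metric_gblup, metric_ab
    elif kind == "cor":
        num, den = metric_ab, metric_gblup
    else:
        raise ValueError(f"unknown metric kind {kind!r}")
    if den == 0:
        raise ZeroDivisionError(f"zero denominator in RE_{kind.upper()}")
    return float(num / den)


@dataclass
class FamilyMetrics:
    """Trait-averaged prediction metrics for one held-out family."""

    family_id: str
    mse: float
    cor: float
    nrmse: float
    n_test: int
    per_trait: pd.DataFrame | None = None


@dataclass
class REReport:
    """Per-family + across-family comparison table for the two methods."""

    table: pd.DataFrame  # per-family rows followed by an "AF" row

    def rounded(self, decimals: int = 3) -> pd.DataFrame:
        out = self.table.copy()
        num = out.select_dtypes("number").columns
        out[num] = out[num].round(decimals)
        return out

    def to_csv(self, path) -> None:
        self.rounded().to_csv(path, index=False)


def _nanmean(values) -> float:
    arr = np.asarray(values, float)
    if np.all(np.isnan(arr)):
        return float("nan")
    return float(np.nanmean(arr))


def compute_re_table(per_family: pd.DataFrame, dataset_name: str = "") -> REReport:
    """RE columns + across-family row from per-family metric columns.

    ``per_family`` needs columns ``Family`` and the six metric columns
    (MSE/COR/NRMSE for each method).  Per-family REs are computed from
    the metric columns; the AF row is the arithmetic mean of each metric
    column and of each RE column.  Families with undefined correlation
    are excluded from the COR and RE_COR averages only.
    """
    df = per_family.copy()
    missing = [c for c in ["Family", *METRIC_COLUMNS] if c not in df.columns]
    if missing:
        raise ValueError(f"per-family table missing column(s): {missing}")
    df["RE_MSE"] = df["MSE_GBLUP"] / df["MSE_AB"]
    df["RE_COR"] = df["COR_AB"] / df["COR_GBLUP"]
    df["RE_NRMSE"] = df["NRMSE_GBLUP"] / df["NRMSE_AB"]
    af = {"Family": "AF"}
    for col in METRIC_COLUMNS + RE_COLUMNS:
        af[col] = _nanmean(df[col])
    out = pd.concat([df, pd.DataFrame([af])], ignore_index=True)
    if dataset_name:
        out.insert(0, "Data_set", dataset_name)
    return REReport(out)


def aggregate_report(
    metrics_gblup: list[FamilyMetrics],
    metrics_ab: list[FamilyMetrics],
    dataset_name: str = "",
) -> REReport:
    """Pair per-family metrics of the two methods into the report table."""
    fams_g = [m.family_id for m in metrics_gblup]
    fams_a = [m.family_id for m in metrics_ab]
    if fams_g != fams_a:
        raise ValueError(
            f"family sets differ between methods: {fams_g} vs {fams_a}"
        )
    rows = []
    for g, a in zip(metrics_gblup, metrics_ab):
        rows.append(
            {
                "Family": g.family_id,
                "MSE_GBLUP": g.mse,
                "COR_GBLUP": g.cor,
                "NRMSE_GBLUP": g.nrmse,
                "MSE_AB": a.mse,
                "COR_AB": a.cor,
                "NRMSE_AB": a.nrmse,
            }
        )
    return compute_re_table(pd.DataFrame(rows), dataset_name=dataset_name)


def plot_re_bars(report: REReport, path) -> None:
    """One bar panel per RE metric, families on the x-axis plus the AF
    bar, with a reference line at RE = 1 (parity between methods)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    table = report.table
    fig, axes = plt.subplots(1, len(RE_COLUMNS), figsize=(4 * len(RE_COLUMNS), 3.2))
    for ax, col in zip(np.atleast_1d(axes), RE_COLUMNS):
        ax.bar(table["Family"].astype(str), table[col], color="steelblue")
        ax.axhline(1.0, color="black", lw=0.8, ls="--")
        ax.set_title(col)
        ax.tick_params(axis="x", rotation=90)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _fold_metrics(
    dataset: Dataset,
    family: str,
    G,
    mcmc: MCMCSettings,
) -> FamilyMetrics:
    """Fit one masked-family fold per trait and score the held-out family."""
    pheno = dataset.phenotypes.records
    line_ids = dataset.markers.line_ids
    rows = []
    for trait in dataset.phenotypes.traits:
        sub = pheno[pheno["trait"] == trait]
        is_test = (sub["family"] == family).to_numpy()
        y = sub["value"].to_numpy(dtype=float).copy()
        y_obs_test = y[is_test].copy()
        y[is_test] = np.nan
        spec = ModelSpec(
            obs=sub[["line", "env"]].reset_index(drop=True),
            y=y,
            G=G.values,
            line_ids=line_ids,
            trait=trait,
        )
        summary = fit_predict(spec, mcmc)
        y_pred = summary.predictions["y_pred"].to_numpy()
        rows.append(
            {
                "trait": trait,
                "mse": mse(y_obs_test, y_pred),
                "cor": pearson_cor(y_obs_test, y_pred),
                "nrmse": nrmse(y_obs_test, y_pred),
                "n_test": int(is_test.sum()),
            }
        )
    per_trait = pd.DataFrame(rows)
    return FamilyMetrics(
        family_id=family,
        mse=_nanmean(per_trait["mse"]),
        cor=_nanmean(per_trait["cor"]),
        nrmse=_nanmean(per_trait["nrmse"]),
        n_test=int(per_trait["n_test"].sum()),
        per_trait=per_trait,
    )


def lofo_cv(
    dataset: Dataset,
    method: str,
    boruta_config: BorutaConfig | None = None,
    mcmc: MCMCSettings | None = None,
    seed: int = 0,
    ab_weights_override: dict[str, WeightVector] | None = None,
) -> list[FamilyMetrics]:
    """Leave-one-family-out cross-validation for one method.

    Exactly one fold per family; the held-out family's phenotypes are
    masked, the GRM (``method='gblup'``) or the adversarially weighted
    GRM (``method='ab'``) is built over ALL lines, and predictions are
    scored on the held-out family.  Folds derive their MCMC seed as
    ``seed + family index``, so the two methods run under identical
    fold seeds and RE differences reflect only G vs G*.

    ``ab_weights_override`` maps family IDs to precomputed weight
    vectors, bypassing the adversarial run (used to force the degenerate
    uniform-weight fallback).
    """
    if method not in ("gblup", "ab"):
        raise ValueError(f"unknown method {method!r}")
    boruta_config = boruta_config or BorutaConfig(seed=seed)
    mcmc = mcmc or MCMCSettings(seed=seed)
    families = dataset.families
    if len(families) < 2:
        raise ValueError("leave-one-family-out needs at least 2 families")
    M = dataset.markers.M
    line_ids = dataset.markers.line_ids
    G_plain = compute_grm(M, line_ids)
    results: list[FamilyMetrics] = []
    pheno = dataset.phenotypes.records
    for fam_index, family in enumerate(families):
        if not (pheno["family"] == family).any():
            logger.warning("family %s has no phenotyped lines; fold skipped", family)
            continue
        if method == "ab":
            if ab_weights_override is not None and family in ab_weights_override:
                w = ab_weights_override[family]
            else:
                w = ab_weights(dataset, family, boruta_config)
            G = compute_weighted_grm(M, w, line_ids)
        else:
            G = G_plain
        fold_mcmc = MCMCSettings(
            n_iter=mcmc.n_iter,
            burn_in=mcmc.burn_in,
            thin=mcmc.thin,
            seed=(mcmc.seed + fam_index) % (2**31 - 1),
            df_prior=mcmc.df_prior,
            r2=mcmc.r2,
        )
        results.append(_fold_metrics(dataset, family, G, fold_mcmc))
    return results
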