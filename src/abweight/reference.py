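"""Access to the bundled reference per-family prediction metrics.

The package ships a small table of published per-family MSE, Pearson
correlation and NRMSE values for the unweighted- and weighted-GRM
methods across four multi-family benchmark datasets.  It is used to
validate the relative-efficiency and across-family aggregation
arithmetic: the RE columns and AF rows are recomputed from the metric
columns alone and compared against the published values.
"""

from __future__ import annotations

from importlib.resources import files

import pandas as pd

from .evaluation import REReport, compute_re_table


def load_reference_metrics() -> pd.DataFrame:
    """The bundled per-family metric columns (no RE or AF rows)."""
    path = files("abweight").joinpath("resources/reference_family_metrics.csv")
    with path.open("rb") as fh:
        return pd.read_csv(fh, dtype={"Family": str})


def reference_report(dataset_name: str) -> REReport:
    """Recompute the RE columns and AF row for one benchmark dataset."""
    df = load_reference_metrics()
    sub = df[df["Data_set"] == dataset_name].drop(columns="Data_set")
    if sub.empty:
        known = sorted(df["Data_set"].unique())
        raise ValueError(f"unknown dataset {dataset_name!r}; available: {known}")
    return compute_re_table(sub.reset_index(drop=True), dataset_name=dataset_name)
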