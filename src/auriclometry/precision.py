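"""Statistics harness for repeated auricle measurements.

Works on long-format measurement tables (specimen, side, method,
observer_or_repeat, scanner, dose, parameter, value) and reproduces the
analyses a precision study needs:

* per-condition precision — the sample SD across repeated measurements;
* Levene's test comparing variability between measurement methods;
* one-way ANOVA with Tukey-HSD post hoc comparisons of method means;
* per-parameter OLS regression of the measurement on method variant,
  scanner and dose (dummy-coded);
* error percentages of each method's mean relative to the caliper.

Observers and rounds are pooled into repeats by default, so the per-cell
SD mixes inter- and intra-rater variability; a stratified variant is
available through ``group_keys``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
import warnings

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm
from statsmodels.stats.multicomp import pairwise_tukeyhsd
from statsmodels.stats.multitest import multipletests

from .errors import ArgumentError

__all__ = [
    "MeasurementTable",
    "PrecisionReport",
    "precision_sd",
    "levene_test",
    "anova_posthoc",
    "effects_regression",
    "error_percentage",
    "build_report",
]

COLUMNS = [
    "specimen",
    "side",
    "method",
    "observer_or_repeat",
    "scanner",
    "dose",
    "parameter",
    "value",
]

METHODS = (
    "caliper",
    "landmarking",
    "auto_pca",
    "auto_diameter",
    "auto_sagittal",
    "auto_mastoid",
)


@dataclass
class MeasurementTable:
    """Long-format repeated-measurement table (see :data:`COLUMNS`)."""

    df: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in COLUMNS if c not in self.df.columns]
        if missing:
            raise ArgumentError(f"measurement table lacks columns: {missing}")
        if not np.isfinite(self.df["value"].to_numpy(dtype=float)).all():
            raise ArgumentError("measurement values must be finite")

    @classmethod
    def from_csv(cls, path) -> "MeasurementTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.df.to_csv(path, index=False)

    @classmethod
    def from_records(cls, records) -> "MeasurementTable":
        return cls(pd.DataFrame.from_records(records, columns=COLUMNS))


def _frame(table) -> pd.DataFrame:
    return table.df if isinstance(table, MeasurementTable) else table


def precision_sd(
    table, group_keys=("parameter", "side", "method")
) -> pd.DataFrame:
    """Sample SD (n−1) of repeated values per group.

    Groups with fewer than two values cannot yield an SD and are dropped
    with a warning.
    """
    df = _frame(table)
    g = df.groupby(list(group_keys))["value"]
    out = g.agg(sd=lambda v: v.std(ddof=1), n="count").reset_index()
    single = out["n"] < 2
    if single.any():
        warnings.warn(f"excluding {int(single.sum())} singleton group(s) from SDs")
        out = out[~single]
    return out.reset_index(drop=True)


def levene_test(groups, center: str = "mean") -> tuple[float, float]:
    """Levene's W comparing variances across groups.

    ``center='mean'`` is the classic test (ANOVA on absolute deviations
    from the group mean); ``center='median'`` is the Brown–Forsythe
    variant.  Degenerate input (all deviations zero) returns W = 0, p = 1.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ArgumentError("Levene test needs >= 2 groups with >= 2 values each")
    devs = [
        np.abs(g - (np.mean(g) if center == "mean" else np.median(g))) for g in groups
    ]
    if all(np.allclose(d, 0) for d in devs):
        return 0.0, 1.0
    w, p = stats.levene(*groups, center=center)
    return float(w), float(p)


def anova_posthoc(table, parameter: str, factor: str = "method", alpha: float = 0.05):
    """One-way ANOVA across ``factor`` levels plus Tukey-HSD post hoc.

    Returns ``(F, p, posthoc)`` where ``posthoc`` is a DataFrame of
    pairwise mean differences with adjusted p-values and rejection flags.
    """
    df = _frame(table)
    sub = df[df["parameter"] == parameter]
    levels = sub[factor].unique()
    if len(levels) < 2:
        raise ArgumentError("ANOVA needs at least 2 groups")
    groups = [sub.loc[sub[factor] == lv, "value"].to_numpy(dtype=float) for lv in levels]
    if all(np.allclose(g, np.concatenate(groups).mean()) for g in groups):
        F, p = 0.0, 1.0
    else:
        F, p = stats.f_oneway(*groups)
        if np.isnan(F):  # zero within-group variance with equal means
            F, p = 0.0, 1.0
    tuk = pairwise_tukeyhsd(
        sub["value"].to_numpy(dtype=float), sub[factor].to_numpy(), alpha=alpha
    )
    posthoc = pd.DataFrame(
        tuk.summary().data[1:], columns=[str(c) for c in tuk.summary().data[0]]
    )
    return float(F), float(p), posthoc


def effects_regression(
    table, parameter: str, factors=("method", "scanner", "dose")
) -> pd.DataFrame:
    """Per-parameter OLS of the measured value on dummy-coded factors.

    Returns a table of estimates (mm or degrees), standard errors and
    p-values.  Raises on a rank-deficient design, naming the aliased
    column.
    """
    df = _frame(table)
    sub = df[df["parameter"] == parameter].copy()
    if sub.empty:
        raise ArgumentError(f"no rows for parameter {parameter!r}")
    active = [f for f in factors if sub[f].nunique() > 1]
    if not active:
        raise ArgumentError("no factor varies; regression is unidentifiable")
    X = pd.get_dummies(sub[list(active)].astype(str), drop_first=True, dtype=float)
    X = sm.add_constant(X)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify an aliased column by leave-one-out rank
        for col in X.columns[1:]:
            if np.linalg.matrix_rank(X.drop(columns=col).to_numpy()) == rank:
                raise ArgumentError(f"rank-deficient design: column {col!r} is aliased")
        raise ArgumentError("rank-deficient design")
    fit = sm.OLS(sub["value"].to_numpy(dtype=float), X).fit()
    return pd.DataFrame(
        {
            "term": X.columns,
            "estimate": fit.params,
            "std_err": fit.bse,
            "p_value": fit.pvalues,
        }
    ).reset_index(drop=True)


def error_percentage(
    table, reference_method: str = "caliper", round_to_int: bool = True
) -> pd.DataFrame:
    """|mean(method) − mean(reference)| / mean(reference) × 100.

    Computed per (parameter, side, method); printed tables round to whole
    percent.  Raises if the reference method is absent.
    """
    df = _frame(table)
    if reference_method not in df["method"].unique():
        raise ArgumentError(f"reference method {reference_method!r} not in table")
    means = (
        df.groupby(["parameter", "side", "method"])["value"].mean().reset_index()
    )
    ref = means[means["method"] == reference_method].rename(
        columns={"value": "ref_mean"}
    )[["parameter", "side", "ref_mean"]]
    merged = means.merge(ref, on=["parameter", "side"], how="inner")
    merged = merged[merged["method"] != reference_method].copy()
    merged["error_pct"] = (
        (merged["value"] - merged["ref_mean"]).abs() / merged["ref_mean"].abs() * 100.0
    )
    if round_to_int:
        merged["error_pct"] = merged["error_pct"].round().astype(int)
    return merged[["parameter", "side", "method", "error_pct"]].reset_index(drop=True)


@dataclass
class PrecisionReport:
    """All computed statistics of a measurement table, JSON-serializable."""

    precision: pd.DataFrame
    levene: pd.DataFrame
    anova: dict
    regression: dict
    error_pct: pd.DataFrame | None
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "config": self.config,
            "precision_sd": self.precision.round(6).to_dict(orient="records"),
            "levene": self.levene.round(6).to_dict(orient="records"),
            "anova": self.anova,
            "regression": {
                k: v.round(6).to_dict(orient="records") for k, v in self.regression.items()
            },
            "error_percentage": (
                self.error_pct.to_dict(orient="records")
                if self.error_pct is not None
                else None
            ),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(x):
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    if isinstance(x, np.bool_):
        return bool(x)
    raise TypeError(f"not JSON-serializable: {type(x)}")


def build_report(
    table,
    reference_method: str = "caliper",
    levene_center: str = "mean",
    holm_correction: bool = False,
) -> PrecisionReport:
    """Full precision report for a measurement table.

    Per (parameter, side): SDs per method, pairwise Levene tests between
    methods, ANOVA + Tukey on method means, and per-parameter regressions
    on whichever of method/scanner/dose vary.  Error percentages are
    included when the reference method is present.  No multiple-testing
    correction is applied across parameters by default (per-parameter
    reporting); ``holm_correction=True`` adds Holm-adjusted Levene p's.
    """
    df = _frame(table)
    prec = precision_sd(df)
    lev_rows = []
    for (param, side), sub in df.groupby(["parameter", "side"]):
        methods = [m for m in sub["method"].unique()]
        for i in range(len(methods)):
            for j in range(i + 1, len(methods)):
                a = sub.loc[sub["method"] == methods[i], "value"].to_numpy(float)
                b = sub.loc[sub["method"] == methods[j], "value"].to_numpy(float)
                if len(a) < 2 or len(b) < 2:
                    continue
                w, p = levene_test([a, b], center=levene_center)
                lev_rows.append(
                    {
                        "parameter": param,
                        "side": side,
                        "method_a": methods[i],
                        "method_b": methods[j],
                        "W": w,
                        "p": p,
                    }
                )
    levene_df = pd.DataFrame(lev_rows)
    if holm_correction and not levene_df.empty:
        levene_df["p_holm"] = multipletests(levene_df["p"], method="holm")[1]

    anova_out = {}
    regression_out = {}
    for param in df["parameter"].unique():
        sub = df[df["parameter"] == param]
        if sub["method"].nunique() >= 2:
            F, p, posthoc = anova_posthoc(df, param)
            anova_out[param] = {
                "F": round(F, 6),
                "p": round(p, 6),
                "posthoc": posthoc.to_dict(orient="records"),
            }
        varying = [f for f in ("method", "scanner", "dose") if sub[f].nunique() > 1]
        if varying:
            regression_out[param] = effects_regression(df, param, tuple(varying))

    err = None
    if reference_method in df["method"].unique():
        err = error_percentage(df, reference_method)
    return PrecisionReport(
        precision=prec,
        levene=levene_df,
        anova=anova_out,
        regression=regression_out,
        error_pct=err,
        config={
            "reference_method": reference_method,
            "levene_center": levene_center,
            "holm_correction": holm_correction,
        },
    )
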