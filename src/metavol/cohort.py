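"""End-to-end prognostic cohort analysis.

The cohort lives in a pandas DataFrame with one validated row per patient
(see :data:`COHORT_COLUMNS` for the CSV schema). The analysis mirrors the
standard single-centre retrospective workflow for PET-based prognostic
markers in lymphoma:

1. cohort summary (counts / percentages, missing values reduce the
   denominator, never become zeros);
2. group comparisons by mortality and by relapse — continuous variables
   gated through a Lilliefors normality test into Mann-Whitney U or
   Student's t, categorical variables through Pearson chi-square (Fisher
   exact when an expected cell count falls below 5);
3. ROC curves with Youden-index cutoffs for the candidate markers;
4. Kaplan-Meier / log-rank stratification at the configured (or
   ROC-derived) cutoffs for overall and relapse-free survival;
5. univariate logistic regression per dichotomized marker, then a
   multivariate model over the univariately significant markers.

The module follows the statsmodels idiom: build a :class:`CohortAnalysis`
from a DataFrame and an :class:`AnalysisConfig`, call :meth:`fit`, and
read the :class:`CohortAnalysisResults` (``.report``, ``.summary()``,
``.to_json()``, ``.plot_km()``).

Inflammation-nutrition indices use the standard literature definitions:
NLR = neutrophils / lymphocytes; dNLR = neutrophils / (WBC - neutrophils);
SII = platelets * neutrophils / lymphocytes;
PNI = 10 * albumin [g/dL] + 0.005 * lymphocytes [per mm^3].
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import stats as st

__all__ = [
    "COHORT_COLUMNS",
    "MarkerCutoff",
    "AnalysisConfig",
    "AnalysisReport",
    "CohortAnalysis",
    "CohortAnalysisResults",
    "load_cohort",
    "derive_indices",
    "summarize_cohort",
    "dichotomize_and_compare",
    "run_full_analysis",
]

#: CSV schema: one row per patient, UTF-8, '.' decimal, empty field = missing.
COHORT_COLUMNS = [
    "id",
    "age_years",
    "sex",                  # M / F
    "ann_arbor_stage",      # 1-4
    "extranodal_gt1",       # 0/1
    "regimen",              # R-CHOP / R-EPOCH
    "ecog",                 # 1-3
    "ipi_group",            # low_lowint / highint_high
    "bone_marrow",          # 0/1
    "bulky",                # 0/1
    "ki67_percent",
    "ldh_u_per_l",
    "albumin_g_per_dl",
    "wbc_per_mm3",
    "neutrophils_per_mm3",
    "lymphocytes_per_mm3",
    "platelets_per_mm3",
    "suv_max",
    "suv_mean",
    "suv_sd",
    "suv_peak",
    "mtv_2_5",
    "mtv_3_0",
    "mtv_3_5",
    "tlg_2_5",
    "hi1",
    "hi2",
    "suvmax_liver",
    "suvmean_liver",
    "response",             # 0/1: any treatment response
    "complete_or_near",     # 0/1: complete or near-complete response
    "relapse",              # 0/1
    "death",                # 0/1
    "os_months",
    "rfs_months",
]

_NUMERIC_COLUMNS = [
    c for c in COHORT_COLUMNS if c not in ("id", "sex", "regimen", "ipi_group")
]

ENDPOINTS = {"OS": ("os_months", "death"), "RFS": ("rfs_months", "relapse")}


# ---------------------------------------------------------------------------
# loading and validation


def _row_problems(row: pd.Series) -> list[str]:
    problems = []
    for col in ("wbc_per_mm3", "neutrophils_per_mm3", "lymphocytes_per_mm3",
                "platelets_per_mm3"):
        v = row.get(col)
        if pd.notna(v) and v < 0:
            problems.append(f"{col} < 0")
    wbc, neut, lymph = (row.get(c) for c in
                        ("wbc_per_mm3", "neutrophils_per_mm3", "lymphocytes_per_mm3"))
    if pd.notna(wbc) and pd.notna(neut) and neut > wbc:
        problems.append("neutrophils_per_mm3 > wbc_per_mm3")
    if pd.notna(wbc) and pd.notna(lymph) and lymph > wbc:
        problems.append("lymphocytes_per_mm3 > wbc_per_mm3")
    for col in ("os_months", "rfs_months"):
        v = row.get(col)
        if pd.notna(v) and v <= 0:
            problems.append(f"{col} <= 0")
    osm, rfsm, rel = row.get("os_months"), row.get("rfs_months"), row.get("relapse")
    if pd.notna(osm) and pd.notna(rfsm) and pd.notna(rel) and rel == 1 and rfsm > osm:
        problems.append("os_months < rfs_months despite relapse")
    return problems


def load_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a cohort CSV.

    Rows violating the record invariants are dropped; the diagnostics
    (row index, reasons) are kept in ``df.attrs['rejected_rows']``.
    Unknown columns raise a warning and are kept; missing required
    columns raise.
    """
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cohort file is missing required columns: {missing}")
    derived = ("nlr", "dnlr", "sii", "pni")
    unknown = [c for c in df.columns if c not in COHORT_COLUMNS and c not in derived]
    if unknown:
        warnings.warn(f"ignoring unknown cohort columns: {unknown}", stacklevel=2)
    for col in _NUMERIC_COLUMNS + [c for c in derived if c in df.columns]:
        df[col] = pd.to_numeric(df[col], errors="coerce")
    rejected = []
    keep = np.ones(len(df), dtype=bool)
    for i, (_, row) in enumerate(df.iterrows()):
        problems = _row_problems(row)
        if problems:
            keep[i] = False
            rejected.append({"row": i, "id": row.get("id"), "problems": problems})
    out = df.loc[keep].reset_index(drop=True)
    out.attrs["rejected_rows"] = rejected
    return out


# ---------------------------------------------------------------------------
# derived indices


def derive_indices(df: pd.DataFrame) -> pd.DataFrame:
    """Append nlr / dnlr / sii / pni columns (NaN where a denominator is 0)."""
    out = df.copy()
    neut = out["neutrophils_per_mm3"]
    lymph = out["lymphocytes_per_mm3"]
    wbc = out["wbc_per_mm3"]
    plate = out["platelets_per_mm3"]
    alb = out["albumin_g_per_dl"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["nlr"] = np.where(lymph > 0, neut / lymph, np.nan)
        rest = wbc - neut
        out["dnlr"] = np.where(rest > 0, neut / rest, np.nan)
        out["sii"] = np.where(lymph > 0, plate * neut / lymph, np.nan)
    out["pni"] = 10.0 * alb + 0.005 * lymph
    return out


# ---------------------------------------------------------------------------
# cohort summary


def _summary_items(df: pd.DataFrame, ldh_uln: float) -> list[tuple[str, str, pd.Series]]:
    """(variable, category, boolean series with NaN for missing) triples."""
    def num(col):
        return df[col]

    items = [
        ("age", "> 60 years", num("age_years") > 60),
        ("age", "<= 60 years", num("age_years") <= 60),
        ("sex", "male", df["sex"] == "M"),
        ("sex", "female", df["sex"] == "F"),
    ]
    for s in (1, 2, 3, 4):
        items.append(("stage", f"stage {s}", num("ann_arbor_stage") == s))
    items += [
        ("advanced_stage", "stage 3-4", num("ann_arbor_stage") >= 3),
        ("extranodal_gt1", "yes", num("extranodal_gt1") == 1),
        ("regimen", "R-CHOP", df["regimen"] == "R-CHOP"),
        ("regimen", "R-EPOCH", df["regimen"] == "R-EPOCH"),
        ("ecog", "score 1", num("ecog") == 1),
        ("ecog", "score 2", num("ecog") == 2),
        ("ecog", "score 3", num("ecog") == 3),
        ("ecog_ge2", "yes", num("ecog") >= 2),
        ("treatment_response", "response present", num("response") == 1),
        ("response_type", "complete or near complete", num("complete_or_near") == 1),
        ("mortality", "yes", num("death") == 1),
        ("relapse", "yes", num("relapse") == 1),
        ("elevated_ldh", "yes", num("ldh_u_per_l") > ldh_uln),
        ("ipi_group", "low / low-intermediate", df["ipi_group"] == "low_lowint"),
        ("ipi_group", "high-intermediate / high", df["ipi_group"] == "highint_high"),
        ("bone_marrow", "yes", num("bone_marrow") == 1),
        ("ki67", ">= 70%", num("ki67_percent") >= 70),
        ("bulky", "yes", num("bulky") == 1),
    ]
    # masks must not count missing source values
    source = {
        "age": "age_years", "sex": "sex", "stage": "ann_arbor_stage",
        "advanced_stage": "ann_arbor_stage", "extranodal_gt1": "extranodal_gt1",
        "regimen": "regimen", "ecog": "ecog", "ecog_ge2": "ecog",
        "treatment_response": "response", "response_type": "complete_or_near",
        "mortality": "death", "relapse": "relapse", "elevated_ldh": "ldh_u_per_l",
        "ipi_group": "ipi_group", "bone_marrow": "bone_marrow",
        "ki67": "ki67_percent", "bulky": "bulky",
    }
    return [(v, c, mask & df[source[v]].notna()) for v, c, mask in items], source


def summarize_cohort(df: pd.DataFrame, ldh_uln: float = 245.0) -> pd.DataFrame:
    """Counts and percentages for every cohort-summary category.

    Denominators exclude patients whose source variable is missing, so a
    variable known for only part of the cohort is summarized over that
    part. Also reports mortality among relapsed patients (the joint cell
    that links the relapse and mortality margins).
    """
    if len(df) == 0:
        raise ValueError("cohort is empty")
    items, source = _summary_items(df, ldh_uln)
    rows = []
    for variable, category, mask in items:
        denom = int(df[source[variable]].notna().sum())
        count = int(mask.sum())
        pct = round(100.0 * count / denom, 1) if denom else float("nan")
        rows.append((variable, category, count, denom, pct))
    relapsed = df[df["relapse"] == 1]
    if len(relapsed):
        dead = int((relapsed["death"] == 1).sum())
        rows.append(
            ("mortality_in_relapsed", "yes", dead, len(relapsed),
             round(100.0 * dead / len(relapsed), 1))
        )
    return pd.DataFrame(
        rows, columns=["variable", "category", "count", "denominator", "percent"]
    )


# ---------------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class MarkerCutoff:
    variable: str          # cohort column holding the marker
    value: float
    direction: str         # low_positive: value <= cutoff predicts the event

    def __post_init__(self) -> None:
        if self.direction not in ("low_positive", "high_positive"):
            raise ValueError(f"unknown direction {self.direction!r}")

    def cutoff_label(self) -> str:
        op = "<=" if self.direction == "low_positive" else ">"
        return f"{op} {self.value:g}"

    def exposure(self, series: pd.Series) -> pd.Series:
        """Event-predicting indicator (NaN preserved)."""
        if self.direction == "low_positive":
            ind = series <= self.value
        else:
            ind = series > self.value
        return ind.astype(float).where(series.notna())


def _default_markers() -> dict[str, tuple[MarkerCutoff, ...]]:
    return {
        "OS": (
            MarkerCutoff("suvmax_liver", 22.0, "low_positive"),
            MarkerCutoff("hi2", 62.3, "high_positive"),
            MarkerCutoff("ldh_u_per_l", 301.0, "high_positive"),
        ),
        "RFS": (
            MarkerCutoff("ldh_u_per_l", 301.0, "high_positive"),
            MarkerCutoff("suvmax_liver", 21.0, "low_positive"),
            MarkerCutoff("hi2", 87.9, "high_positive"),
        ),
    }


@dataclass
class AnalysisConfig:
    """Cutoffs, directions and options for the full cohort analysis.

    Default cutoffs dichotomize at SUVmax_liver <= 22 (OS) / <= 21 (RFS),
    HI2 > 62.3 (OS) / > 87.9 (RFS), LDH > 301 and Ki-67 >= 70%; each is a
    configuration value, not a constant, since the uptake scale of a
    cohort depends on the acquisition pipeline.
    """

    markers: dict[str, tuple[MarkerCutoff, ...]] = field(default_factory=_default_markers)
    ki67_cutoff: float = 70.0
    ldh_uln: float = 245.0       # upper limit of normal, defines "elevated LDH"
    alpha: float = 0.05
    derive_cutoffs_by_roc: bool = False
    seed: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        """Flat key-value YAML: ``marker_<endpoint>_<column>: "22,low_positive"``
        plus optional ``alpha``, ``ldh_uln``, ``ki67_cutoff``,
        ``derive_cutoffs_by_roc``, ``seed``."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls()
        markers: dict[str, list[MarkerCutoff]] = {"OS": [], "RFS": []}
        seen_markers = False
        for key, value in raw.items():
            if key.startswith("marker_"):
                _, endpoint, column = key.split("_", 2)
                endpoint = endpoint.upper()
                cut, direction = str(value).split(",")
                markers[endpoint].append(
                    MarkerCutoff(column, float(cut), direction.strip())
                )
                seen_markers = True
            elif key in ("alpha", "ldh_uln", "ki67_cutoff"):
                setattr(cfg, key, float(value))
            elif key == "derive_cutoffs_by_roc":
                cfg.derive_cutoffs_by_roc = bool(value)
            elif key == "seed":
                cfg.seed = int(value)
            else:
                warnings.warn(f"unknown config key {key!r}", stacklevel=2)
        if seen_markers:
            cfg.markers = {k: tuple(v) for k, v in markers.items() if v}
        return cfg


# ---------------------------------------------------------------------------
# stratified comparison


@dataclass
class StratifiedComparison:
    variable: str
    cutoff: float
    direction: str
    endpoint: str
    n_low: int
    n_high: int
    estimable: bool
    logrank_chi2: float = float("nan")
    logrank_p: float = float("nan")
    mean_low: st.MeanSurvival | None = None
    mean_high: st.MeanSurvival | None = None
    curve_low: st.SurvivalCurve | None = None
    curve_high: st.SurvivalCurve | None = None


def dichotomize_and_compare(
    df: pd.DataFrame,
    variable: str,
    cutoff: float,
    direction: str,
    endpoint: str,
) -> StratifiedComparison:
    """Split at the cutoff (low = value <= cutoff) and compare survival.

    Runs Kaplan-Meier per stratum and the log-rank test on the requested
    endpoint ("OS" or "RFS"). An empty (or single-patient) stratum makes
    the comparison not estimable rather than an error.
    """
    time_col, event_col = ENDPOINTS[endpoint]
    data = df[[variable, time_col, event_col]].dropna()
    low = data[data[variable] <= cutoff]
    high = data[data[variable] > cutoff]
    result = StratifiedComparison(
        variable=variable, cutoff=cutoff, direction=direction, endpoint=endpoint,
        n_low=len(low), n_high=len(high), estimable=len(low) >= 2 and len(high) >= 2,
    )
    if not result.estimable:
        return result
    samples = [
        st.SurvivalSample(g[time_col].to_numpy(), g[event_col].to_numpy().astype(bool))
        for g in (low, high)
    ]
    chi2, _, p = st.logrank_test(samples)
    result.logrank_chi2, result.logrank_p = chi2, p
    result.curve_low = st.km_estimator(samples[0])
    result.curve_high = st.km_estimator(samples[1])
    result.mean_low = st.mean_survival(result.curve_low)
    result.mean_high = st.mean_survival(result.curve_high)
    return result


# ---------------------------------------------------------------------------
# full analysis


_CONTINUOUS_COMPARED = [
    "age_years", "ldh_u_per_l", "albumin_g_per_dl", "wbc_per_mm3",
    "neutrophils_per_mm3", "lymphocytes_per_mm3", "platelets_per_mm3",
    "suvmax_liver", "suv_max", "suv_peak", "suv_mean", "suvmean_liver",
    "mtv_2_5", "mtv_3_0", "mtv_3_5", "suv_sd", "pni", "sii", "nlr", "dnlr",
    "hi1", "hi2", "ki67_percent",
]


@dataclass
class AnalysisReport:
    """Full analysis output; tables are plain DataFrames, JSON-serializable."""

    cohort_summary: pd.DataFrame
    group_comparisons: dict[str, pd.DataFrame]
    roc_tables: dict[str, pd.DataFrame]
    km_tables: dict[str, pd.DataFrame]
    km_details: dict[str, dict[str, StratifiedComparison]]
    logistic_tables: dict[str, pd.DataFrame]
    errors: list[str]

    def to_dict(self) -> dict[str, Any]:
        def frame(df):
            return json.loads(df.to_json(orient="records"))
        return {
            "cohort_summary": frame(self.cohort_summary),
            "group_comparisons": {k: frame(v) for k, v in self.group_comparisons.items()},
            "roc": {k: frame(v) for k, v in self.roc_tables.items()},
            "km": {k: frame(v) for k, v in self.km_tables.items()},
            "logistic": {k: frame(v) for k, v in self.logistic_tables.items()},
            "errors": list(self.errors),
        }

    def to_json(self, indent: int = 2) -> str:
        return json.dumps(self.to_dict(), indent=indent, sort_keys=True)


class CohortAnalysis:
    """Prognostic-stratification model for a validated cohort DataFrame.

    Parameters
    ----------
    data : DataFrame following :data:`COHORT_COLUMNS` (derived-index
        columns are added automatically if absent).
    config : AnalysisConfig, optional.
    """

    def __init__(self, data: pd.DataFrame, config: AnalysisConfig | None = None):
        if len(data) == 0:
            raise ValueError("cohort is empty")
        self.config = config or AnalysisConfig()
        if "nlr" not in data.columns:
            data = derive_indices(data)
        self.data = data

    @classmethod
    def from_csv(cls, path: str | Path, config: AnalysisConfig | None = None):
        return cls(load_cohort(path), config)

    def fit(self) -> "CohortAnalysisResults":
        """Run every analysis stage; stage failures are recorded, not raised."""
        errors: list[str] = []
        df = self.data
        cfg = self.config

        def stage(fn, label, default):
            try:
                return fn()
            except Exception as exc:  # keep going, record the failure
                errors.append(f"{label}: {exc}")
                return default

        summary = stage(lambda: summarize_cohort(df, cfg.ldh_uln),
                        "cohort_summary", pd.DataFrame())
        comparisons = {
            key: stage(lambda c=col: self._compare_groups(df, c),
                       f"group_comparisons[{key}]", pd.DataFrame())
            for key, col in (("mortality", "death"), ("relapse", "relapse"))
        }
        roc_tables = {
            ep: stage(lambda e=ep: self._roc_table(df, e), f"roc[{ep}]", pd.DataFrame())
            for ep in cfg.markers
        }
        markers = cfg.markers
        if cfg.derive_cutoffs_by_roc:
            markers = stage(lambda: self._cutoffs_from_roc(roc_tables),
                            "derive_cutoffs_by_roc", cfg.markers)
        km_tables: dict[str, pd.DataFrame] = {}
        km_details: dict[str, dict[str, StratifiedComparison]] = {}
        for ep, cuts in markers.items():
            details = {}
            rows = []
            for mc in cuts:
                comp = stage(
                    lambda m=mc, e=ep: dichotomize_and_compare(
                        df, m.variable, m.value, m.direction, e),
                    f"km[{ep}:{mc.variable}]", None)
                if comp is None:
                    continue
                details[mc.variable] = comp
                rows.append({
                    "variable": mc.variable, "cutoff": mc.cutoff_label(),
                    "n_low": comp.n_low, "n_high": comp.n_high,
                    "estimable": comp.estimable,
                    "logrank_chi2": comp.logrank_chi2, "logrank_p": comp.logrank_p,
                    "mean_low": comp.mean_low.mean_months if comp.mean_low else np.nan,
                    "se_low": comp.mean_low.se_months if comp.mean_low else np.nan,
                    "mean_high": comp.mean_high.mean_months if comp.mean_high else np.nan,
                    "se_high": comp.mean_high.se_months if comp.mean_high else np.nan,
                })
            km_tables[ep] = pd.DataFrame(rows)
            km_details[ep] = details
        logistic_tables = {
            ep: stage(lambda e=ep, m=markers: self._logistic_table(df, m[e], e),
                      f"logistic[{ep}]", pd.DataFrame())
            for ep in markers
        }
        report = AnalysisReport(
            cohort_summary=summary,
            group_comparisons=comparisons,
            roc_tables=roc_tables,
            km_tables=km_tables,
            km_details=km_details,
            logistic_tables=logistic_tables,
            errors=errors,
        )
        return CohortAnalysisResults(self, report)

    # -- stages ------------------------------------------------------------

    def _compare_groups(self, df: pd.DataFrame, group_col: str) -> pd.DataFrame:
        """Continuous-variable comparison between the two outcome groups."""
        rows = []
        for var in _CONTINUOUS_COMPARED:
            if var not in df.columns:
                continue
            sub = df[[var, group_col]].dropna()
            g1 = sub.loc[sub[group_col] == 1, var].to_numpy()
            g0 = sub.loc[sub[group_col] == 0, var].to_numpy()
            if g1.size < 2 or g0.size < 2:
                continue
            pooled = np.concatenate([g1, g0])
            try:
                route = st.ks_normality(pooled)
            except ValueError:
                continue
            if route.is_normal:
                test = "t"
                _, p = sps.ttest_ind(g1, g0, equal_var=True)
            else:
                test = "mann_whitney"
                _, p = st.mann_whitney_u(g1, g0)
            q = lambda a, v: float(np.percentile(a, v))
            rows.append({
                "variable": var, "test": test, "p": float(p),
                "median_pos": q(g1, 50), "q1_pos": q(g1, 25), "q3_pos": q(g1, 75),
                "median_neg": q(g0, 50), "q1_neg": q(g0, 25), "q3_neg": q(g0, 75),
                "n_pos": int(g1.size), "n_neg": int(g0.size),
            })
        return pd.DataFrame(rows)

    def _roc_table(self, df: pd.DataFrame, endpoint: str) -> pd.DataFrame:
        _, event_col = ENDPOINTS[endpoint]
        rows = []
        for mc in self.config.markers[endpoint]:
            sub = df[[mc.variable, event_col]].dropna()
            score = sub[mc.variable].to_numpy()
            label = sub[event_col].to_numpy().astype(bool)
            roc = st.roc_with_youden(score, label, mc.direction)
            # AUC significance via the Mann-Whitney identity
            _, p = st.mann_whitney_u(score[label], score[~label])
            rows.append({
                "variable": mc.variable, "direction": mc.direction,
                "auc": roc.auc, "p": float(p), "best_cutoff": roc.best_cutoff,
                "sensitivity": roc.best_sens, "specificity": roc.best_spec,
                "n": int(len(sub)),
            })
        return pd.DataFrame(rows)

    def _cutoffs_from_roc(self, roc_tables) -> dict[str, tuple[MarkerCutoff, ...]]:
        markers = {}
        for ep, cuts in self.config.markers.items():
            table = roc_tables[ep].set_index("variable")
            markers[ep] = tuple(
                MarkerCutoff(mc.variable, float(table.loc[mc.variable, "best_cutoff"]),
                             mc.direction)
                for mc in cuts
            )
        return markers

    def _logistic_table(
        self, df: pd.DataFrame, cuts: tuple[MarkerCutoff, ...], endpoint: str
    ) -> pd.DataFrame:
        """Univariate logistic per marker; multivariate over significant ones.

        The exposure indicator points in the event-predicting direction
        (e.g. low liver SUVmax, high HI2), so odds ratios read as risk of
        the event for exposed vs unexposed patients.
        """
        _, event_col = ENDPOINTS[endpoint]
        rows = []
        indicators: dict[str, pd.Series] = {}
        for mc in cuts:
            ind = mc.exposure(df[mc.variable])
            indicators[mc.variable] = ind
            sub = pd.DataFrame({"x": ind, "y": df[event_col]}).dropna()
            X = np.column_stack([np.ones(len(sub)), sub["x"].to_numpy()])
            fit = st.logistic_fit(X, sub["y"].to_numpy().astype(bool))
            rows.append({
                "variable": mc.variable, "cutoff": mc.cutoff_label(),
                "model": "univariate", "odds_ratio": float(fit.odds_ratios[1]),
                "ci_low": float(fit.wald_ci_95[1, 0]),
                "ci_high": float(fit.wald_ci_95[1, 1]),
                "p": float(fit.p_values[1]), "converged": fit.converged,
                "n": int(len(sub)),
            })
        uni = pd.DataFrame(rows)
        significant = [
            mc for mc in cuts
            if bool(uni.loc[uni["variable"] == mc.variable, "p"].iloc[0]
                    < self.config.alpha)
            and bool(uni.loc[uni["variable"] == mc.variable, "converged"].iloc[0])
        ]
        if len(significant) >= 2:
            cols = {mc.variable: indicators[mc.variable] for mc in significant}
            sub = pd.DataFrame({**cols, "y": df[event_col]}).dropna()
            X = np.column_stack(
                [np.ones(len(sub))] + [sub[mc.variable].to_numpy() for mc in significant]
            )
            fit = st.logistic_fit(X, sub["y"].to_numpy().astype(bool))
            for j, mc in enumerate(significant, start=1):
                rows.append({
                    "variable": mc.variable, "cutoff": mc.cutoff_label(),
                    "model": "multivariate", "odds_ratio": float(fit.odds_ratios[j]),
                    "ci_low": float(fit.wald_ci_95[j, 0]),
                    "ci_high": float(fit.wald_ci_95[j, 1]),
                    "p": float(fit.p_values[j]), "converged": fit.converged,
                    "n": int(len(sub)),
                })
        return pd.DataFrame(rows)


class CohortAnalysisResults:
    """Fitted analysis: report tables plus presentation helpers."""

    def __init__(self, model: CohortAnalysis, report: AnalysisReport):
        self.model = model
        self.report = report

    def summary(self) -> str:
        """Human-readable multi-block report (cohort, ROC, KM, logistic)."""
        blocks = ["Cohort summary", "=" * 64,
                  self.report.cohort_summary.to_string(index=False)]
        for ep, table in self.report.roc_tables.items():
            blocks += [f"\nROC / Youden cutoffs ({ep})", "-" * 64,
                       table.to_string(index=False)]
        for ep, table in self.report.km_tables.items():
            blocks += [f"\nKaplan-Meier stratification ({ep})", "-" * 64,
                       table.to_string(index=False)]
        for ep, table in self.report.logistic_tables.items():
            blocks += [f"\nLogistic regression ({ep})", "-" * 64,
                       table.to_string(index=False)]
        if self.report.errors:
            blocks += ["\nStage errors", "-" * 64] + self.report.errors
        return "\n".join(blocks)

    def to_json(self, indent: int = 2) -> str:
        return self.report.to_json(indent=indent)

    def save(self, out_dir: str | Path) -> None:
        """Write report.json plus one TSV per table block."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "report.json").write_text(self.to_json())
        self.report.cohort_summary.to_csv(out / "cohort_summary.tsv", sep="\t", index=False)
        for name, group in (
            ("comparison", self.report.group_comparisons),
            ("roc", self.report.roc_tables),
            ("km", self.report.km_tables),
            ("logistic", self.report.logistic_tables),
        ):
            for key, table in group.items():
                table.to_csv(out / f"{name}_{key}.tsv", sep="\t", index=False)

    def plot_km(self, endpoint: str, variable: str, ax=None):
        """Kaplan-Meier curves of the two strata of one marker."""
        import matplotlib.pyplot as plt

        comp = self.report.km_details[endpoint][variable]
        if not comp.estimable:
            raise ValueError(f"{variable} stratification not estimable for {endpoint}")
        if ax is None:
            _, ax = plt.subplots()
        for curve, label in ((comp.curve_low, f"{variable} <= {comp.cutoff}"),
                             (comp.curve_high, f"{variable} > {comp.cutoff}")):
            t = np.concatenate([[0.0], np.repeat(curve.event_times, 2),
                                [curve.max_observed_time]])
            s = np.concatenate([[1.0, 1.0], np.repeat(curve.survival, 2)])
            ax.plot(t, s[: t.size], label=label)
        ax.set_xlabel(f"{endpoint} (months)")
        ax.set_ylabel("survival probability")
        ax.set_ylim(0, 1.05)
        ax.legend()
        ax.set_title(f"log-rank p = {comp.logrank_p:.3f}")
        return ax


def run_full_analysis(
    df: pd.DataFrame, config: AnalysisConfig | None = None
) -> AnalysisReport:
    """Convenience wrapper: build, fit, and return the report."""
    return CohortAnalysis(df, config).fit().report
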