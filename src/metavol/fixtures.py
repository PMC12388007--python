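"""Packaged machine-readable transcriptions of the reference study tables.

The reference cohort (n = 70) is not deposited anywhere, so its printed
aggregate tables are shipped with the package as small CSV/JSON files:
the demographic summary, the mortality-stratified categorical and
continuous comparisons, the two logistic-regression tables, and the
survival / ROC headline numbers. They back the regression tests and the
internal-consistency reconstructions; they are transcriptions of printed
aggregates, never inputs to the estimators.

Values are stored verbatim as printed, including bounds such as
``<0.001`` in p-value columns (those columns are therefore strings).
"""

from __future__ import annotations

import hashlib
import json
from importlib import resources

import pandas as pd

__all__ = [
    "load_demographics",
    "load_mortality_categorical",
    "load_mortality_continuous",
    "load_mortality_logistic",
    "load_relapse_logistic",
    "load_survival_summary",
    "package_fixtures",
    "fixture_checksums",
]

_FILES = {
    "demographics": "demographics.csv",
    "mortality_categorical": "mortality_categorical.csv",
    "mortality_continuous": "mortality_continuous.csv",
    "mortality_logistic": "mortality_logistic.csv",
    "relapse_logistic": "relapse_logistic.csv",
    "survival_roc_summary": "survival_roc_summary.json",
}


def _path(name: str):
    return resources.files("metavol.data") / _FILES[name]


def _read_csv(name: str) -> pd.DataFrame:
    with resources.as_file(_path(name)) as p:
        return pd.read_csv(p, dtype={"p_value": str})


def load_demographics() -> pd.DataFrame:
    """Cohort demographic summary (counts and percentages, n = 70)."""
    return _read_csv("demographics")


def load_mortality_categorical() -> pd.DataFrame:
    """Categorical characteristics by mortality status."""
    return _read_csv("mortality_categorical")


def load_mortality_continuous() -> pd.DataFrame:
    """Continuous characteristics by mortality status (median [IQR])."""
    return _read_csv("mortality_continuous")


def load_mortality_logistic() -> pd.DataFrame:
    """Uni-/multivariate logistic odds ratios for mortality."""
    return _read_csv("mortality_logistic")


def load_relapse_logistic() -> pd.DataFrame:
    """Uni-/multivariate logistic odds ratios for relapse."""
    return _read_csv("relapse_logistic")


def load_survival_summary() -> dict:
    """Headline mean-survival, ROC-AUC and log-rank values."""
    return json.loads(_path("survival_roc_summary").read_text())


def package_fixtures() -> dict:
    """Every packaged fixture in one bundle keyed by table name."""
    return {
        "demographics": load_demographics(),
        "mortality_categorical": load_mortality_categorical(),
        "mortality_continuous": load_mortality_continuous(),
        "mortality_logistic": load_mortality_logistic(),
        "relapse_logistic": load_relapse_logistic(),
        "survival_roc_summary": load_survival_summary(),
    }


def fixture_checksums() -> dict[str, str]:
    """SHA-256 of each packaged fixture file (stability check)."""
    out = {}
    for name in _FILES:
        data = _path(name).read_bytes()
        out[name] = hashlib.sha256(data).hexdigest()
    return out
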