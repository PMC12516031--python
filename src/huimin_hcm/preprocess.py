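"""Quality control, descriptive statistics, and scale diagnostics.

The attentiveness filter drops respondents who picked the dominated
alternative in the QC task (opting out of the QC task keeps the respondent).
Scale diagnostics are the classical reliability/validity summaries:
Cronbach's alpha, composite reliability (CR) and average variance extracted
(AVE), the latter two from standardized loadings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import ChoiceDesign, is_dominated
from .simulate import SurveyDataset

SCALES = {
    "HR": ["hr1", "hr2", "hr3", "hr4", "hr5"],
    "AW": ["aw1", "aw2", "aw3"],
    "VAL": ["val1", "val2", "val3"],
}

SCALE_LABELS = {
    "HR": "Health risk perceptions",
    "AW": "Awareness of the scheme",
    "VAL": "Perceptions of its value",
}


@dataclass
class QCResult:
    retained: pd.Index
    excluded: pd.Index

    @property
    def n_retained(self) -> int:
        return len(self.retained)

    @property
    def n_excluded(self) -> int:
        return len(self.excluded)


def apply_qc_filter(choices: pd.DataFrame, design: ChoiceDesign) -> QCResult:
    """Exclude respondents whose QC choice is the dominated alternative."""
    qc_sets = design.qc_sets
    if not qc_sets:
        raise ValueError("design has no QC set")
    qc = qc_sets[0]
    a0, a1 = qc.alternatives
    dominated_alt = 2 if is_dominated(a1, a0, design.attrs) else 1

    qc_rows = choices[(choices["set_id"] == qc.set_id) & (choices["chosen"] == 1)]
    all_resp = pd.Index(choices["respondent"].unique())
    missing = all_resp.difference(qc_rows["respondent"])
    if len(missing):
        raise ValueError(f"missing QC record for respondent(s) {list(missing[:5])}")
    bad = qc_rows.loc[qc_rows["alt_id"] == dominated_alt, "respondent"]
    excluded = pd.Index(sorted(bad))
    retained = all_resp.difference(excluded).sort_values()
    return QCResult(retained=retained, excluded=excluded)


def round_half_up(x: float, decimals: int) -> float:
    q = 10.0 ** decimals
    return math.floor(abs(x) * q + 0.5) / q * (1 if x >= 0 else -1)


def descriptives(dataset: SurveyDataset, decimals: int = 1) -> pd.DataFrame:
    """Counts and percentages per binary/categorical field; scale means and SDs.

    Percentages are rounded half-up to ``decimals`` (2 for the rarest field,
    catastrophic-disease experience, matching conventional reporting of small
    shares).
    """
    resp = dataset.respondents
    if resp.empty:
        raise ValueError("empty dataset")
    n = len(resp)
    rows = []

    def add_binary(field, label0, label1, dec=decimals):
        c1 = int(resp[field].sum())
        c0 = n - c1
        rows.append({"variable": field, "level": label0, "n": c0,
                     "pct": round_half_up(100.0 * c0 / n, dec)})
        rows.append({"variable": field, "level": label1, "n": c1,
                     "pct": round_half_up(100.0 * c1 / n, dec)})

    add_binary("residence", "0 = Rural", "1 = Urban")
    add_binary("gender", "0 = Male", "1 = Female")
    for band in sorted(resp["age_band"].unique()):
        c = int((resp["age_band"] == band).sum())
        rows.append({"variable": "age_band", "level": band, "n": c,
                     "pct": round_half_up(100.0 * c / n, decimals)})
    add_binary("education", "0 = No college", "1 = College or above")
    add_binary("income", "0 = At/below average income", "1 = Above average income")
    add_binary("private_insurance", "0 = Never bought private insurance",
               "1 = Ever bought private insurance")
    add_binary("catastrophic", "0 = No catastrophic-disease experience",
               "1 = Catastrophic-disease experience", dec=2)
    table = pd.DataFrame(rows)

    ind = dataset.indicators.set_index("respondent").loc[resp["respondent"]]
    scale_rows = []
    for key, items in SCALES.items():
        means = ind[items].mean(axis=1)
        scale_rows.append({"scale": SCALE_LABELS[key],
                           "mean": round_half_up(float(means.mean()), 2),
                           "sd": round_half_up(float(means.std(ddof=1)) if n > 1 else 0.0, 2)})
    table.attrs["scales"] = pd.DataFrame(scale_rows)
    return table


def cronbach_alpha(items: pd.DataFrame | np.ndarray) -> float:
    """alpha = k/(k-1) * (1 - sum of item variances / variance of the total)."""
    X = np.asarray(items, float)
    k = X.shape[1]
    if k < 2:
        raise ValueError("Cronbach's alpha needs at least 2 items")
    total_var = np.var(X.sum(axis=1), ddof=1)
    if total_var <= 0:
        raise ValueError("degenerate scale: zero total variance")
    item_var = np.var(X, axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def composite_reliability(loadings) -> float:
    """CR = (sum lam)^2 / ((sum lam)^2 + sum(1 - lam^2)), standardized loadings."""
    lam = np.asarray(loadings, float)
    s = lam.sum()
    denom = s**2 + np.sum(1.0 - lam**2)
    return float(s**2 / denom) if denom > 0 else 0.0


def ave(loadings) -> float:
    """Average variance extracted: mean squared standardized loading."""
    lam = np.asarray(loadings, float)
    return float(np.mean(lam**2))


def standardized_loadings(zeta) -> np.ndarray:
    """Standardize ordered-logit loadings: lam = zeta / sqrt(zeta^2 + pi^2/3).

    The logistic measurement error has variance pi^2/3, so this is the implied
    correlation between indicator propensity and a unit-variance construct.
    """
    z = np.asarray(zeta, float)
    return z / np.sqrt(z**2 + np.pi**2 / 3.0)


def scale_diagnostics(dataset: SurveyDataset, zeta_by_scale: dict | None = None) -> pd.DataFrame:
    """Alpha per scale from the indicator matrix; CR/AVE if loadings supplied.

    ``zeta_by_scale`` maps scale key -> ordered-logit loadings (unstandardized);
    they are standardized internally before CR/AVE.
    """
    ind = dataset.indicators
    rows = []
    for key, items in SCALES.items():
        row = {"scale": SCALE_LABELS[key], "n_items": len(items),
               "cronbach_alpha": cronbach_alpha(ind[items])}
        if zeta_by_scale and key in zeta_by_scale:
            lam = standardized_loadings(zeta_by_scale[key])
            row["composite_reliability"] = composite_reliability(lam)
            row["ave"] = ave(lam)
        rows.append(row)
    return pd.DataFrame(rows)


def filter_dataset(dataset: SurveyDataset) -> tuple[SurveyDataset, QCResult]:
    """Apply the QC filter and return the retained-subsample dataset."""
    qc = apply_qc_filter(dataset.choices, dataset.design)
    keep = qc.retained
    resp = dataset.respondents[dataset.respondents["respondent"].isin(keep)].reset_index(drop=True)
    ind = dataset.indicators[dataset.indicators["respondent"].isin(keep)].reset_index(drop=True)
    cho = dataset.choices[dataset.choices["respondent"].isin(keep)].reset_index(drop=True)
    filtered = SurveyDataset(respondents=resp, indicators=ind, choices=cho,
                             design=dataset.design,
                             meta={**dataset.meta, "qc_excluded": qc.n_excluded})
    return filtered, qc
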