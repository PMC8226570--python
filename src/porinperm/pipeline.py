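"""Accumulation analysis: filters, categories, and the ln-ln regression.

Given a table of compounds with descriptors and whole-cell accumulation
(nmol per 10^12 CFUs), the pipeline scores permeability through the
configured porin, removes compounds whose accumulation is below the assay
detection cutoff (default 45 nmol per 10^12 CFUs) and non-polar compounds
that bypass porins (alogP > 2.9), cross-tabulates accumulation and
permeability categories, and regresses ln(accumulation) on
ln(percent permeability) reporting the Pearson correlation.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .pore import PoreModel, ScoringCoefficients
from .scoring import (
    CalibrationError,
    PorinPermeabilityModel,
    calibrate_glycine_score,
    categorize_permeability,
    percent_of_glycine,
)

__all__ = [
    "RegressionResult",
    "ACCUMULATION_CATEGORIES",
    "DEFAULT_ACCUMULATION_CUTOFF",
    "DEFAULT_ALOGP_CUTOFF",
    "filter_dataset",
    "categorize_accumulation",
    "loglog_regression",
    "run_pipeline",
]

ACCUMULATION_CATEGORIES = ("low", "accumulator", "good", "excellent")

#: Detection-limit cutoff on accumulation, nmol per 10^12 CFUs.
DEFAULT_ACCUMULATION_CUTOFF = 45.0
#: Hydrophobicity cutoff above which compounds are treated as non-porin
#: permeants.
DEFAULT_ALOGP_CUTOFF = 2.9


@dataclass
class RegressionResult:
    """OLS of ln(accumulation) on ln(percent permeability)."""

    n: int
    r: float
    p_value: float
    slope: float
    intercept: float

    def __post_init__(self) -> None:
        if self.n < 3:
            raise ValueError("regression needs at least 3 points")
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| cannot exceed 1")


def filter_dataset(
    records: pd.DataFrame,
    accumulation_cutoff: float = DEFAULT_ACCUMULATION_CUTOFF,
    alogp_cutoff: float = DEFAULT_ALOGP_CUTOFF,
) -> tuple[pd.DataFrame, dict]:
    """Drop low-accumulation and non-polar compounds; return survivors + audit.

    A record is dropped if ``accumulation < accumulation_cutoff`` (strictly
    below: a value exactly at the cutoff is kept) or ``alogp >
    alogp_cutoff`` (strictly above).  The result is independent of rule
    order; the audit counts each rule and their overlap so that
    ``kept = total - low_accumulation - nonpolar + overlap`` always holds.
    """
    if records.empty:
        raise ValueError("record table is empty")
    low = records["accumulation"] < accumulation_cutoff
    nonpolar = records["alogp"] > alogp_cutoff
    kept = records.loc[~low & ~nonpolar].copy()
    audit = {
        "total": int(len(records)),
        "low_accumulation": int(low.sum()),
        "nonpolar": int(nonpolar.sum()),
        "overlap": int((low & nonpolar).sum()),
        "kept": int(len(kept)),
        "warnings": [] if len(kept) else ["empty survivor set"],
    }
    return kept, audit


def categorize_accumulation(value: float) -> str:
    """Accumulation (nmol per 10^12 CFUs) -> {low, accumulator, good, excellent}.

    Bands: low [0, 250), accumulator [250, 550], good (550, 1000],
    excellent (1000, inf).
    """
    if value < 0:
        raise ValueError("accumulation cannot be negative")
    if value < 250.0:
        return "low"
    if value <= 550.0:
        return "accumulator"
    if value <= 1000.0:
        return "good"
    return "excellent"


def loglog_regression(records: pd.DataFrame) -> RegressionResult:
    """Pearson correlation and OLS line of ln(accumulation) vs ln(percent).

    Requires every accumulation and percent value to be strictly positive
    (the filters should already guarantee this); offending compound ids are
    named otherwise.  The p-value is the two-sided t-test on the
    correlation with n - 2 degrees of freedom.
    """
    if len(records) < 3:
        raise ValueError(f"regression needs >= 3 points; got {len(records)}")
    bad = records.loc[
        (records["accumulation"] <= 0) | (records["percent_of_glycine"] <= 0)
    ]
    if len(bad):
        raise ValueError(
            "non-positive values reaching the logarithm for ids: "
            f"{bad['id'].tolist()}"
        )
    x = np.log(records["percent_of_glycine"].to_numpy(dtype=float))
    y = np.log(records["accumulation"].to_numpy(dtype=float))
    fit = stats.linregress(x, y)
    return RegressionResult(
        n=len(records),
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
    )


def _crosstab(records: pd.DataFrame) -> dict:
    """Permeability x accumulation category counts as a nested dict."""
    table = {
        p: {a: 0 for a in ACCUMULATION_CATEGORIES}
        for p in ("very_bad", "poor", "good", "excellent")
    }
    for p_cat, a_cat in zip(
        records["permeability_category"], records["accumulation_category"]
    ):
        table[p_cat][a_cat] += 1
    return table


def run_pipeline(
    table: pd.DataFrame,
    pore: PoreModel,
    coefficients: ScoringCoefficients | None,
    accumulation_cutoff: float = DEFAULT_ACCUMULATION_CUTOFF,
    alogp_cutoff: float = DEFAULT_ALOGP_CUTOFF,
) -> tuple[pd.DataFrame, dict]:
    """Score -> filter -> categorize -> regress; return per-compound table + report.

    The glycine anchor is (re)calibrated under the active coefficients at
    the start, so percent-of-glycine values are always consistent with the
    configuration in use.  The report is a JSON-serialisable dict with the
    filter audit, category counts, the permeability x accumulation
    cross-tabulation of the analysed subset, and the regression block.
    """
    if coefficients is None:
        raise CalibrationError(
            "configuration provides no scoring coefficients; fit or supply "
            "them before running the pipeline"
        )
    required = {
        "id",
        "net_charge",
        "transversal_dipole",
        "mpa_mean",
        "mpa_sd",
        "alogp",
        "accumulation",
    }
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"input table missing columns: {sorted(missing)}")

    calibrate_glycine_score(pore, coefficients)
    model = PorinPermeabilityModel(pore=pore, coefficients=coefficients)

    scored = table.copy()
    scored["score"] = model.predict(scored)
    scored["percent_of_glycine"] = [
        percent_of_glycine(s, pore) for s in scored["score"]
    ]
    scored["permeability_category"] = [
        categorize_permeability(p) for p in scored["percent_of_glycine"]
    ]
    scored["accumulation_category"] = [
        categorize_accumulation(a) for a in scored["accumulation"]
    ]

    analysed, audit = filter_dataset(scored, accumulation_cutoff, alogp_cutoff)
    analysed = analysed.assign(analysed=True)
    scored["analysed"] = scored["id"].isin(analysed["id"])

    report: dict = {
        "n_input": int(len(table)),
        "filter_audit": audit,
        "glycine_score": pore.glycine_score,
        "accumulation_category_counts": {
            c: int((analysed["accumulation_category"] == c).sum())
            for c in ACCUMULATION_CATEGORIES
        },
        "permeability_category_counts": {
            c: int((analysed["permeability_category"] == c).sum())
            for c in ("very_bad", "poor", "good", "excellent")
        },
        "crosstab": _crosstab(analysed),
        "warnings": list(audit["warnings"]),
    }
    if len(analysed) >= 3:
        report["regression"] = asdict(loglog_regression(analysed))
    else:
        report["regression"] = None
        report["warnings"].append(
            "fewer than 3 analysed compounds; regression skipped"
        )
    return scored, report
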