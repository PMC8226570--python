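"""Interaction-based porin permeability scoring.

The permeability of a compound through a general porin is scored as

    P = alpha * U_steric + beta * Q * V_pore + gamma * D * E_pore + delta

where ``U_steric`` is the size-exclusion term built from the MPA
distribution, ``Q`` the net charge, ``D`` the transversal dipole moment
and ``(V_pore, E_pore)`` the pore's electrostatic potential and
transversal field.  The score is a *log*-permeability: it is linear in
charge while measured permeability grows exponentially with charge, so
percent-of-glycine values exponentiate score differences,
``percent = 100 * exp(P - P_glycine)``.

:class:`PorinPermeabilityModel` is a scikit-learn style estimator: with
coefficients supplied it predicts scores; ``fit`` recovers the four
coefficients by ordinary least squares from reference log-permeabilities,
which is also how the model is calibrated against training sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

from .pore import GLYCINE_REFERENCE, PoreModel, ScoringCoefficients, steric_term

__all__ = [
    "CalibrationError",
    "PermeabilityResult",
    "PorinPermeabilityModel",
    "permeability_score",
    "percent_of_glycine",
    "categorize_permeability",
    "fit_coefficients",
    "calibrate_glycine_score",
    "PERMEABILITY_CATEGORIES",
]

PERMEABILITY_CATEGORIES = ("very_bad", "poor", "good", "excellent")

_DESIGN_COLUMNS = ("steric", "charge", "dipole", "intercept")


class CalibrationError(RuntimeError):
    """Raised when scoring is attempted without the required calibration."""


@dataclass
class PermeabilityResult:
    """Score of one compound with its per-term breakdown."""

    compound_id: str
    score: float
    steric_term: float
    charge_term: float
    dipole_term: float
    intercept_term: float
    percent_of_glycine: float | None = None
    category: str | None = None

    terms_sum_tolerance: float = field(default=1e-12, repr=False)

    def __post_init__(self) -> None:
        total = (
            self.steric_term
            + self.charge_term
            + self.dipole_term
            + self.intercept_term
        )
        if abs(total - self.score) > self.terms_sum_tolerance * max(
            1.0, abs(self.score)
        ):
            raise ValueError("stored terms do not reconstruct the score")


def _as_frame(X) -> pd.DataFrame:
    """Accept a DataFrame or a list of DescriptorSet-like objects."""
    if isinstance(X, pd.DataFrame):
        return X
    rows = []
    for d in X:
        rows.append(
            {
                "id": d.compound_id,
                "net_charge": d.net_charge,
                "transversal_dipole": d.transversal_dipole_mean,
                "mpa_mean": d.mpa_mean,
                "mpa_sd": d.mpa_sd,
            }
        )
    return pd.DataFrame(rows)


def _design_matrix(frame: pd.DataFrame, pore: PoreModel) -> np.ndarray:
    required = {"net_charge", "transversal_dipole", "mpa_mean", "mpa_sd"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"descriptor table missing columns: {sorted(missing)}")
    steric = np.array(
        [
            steric_term(m, s, pore)
            for m, s in zip(frame["mpa_mean"], frame["mpa_sd"])
        ]
    )
    charge = frame["net_charge"].to_numpy(dtype=float) * pore.v_pore
    dipole = frame["transversal_dipole"].to_numpy(dtype=float) * pore.e_pore
    return np.column_stack((steric, charge, dipole, np.ones(len(frame))))


class PorinPermeabilityModel(BaseEstimator, RegressorMixin):
    """Linear permeability scorer for one configurable general porin.

    Parameters
    ----------
    pore:
        :class:`~porinperm.pore.PoreModel` with the porin's electrostatic
        and size parameters.
    coefficients:
        Optional :class:`~porinperm.pore.ScoringCoefficients`.  When given,
        ``predict`` works immediately; otherwise call :meth:`fit` with
        reference log-permeabilities first.

    Attributes
    ----------
    coefficients_ : ScoringCoefficients
        Active coefficients after ``fit`` (or copied from the constructor).
    stderr_ : ndarray of shape (4,)
        OLS standard errors of (alpha, beta, gamma, delta); NaN when the
        fit is exactly determined.
    residual_sd_ : float
        Residual standard deviation of the fit.
    """

    def __init__(
        self,
        pore: PoreModel | None = None,
        coefficients: ScoringCoefficients | None = None,
    ):
        self.pore = pore
        self.coefficients = coefficients

    # -- sklearn surface ----------------------------------------------------

    def _pore(self) -> PoreModel:
        return self.pore if self.pore is not None else PoreModel()

    def fit(self, X, y):
        """OLS fit of (alpha, beta, gamma, delta) to reference scores.

        ``X`` is a descriptor table (DataFrame with canonical columns or a
        list of descriptor sets); ``y`` the reference log-permeabilities.
        Requires at least 4 rows and a full-rank design; a rank-deficient
        design raises an error naming the collinear columns.
        """
        frame = _as_frame(X)
        y = np.asarray(y, dtype=float)
        if len(frame) != len(y):
            raise ValueError("X and y lengths differ")
        if len(frame) < 4:
            raise ValueError(
                f"need at least 4 training rows to identify 4 coefficients; "
                f"got {len(frame)}"
            )
        design = _design_matrix(frame, self._pore())
        rank = np.linalg.matrix_rank(design)
        if rank < 4:
            _, _, vt = np.linalg.svd(design, full_matrices=False)
            null = np.abs(vt[-1])
            collinear = [
                _DESIGN_COLUMNS[i]
                for i in range(4)
                if null[i] > 0.1 * null.max()
            ]
            raise ValueError(
                f"rank-deficient design (rank {rank} < 4); "
                f"collinear columns: {collinear}"
            )
        coef, rss, _, _ = np.linalg.lstsq(design, y, rcond=None)
        n = len(y)
        dof = n - 4
        if dof > 0:
            residuals = y - design @ coef
            sigma2 = float(residuals @ residuals) / dof
            cov = sigma2 * np.linalg.inv(design.T @ design)
            self.stderr_ = np.sqrt(np.diag(cov))
            self.residual_sd_ = float(np.sqrt(sigma2))
        else:
            self.stderr_ = np.full(4, np.nan)
            self.residual_sd_ = 0.0
        self.coefficients_ = ScoringCoefficients(*coef)
        self.n_features_in_ = design.shape[1]
        return self

    def _active_coefficients(self) -> ScoringCoefficients:
        if hasattr(self, "coefficients_"):
            return self.coefficients_
        if self.coefficients is not None:
            return self.coefficients
        raise CalibrationError(
            "no scoring coefficients: pass coefficients= or call fit() "
            "with reference log-permeabilities"
        )

    def predict(self, X) -> np.ndarray:
        """Permeability scores (log scale) for a descriptor table."""
        frame = _as_frame(X)
        design = _design_matrix(frame, self._pore())
        return design @ np.array(self._active_coefficients().as_tuple())

    # -- domain surface -----------------------------------------------------

    def score_compounds(
        self, X, percent: bool = True
    ) -> list[PermeabilityResult]:
        """Per-compound results with term breakdown, percent and category.

        ``percent=True`` requires ``pore.glycine_score``; call
        :func:`calibrate_glycine_score` (or :meth:`calibrate_glycine`)
        first so the 100% anchor matches the active coefficients.
        """
        frame = _as_frame(X)
        pore = self._pore()
        c = self._active_coefficients()
        design = _design_matrix(frame, pore)
        ids = (
            frame["id"].astype(str).tolist()
            if "id" in frame.columns
            else [str(i) for i in range(len(frame))]
        )
        results = []
        for row_id, row in zip(ids, design):
            terms = row * np.array(c.as_tuple())
            score = float(terms.sum())
            res = PermeabilityResult(
                compound_id=row_id,
                score=score,
                steric_term=float(terms[0]),
                charge_term=float(terms[1]),
                dipole_term=float(terms[2]),
                intercept_term=float(terms[3]),
            )
            if percent:
                res.percent_of_glycine = percent_of_glycine(score, pore)
                res.category = categorize_permeability(res.percent_of_glycine)
            results.append(res)
        return results

    def calibrate_glycine(self, glycine: dict | None = None) -> float:
        """Set ``pore.glycine_score`` by scoring the glycine reference."""
        pore = self._pore()
        score = calibrate_glycine_score(
            pore, self._active_coefficients(), glycine
        )
        if self.pore is None:
            self.pore = pore
        return score


# ---------------------------------------------------------------------------
# functional wrappers


def permeability_score(
    descriptors, pore: PoreModel, coefficients: ScoringCoefficients
) -> PermeabilityResult:
    """Score a single descriptor set (no percent/category attached)."""
    model = PorinPermeabilityModel(pore=pore, coefficients=coefficients)
    return model.score_compounds([descriptors], percent=False)[0]


def percent_of_glycine(score: float, pore: PoreModel) -> float:
    """Permeability as a percentage of glycine's: ``100 * exp(P - P_gly)``.

    Strictly increasing in the score; glycine itself maps to 100%.
    """
    if pore.glycine_score is None:
        raise CalibrationError(
            "pore.glycine_score is unset; calibrate the glycine anchor "
            "under the active coefficients first "
            "(calibrate_glycine_score or the `calibrate` command)"
        )
    return 100.0 * float(np.exp(score - pore.glycine_score))


def categorize_permeability(percent: float) -> str:
    """Glycine-relative percent -> {very_bad, poor, good, excellent}.

    Bands: very_bad [0, 30), poor [30, 50), good [50, 70], excellent
    (70, inf).
    """
    if percent <= 0:
        raise ValueError("percent must be positive")
    if percent < 30.0:
        return "very_bad"
    if percent < 50.0:
        return "poor"
    if percent <= 70.0:
        return "good"
    return "excellent"


def fit_coefficients(
    training, reference_scores, pore: PoreModel
) -> tuple[ScoringCoefficients, dict]:
    """OLS coefficient recovery from (descriptors, reference score) pairs.

    Returns the fitted :class:`ScoringCoefficients` and a diagnostics dict
    with standard errors and the residual standard deviation.
    """
    model = PorinPermeabilityModel(pore=pore)
    model.fit(training, reference_scores)
    diagnostics = {
        "stderr": dict(zip(("alpha", "beta", "gamma", "delta"), model.stderr_)),
        "residual_sd": model.residual_sd_,
        "n": len(reference_scores),
    }
    return model.coefficients_, diagnostics


def calibrate_glycine_score(
    pore: PoreModel,
    coefficients: ScoringCoefficients,
    glycine: dict | None = None,
) -> float:
    """Score the glycine reference descriptors and store the anchor.

    Mutates ``pore.glycine_score`` so every later percent-of-glycine uses
    an anchor consistent with the active coefficients and pore parameters.
    """
    ref = dict(GLYCINE_REFERENCE if glycine is None else glycine)
    frame = pd.DataFrame([ref])
    model = PorinPermeabilityModel(pore=pore, coefficients=coefficients)
    score = float(model.predict(frame)[0])
    pore.glycine_score = score
    return score
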