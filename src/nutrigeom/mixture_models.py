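"""Scheffé mixture-model fitting and AIC selection for diet-response data.

In a mixture experiment the predictors are proportions x1, x2, x3 summing
to one (here: protein, carbohydrate and fat energy fractions), so the
usual intercept is redundant and the canonical regression family is the
Scheffé polynomials. Five candidates are fitted:

========  ==========================================================  ==
model     terms                                                        k
========  ==========================================================  ==
null      1 (grand mean; no composition effect)                        1
1         x1, x2, x3 (linear blending)                                 3
2         + x1x2, x1x3, x2x3 (quadratic: pairwise blending)            6
3         model 2 + x1x2x3 (special cubic)                             7
4         model 2 + x1x2(x1-x2), x1x3(x1-x3), x2x3(x2-x3), x1x2x3     10
          (full cubic)
========  ==========================================================  ==

Each candidate is fitted by least squares and scored with
``AIC = n·ln(RSS/n) + 2(k+1)`` (the error variance counted as a
parameter); the lowest-AIC candidate wins, ties going to the smaller
model. Responses are modelled on their raw scale by default (e.g. Treg %
of CD4+ cells); an optional logit transform is available for proportions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .diet_design import DietComposition

__all__ = [
    "MODEL_IDS",
    "MODEL_NPARAMS",
    "DietResponseTable",
    "MixtureModelFit",
    "SingularDesignError",
    "InsufficientDataError",
    "DegenerateFitError",
    "build_design_matrix",
    "fit_mixture_model",
    "aic",
    "select_model",
    "predict_mixture",
]

MODEL_IDS = ("null", "1", "2", "3", "4")

#: Number of coefficients per model.
MODEL_NPARAMS = {"null": 1, "1": 3, "2": 6, "3": 7, "4": 10}

_TERMS = {
    "null": ["intercept"],
    "1": ["p", "c", "f"],
    "2": ["p", "c", "f", "p:c", "p:f", "c:f"],
    "3": ["p", "c", "f", "p:c", "p:f", "c:f", "p:c:f"],
    "4": [
        "p", "c", "f",
        "p:c", "p:f", "c:f",
        "p:c:(p-c)", "p:f:(p-f)", "c:f:(c-f)",
        "p:c:f",
    ],
}

#: Exact AIC tie tolerance; ties break toward the smaller model.
_AIC_TIE_TOL = 1e-9
_EXACT_FIT_TOL = 1e-10


class SingularDesignError(np.linalg.LinAlgError):
    """Design matrix is rank deficient (collinear Scheffé terms)."""


class InsufficientDataError(ValueError):
    """Fewer observations than model coefficients."""


class DegenerateFitError(ArithmeticError):
    """RSS is zero: the AIC's log-likelihood term is undefined."""


def _normalize_model_id(model_id) -> str:
    mid = str(model_id)
    if mid not in MODEL_IDS:
        raise ValueError(f"unknown mixture model id {model_id!r}; expected one of {MODEL_IDS}")
    return mid


@dataclass(frozen=True)
class DietResponseTable:
    """Per-sample responses keyed to diet compositions.

    One row per observation (e.g. per animal): the diet it received and
    the measured outcome. Several rows may share a diet.
    """

    diets: tuple[DietComposition, ...]
    responses: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "diets", tuple(self.diets))
        y = np.asarray(self.responses, dtype=float)
        object.__setattr__(self, "responses", y)
        if len(self.diets) == 0:
            raise ValueError("diet-response table must have at least one row")
        if y.shape != (len(self.diets),):
            raise ValueError(
                f"responses shape {y.shape} does not match {len(self.diets)} diets"
            )
        if not np.all(np.isfinite(y)):
            raise ValueError("responses must be finite")

    def __len__(self) -> int:
        return len(self.diets)

    @property
    def composition_matrix(self) -> np.ndarray:
        return np.array([d.fractions for d in self.diets])


@dataclass(frozen=True)
class MixtureModelFit:
    """A fitted Scheffé polynomial.

    Attributes
    ----------
    model_id
        ``"null"``, ``"1"``, ``"2"``, ``"3"`` or ``"4"``.
    coefficients
        Least-squares coefficients, ordered as ``term_names``.
    n_obs, n_params
        Rows fitted and number of coefficients k.
    rss
        Residual sum of squares.
    aic
        ``n·ln(rss/n) + 2(k+1)``; ``-inf`` for an exact (rss = 0) fit.
    """

    model_id: str
    coefficients: np.ndarray
    n_obs: int
    n_params: int
    rss: float
    aic: float
    term_names: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.n_params != MODEL_NPARAMS[self.model_id]:
            raise ValueError(
                f"model {self.model_id} has {MODEL_NPARAMS[self.model_id]} parameters, "
                f"got n_params={self.n_params}"
            )
        if self.rss < 0:
            raise ValueError("rss must be >= 0")

    @property
    def is_exact(self) -> bool:
        return self.rss <= _EXACT_FIT_TOL * max(1.0, self.n_obs)

    def predict(self, diets) -> np.ndarray:
        return predict_mixture(self, diets)

    def to_dict(self) -> dict:
        return {
            "model_id": self.model_id,
            "term_names": list(self.term_names),
            "coefficients": [float(b) for b in self.coefficients],
            "n_obs": int(self.n_obs),
            "n_params": int(self.n_params),
            "rss": float(self.rss),
            "aic": float(self.aic),
        }


def build_design_matrix(diets, model_id) -> np.ndarray:
    """Scheffé design matrix: one row per diet, one column per term.

    Models 1-4 carry no intercept column — on the simplex the linear
    terms already span the constant (x1 + x2 + x3 = 1).
    """
    mid = _normalize_model_id(model_id)
    comp = np.atleast_2d(np.array([d.fractions for d in diets]))
    p, c, f = comp[:, 0], comp[:, 1], comp[:, 2]
    if mid == "null":
        return np.ones((len(comp), 1))
    cols = [p, c, f]
    if mid in ("2", "3", "4"):
        cols += [p * c, p * f, c * f]
    if mid == "3":
        cols += [p * c * f]
    if mid == "4":
        cols += [p * c * (p - c), p * f * (p - f), c * f * (c - f), p * c * f]
    return np.column_stack(cols)


def _aic_value(n: int, rss: float, k: int) -> float:
    return n * math.log(rss / n) + 2 * (k + 1)


def aic(fit: MixtureModelFit) -> float:
    """AIC of a fit: ``n·ln(rss/n) + 2(k+1)``, σ² counted as a parameter."""
    if fit.is_exact:
        raise DegenerateFitError(
            f"model {fit.model_id} fits exactly (rss = {fit.rss!r}); AIC is undefined"
        )
    return _aic_value(fit.n_obs, fit.rss, fit.n_params)


def fit_mixture_model(data: DietResponseTable, model_id) -> MixtureModelFit:
    """Least-squares fit of one Scheffé candidate.

    Uses a rank-revealing orthogonal solve (LAPACK gelsd) rather than
    explicit normal equations, for stability near collinear designs.

    Raises
    ------
    InsufficientDataError
        If there are fewer rows than coefficients.
    SingularDesignError
        If the design matrix is rank deficient; the message names the
        terms involved in the collinearity.
    """
    mid = _normalize_model_id(model_id)
    y = data.responses
    n = len(data)
    k = MODEL_NPARAMS[mid]
    if n < k:
        raise InsufficientDataError(
            f"model {mid} needs at least {k} observations, table has {n}"
        )
    X = build_design_matrix(data.diets, mid)
    beta, _, rank, _ = scipy.linalg.lstsq(X, y, lapack_driver="gelsd")
    if rank < k:
        # name the columns whose removal restores full rank
        _, r = np.linalg.qr(X)
        dep = [
            _TERMS[mid][j]
            for j in range(k)
            if abs(r[j, j]) < 1e-10 * max(1.0, abs(r[0, 0]))
        ]
        raise SingularDesignError(
            f"design matrix for model {mid} is rank deficient "
            f"(rank {rank} < {k}); collinear terms: {dep or 'unresolved'}"
        )
    resid = y - X @ beta
    rss = float(resid @ resid)
    aic_val = _aic_value(n, rss, k) if rss > _EXACT_FIT_TOL * max(1.0, n) else -math.inf
    return MixtureModelFit(
        model_id=mid,
        coefficients=beta,
        n_obs=n,
        n_params=k,
        rss=rss,
        aic=aic_val,
        term_names=tuple(_TERMS[mid]),
    )


def select_model(
    data: DietResponseTable, candidates=MODEL_IDS
) -> tuple[MixtureModelFit, list[MixtureModelFit]]:
    """Fit every feasible candidate and return the lowest-AIC fit.

    Exact (rss = 0) fits beat any positive-rss fit; ties — exact or
    within 1e-9 of AIC — break toward the smaller model. Candidates with
    too few rows or a singular design are skipped.

    Returns
    -------
    best, all_fits
        The winning fit and the list of every candidate that could be
        fitted, in candidate order.
    """
    fits: list[MixtureModelFit] = []
    failures: dict[str, Exception] = {}
    for mid in candidates:
        try:
            fits.append(fit_mixture_model(data, mid))
        except (InsufficientDataError, SingularDesignError) as exc:
            failures[str(mid)] = exc
    if not fits:
        raise InsufficientDataError(
            f"no mixture candidate could be fitted: "
            + "; ".join(f"model {m}: {e}" for m, e in failures.items())
        )
    exact = [f for f in fits if f.is_exact]
    if exact:
        best = min(exact, key=lambda f: f.n_params)
    else:
        best = fits[0]
        for f in fits[1:]:
            if f.aic < best.aic - _AIC_TIE_TOL:
                best = f
            elif abs(f.aic - best.aic) <= _AIC_TIE_TOL and f.n_params < best.n_params:
                best = f
    return best, fits


def predict_mixture(fit: MixtureModelFit, diets) -> np.ndarray:
    """Predicted responses for new compositions: ``X(diets) @ coefficients``."""
    X = build_design_matrix(diets, fit.model_id)
    return X @ fit.coefficients
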