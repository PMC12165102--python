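"""Penalized-spline GAMMs for country-year macronutrient-supply panels.

The ecological question: across ~150 countries and ~29 years, how do
per-capita macronutrient energy supplies (protein, carbohydrate, fat, in
kcal/capita/day) relate to a disease-burden rate, after adjusting for
socioeconomic status (GDP per capita) and time, when all of these are
intercorrelated? The model family is a generalized additive mixed model:

    g(rate) = beta0 + sum_t f_t(predictors_t) + u_country + eps

where each f_t is a penalized-spline smooth (possibly a tensor-product
smooth of several predictors) and u_country is a country-level random
intercept. Smooths are P-splines: cubic B-spline bases with equally
spaced knots and a difference penalty on adjacent coefficients. Random
intercepts enter as a dummy-coded block under an identity (ridge)
penalty with its own smoothing parameter, so the whole model is one
penalized least-squares problem:

    min_beta ||y - X beta||^2 + sum_b lambda_b beta' S_b beta

Smoothing parameters are chosen by generalized cross-validation,
GCV = n*RSS/(n - edf)^2, via coordinate descent on a log10 grid; edf is
the trace of the influence matrix. Candidate model structures (which
predictors enter, additively or jointly) are compared by
AIC = n*ln(RSS/n) + 2*(edf + 1) and the lowest-AIC candidate selected.

The default response transform is log(rate + 0.5): rates per 100,000
are positive and right-skewed. GDP enters as log dollars.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg

__all__ = [
    "CountryPanel",
    "SmoothTerm",
    "GAMMSpec",
    "GAMMFit",
    "NutrientSurface",
    "OutOfRangeError",
    "PanelSchemaError",
    "PanelDataError",
    "GAMMSelectionError",
    "bspline_basis",
    "make_knots",
    "difference_penalty",
    "tensor_smooth",
    "enumerate_candidates",
    "fit_gamm",
    "select_gamm",
    "predict_gamm",
    "predict_nutrient_surface",
    "isocaloric_line",
    "energy_radial",
    "render_nutrient_surface",
]

log = logging.getLogger(__name__)

#: Panel columns required by the fitting routines.
PANEL_COLUMNS = ["country", "year", "stratum", "protein_kcal", "carb_kcal", "fat_kcal", "gdp", "rate"]

#: Model variables -> panel columns; gdp is log-transformed on extraction.
VARIABLE_COLUMNS = {
    "protein": "protein_kcal",
    "carb": "carb_kcal",
    "fat": "fat_kcal",
    "gdp": "gdp",
    "year": "year",
}

_LOG10_GRID = np.arange(-4.0, 5.0)  # lambda grid 1e-4 ... 1e4
_N_SWEEPS = 3
_RATE_OFFSET = 0.5  # per 100,000, added before the log transform


class OutOfRangeError(ValueError):
    """Evaluation point outside the boundary knots of a spline basis."""


class PanelSchemaError(KeyError):
    """Panel is missing a required column."""


class PanelDataError(ValueError):
    """Panel contains invalid values (non-finite, non-positive, duplicated keys)."""


class GAMMSelectionError(RuntimeError):
    """Every candidate model failed to fit."""


# ---------------------------------------------------------------------------
# panel container
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountryPanel:
    """Long-format country x year records of supplies, GDP and burden rate.

    Wraps a validated DataFrame with columns ``country, year, stratum,
    protein_kcal, carb_kcal, fat_kcal, gdp, rate``: supplies and GDP
    strictly positive, rate non-negative, (country, year, stratum) unique.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.data
        missing = [c for c in PANEL_COLUMNS if c not in df.columns]
        if missing:
            raise PanelSchemaError(f"panel missing required column(s): {missing}")
        num = df[["protein_kcal", "carb_kcal", "fat_kcal", "gdp", "rate", "year"]]
        if not np.all(np.isfinite(num.to_numpy(dtype=float))):
            raise PanelDataError("panel contains non-finite numeric values")
        for col in ("protein_kcal", "carb_kcal", "fat_kcal", "gdp"):
            if (df[col] <= 0).any():
                raise PanelDataError(f"panel column {col!r} must be strictly positive")
        if (df["rate"] < 0).any():
            raise PanelDataError("panel column 'rate' must be non-negative")
        if df.duplicated(["country", "year", "stratum"]).any():
            raise PanelDataError("(country, year, stratum) keys must be unique")
        object.__setattr__(self, "data", df.reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.data)

    def stratum(self, which: str = "both") -> "CountryPanel":
        """Restrict to one sex stratum (fits always use a single stratum)."""
        sub = self.data[self.data["stratum"] == which]
        if sub.empty:
            raise PanelDataError(f"no rows with stratum {which!r}")
        return CountryPanel(sub)


def _predictor_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Model-scale predictors: supplies as-is, gdp -> log(gdp), year as-is."""
    out = pd.DataFrame(index=df.index)
    for var, col in VARIABLE_COLUMNS.items():
        x = df[col].to_numpy(dtype=float)
        out[var] = np.log(x) if var == "gdp" else x
    return out


# ---------------------------------------------------------------------------
# spline machinery
# ---------------------------------------------------------------------------


def make_knots(lo: float, hi: float, n_basis: int, degree: int = 3) -> np.ndarray:
    """Equally spaced B-spline knots over [lo, hi] with boundary extension.

    The full knot vector has ``n_basis + degree + 1`` entries; the basis
    is a partition of unity on the closed interval [lo, hi].
    """
    if n_basis < degree + 1:
        raise ValueError(f"n_basis must be >= degree + 1 = {degree + 1}, got {n_basis}")
    if hi <= lo:  # constant predictor: widen to a degenerate-safe interval
        lo, hi = lo - 0.5, hi + 0.5
    h = (hi - lo) / (n_basis - degree)
    return lo + h * np.arange(-degree, n_basis + 1)


def bspline_basis(
    x, n_basis: int, degree: int = 3, knots: np.ndarray | None = None
) -> np.ndarray:
    """Cubic (by default) B-spline basis matrix at the points ``x``.

    Knots are equally spaced over [min(x), max(x)] unless an explicit
    knot vector (from :func:`make_knots`) is supplied, as when
    evaluating a fitted smooth at new points. Rows sum to one.

    Raises
    ------
    OutOfRangeError
        If any point lies outside the boundary knots (beyond a small
        floating-point tolerance, within which points are clamped).
    """
    x = np.asarray(x, dtype=float)
    if knots is None:
        knots = make_knots(float(np.min(x)), float(np.max(x)), n_basis, degree)
    knots = np.asarray(knots, dtype=float)
    if len(knots) != n_basis + degree + 1:
        raise ValueError(
            f"knot vector has {len(knots)} entries, expected n_basis + degree + 1 = "
            f"{n_basis + degree + 1}"
        )
    lo, hi = knots[degree], knots[-degree - 1]
    tol = 1e-8 * max(hi - lo, 1.0)
    if np.any(x < lo - tol) or np.any(x > hi + tol):
        bad = x[(x < lo - tol) | (x > hi + tol)]
        raise OutOfRangeError(
            f"{bad.size} point(s) outside spline range [{lo:g}, {hi:g}]: "
            f"e.g. {bad.flat[0]:g}"
        )
    xc = np.clip(x, lo, hi)
    from scipy.interpolate import BSpline

    B = BSpline.design_matrix(xc.ravel(), knots, degree).toarray()
    return B.reshape(x.shape + (n_basis,)) if x.ndim > 1 else B


def difference_penalty(n_basis: int, order: int = 2) -> np.ndarray:
    """P-spline difference penalty ``S = D'D`` of the given order.

    ``D`` is the ``order``-th difference operator on the coefficient
    vector; S is symmetric positive semidefinite with null space the
    polynomials of degree < order in the coefficient index (so an
    order-2 penalty leaves straight lines unpenalized).
    """
    if n_basis <= order:
        raise ValueError(f"n_basis must exceed penalty order, got {n_basis} <= {order}")
    D = np.diff(np.eye(n_basis), n=order, axis=0)
    return D.T @ D


# ---------------------------------------------------------------------------
# model terms and specs
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SmoothTerm:
    """One penalized smooth: 1-4 variables, marginal basis sizes, penalty order.

    A multi-variable term is a tensor-product smooth: the row-wise
    Kronecker product of the marginal B-spline bases, with one
    difference penalty per margin.
    """

    variables: tuple[str, ...]
    basis_size: int = 5
    penalty_order: int = 2
    degree: int = 3

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        if not 1 <= len(self.variables) <= 4:
            raise ValueError("a smooth term takes 1-4 variables")
        unknown = [v for v in self.variables if v not in VARIABLE_COLUMNS]
        if unknown:
            raise ValueError(f"unknown model variable(s) {unknown}; allowed: {list(VARIABLE_COLUMNS)}")
        if self.basis_size < self.penalty_order + 1:
            raise ValueError("basis_size must be >= penalty_order + 1")

    @property
    def n_columns(self) -> int:
        return self.basis_size ** len(self.variables)

    @property
    def name(self) -> str:
        kind = "s" if len(self.variables) == 1 else "te"
        return f"{kind}({','.join(self.variables)})"


@dataclass(frozen=True)
class GAMMSpec:
    """A candidate model: smooth terms + optional country random intercept."""

    name: str
    terms: tuple[SmoothTerm, ...] = ()
    include_random_country: bool = True
    response_transform: str = "log"  # "log": log(rate + 0.5); "identity"

    def __post_init__(self) -> None:
        object.__setattr__(self, "terms", tuple(self.terms))
        varsets = [frozenset(t.variables) for t in self.terms]
        if len(set(varsets)) != len(varsets):
            raise ValueError("smooth terms must have distinct variable sets")
        if not self.terms and not self.include_random_country:
            raise ValueError("spec needs at least one smooth term or the random effect")
        if self.response_transform not in ("log", "identity"):
            raise ValueError(f"unknown response_transform {self.response_transform!r}")

    @property
    def n_smooth_columns(self) -> int:
        return sum(t.n_columns for t in self.terms)


def enumerate_candidates(max_interaction_order: int = 2) -> list[GAMMSpec]:
    """The fixed candidate set over nutrient, GDP and year effects.

    Built from four blocks — N = joint smooth of the three supplies,
    G = smooth(gdp), Y = smooth(year), NxG = joint smooth of supplies
    and gdp — giving ten structures: null, N, G, Y, N+G, N+Y, G+Y,
    N+G+Y, NxG, NxG+Y. Every candidate includes the country random
    intercept. ``max_interaction_order`` = 2 caps interactions at the
    nutrient-block x GDP tensor (no 3-way tensor with year).
    """
    N = SmoothTerm(("protein", "carb", "fat"), basis_size=4)
    G = SmoothTerm(("gdp",), basis_size=5)
    Y = SmoothTerm(("year",), basis_size=5)
    # 3 basis functions per margin require degree 2 (quadratic marginals);
    # keeps the 4D tensor at 81 columns
    NxG = SmoothTerm(("protein", "carb", "fat", "gdp"), basis_size=3, degree=2)
    blocks: list[tuple[str, tuple[SmoothTerm, ...]]] = [("null", ())]
    for combo in itertools.chain.from_iterable(
        itertools.combinations((("N", N), ("G", G), ("Y", Y)), r) for r in (1, 2, 3)
    ):
        blocks.append(("+".join(k for k, _ in combo), tuple(t for _, t in combo)))
    if max_interaction_order >= 2:
        blocks.append(("NxG", (NxG,)))
        blocks.append(("NxG+Y", (NxG, Y)))
    return [GAMMSpec(name=n, terms=t, include_random_country=True) for n, t in blocks]


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


@dataclass
class _TermDesign:
    term: SmoothTerm
    knots: list[np.ndarray]
    col_means: np.ndarray
    sl: slice = field(default_factory=lambda: slice(0, 0))


def _row_kron(mats: list[np.ndarray]) -> np.ndarray:
    out = mats[0]
    for B in mats[1:]:
        out = (out[:, :, None] * B[:, None, :]).reshape(out.shape[0], -1)
    return out


def tensor_smooth(
    term: SmoothTerm, data, design: _TermDesign | None = None
) -> tuple[np.ndarray, list[np.ndarray], _TermDesign]:
    """Model columns and penalty blocks for one (possibly tensor) smooth.

    Columns are the row-wise Kronecker product of the marginal B-spline
    bases, centered to sum to zero over the training rows for
    identifiability against the intercept; there is one penalty block
    per margin (the marginal difference penalty Kronecker identity on
    the other margins). Passing a stored ``design`` re-evaluates the
    same basis (same knots, same centering) at new data.
    """
    if isinstance(data, CountryPanel):
        data = _predictor_frame(data.data)
    elif not isinstance(data, pd.DataFrame):
        raise TypeError("data must be a CountryPanel or predictor DataFrame")
    missing = [v for v in term.variables if v not in data.columns]
    if missing:
        raise PanelSchemaError(f"predictor frame missing variable(s): {missing}")

    K, d = term.basis_size, term.degree
    margins: list[np.ndarray] = []
    knots: list[np.ndarray] = []
    for i, v in enumerate(term.variables):
        x = data[v].to_numpy(dtype=float)
        kn = design.knots[i] if design is not None else make_knots(x.min(), x.max(), K, d)
        margins.append(bspline_basis(x, K, d, knots=kn))
        knots.append(kn)
    cols = _row_kron(margins)
    if design is None:
        col_means = cols.mean(axis=0)
        if cols.shape[1] > cols.shape[0]:
            warnings.warn(
                f"smooth {term.name} has {cols.shape[1]} columns for {cols.shape[0]} rows; "
                "penalties will regularize the fit",
                stacklevel=2,
            )
        design = _TermDesign(term=term, knots=knots, col_means=col_means)
    cols = cols - design.col_means

    S1 = difference_penalty(K, term.penalty_order)
    penalties = []
    m = len(term.variables)
    for j in range(m):
        mats = [S1 if i == j else np.eye(K) for i in range(m)]
        S = mats[0]
        for M in mats[1:]:
            S = np.kron(S, M)
        penalties.append(S)
    # The centered columns satisfy X @ 1 = 0 exactly (B-spline rows sum to
    # one), and every difference penalty also annihilates the constant
    # coefficient direction, so the penalized system would be singular
    # along it. Pin that direction in the first penalty block: this only
    # constrains a coefficient combination that never touches the fitted
    # values.
    p = cols.shape[1]
    penalties[0] = penalties[0] + np.full((p, p), 1.0 / p)
    return cols, penalties, design


@dataclass
class _ModelDesign:
    """Full fixed+random design: intercept | term blocks | country dummies."""

    spec: GAMMSpec
    term_designs: list[_TermDesign]
    countries: np.ndarray | None  # level order for the dummy block
    country_sl: slice | None
    n_columns: int
    penalty_blocks: list[tuple[str, slice, np.ndarray]]  # (name, slice, S)

    def build(self, df: pd.DataFrame, pred: pd.DataFrame) -> np.ndarray:
        n = len(pred)
        X = np.zeros((n, self.n_columns))
        X[:, 0] = 1.0
        for td in self.term_designs:
            cols, _, _ = tensor_smooth(td.term, pred, design=td)
            X[:, td.sl] = cols
        if self.countries is not None:
            codes = pd.Categorical(df["country"], categories=self.countries).codes
            if (codes < 0).any():
                raise PanelDataError("unknown country level in prediction data")
            X[np.arange(n), self.country_sl.start + codes] = 1.0
        return X


def _build_design(spec: GAMMSpec, panel: CountryPanel) -> tuple[np.ndarray, _ModelDesign]:
    df = panel.data
    pred = _predictor_frame(df)
    term_designs: list[_TermDesign] = []
    penalty_blocks: list[tuple[str, slice, np.ndarray]] = []
    pieces: list[np.ndarray] = [np.ones((len(df), 1))]
    pos = 1
    for term in spec.terms:
        cols, pens, td = tensor_smooth(term, pred)
        td.sl = slice(pos, pos + cols.shape[1])
        for j, S in enumerate(pens):
            pname = td.term.name if len(pens) == 1 else f"{td.term.name}[{term.variables[j]}]"
            penalty_blocks.append((pname, td.sl, S))
        term_designs.append(td)
        pieces.append(cols)
        pos += cols.shape[1]
    countries = None
    country_sl = None
    if spec.include_random_country:
        countries = np.asarray(pd.unique(df["country"]))
        codes = pd.Categorical(df["country"], categories=countries).codes
        Z = np.zeros((len(df), len(countries)))
        Z[np.arange(len(df)), codes] = 1.0
        country_sl = slice(pos, pos + len(countries))
        penalty_blocks.append(("country", country_sl, np.eye(len(countries))))
        pieces.append(Z)
        pos += len(countries)
    X = np.hstack(pieces)
    md = _ModelDesign(
        spec=spec,
        term_designs=term_designs,
        countries=countries,
        country_sl=country_sl,
        n_columns=pos,
        penalty_blocks=penalty_blocks,
    )
    return X, md


# ---------------------------------------------------------------------------
# penalized fitting with GCV
# ---------------------------------------------------------------------------


@dataclass
class GAMMFit:
    """A fitted penalized-spline GAMM.

    Attributes
    ----------
    spec
        The model structure that was fitted.
    coefficients
        Full coefficient vector: intercept, smooth-term blocks, country
        intercepts (in design order).
    lambdas
        One smoothing parameter per penalty block, keyed by block name.
    edf
        Effective degrees of freedom, trace of the influence matrix.
    rss, gcv, aic
        Residual sum of squares on the transformed scale, the GCV score
        at the selected lambdas, and ``n*ln(rss/n) + 2*(edf+1)``.
    aic_table
        When produced by :func:`select_gamm`, one row per candidate,
        sorted by AIC ascending.
    """

    spec: GAMMSpec
    coefficients: np.ndarray
    lambdas: dict[str, float]
    edf: float
    rss: float
    gcv: float
    aic: float
    n_obs: int
    design: _ModelDesign
    fitted_values: np.ndarray
    aic_table: pd.DataFrame | None = None
    _train_df: pd.DataFrame | None = None

    @property
    def intercept(self) -> float:
        return float(self.coefficients[0])

    @property
    def country_intercepts(self) -> pd.Series | None:
        if self.design.countries is None:
            return None
        return pd.Series(
            self.coefficients[self.design.country_sl], index=self.design.countries
        )

    def transform_response(self, rate: np.ndarray) -> np.ndarray:
        rate = np.asarray(rate, dtype=float)
        return np.log(rate + _RATE_OFFSET) if self.spec.response_transform == "log" else rate

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.name,
            "terms": [t.name for t in self.spec.terms],
            "lambdas": {k: float(v) for k, v in self.lambdas.items()},
            "edf": float(self.edf),
            "rss": float(self.rss),
            "gcv": float(self.gcv),
            "aic": float(self.aic),
            "n_obs": int(self.n_obs),
        }


def _solve_penalized(
    XtX: np.ndarray,
    Xty: np.ndarray,
    yty: float,
    n: int,
    blocks: list[tuple[str, slice, np.ndarray]],
    lambdas: np.ndarray,
) -> tuple[np.ndarray, float, float, float]:
    """beta, rss, edf, gcv at one smoothing-parameter vector."""
    A = XtX.copy()
    for (_, sl, S), lam in zip(blocks, lambdas):
        A[sl, sl] += lam * S
    use_pinv = len(lambdas) > 0 and float(np.min(lambdas)) <= 0.0
    if not use_pinv:
        try:
            c = scipy.linalg.cho_factor(A, lower=True, check_finite=False)
            beta = scipy.linalg.cho_solve(c, Xty, check_finite=False)
            H = scipy.linalg.cho_solve(c, XtX, check_finite=False)
        except np.linalg.LinAlgError:
            use_pinv = True
    if use_pinv:
        # a zero smoothing parameter can leave A exactly singular along
        # unidentifiable directions; the minimum-norm solution ignores them
        Ainv = np.linalg.pinv(A, rcond=1e-10, hermitian=True)
        beta = Ainv @ Xty
        H = Ainv @ XtX
    edf = float(np.trace(H))
    rss = max(float(yty - 2.0 * beta @ Xty + beta @ (XtX @ beta)), 0.0)
    denom = n - edf
    gcv = n * rss / (denom * denom) if denom > 1e-8 else np.inf
    return beta, rss, edf, gcv


def fit_gamm(
    spec: GAMMSpec,
    panel: CountryPanel,
    fixed_lambdas=None,
    n_sweeps: int = _N_SWEEPS,
) -> GAMMFit:
    """Fit one candidate GAMM by penalized least squares with GCV.

    Smoothing parameters are selected by coordinate descent over the
    log10 grid {-4, ..., +4}, ``n_sweeps`` sweeps, minimizing
    GCV = n*RSS/(n - edf)^2; pass ``fixed_lambdas`` (scalar, sequence,
    or dict by block name) to skip selection — e.g. a very large value
    reduces an order-2 smooth to its linear null space, and 0 gives the
    unpenalized least-squares fit.
    """
    if len(panel) == 0:
        raise PanelDataError("panel is empty")
    df = panel.data
    y = df["rate"].to_numpy(dtype=float)
    if spec.response_transform == "log":
        y = np.log(y + _RATE_OFFSET)
    if not np.all(np.isfinite(y)):
        raise PanelDataError("transformed response contains non-finite values")

    X, md = _build_design(spec, panel)
    n, p = X.shape
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    blocks = md.penalty_blocks
    nb = len(blocks)

    if fixed_lambdas is not None:
        if np.isscalar(fixed_lambdas):
            lambdas = np.full(nb, float(fixed_lambdas))
        elif isinstance(fixed_lambdas, dict):
            lambdas = np.array([float(fixed_lambdas[name]) for name, _, _ in blocks])
        else:
            lambdas = np.asarray(fixed_lambdas, dtype=float)
            if lambdas.shape != (nb,):
                raise ValueError(f"expected {nb} lambdas, got {lambdas.shape}")
        beta, rss, edf, gcv = _solve_penalized(XtX, Xty, yty, n, blocks, lambdas)
    else:
        grid = 10.0 ** _LOG10_GRID
        lambdas = np.ones(nb)
        cache: dict[tuple, tuple] = {}

        def eval_at(lams: np.ndarray):
            key = tuple(lams)
            if key not in cache:
                cache[key] = _solve_penalized(XtX, Xty, yty, n, blocks, lams)
            return cache[key]

        beta, rss, edf, gcv = eval_at(lambdas)
        for _ in range(n_sweeps):
            for b in range(nb):
                best = (eval_at(lambdas)[3], lambdas[b])
                for lam in grid:
                    trial = lambdas.copy()
                    trial[b] = lam
                    g = eval_at(trial)[3]
                    if g < best[0] - 1e-12:
                        best = (g, lam)
                lambdas[b] = best[1]
            beta, rss, edf, gcv = eval_at(lambdas)

    rss_floor = max(rss, 1e-300)
    aic = n * np.log(rss_floor / n) + 2.0 * (edf + 1.0)
    fitted = X @ beta
    return GAMMFit(
        spec=spec,
        coefficients=beta,
        lambdas={name: float(l) for (name, _, _), l in zip(blocks, lambdas)},
        edf=edf,
        rss=rss,
        gcv=gcv,
        aic=float(aic),
        n_obs=n,
        design=md,
        fitted_values=fitted,
        _train_df=df,
    )


def select_gamm(panel: CountryPanel, candidates=None) -> GAMMFit:
    """Fit every candidate and return the lowest-AIC fit.

    Ties (within 1e-9 of AIC) break toward the candidate with fewer
    model columns. The returned fit carries an ``aic_table`` with one
    row per successfully fitted candidate, sorted by AIC ascending.
    """
    if candidates is None:
        candidates = enumerate_candidates()
    fits: list[GAMMFit] = []
    failures: dict[str, Exception] = {}
    for spec in candidates:
        try:
            fits.append(fit_gamm(spec, panel))
        except Exception as exc:  # aggregate: selection reports all failures
            failures[spec.name] = exc
            log.warning("candidate %s failed: %s", spec.name, exc)
    if not fits:
        raise GAMMSelectionError(
            "all GAMM candidates failed: "
            + "; ".join(f"{k}: {v}" for k, v in failures.items())
        )
    best = fits[0]
    for f in fits[1:]:
        if f.aic < best.aic - 1e-9:
            best = f
        elif abs(f.aic - best.aic) <= 1e-9 and f.design.n_columns < best.design.n_columns:
            best = f
    table = pd.DataFrame(
        [
            {
                "candidate": f.spec.name,
                "n_columns": f.design.n_columns,
                "edf": f.edf,
                "rss": f.rss,
                "gcv": f.gcv,
                "aic": f.aic,
            }
            for f in fits
        ]
    ).sort_values("aic", ignore_index=True)
    best.aic_table = table
    return best


# ---------------------------------------------------------------------------
# prediction and nutrient-space geometry
# ---------------------------------------------------------------------------


def predict_gamm(fit: GAMMFit, new_data: pd.DataFrame, use_country: bool = False) -> np.ndarray:
    """Predict (on the transformed-response scale) at new rows.

    ``new_data`` needs the panel supply/gdp/year columns; with
    ``use_country=False`` the country random intercept is set to zero
    (population-level prediction), otherwise rows must carry a known
    ``country``.
    """
    pred = _predictor_frame(new_data)
    md = fit.design
    if use_country:
        X = md.build(new_data, pred)
        return X @ fit.coefficients
    n = len(pred)
    out = np.full(n, fit.intercept)
    for td in md.term_designs:
        cols, _, _ = tensor_smooth(td.term, pred, design=td)
        out += cols @ fit.coefficients[td.sl]
    return out


@dataclass(frozen=True)
class NutrientSurface:
    """Predicted response over a (fat, carb) supply grid.

    ``values[i, j]`` is the prediction at (fat_grid[j], carb_grid[i]) on
    the transformed-response scale, NaN outside ``mask`` (the convex
    hull of the observed supply pairs); protein, GDP and year are held
    fixed at the stated values.
    """

    fat_grid: np.ndarray
    carb_grid: np.ndarray
    values: np.ndarray
    mask: np.ndarray
    protein_value: float
    gdp_value: float
    year: float


def predict_nutrient_surface(
    fit: GAMMFit,
    fat_grid: np.ndarray | None = None,
    carb_grid: np.ndarray | None = None,
    protein_quantile: float = 0.5,
    gdp_value: float | None = None,
    year: float | None = None,
    n_grid: int = 41,
) -> NutrientSurface:
    """Response surface over fat x carb supply at fixed protein quantile.

    Protein supply is held at the requested quantile of the training
    panel (the conventional display uses the 25%, 50% and 75%
    quantiles); GDP defaults to the panel median and year to the latest
    observed year. Predictions are population-level (country intercept
    zero) and masked to the convex hull of the observed (fat, carb)
    supply pairs — no extrapolation outside supported supply space.
    """
    if not 0.0 < protein_quantile < 1.0:
        raise ValueError(f"protein_quantile must be in (0, 1), got {protein_quantile}")
    df = fit._train_df
    if df is None:
        raise ValueError("fit does not carry training data; cannot build surface")
    fat_obs = df["fat_kcal"].to_numpy(dtype=float)
    carb_obs = df["carb_kcal"].to_numpy(dtype=float)
    if fat_grid is None:
        fat_grid = np.linspace(fat_obs.min(), fat_obs.max(), n_grid)
    if carb_grid is None:
        carb_grid = np.linspace(carb_obs.min(), carb_obs.max(), n_grid)
    fat_grid = np.asarray(fat_grid, dtype=float)
    carb_grid = np.asarray(carb_grid, dtype=float)
    protein_value = float(np.quantile(df["protein_kcal"], protein_quantile))
    if gdp_value is None:
        gdp_value = float(df["gdp"].median())
    if year is None:
        year = float(df["year"].max())

    F, C = np.meshgrid(fat_grid, carb_grid)
    from scipy.spatial import Delaunay, QhullError

    try:
        tri = Delaunay(np.column_stack([fat_obs, carb_obs]))
        mask = (tri.find_simplex(np.column_stack([F.ravel(), C.ravel()])) >= 0).reshape(F.shape)
    except QhullError:  # degenerate observed cloud: fall back to the bounding box
        mask = (
            (F >= fat_obs.min()) & (F <= fat_obs.max())
            & (C >= carb_obs.min()) & (C <= carb_obs.max())
        )
    values = np.full(F.shape, np.nan)
    if mask.any():
        grid_df = pd.DataFrame(
            {
                "protein_kcal": protein_value,
                "carb_kcal": C[mask],
                "fat_kcal": F[mask],
                "gdp": gdp_value,
                "year": year,
            }
        )
        values[mask] = predict_gamm(fit, grid_df, use_country=False)
    return NutrientSurface(
        fat_grid=fat_grid,
        carb_grid=carb_grid,
        values=values,
        mask=mask,
        protein_value=protein_value,
        gdp_value=gdp_value,
        year=year,
    )


def isocaloric_line(total_energy: float, protein_fixed: float) -> np.ndarray:
    """Isocaloric line in (fat, carb) supply space, as its two endpoints.

    The locus f + c = total_energy - protein_fixed (f, c >= 0): total
    macronutrient energy is constant while the carbohydrate:fat ratio
    varies along it; slope -1 everywhere. Returns
    ``[[0, E], [E, 0]]`` with E the non-protein energy.
    """
    rem = total_energy - protein_fixed
    if protein_fixed <= 0 or rem <= 0:
        raise ValueError(
            f"need total_energy > protein_fixed > 0, got total={total_energy}, "
            f"protein={protein_fixed}"
        )
    return np.array([[0.0, rem], [rem, 0.0]])


def energy_radial(cf_ratio: float, max_energy: float) -> np.ndarray:
    """Radial in (fat, carb) space: constant carbohydrate:fat ratio.

    The ray c = cf_ratio * f from the origin, truncated where total
    non-protein energy f + c reaches ``max_energy``; moving outward
    raises total energy at a fixed macronutrient balance. Returns the
    two endpoints ``[[~0, ~0], [f_max, c_max]]``.
    """
    if cf_ratio <= 0:
        raise ValueError(f"cf_ratio must be > 0, got {cf_ratio}")
    if max_energy <= 0:
        raise ValueError(f"max_energy must be > 0, got {max_energy}")
    f_max = max_energy / (1.0 + cf_ratio)
    return np.array([[0.0, 0.0], [f_max, cf_ratio * f_max]])


def render_nutrient_surface(
    surface: NutrientSurface,
    path,
    isocaloric_total: float | None = None,
    radial_ratios=(0.5, 1.0, 2.0),
    palette: str = "RdYlGn_r",
    title: str | None = None,
):
    """Render a nutrient-supply surface with isocaloric line and radials.

    Filled contours (red = higher burden, green = lower, matching the
    conventional display), a purple isocaloric line at
    ``isocaloric_total`` kcal (default: the median observed total
    supply), and red radials of constant carbohydrate:fat ratio.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    F, C = np.meshgrid(surface.fat_grid, surface.carb_grid)
    z = np.ma.masked_invalid(surface.values)
    fig, ax = plt.subplots(figsize=(5.5, 5))
    filled = ax.contourf(F, C, z, levels=32, cmap=palette)
    cs = ax.contour(F, C, z, levels=8, colors="k", linewidths=0.5)
    ax.clabel(cs, fmt="%.2f", fontsize=7)
    if isocaloric_total is None:
        isocaloric_total = float(
            np.median(surface.fat_grid) + np.median(surface.carb_grid) + surface.protein_value
        )
    seg = isocaloric_line(isocaloric_total, surface.protein_value)
    ax.plot(seg[:, 0], seg[:, 1], color="purple", lw=2, label="isocaloric")
    e_max = float(surface.fat_grid.max() + surface.carb_grid.max())
    for r in radial_ratios:
        ray = energy_radial(r, e_max)
        ax.plot(ray[:, 0], ray[:, 1], color="red", lw=1, ls="--")
    ax.set_xlim(surface.fat_grid.min(), surface.fat_grid.max())
    ax.set_ylim(surface.carb_grid.min(), surface.carb_grid.max())
    ax.set_xlabel("Fat supply (kcal/capita/day)")
    ax.set_ylabel("Carbohydrate supply (kcal/capita/day)")
    if title is None:
        title = f"protein = {surface.protein_value:.0f} kcal, year = {surface.year:.0f}"
    ax.set_title(title)
    fig.colorbar(filled, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
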