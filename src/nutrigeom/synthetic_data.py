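"""Seeded generators with known ground truth.

Two input classes are emulated:

* a global country-year panel (~150 countries, 1990-2018) of
  macronutrient supplies, GDP per capita and a disease-burden rate, with
  the intercorrelation structure that makes the ecological analysis
  hard: GDP drifts upward as a per-country random walk, supplies trend
  upward with time and couple positively to log-GDP, and the rate
  responds smoothly to supplies with a known (returned) truth surface —
  rising in carbohydrate supply, falling in fat supply, mildly
  saturating, optionally modulated by GDP;

* a 10-diet isocaloric feeding experiment: per-animal responses (e.g.
  Treg % of CD4+ cells) generated from a known Scheffé polynomial over
  the diet compositions plus Gaussian noise, the default truth being
  linear and fat-dominant.

Every generator takes a mandatory seed and is byte-reproducible; every
returned dataset comes with its generating truth, so recovery and
model-selection tests always have a reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diet_design import DietDesign, make_full_design
from .gamm_surface import CountryPanel
from .mixture_models import MODEL_NPARAMS, DietResponseTable, build_design_matrix

__all__ = [
    "PanelConfig",
    "PanelTruth",
    "TregConfig",
    "gen_country_panel",
    "gen_treg_experiment",
]


@dataclass(frozen=True)
class PanelConfig:
    """Generator settings for the country-year panel.

    The defaults emulate the real analysis conditions: 150 countries
    observed yearly 1990-2018 (4,350 rows per stratum), supplies in
    kcal/capita/day near global averages (protein ~300, carbohydrate
    ~1500, fat ~600), GDP per capita log-normally spread with upward
    drift, and a burden rate of order tens per 100,000.

    ``surface_amplitudes`` = (carb_slope, fat_slope, nonlinearity,
    gdp_interaction, year_trend) controls the truth on the log-rate
    scale: the response rises with carbohydrate supply and falls with
    fat supply (mildly saturating via tanh), the nutrient effect is
    scaled by ``1 + gdp_interaction * tanh(log-GDP deviation)``, and the
    rate drifts with calendar year. Set ``gdp_interaction`` to 0 for a
    purely additive truth.
    """

    n_countries: int = 150
    year_start: int = 1990
    year_end: int = 2018
    strata: tuple[str, ...] = ("both",)
    # GDP per capita: per-country log-scale random walk with drift
    gdp_log_mean: float = 9.0  # ~8,100 constant dollars
    gdp_log_sd: float = 1.0
    gdp_drift: float = 0.02  # log-dollars per year
    gdp_noise: float = 0.03  # random-walk innovation sd
    # supplies, kcal/capita/day: baseline + trend*(year-start) + coupling*logGDP + noise
    supply_base: tuple[float, float, float] = (300.0, 1500.0, 600.0)  # P, C, F
    supply_country_sd: tuple[float, float, float] = (40.0, 150.0, 100.0)
    supply_trend: tuple[float, float, float] = (1.5, 6.0, 5.0)  # kcal/year
    supply_gdp_coupling: tuple[float, float, float] = (30.0, 120.0, 80.0)  # kcal per log-dollar
    supply_noise_sd: tuple[float, float, float] = (10.0, 40.0, 25.0)
    # truth surface on the log-rate scale
    surface_amplitudes: tuple[float, float, float, float, float] = (0.4, 0.4, 0.6, 0.6, -0.004)
    baseline_log_rate: float = 3.3  # rate ~ exp(3.3) ~ 27 per 100,000
    country_sd: float = 0.3  # random-intercept scale, log-rate units
    noise_sd: float = 0.10  # residual scale, log-rate units
    dropout: float = 0.0  # uniform row-dropout probability
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_countries <= 0:
            raise ValueError("n_countries must be positive")
        if self.year_end < self.year_start:
            raise ValueError("years must be ordered")
        if self.country_sd < 0 or self.noise_sd < 0 or self.gdp_noise < 0:
            raise ValueError("noise scales must be non-negative")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must be in [0, 1)")


# reference points and scales for standardizing supplies / GDP in the truth
_C_REF, _C_SCALE = 1500.0, 400.0
_F_REF, _F_SCALE = 600.0, 250.0
_G_REF = 9.0


@dataclass(frozen=True)
class PanelTruth:
    """The generating response surface, evaluable anywhere in supply space.

    ``surface(P, C, F, gdp)`` returns the nutrient/GDP part of the
    log-rate (no intercept, year trend or country effect) — the
    reference for surface-recovery comparisons; ``linear_predictor``
    adds the intercept and year trend back.
    """

    amplitudes: tuple[float, float, float, float, float]
    baseline_log_rate: float
    year_ref: float

    def surface(self, protein, carb, fat, gdp) -> np.ndarray:
        a_c, a_f, nl, a_int, _ = self.amplitudes
        zc = (np.asarray(carb, dtype=float) - _C_REF) / _C_SCALE
        zf = (np.asarray(fat, dtype=float) - _F_REF) / _F_SCALE
        zg = np.log(np.asarray(gdp, dtype=float)) - _G_REF
        if nl > 0:
            g = lambda z: np.tanh(nl * z) / nl
        else:
            g = lambda z: z
        f_nut = a_c * g(zc) - a_f * g(zf)
        return (1.0 + a_int * np.tanh(zg)) * f_nut

    def linear_predictor(self, protein, carb, fat, gdp, year) -> np.ndarray:
        trend = self.amplitudes[4]
        return (
            self.baseline_log_rate
            + self.surface(protein, carb, fat, gdp)
            + trend * (np.asarray(year, dtype=float) - self.year_ref)
        )


def gen_country_panel(config: PanelConfig) -> tuple[CountryPanel, PanelTruth]:
    """Simulate the country-year panel and return it with its truth surface.

    Within each country, log-GDP follows a random walk with drift from a
    log-normal baseline; each macronutrient supply is its country
    baseline plus a calendar trend plus a positive coupling to log-GDP
    plus noise (so supplies, GDP and time are intercorrelated, as in the
    real sources); the rate is
    ``exp(b0 + f_true(C, F; gdp) + trend*(year - year_ref) + u_country + eps)``
    with ``u_country ~ N(0, country_sd)`` and ``eps ~ N(0, noise_sd)``.
    Supplies are floored at 30 kcal to stay positive.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    years = np.arange(cfg.year_start, cfg.year_end + 1)
    T = len(years)
    m = cfg.n_countries
    year_ref = float(years.mean())

    base_log_gdp = rng.normal(cfg.gdp_log_mean, cfg.gdp_log_sd, size=m)
    steps = cfg.gdp_drift + rng.normal(0.0, cfg.gdp_noise, size=(m, T))
    log_gdp = base_log_gdp[:, None] + np.cumsum(steps, axis=1) - steps[:, :1]
    gdp = np.exp(log_gdp)

    country_base = {
        j: rng.normal(cfg.supply_base[j], cfg.supply_country_sd[j], size=m) for j in range(3)
    }
    supplies = np.empty((3, m, T))
    for j in range(3):
        supplies[j] = (
            country_base[j][:, None]
            + cfg.supply_trend[j] * (years - cfg.year_start)[None, :]
            + cfg.supply_gdp_coupling[j] * (log_gdp - _G_REF)
            + rng.normal(0.0, cfg.supply_noise_sd[j], size=(m, T))
        )
    supplies = np.maximum(supplies, 30.0)

    truth = PanelTruth(
        amplitudes=cfg.surface_amplitudes,
        baseline_log_rate=cfg.baseline_log_rate,
        year_ref=year_ref,
    )
    u_country = rng.normal(0.0, cfg.country_sd, size=m)

    frames = []
    countries = np.array([f"C{i:03d}" for i in range(m)])
    yy = np.tile(years, m)
    cc = np.repeat(countries, T)
    P = supplies[0].ravel()
    C = supplies[1].ravel()
    F = supplies[2].ravel()
    G = gdp.ravel()
    lp = truth.linear_predictor(P, C, F, G, yy) + np.repeat(u_country, T)
    for stratum in cfg.strata:
        eps = rng.normal(0.0, cfg.noise_sd, size=m * T)
        rate = np.exp(lp + eps)
        frames.append(
            pd.DataFrame(
                {
                    "country": cc,
                    "year": yy,
                    "stratum": stratum,
                    "protein_kcal": P,
                    "carb_kcal": C,
                    "fat_kcal": F,
                    "gdp": G,
                    "rate": rate,
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    if cfg.dropout > 0:
        keep = rng.random(len(df)) >= cfg.dropout
        df = df[keep].reset_index(drop=True)
    return CountryPanel(df), truth


@dataclass(frozen=True)
class TregConfig:
    """Generator settings for the 10-diet feeding experiment.

    Defaults: the reference 10-diet isocaloric design, 8 animals per
    diet (the experimental N was 6-8), a linear (model-1) fat-dominant
    truth beta = (2, 4, 12) — so predicted responses range from ~4% on
    the high-protein diet to ~10% on the high-fat diet — and unit
    Gaussian noise.
    """

    design: DietDesign = field(default_factory=lambda: make_full_design(10, seed=0))
    n_per_diet: int = 8
    truth_model: str = "1"
    beta: tuple[float, ...] = (2.0, 4.0, 12.0)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_per_diet < 1:
            raise ValueError("n_per_diet must be >= 1")
        mid = str(self.truth_model)
        if mid not in MODEL_NPARAMS or mid == "null":
            raise ValueError(f"truth_model must be one of 1-4, got {self.truth_model!r}")
        object.__setattr__(self, "truth_model", mid)
        if len(self.beta) != MODEL_NPARAMS[mid]:
            raise ValueError(
                f"beta length {len(self.beta)} does not match model {mid} "
                f"({MODEL_NPARAMS[mid]} coefficients)"
            )
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")


def gen_treg_experiment(config: TregConfig) -> tuple[DietResponseTable, np.ndarray]:
    """Simulate per-animal responses from a known Scheffé truth.

    Each of the ``n_per_diet`` animals on each diet gets
    ``response = X(diet, truth_model) @ beta + N(0, noise_sd)``.
    Returns the table and the true coefficient vector.
    """
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    beta = np.asarray(cfg.beta, dtype=float)
    diets = [d for d in cfg.design for _ in range(cfg.n_per_diet)]
    X = build_design_matrix(diets, cfg.truth_model)
    y = X @ beta + rng.normal(0.0, cfg.noise_sd, size=len(diets))
    return DietResponseTable(diets=tuple(diets), responses=y), beta
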