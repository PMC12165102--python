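"""Isocaloric diet designs on the macronutrient simplex.

A diet is described by the fractions of its metabolizable energy coming
from protein (P), carbohydrate (C) and fat (F); the three fractions live
on the 2-simplex (they sum to one). An *isocaloric design* is a set of
such diets sharing a single energy density, so that animals on different
diets differ only in the macronutrient mixture, not in energy per gram.

The reference design used throughout the package is a 10-diet array
anchored at three "apex" diets — high-protein (HP, 60:20:20), high-
carbohydrate (HC, 5:75:20) and high-fat (HF, 5:20:75) — with the
remaining diets space-filling the window 5-60% protein, 20-75%
carbohydrate, 20-75% fat at a shared energy density of 14.5 MJ/kg.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "DietComposition",
    "DietDesign",
    "APEX_ENERGY_DENSITY",
    "DESIGN_BOUNDS",
    "make_apex_diets",
    "make_full_design",
    "classify_ketogenic",
]

#: Shared energy density of the reference isocaloric design, MJ per kg dry food.
APEX_ENERGY_DENSITY: float = 14.5

#: Macronutrient window of the reference design, as energy-fraction
#: (low, high) bounds for protein, carbohydrate and fat.
DESIGN_BOUNDS: dict[str, tuple[float, float]] = {
    "protein": (0.05, 0.60),
    "carb": (0.20, 0.75),
    "fat": (0.20, 0.75),
}

_CLOSURE_TOL = 1e-8


@dataclass(frozen=True)
class DietComposition:
    """One diet as macronutrient energy fractions plus energy density.

    Parameters
    ----------
    label
        Short identifier (e.g. ``"HF"``).
    protein_frac, carb_frac, fat_frac
        Fractions of metabolizable energy from each macronutrient;
        non-negative and summing to one within 1e-8.
    energy_density
        MJ per kg dry food; strictly positive.
    """

    label: str
    protein_frac: float
    carb_frac: float
    fat_frac: float
    energy_density: float = APEX_ENERGY_DENSITY

    def __post_init__(self) -> None:
        fracs = (self.protein_frac, self.carb_frac, self.fat_frac)
        if any(f < 0 for f in fracs):
            raise ValueError(f"diet {self.label!r}: negative energy fraction {fracs}")
        total = sum(fracs)
        if abs(total - 1.0) > _CLOSURE_TOL:
            raise ValueError(
                f"diet {self.label!r}: fractions sum to {total!r}, not 1 within {_CLOSURE_TOL}"
            )
        if not self.energy_density > 0:
            raise ValueError(f"diet {self.label!r}: energy_density must be > 0")

    @property
    def fractions(self) -> np.ndarray:
        """``array([protein, carb, fat])`` energy fractions."""
        return np.array([self.protein_frac, self.carb_frac, self.fat_frac])

    @classmethod
    def from_percent(
        cls,
        label: str,
        protein_pct: float,
        carb_pct: float,
        fat_pct: float,
        energy_density: float = APEX_ENERGY_DENSITY,
    ) -> "DietComposition":
        """Build from percentages (e.g. 5, 75, 20), normalizing to fractions."""
        return cls(label, protein_pct / 100.0, carb_pct / 100.0, fat_pct / 100.0, energy_density)


@dataclass(frozen=True)
class DietDesign:
    """An ordered collection of diets sharing one energy density."""

    diets: tuple[DietComposition, ...]
    shared_energy_density: float = APEX_ENERGY_DENSITY

    def __post_init__(self) -> None:
        object.__setattr__(self, "diets", tuple(self.diets))
        labels = [d.label for d in self.diets]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate diet labels in design: {labels}")
        for d in self.diets:
            if abs(d.energy_density - self.shared_energy_density) > 1e-12:
                raise ValueError(
                    f"diet {d.label!r} has energy density {d.energy_density}, design "
                    f"requires {self.shared_energy_density} (isocaloric)"
                )

    def __len__(self) -> int:
        return len(self.diets)

    def __iter__(self):
        return iter(self.diets)

    def __getitem__(self, key):
        if isinstance(key, str):
            for d in self.diets:
                if d.label == key:
                    return d
            raise KeyError(key)
        return self.diets[key]

    @property
    def composition_matrix(self) -> np.ndarray:
        """(n_diets, 3) array of [protein, carb, fat] fractions."""
        return np.array([d.fractions for d in self.diets])


def make_apex_diets() -> DietDesign:
    """The three apex diets plus the AIN-93G growth-control diet.

    HP = 60:20:20, HC = 5:75:20 and HF = 5:20:75 (P:C:F energy percent)
    sit at the corners of the sampled macronutrient window; AIN93G
    (20:64:16) is the standard rodent growth diet the array is based on.
    All share the 14.5 MJ/kg energy density.
    """
    diets = (
        DietComposition.from_percent("HP", 60, 20, 20),
        DietComposition.from_percent("HC", 5, 75, 20),
        DietComposition.from_percent("HF", 5, 20, 75),
        DietComposition.from_percent("AIN93G", 20, 64, 16),
    )
    return DietDesign(diets, APEX_ENERGY_DENSITY)


def _window_candidates(rng: np.random.Generator, n: int) -> np.ndarray:
    """Uniform draws from the simplex slice defined by DESIGN_BOUNDS."""
    (p_lo, p_hi) = DESIGN_BOUNDS["protein"]
    (c_lo, c_hi) = DESIGN_BOUNDS["carb"]
    (f_lo, f_hi) = DESIGN_BOUNDS["fat"]
    out = np.empty((n, 3))
    filled = 0
    while filled < n:
        p = rng.uniform(p_lo, p_hi, size=4 * n)
        c = rng.uniform(c_lo, c_hi, size=4 * n)
        f = 1.0 - p - c
        ok = (f >= f_lo) & (f <= f_hi)
        take = min(int(ok.sum()), n - filled)
        sel = np.flatnonzero(ok)[:take]
        out[filled : filled + take] = np.column_stack([p[sel], c[sel], f[sel]])
        filled += take
    return out


def make_full_design(n_diets: int = 10, seed: int = 0) -> DietDesign:
    """Apex diets plus deterministic space-filling interior compositions.

    The three apex diets (HP, HC, HF) are always included; the remaining
    ``n_diets - 3`` compositions are chosen by greedy maximin selection
    from a seeded uniform sample of the constrained simplex window
    (5-60% P, 20-75% C, 20-75% F), spreading them as far as possible
    from each other and from the apices. Deterministic given ``seed``.

    Parameters
    ----------
    n_diets
        Total number of diets, at least 4.
    seed
        Seed for the candidate sample; same seed, same design.
    """
    if n_diets < 4:
        raise ValueError(f"n_diets must be >= 4, got {n_diets}")
    apex = [d for d in make_apex_diets() if d.label != "AIN93G"]
    chosen = [d.fractions for d in apex]

    rng = np.random.default_rng(seed)
    candidates = _window_candidates(rng, 512)
    diets = list(apex)
    for i in range(n_diets - 3):
        dists = np.min(
            np.linalg.norm(candidates[:, None, :] - np.asarray(chosen)[None, :, :], axis=2),
            axis=1,
        )
        best = int(np.argmax(dists))  # maximin: farthest from every chosen diet
        p, c, f = candidates[best]
        f = 1.0 - p - c  # enforce exact closure
        diets.append(DietComposition(f"D{i + 4:02d}", p, c, f, APEX_ENERGY_DENSITY))
        chosen.append(candidates[best])
    return DietDesign(tuple(diets), APEX_ENERGY_DENSITY)


def classify_ketogenic(diet: DietComposition, threshold: float = 0.10) -> bool:
    """Whether a diet is ketogenic: carbohydrate strictly below ``threshold``.

    The conventional cut-off is 10% of energy from carbohydrate; the
    comparison is strict, so a diet at exactly the threshold (such as the
    HF diet at 20% carbohydrate, well above it) is not ketogenic.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    return diet.carb_frac < threshold


def rescale_energy(design: DietDesign, energy_density: float) -> DietDesign:
    """Same compositions at a different shared energy density."""
    diets = tuple(replace(d, energy_density=energy_density) for d in design)
    return DietDesign(diets, energy_density)
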