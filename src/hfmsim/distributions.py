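"""Synthetic forest age-class distributions.

A simulated forest is described only by how its area is spread over 24
five-year age classes (a 120-year rotation).  Distributions are generated
by drawing stand "ages" on the unit interval from a Beta distribution (or
a small mixture of Betas, needed for well-separated bimodal shapes),
binning them into the 24 classes, and scaling the bin shares to the total
forest area.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

N_CLASSES = 24
CLASS_WIDTH_YEARS = 5
DEFAULT_TOTAL_AREA_KM2 = 10_000.0

#: bin edges on [0, 1]; the last bin is closed at 1 (np.histogram convention)
_BIN_EDGES = np.linspace(0.0, 1.0, N_CLASSES + 1)


@dataclass(frozen=True)
class BetaComponent:
    """One Beta(alpha, beta) component of a (possibly single-component) mixture."""

    alpha: float
    beta: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if not (self.alpha > 0 and self.beta > 0):
            raise ValueError(
                f"Beta shape parameters must be positive, got ({self.alpha}, {self.beta})"
            )
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError(f"mixture weight must lie in [0, 1], got {self.weight}")


@dataclass(frozen=True)
class ShapeSpec:
    """Recipe for one descriptive age-structure shape.

    Parameters
    ----------
    name
        Shape label; the shipped catalog uses ``unif``, ``norm``, ``skwj``,
        ``revj``, ``bimod1`` and ``bimod2``.
    components
        Beta mixture components; weights must sum to 1.
    n_samples
        Number of stand ages drawn before binning.
    seed
        Seed of the generator used for the draws; identical seeds give
        bit-identical distributions.
    """

    name: str
    components: tuple[BetaComponent, ...]
    n_samples: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.components) == 0:
            raise ValueError("ShapeSpec needs at least one Beta component")
        total = sum(c.weight for c in self.components)
        if abs(total - 1.0) > 1e-12:
            raise ValueError(f"component weights must sum to 1, got {total}")
        if self.n_samples < 1:
            raise ValueError("n_samples must be at least 1")

    def with_seed(self, seed: int) -> "ShapeSpec":
        return dataclasses.replace(self, seed=int(seed))


@dataclass
class AgeClassDistribution:
    """Forest area (km²) per 24 five-year age classes.

    ``total_area`` is derived from the class areas, so area conservation
    holds by construction.
    """

    areas: np.ndarray
    label: str = ""
    nominal_year: int = 2000
    class_width: int = CLASS_WIDTH_YEARS

    def __post_init__(self) -> None:
        self.areas = np.asarray(self.areas, dtype=float)
        if self.areas.shape != (N_CLASSES,):
            raise ValueError(f"expected {N_CLASSES} age classes, got shape {self.areas.shape}")
        if np.any(self.areas < 0):
            raise ValueError("age-class areas must be non-negative")
        if not self.areas.sum() > 0:
            raise ValueError("total area must be positive")

    @property
    def total_area(self) -> float:
        return float(self.areas.sum())

    def replace(self, **kw) -> "AgeClassDistribution":
        return dataclasses.replace(self, **kw)

    def to_frame(self) -> pd.DataFrame:
        lower = np.arange(N_CLASSES) * self.class_width
        return pd.DataFrame(
            {
                "age_class": np.arange(1, N_CLASSES + 1),
                "age_lower_yr": lower,
                "age_upper_yr": lower + self.class_width,
                "area_km2": self.areas,
            }
        )

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, label: str = "", nominal_year: int = 2000):
        frame = frame.sort_values("age_class")
        return cls(frame["area_km2"].to_numpy(float), label=label, nominal_year=nominal_year)

    @classmethod
    def read_csv(cls, path, label: str = "", nominal_year: int = 2000):
        return cls.from_frame(pd.read_csv(path), label=label, nominal_year=nominal_year)

    @classmethod
    def uniform(cls, total_area: float = DEFAULT_TOTAL_AREA_KM2, label: str = "unif-exact"):
        """Exactly uniform distribution — the stationary state of the dynamics."""
        return cls(np.full(N_CLASSES, total_area / N_CLASSES), label=label)


def sample_age_distribution(
    spec: ShapeSpec, total_area: float = DEFAULT_TOTAL_AREA_KM2
) -> AgeClassDistribution:
    """Draw ``spec.n_samples`` ages from the Beta mixture and bin into 24 classes.

    The area of class *i* is the share of draws landing in bin *i* times
    ``total_area``, so the class areas always sum to ``total_area`` exactly
    (up to floating point).
    """
    if not total_area > 0:
        raise ValueError(f"total_area must be positive, got {total_area}")
    rng = np.random.default_rng(spec.seed)
    weights = np.array([c.weight for c in spec.components])
    which = rng.choice(len(spec.components), size=spec.n_samples, p=weights)
    values = np.empty(spec.n_samples)
    for k, comp in enumerate(spec.components):
        mask = which == k
        values[mask] = rng.beta(comp.alpha, comp.beta, mask.sum())
    counts, _ = np.histogram(values, bins=_BIN_EDGES)
    areas = counts / spec.n_samples * total_area
    return AgeClassDistribution(areas, label=spec.name)


def expected_class_shares(spec: ShapeSpec) -> np.ndarray:
    """Infinite-sample class shares: the mixture density integrated over each bin."""
    shares = np.zeros(N_CLASSES)
    for comp in spec.components:
        cdf = stats.beta(comp.alpha, comp.beta).cdf(_BIN_EDGES)
        shares += comp.weight * np.diff(cdf)
    return shares


def default_shape_catalog() -> tuple[ShapeSpec, ...]:
    """The six shipped descriptive shapes with fixed per-shape seeds.

    unif is flat; norm has an interior mode; skwj is a J-shape with mass in
    the old classes; revj is its reverse (young forest); bimod1/bimod2 are
    two-component mixtures with two well-separated peaks (a single Beta can
    only be bimodal with both modes at the boundary).
    """
    return (
        ShapeSpec("unif", (BetaComponent(1, 1),), seed=1),
        ShapeSpec("norm", (BetaComponent(6, 6),), seed=2),
        ShapeSpec("skwj", (BetaComponent(8, 1),), seed=3),
        ShapeSpec("revj", (BetaComponent(1, 5),), seed=4),
        ShapeSpec("bimod1", (BetaComponent(8, 2, 0.5), BetaComponent(2, 8, 0.5)), seed=5),
        ShapeSpec(
            "bimod2", (BetaComponent(10, 3, 0.35), BetaComponent(3, 10, 0.65)), seed=6
        ),
    )
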