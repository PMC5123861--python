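"""Lipid composition bookkeeping and the shared additive-noise model."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .constants import LIPIDS_PER_VESICLE, OUTER_LEAFLET_FRACTION

_FRACTION_TOL = 1e-9


@dataclass(frozen=True)
class LipidComposition:
    """Mole-fraction description of a vesicle preparation.

    Parameters
    ----------
    species : tuple of (str, float)
        Lipid names and their mole fractions; fractions must sum to 1.
    lipids_per_vesicle : int
        Phospholipid count per vesicle, used to convert bulk lipid
        concentration to vesicle (particle) concentration.
    accessible_fraction : float
        Fraction of total lipid exposed on the outer leaflet and hence
        available for protein binding. Defaults to 0.5 for a large
        unilamellar vesicle.
    """

    species: tuple[tuple[str, float], ...]
    lipids_per_vesicle: int = LIPIDS_PER_VESICLE
    accessible_fraction: float = OUTER_LEAFLET_FRACTION

    def __post_init__(self):
        fracs = [f for _, f in self.species]
        if any(f < 0 for f in fracs):
            raise ValueError("mole fractions must be non-negative")
        if abs(sum(fracs) - 1.0) > _FRACTION_TOL:
            raise ValueError(f"mole fractions must sum to 1, got {sum(fracs)!r}")
        if self.lipids_per_vesicle <= 0:
            raise ValueError("lipids_per_vesicle must be positive")
        if not 0.0 < self.accessible_fraction <= 1.0:
            raise ValueError("accessible_fraction must be in (0, 1]")
        # normalise to tuple-of-tuples so instances are hashable
        object.__setattr__(self, "species", tuple((str(n), float(f)) for n, f in self.species))

    def mole_fraction(self, name: str) -> float:
        for n, f in self.species:
            if n == name:
                return f
        return 0.0

    @classmethod
    def from_dict(cls, fractions: dict[str, float], **kwargs) -> "LipidComposition":
        return cls(species=tuple(fractions.items()), **kwargs)


#: Plain phosphatidylcholine background, the standard inert matrix lipid.
POPC = LipidComposition.from_dict({"PtdChol": 1.0})


@dataclass
class NoiseModel:
    """Additive Gaussian noise applied to a simulated observable.

    sigma is expressed in the units of the signal it perturbs (fluorescence
    counts, kJ, fraction bound, ppm, ...). Identical (sigma, seed) always
    reproduces the same noise stream.
    """

    sigma: float = 0.0
    seed: int = 0
    _rng: np.random.Generator = field(init=False, repr=False)

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        self._rng = np.random.default_rng(self.seed)

    def perturb(self, values: np.ndarray) -> np.ndarray:
        values = np.asarray(values, dtype=float)
        if self.sigma == 0.0:
            return values.copy()
        return values + self._rng.normal(0.0, self.sigma, size=values.shape)

    def reset(self) -> None:
        """Rewind the noise stream to its seeded start."""
        self._rng = np.random.default_rng(self.seed)
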