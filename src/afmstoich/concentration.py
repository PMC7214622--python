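"""Particle surface density to sample molarity.

Purified receptor is adsorbed onto mica from a known droplet volume; after
imaging, the number of particles of a species per scanned area — counted
inside an inclusive molecular-volume window around the species' peak —
extrapolates over the whole deposit and converts to solution molarity:

    M = density(1/um^2) * total_mica_area(um^2) * 1e6(ul/L)
        / (elution_volume(ul) * N_A)

with N_A Avogadro's number.  This assumes every particle in the droplet
adsorbed (100% efficiency): incomplete adsorption makes M an
underestimate of the true solution concentration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import AfmStoichError, ContractError

AVOGADRO = 6.02214076e23  # particles per mole
MICROLITRE_PER_LITRE = 1e6


@dataclass(frozen=True)
class CountingWindow:
    """Inclusive molecular-volume window [lo, hi] (nm^3) around a species
    peak, used to count particles of that species."""

    lo: float
    hi: float
    species: str = ""

    def __post_init__(self):
        if not (0 < self.lo < self.hi):
            raise ContractError(
                f"window must satisfy 0 < lo < hi, got [{self.lo}, {self.hi}]"
            )

    def contains(self, volumes) -> np.ndarray:
        v = np.asarray(volumes, dtype=float)
        return (v >= self.lo) & (v <= self.hi)


@dataclass(frozen=True)
class ConcentrationEstimate:
    """Molarity derived from a particle surface density."""

    density_per_um2: float
    total_mica_area_um2: float
    elution_volume_ul: float
    molarity_M: float
    n_particles: int = 0
    scanned_area_um2: float = 0.0

    @property
    def molarity_pM(self) -> float:
        return self.molarity_M * 1e12

    def to_dict(self) -> dict:
        return {
            "density_per_um2": self.density_per_um2,
            "total_mica_area_um2": self.total_mica_area_um2,
            "elution_volume_ul": self.elution_volume_ul,
            "scanned_area_um2": self.scanned_area_um2,
            "n_particles": self.n_particles,
            "molarity_M": self.molarity_M,
            "molarity_pM": self.molarity_pM,
        }


def count_density(volumes, window: CountingWindow, scanned_area: float) -> float:
    """Particles per um^2 with volume inside the window.

    ``scanned_area`` is the total imaged area in um^2 (e.g. 50 scans of
    4 um^2 each -> 200 um^2).
    """
    if not scanned_area > 0:
        raise ContractError("scanned_area must be positive")
    v = np.asarray(volumes, dtype=float)
    if v.size == 0:
        return 0.0
    return float(window.contains(v).sum()) / scanned_area


def estimate_molarity(
    density: float, total_mica_area: float, elution_volume: float
) -> float:
    """Molarity (mol/L) from surface density (1/um^2).

    ``total_mica_area`` is the full area wetted by the deposit (um^2);
    ``elution_volume`` the adsorbed droplet volume (ul).
    """
    if not (total_mica_area > 0 and elution_volume > 0):
        raise ContractError("mica area and elution volume must be positive")
    if density < 0:
        raise ContractError("density must be >= 0")
    return density * total_mica_area * MICROLITRE_PER_LITRE / (
        elution_volume * AVOGADRO
    )


def density_from_molarity(
    molarity: float, total_mica_area: float, elution_volume: float
) -> float:
    """Algebraic inverse of :func:`estimate_molarity` (1/um^2)."""
    if not (total_mica_area > 0 and elution_volume > 0):
        raise ContractError("mica area and elution volume must be positive")
    return molarity * elution_volume * AVOGADRO / (
        total_mica_area * MICROLITRE_PER_LITRE
    )


def estimate_concentration(
    volumes,
    window: CountingWindow,
    scanned_area: float,
    total_mica_area: float,
    elution_volume: float,
) -> ConcentrationEstimate:
    """Count particles in the window and convert to molarity in one step."""
    density = count_density(volumes, window, scanned_area)
    v = np.asarray(volumes, dtype=float)
    n_in = int(window.contains(v).sum()) if v.size else 0
    return ConcentrationEstimate(
        density_per_um2=density,
        total_mica_area_um2=total_mica_area,
        elution_volume_ul=elution_volume,
        molarity_M=estimate_molarity(density, total_mica_area, elution_volume),
        n_particles=n_in,
        scanned_area_um2=scanned_area,
    )


def aggregate_series(values) -> tuple[float, float]:
    """Mean and standard error over replicate estimates.

    Replicates are independent purification/imaging series; SE is
    SD/sqrt(n) with the sample (ddof=1) SD.  Requires n >= 2.
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 2:
        raise AfmStoichError(
            f"aggregation needs at least 2 replicates, got {v.size}"
        )
    return float(v.mean()), float(v.std(ddof=1) / math.sqrt(v.size))
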