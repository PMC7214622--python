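"""Subunit-composition inference from fitted volume peaks.

AFM molecular volumes are, to first order, additive: a complex of m copies
of receptor A and n copies of receptor B has volume m*V_A + n*V_B.  Given
a fitted peak (mean ± uncertainty) and reference volumes for the candidate
components — e.g. 417 nm^3 for the trimeric P2X4 receptor and 757 nm^3 for
the pentameric 5-HT3A receptor — every composition up to a maximum count
is enumerated and ranked by how many combined-uncertainty units separate
its predicted volume from the peak.  A peak at ~1100 nm^3 against those
references lands on (1, 1): a 1:1 receptor complex.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from .errors import ContractError


@dataclass(frozen=True)
class ReferenceComponent:
    """A candidate building block: name, AFM volume and its uncertainty (nm^3)."""

    name: str
    volume: float
    volume_uncertainty: float = 0.0

    def __post_init__(self):
        if not self.volume > 0:
            raise ContractError(f"reference volume must be > 0, got {self.volume}")
        if self.volume_uncertainty < 0:
            raise ContractError("reference volume_uncertainty must be >= 0")


@dataclass(frozen=True)
class StoichiometryAssignment:
    """One candidate composition with its volume residual against the peak."""

    counts: tuple[int, ...]  # copies per reference component
    predicted_volume: float  # nm^3
    residual: float  # |peak - predicted|, nm^3
    z: float  # residual in combined-uncertainty units
    accepted: bool

    def label(self, refs: tuple[ReferenceComponent, ...]) -> str:
        return " + ".join(
            f"{c}x{r.name}" for c, r in zip(self.counts, refs) if c
        )

    def to_dict(self) -> dict:
        return {
            "counts": list(self.counts),
            "predicted_volume_nm3": self.predicted_volume,
            "residual_nm3": self.residual,
            "z": self.z,
            "accepted": self.accepted,
        }


def predict_complex_volume(
    counts: tuple[int, ...], refs: tuple[ReferenceComponent, ...]
) -> float:
    """Additive volume of a composition: sum of count_i * volume_i."""
    counts = tuple(int(c) for c in counts)
    if len(counts) != len(refs):
        raise ContractError(
            f"{len(counts)} counts given for {len(refs)} reference components"
        )
    if any(c < 0 for c in counts):
        raise ContractError("counts must be non-negative")
    if not any(counts):
        raise ContractError("at least one count must be positive")
    return float(sum(c * r.volume for c, r in zip(counts, refs)))


def assign_stoichiometry(
    peak_mean: float,
    peak_uncertainty: float,
    refs: tuple[ReferenceComponent, ...] | list[ReferenceComponent],
    max_counts: int = 3,
    tolerance_z: float = 3.0,
    packing_loss: float = 0.0,
) -> list[StoichiometryAssignment]:
    """Rank every composition up to ``max_counts`` copies per component.

    For each candidate, ``residual = |peak_mean - predicted|`` with
    ``predicted = (1 - packing_loss) * sum_i count_i * V_i`` (packing_loss
    accommodates the tendency of measured complex volumes to undershoot
    strict additivity; default 0), and

        z = residual / sqrt(peak_unc^2 + sum_i count_i^2 * ref_unc_i^2)

    A candidate is ``accepted`` iff ``z <= tolerance_z``.  The list is
    sorted by ascending z; ties go to the fewest total subunits
    (parsimony).  A zero combined uncertainty with zero residual gives
    z = 0; with nonzero residual, z = inf (never accepted unless exact).
    """
    refs = tuple(refs)
    if not refs:
        raise ContractError("at least one reference component is required")
    if max_counts < 1:
        raise ContractError("max_counts must be >= 1")
    if peak_uncertainty < 0:
        raise ContractError("peak uncertainty must be >= 0")
    if not 0.0 <= packing_loss < 1.0:
        raise ContractError("packing_loss must lie in [0, 1)")

    assignments = []
    for counts in itertools.product(range(max_counts + 1), repeat=len(refs)):
        if not any(counts):
            continue
        predicted = (1.0 - packing_loss) * predict_complex_volume(counts, refs)
        residual = abs(peak_mean - predicted)
        combined = math.sqrt(
            peak_uncertainty**2
            + sum(c * c * r.volume_uncertainty**2 for c, r in zip(counts, refs))
        )
        if combined > 0:
            z = residual / combined
        else:
            z = 0.0 if residual == 0.0 else math.inf
        assignments.append(
            StoichiometryAssignment(
                counts=counts,
                predicted_volume=predicted,
                residual=residual,
                z=z,
                accepted=z <= tolerance_z,
            )
        )
    assignments.sort(key=lambda a: (a.z, a.residual, sum(a.counts), a.counts))
    return assignments
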