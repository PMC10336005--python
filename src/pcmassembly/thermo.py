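"""Square-lattice mass-action model of heterotetramer self-association.

The Cep63•Cep152 heterotetramer is treated as a square building block whose
four faces each contribute a contact free energy ``epsilon`` (in units of
kBT) when bound to a neighbour.  Two dissociation constants parameterize the
model:

* ``k8``  — octamer ⇌ 2 tetramers, ``k8 = c4²/c8 = c0·exp(ε)``   (M)
* ``k16`` — hexadecamer ⇌ 4 tetramers, ``k16 = c4⁴/c16 = c0³·exp(4ε)`` (M³)

where ``c0`` is a reference concentration fixing units.  From the two
measured constants the pair ``(ε, c0)`` follows in closed form, and with it
the concentration of any intermediate assembly, the saturation concentration
for macroscopic lattice growth, and the classical-nucleation free-energy
profile ``G(L)`` of square L×L assemblies.

All concentrations are molar internally; energies are in kBT units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import bisect

__all__ = [
    "DissociationConstants",
    "InteractionParams",
    "SpeciesState",
    "FreeEnergyProfile",
    "NucleationResult",
    "derive_interaction_params",
    "dissociation_constants",
    "species_distribution",
    "predict_dodecamer",
    "saturation_concentration",
    "stepwise_octamer_kd",
    "free_energy_profile",
    "critical_nucleus",
]


@dataclass(frozen=True)
class DissociationConstants:
    """Measured dissociation constants of the two anchoring equilibria.

    Parameters
    ----------
    k8 : float
        Octamer dissociation constant ``c4²/c8`` in M.
    k16 : float
        Hexadecamer dissociation constant ``c4⁴/c16`` in M³.
    """

    k8: float
    k16: float

    def __post_init__(self) -> None:
        if not (self.k8 > 0 and math.isfinite(self.k8)):
            raise ValueError(f"k8 must be positive and finite, got {self.k8}")
        if not (self.k16 > 0 and math.isfinite(self.k16)):
            raise ValueError(f"k16 must be positive and finite, got {self.k16}")


@dataclass(frozen=True)
class InteractionParams:
    """Lattice-model parameters: contact energy and reference concentration.

    ``epsilon`` is the free energy of one tetramer–tetramer contact in kBT
    units (negative = attractive); ``c0`` is the reference concentration (M).
    """

    epsilon: float
    c0: float

    def __post_init__(self) -> None:
        if not (self.c0 > 0 and math.isfinite(self.c0)):
            raise ValueError(f"c0 must be positive and finite, got {self.c0}")
        if not math.isfinite(self.epsilon):
            raise ValueError("epsilon must be finite")


@dataclass(frozen=True)
class SpeciesState:
    """Equilibrium species concentrations at one total loading.

    ``total`` and all species concentrations are molar, with the total
    expressed in tetramer units (``c4 + 2 c8 + 4 c16 = total``).
    """

    total: float
    c4: float
    c8: float
    c16: float

    @property
    def mass_fractions(self) -> tuple[float, float, float]:
        """Mass fractions (tetramer units) of tetramer, octamer, hexadecamer."""
        if self.total == 0.0:
            return (1.0, 0.0, 0.0)
        return (
            self.c4 / self.total,
            2.0 * self.c8 / self.total,
            4.0 * self.c16 / self.total,
        )


@dataclass(frozen=True)
class FreeEnergyProfile:
    """Free energy G(L) (kBT) of square L×L assemblies at fixed c4."""

    L: np.ndarray
    G: np.ndarray

    def __post_init__(self) -> None:
        if len(self.L) != len(self.G):
            raise ValueError("L and G must have equal length")


@dataclass(frozen=True)
class NucleationResult:
    """Critical nucleus size and barrier; flagged when not supersaturated."""

    L_star: int | None
    barrier: float | None
    supersaturated: bool
    profile: FreeEnergyProfile | None = field(default=None, repr=False)


def derive_interaction_params(k: DissociationConstants) -> InteractionParams:
    """Solve ``k8 = c0·e^ε`` and ``k16 = c0³·e^{4ε}`` for ``(ε, c0)``.

    The log-linear 2×2 system has the unique closed-form solution
    ``c0 = k8⁴/k16`` and ``ε = ln(k8/c0)``.
    """
    c0 = k.k8**4 / k.k16
    epsilon = math.log(k.k8 / c0)
    return InteractionParams(epsilon=epsilon, c0=c0)


def dissociation_constants(p: InteractionParams) -> DissociationConstants:
    """Inverse of :func:`derive_interaction_params` (round-trip identity)."""
    return DissociationConstants(
        k8=p.c0 * math.exp(p.epsilon),
        k16=p.c0**3 * math.exp(4.0 * p.epsilon),
    )


def species_distribution(total: float, k: DissociationConstants) -> SpeciesState:
    """Solve the tetramer–octamer–hexadecamer equilibrium at a total loading.

    Conservation in tetramer units reads

        c4 + 2·c4²/k8 + 4·c4⁴/k16 = total

    which is strictly increasing in ``c4``, so bisection on [0, total] is
    guaranteed to converge.  ``total`` is molar in tetramer units.
    """
    if total < 0:
        raise ValueError(f"total must be non-negative, got {total}")
    if total == 0.0:
        return SpeciesState(total=0.0, c4=0.0, c8=0.0, c16=0.0)

    def conservation(c4: float) -> float:
        return c4 + 2.0 * c4**2 / k.k8 + 4.0 * c4**4 / k.k16 - total

    c4 = bisect(conservation, 0.0, total, rtol=8.9e-16, xtol=1e-300)
    return SpeciesState(total=total, c4=c4, c8=c4**2 / k.k8, c16=c4**4 / k.k16)


def predict_dodecamer(c4: float, k: DissociationConstants) -> float:
    """Dodecamer concentration from free tetramer: ``c12 = c4³/k8²``.

    A linear trimer of tetramers carries two contacts, so
    ``c4³/c12 = c0²·e^{2ε} = k8²``.
    """
    if c4 < 0:
        raise ValueError("c4 must be non-negative")
    return c4**3 / k.k8**2


def saturation_concentration(p: InteractionParams) -> float:
    """Tetramer concentration in equilibrium with the macroscopic lattice.

    Balancing the dilute chemical potential ``ln(c4/c0)`` against the bulk
    value ``2ε`` (each added tetramer contributes two contacts) gives
    ``c_sat = c0·e^{2ε}``, algebraically equal to ``k16/k8²``.
    """
    return p.c0 * math.exp(2.0 * p.epsilon)


def stepwise_octamer_kd(k: DissociationConstants) -> float:
    """Stepwise octamer–octamer dissociation constant ``c8²/c16 = k16/k8²``."""
    return k.k16 / k.k8**2


def free_energy_profile(
    p: InteractionParams, c4: float, L_max: int
) -> FreeEnergyProfile:
    """Evaluate ``G(L) = 2L(L−1)ε − L²·ln(c4/c0)`` for integer L = 1..L_max.

    The first term counts the attractive contacts of a square L×L assembly,
    the second the translational-entropy cost of gathering L² tetramers from
    a solution at free-tetramer concentration ``c4``.
    """
    if c4 <= 0:
        raise ValueError("c4 must be positive (log undefined otherwise)")
    if L_max < 1:
        raise ValueError("L_max must be >= 1")
    L = np.arange(1, L_max + 1)
    G = 2.0 * L * (L - 1) * p.epsilon - L**2 * math.log(c4 / p.c0)
    return FreeEnergyProfile(L=L, G=G)


def critical_nucleus(
    p: InteractionParams, c4: float, L_max: int = 50
) -> NucleationResult:
    """Locate the nucleation barrier: ``L* = argmax G(L)``, barrier ``G(L*)``.

    Only meaningful in the supersaturated window ``c_sat < c4``; below
    saturation G grows without bound and no finite barrier exists, so a
    flagged no-barrier result is returned instead of raising.
    """
    profile = free_energy_profile(p, c4, L_max)
    if c4 <= saturation_concentration(p):
        return NucleationResult(
            L_star=None, barrier=None, supersaturated=False, profile=profile
        )
    i = int(np.argmax(profile.G))
    return NucleationResult(
        L_star=int(profile.L[i]),
        barrier=float(profile.G[i]),
        supersaturated=True,
        profile=profile,
    )
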