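"""Single-patch age-structured demography.

A patch population with ``m`` age classes is projected one year forward by a
Leslie matrix: the first row holds per-class fertilities ``f_k`` (discounted
by the self-recruitment fraction ``sigma``, since only that share of juveniles
returns to the natal patch) and the first subdiagonal holds the survival
probabilities ``p_k`` of ageing from class ``k-1`` to ``k``.

The reproductive number ``R = sum_k f_k * l_k`` (with survivorship
``l_1 = 1``, ``l_k = p_2 * ... * p_k``) is the mean lifetime juvenile
production of one recruit.  A patch in isolation grows iff ``sigma * R > 1``
("source"); otherwise it is a "sink".  Juvenile-to-recruit survival is
absorbed into ``sigma`` — only the fertility row is discounted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidDemographyError

__all__ = [
    "PatchDemography",
    "LeslieMatrices",
    "build_matrices",
    "reproductive_number",
    "single_patch_persistence",
]


@dataclass(frozen=True)
class PatchDemography:
    """Survival/fertility/retention parameters of one patch.

    Parameters
    ----------
    m : int
        Number of age classes, ``>= 1``.
    survival : sequence of float
        ``p_k`` for ``k = 2..m`` (length ``m - 1``), each in ``[0, 1]``:
        probability that an individual of age ``k-1`` survives to age ``k``.
    fertility : sequence of float
        ``f_k`` for ``k = 1..m`` (length ``m``), each ``>= 0``: mean juveniles
        produced per age-``k`` individual per year.
    sigma : float
        Self-recruitment fraction in ``[0, 1]``.
    """

    m: int
    survival: tuple[float, ...]
    fertility: tuple[float, ...]
    sigma: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "survival", tuple(float(p) for p in self.survival))
        object.__setattr__(self, "fertility", tuple(float(f) for f in self.fertility))
        object.__setattr__(self, "sigma", float(self.sigma))
        if self.m < 1:
            raise InvalidDemographyError(f"m must be >= 1, got {self.m}")
        if len(self.survival) != self.m - 1:
            raise InvalidDemographyError(
                f"survival must have length m-1={self.m - 1}, got {len(self.survival)}"
            )
        if len(self.fertility) != self.m:
            raise InvalidDemographyError(
                f"fertility must have length m={self.m}, got {len(self.fertility)}"
            )
        if any(not 0.0 <= p <= 1.0 for p in self.survival):
            raise InvalidDemographyError("survival probabilities must lie in [0, 1]")
        if any(f < 0.0 for f in self.fertility):
            raise InvalidDemographyError("fertilities must be nonnegative")
        if not 0.0 <= self.sigma <= 1.0:
            raise InvalidDemographyError("sigma must lie in [0, 1]")

    @classmethod
    def from_dict(cls, d: dict) -> "PatchDemography":
        """Build from a JSON-style record with keys m/survival/fertility/sigma."""
        try:
            return cls(
                m=int(d["m"]),
                survival=tuple(d.get("survival", ())),
                fertility=tuple(d["fertility"]),
                sigma=float(d["sigma"]),
            )
        except KeyError as exc:  # pragma: no cover - message plumbing
            raise InvalidDemographyError(f"missing demography key: {exc}") from exc

    def to_dict(self) -> dict:
        return {
            "m": self.m,
            "survival": list(self.survival),
            "fertility": list(self.fertility),
            "sigma": self.sigma,
        }


@dataclass(frozen=True)
class LeslieMatrices:
    """Survival matrix ``S`` (subdiagonal) and fertility matrix ``F`` (first row).

    ``S + sigma * F`` is the single-patch projection matrix.
    """

    S: np.ndarray = field(repr=False)
    F: np.ndarray = field(repr=False)
    sigma: float = 0.0

    @property
    def projection(self) -> np.ndarray:
        """The single-patch Leslie projection matrix ``S + sigma F``."""
        return self.S + self.sigma * self.F


def build_matrices(demog: PatchDemography) -> LeslieMatrices:
    """Assemble the survival and fertility matrices of one patch.

    ``S`` carries ``p_k`` on the first subdiagonal, ``F`` carries ``f_k`` in
    the first row; ``S + sigma F`` reproduces the update
    ``n_1(t+1) = sigma * sum_k f_k n_k(t)``, ``n_k(t+1) = p_k n_{k-1}(t)``.
    """
    m = demog.m
    S = np.zeros((m, m))
    if m > 1:
        S[np.arange(1, m), np.arange(0, m - 1)] = demog.survival
    F = np.zeros((m, m))
    F[0, :] = demog.fertility
    return LeslieMatrices(S=S, F=F, sigma=demog.sigma)


def survivorship(demog: PatchDemography) -> np.ndarray:
    """Survivorship ``l_k``: probability of reaching age class ``k``.

    ``l_1 = 1`` and ``l_k = prod_{j=2..k} p_j``.
    """
    return np.concatenate(([1.0], np.cumprod(demog.survival)))


def reproductive_number(demog: PatchDemography) -> float:
    """Mean lifetime juvenile production ``R = sum_k f_k l_k`` of one recruit."""
    return float(np.dot(demog.fertility, survivorship(demog)))


def single_patch_persistence(demog: PatchDemography) -> tuple[float, str]:
    """Classify an isolated patch as source or sink.

    Returns ``(chi_single, label)`` with ``chi_single = sigma * R``; the label
    is ``"source"`` iff ``chi_single > 1`` strictly, else ``"sink"``.  The sign
    of ``chi_single - 1`` matches the sign of the dominant eigenvalue of
    ``S + sigma F`` minus one.
    """
    chi = demog.sigma * reproductive_number(demog)
    return chi, ("source" if chi > 1.0 else "sink")
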