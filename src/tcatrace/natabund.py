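"""Natural-isotope-abundance correction of mass isotopologue distributions.

GC-MS fragments are measured after derivatization (TBDMS adds C, H and Si
atoms), so the observed m+0..m+C envelope convolves the tracer-derived MID
with the natural isotope pattern of every atom in the fragment — including
the residual 1.07% 13C of backbone carbons that happen to be unlabelled.
This module builds the lower-triangular correction matrix for a fragment
formula, forward-convolves true MIDs into "measured" ones (the test
oracle's direction), and inverts measured MIDs by nonnegative least
squares (plain inversion can return negative fractions on noisy data).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import nnls

from .tca import MID

__all__ = [
    "ElementalFormula",
    "IsotopeTable",
    "DEFAULT_ISOTOPES",
    "abundance_vector",
    "correction_matrix",
    "convolve",
    "correct",
]

log = logging.getLogger(__name__)

# IUPAC 2021 representative isotope-abundance values, indexed by mass shift
# relative to the lightest isotope.
DEFAULT_ISOTOPES: Mapping[str, tuple[float, ...]] = {
    "C": (0.9893, 0.0107),
    "H": (0.999885, 0.000115),
    "N": (0.99636, 0.00364),
    "O": (0.99757, 0.00038, 0.00205),
    "Si": (0.92223, 0.04685, 0.03092),
    "S": (0.9499, 0.0075, 0.0425, 0.0, 0.0001),
}


@dataclass(frozen=True)
class IsotopeTable:
    """Per-element mass-shift probability vectors."""

    abundances: Mapping[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_ISOTOPES)
    )

    def __post_init__(self) -> None:
        for el, vec in self.abundances.items():
            a = np.asarray(vec, dtype=float)
            if np.any(a < 0) or abs(a.sum() - 1.0) > 1e-6:
                raise ValueError(f"isotope vector for {el} is not a probability vector")

    def vector(self, element: str) -> np.ndarray:
        try:
            return np.asarray(self.abundances[element], dtype=float)
        except KeyError:
            raise KeyError(f"unknown element {element!r} in formula") from None


@dataclass(frozen=True)
class ElementalFormula:
    """Atoms of a measured fragment, split into tracer-capable backbone
    carbons and everything else (backbone-adjacent + derivatization atoms).

    ``backbone_carbons`` must equal MID length − 1; ``other`` counts the
    non-tracer atoms, e.g. ``{"C": 9, "H": 27, "O": 4, "Si": 2}`` for the
    TBDMS adducts of a small acid fragment.
    """

    backbone_carbons: int
    other: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.backbone_carbons < 0:
            raise ValueError("backbone_carbons must be >= 0")
        for el, n in self.other.items():
            if n < 0:
                raise ValueError(f"negative atom count for {el}")


def abundance_vector(
    formula: ElementalFormula, isotopes: IsotopeTable | None = None
) -> np.ndarray:
    """Mass-shift distribution of all non-tracer atoms of a fragment.

    Convolution of one isotope vector per atom; an empty formula gives the
    identity distribution ``(1.0,)``.
    """
    isotopes = isotopes or IsotopeTable()
    out = np.array([1.0])
    for element, count in formula.other.items():
        vec = isotopes.vector(element)
        for _ in range(count):
            out = np.convolve(out, vec)
    return out


def correction_matrix(
    formula: ElementalFormula, isotopes: IsotopeTable | None = None
) -> np.ndarray:
    """Lower-triangular (C+1)x(C+1) matrix K with measured = K @ true.

    Column j is the measured envelope of a pure m+j species: the non-tracer
    atom pattern convolved with the binomial natural-13C pattern of the
    C−j backbone carbons that are not tracer-labelled, shifted by j and
    truncated to the m+0..m+C window.
    """
    isotopes = isotopes or IsotopeTable()
    n = formula.backbone_carbons
    base = abundance_vector(formula, isotopes)
    c13 = isotopes.vector("C")
    if len(c13) != 2:
        raise ValueError("carbon isotope vector must have exactly two entries")
    K = np.zeros((n + 1, n + 1))
    for j in range(n + 1):
        kernel = base.copy()
        residual = np.array([c13[0], c13[1]])
        for _ in range(n - j):
            kernel = np.convolve(kernel, residual)
        for shift, p in enumerate(kernel):
            k = j + shift
            if k <= n:
                K[k, j] = p
    if np.any(np.diag(K) <= 0):
        raise ValueError(f"singular correction matrix for formula {formula}")
    return K


def convolve(
    mid: MID, formula: ElementalFormula, isotopes: IsotopeTable | None = None
) -> MID:
    """Forward model: the MID an instrument would report for a true MID.

    Truncated to the m+0..m+C window and renormalized; the renormalization
    mass loss (envelope mass falling above m+C) is logged.
    """
    if formula.backbone_carbons != mid.n_carbons:
        raise ValueError(
            f"{mid.metabolite}: formula has {formula.backbone_carbons} backbone "
            f"carbons but MID implies {mid.n_carbons}"
        )
    K = correction_matrix(formula, isotopes)
    measured = K @ mid.fractions
    lost = 1.0 - measured.sum()
    if lost > 1e-12:
        log.debug("%s: %.3g envelope mass above m+%d window", mid.metabolite, lost, mid.n_carbons)
    return MID(mid.metabolite, measured / measured.sum())


def correct(
    measured: MID, formula: ElementalFormula, isotopes: IsotopeTable | None = None
) -> MID:
    """Invert the forward model: recover the tracer-only MID.

    Solves ``K x ~= measured`` by nonnegative least squares, then clamps
    round-off negatives and renormalizes.  Round-trip property:
    ``correct(convolve(x)) == x`` to high precision.
    """
    if formula.backbone_carbons != measured.n_carbons:
        raise ValueError(
            f"{measured.metabolite}: formula/measured MID carbon mismatch"
        )
    K = correction_matrix(formula, isotopes)
    cond = np.linalg.cond(K)
    if not np.isfinite(cond) or cond > 1e12:
        raise ValueError(
            f"ill-conditioned correction matrix (cond={cond:.3g}) for formula {formula}"
        )
    x, _ = nnls(K, measured.fractions)
    clamped = int(np.sum(x < 0))
    if clamped:
        log.info("%s: clamped %d negative fractions", measured.metabolite, clamped)
    x = np.clip(x, 0.0, None)
    total = x.sum()
    if total <= 0:
        raise ValueError(f"{measured.metabolite}: correction produced an empty MID")
    return MID(measured.metabolite, x / total)
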