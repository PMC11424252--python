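"""Labelling statistics computed from corrected MIDs and positional data.

All ratio-type metrics use missing-value semantics (``math.nan`` plus a
reason code) rather than exceptions, so cohort tables stay rectangular
when a denominator is absent or zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping

from .tca import MID, PositionalState

__all__ = [
    "FragmentRecord",
    "RespirationRecord",
    "MetricValue",
    "TISSUE_CLASSES",
    "total_labelling",
    "ratio_metric",
    "normalize_to_plasma",
    "glu45_fraction",
    "respiratory_control_ratio",
]

log = logging.getLogger(__name__)

RATIO_TOL = 1e-12

TISSUE_CLASSES = (
    "adjacent_kidney",
    "ccRCC",
    "papillary",
    "chromophobe",
    "oncocytoma",
    "FH_deficient",
)


def _valid_tissue(tissue: str) -> bool:
    return tissue in TISSUE_CLASSES or tissue.startswith("metastasis:")


@dataclass
class MetricValue:
    """A metric result: ``value`` is nan when undefined, with a reason."""

    value: float
    reason: str | None = None

    def __float__(self) -> float:
        return self.value

    @property
    def missing(self) -> bool:
        return math.isnan(self.value)


def _missing(reason: str) -> MetricValue:
    log.debug("metric missing: %s", reason)
    return MetricValue(math.nan, reason)


@dataclass
class FragmentRecord:
    """One tissue fragment's measurements from one patient."""

    patient: str
    tissue: str
    fragment: str
    mids: Mapping[str, MID]
    plasma_mids: Mapping[str, MID] = field(default_factory=dict)
    glutamate_state: PositionalState | None = None

    def __post_init__(self) -> None:
        if not _valid_tissue(self.tissue):
            raise ValueError(
                f"unknown tissue class {self.tissue!r}; expected one of "
                f"{TISSUE_CLASSES} or 'metastasis:<site>'"
            )
        self.mids = {k.lower(): v for k, v in self.mids.items()}
        self.plasma_mids = {k.lower(): v for k, v in self.plasma_mids.items()}


@dataclass
class RespirationRecord:
    """State III / state IV oxygen consumption of one mitochondrial prep."""

    state_iii: float
    state_iv: float
    substrate: str = "CI pyr/mal"

    def __post_init__(self) -> None:
        if self.state_iii <= 0 or self.state_iv <= 0:
            raise ValueError("OCR values must be positive")


def total_labelling(mid: MID) -> float:
    """Total isotopologue labelling, 1 − m+0: all routes of label entry."""
    return 1.0 - mid[0]


def ratio_metric(
    numerator: tuple[str, int],
    denominator: tuple[str, int],
    record: FragmentRecord,
) -> MetricValue:
    """Ratio of two isotopologue fractions, e.g. citrate m+2 / pyruvate m+3.

    Addressing is by (metabolite name, mass shift); names are matched
    case-insensitively.  A denominator at or below tolerance yields a
    missing value with a reason, not zero and not an exception.
    """
    num_met, num_k = numerator
    den_met, den_k = denominator
    try:
        num_mid = record.mids[num_met.lower()]
        den_mid = record.mids[den_met.lower()]
    except KeyError as exc:
        return _missing(f"metabolite {exc.args[0]!r} absent from fragment {record.fragment}")
    for mid, k, name in ((num_mid, num_k, num_met), (den_mid, den_k, den_met)):
        if not 0 <= k <= mid.n_carbons:
            return _missing(f"{name} has no m+{k} isotopologue")
    den = den_mid[den_k]
    if den <= RATIO_TOL:
        return _missing(f"{den_met} m+{den_k} is zero in fragment {record.fragment}")
    return MetricValue(num_mid[num_k] / den)


def normalize_to_plasma(
    tissue_total_labelling: float,
    plasma_mid: MID,
    isotopologue: int,
) -> MetricValue:
    """Tissue total labelling divided by a plasma enrichment (e.g. glucose m+6)."""
    if not 0 <= isotopologue <= plasma_mid.n_carbons:
        return _missing(f"plasma {plasma_mid.metabolite} has no m+{isotopologue}")
    plasma = plasma_mid[isotopologue]
    if plasma <= RATIO_TOL:
        return _missing(f"plasma {plasma_mid.metabolite} m+{isotopologue} is zero")
    return MetricValue(tissue_total_labelling / plasma)


def glu45_fraction(state: PositionalState) -> MetricValue:
    """[4,5-13C]glutamate as a fraction of total glutamate labelling.

    P(pattern == {4,5}) / (1 − P(unlabelled)); the denominator choice
    coincides with the sum over labelled positional species since the
    positional distribution is exhaustive.  Undefined for a fully
    unlabelled pool.
    """
    if state.pool.n_carbons != 5:
        raise ValueError("glu45_fraction expects a 5-carbon glutamate state")
    labelled = 1.0 - float(state.probs[0])
    if labelled <= RATIO_TOL:
        return _missing("glutamate pool fully unlabelled")
    return MetricValue(state.prob_pattern((4, 5)) / labelled)


def respiratory_control_ratio(rec: RespirationRecord) -> float:
    """RCR = state III (ADP-stimulated) / state IV (ADP-unstimulated) OCR."""
    return rec.state_iii / rec.state_iv
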