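"""Discrete-turn positional isotopomer simulator for the TCA cycle.

The simulator propagates exact distributions over the 2**C binary
carbon-labelling patterns of each metabolite pool ("positional states")
through the atom mappings of the TCA cycle, one cycle turn at a time.
Three clinically used tracers are supported:

* ``glucose_U13C``   — uniformly labelled glucose; enters as pyruvate m+3,
  oxidised to acetyl-CoA by PDH and/or carboxylated to OAA by pyruvate
  carboxylase (PC).
* ``acetate_12_13C2`` — [1,2-13C]acetate; enters exclusively as
  acetyl-CoA m+2 and therefore gives citrate m+2 in the first turn and
  [4,5-13C]glutamate via alpha-ketoglutarate.
* ``glutamine_U13C`` — uniformly labelled glutamine; enters as
  alpha-ketoglutarate m+5, oxidised to m+4 four-carbon intermediates or
  reductively carboxylated to citrate m+5 (and malate m+3 after citrate
  cleavage).

Everything is deterministic and exact: a pattern distribution is a length
2**C probability vector and every reaction is a linear map on it, so the
largest object ever handled is the 64-entry citrate vector.  Stochastic
measurement noise lives in :mod:`tcatrace.cohort`, not here.

Carbon-numbering convention (any convention is fine as long as the
observable anchors hold; this one is the standard citrate-synthase /
IDH stereochemistry):

* acetyl-CoA C1 = carboxyl, C2 = methyl; these become glutamate C5 and C4
  respectively, so [1,2-13C]acetyl-CoA yields [4,5-13C]glutamate in turn 1.
* both CO2 molecules released in a turn (IDH and alpha-KGDH steps) derive
  from OAA carbons, so acetyl carbons survive the first turn intact.
* succinate and fumarate are symmetric: their pattern distributions are
  averaged with the carbon-reversed distribution (50/50 scrambling).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "MetabolitePool",
    "PositionalState",
    "MID",
    "TracerSpec",
    "TCAParams",
    "POOLS",
    "TRACERS",
    "unlabelled",
    "delta_state",
    "mix",
    "positional_to_mid",
    "condense",
    "run_oxidative_turn",
    "run_reductive_branch",
    "simulate",
]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class MetabolitePool:
    """A metabolite pool tracked by the simulator."""

    name: str
    n_carbons: int
    symmetric: bool = False

    def __post_init__(self) -> None:
        if self.n_carbons < 1:
            raise ValueError(f"{self.name}: n_carbons must be >= 1")

    @property
    def n_patterns(self) -> int:
        return 1 << self.n_carbons


POOLS: Mapping[str, MetabolitePool] = {
    p.name: p
    for p in (
        MetabolitePool("pyruvate", 3),
        MetabolitePool("acetyl", 2),
        MetabolitePool("oaa", 4),
        MetabolitePool("citrate", 6),
        MetabolitePool("akg", 5),
        MetabolitePool("glutamate", 5),
        MetabolitePool("succinate", 4, symmetric=True),
        MetabolitePool("fumarate", 4, symmetric=True),
        MetabolitePool("malate", 4),
    )
}


@dataclass
class PositionalState:
    """Probability distribution over the 2**C labelling patterns of a pool.

    Pattern ``s`` encodes carbon ``i`` (1-based ``C(i+1)``) as bit ``i``:
    bit set means the carbon is 13C.
    """

    pool: MetabolitePool
    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if self.probs.shape != (self.pool.n_patterns,):
            raise ValueError(
                f"{self.pool.name}: expected {self.pool.n_patterns} pattern "
                f"probabilities, got shape {self.probs.shape}"
            )
        self.validate()

    def validate(self) -> None:
        if np.any(self.probs < -_SUM_TOL):
            raise ValueError(f"{self.pool.name}: negative pattern probability")
        total = float(self.probs.sum())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"{self.pool.name}: pattern probabilities sum to {total}")
        # clip tiny negative round-off
        np.clip(self.probs, 0.0, None, out=self.probs)
        self.probs /= self.probs.sum()

    def expected_labels(self) -> float:
        """Expected number of 13C atoms in the pool."""
        return float(self.probs @ _popcounts(self.pool.n_carbons))

    def prob_pattern(self, carbons: tuple[int, ...]) -> float:
        """Probability of the exact pattern labelling the given 1-based carbons."""
        idx = 0
        for c in carbons:
            idx |= 1 << (c - 1)
        return float(self.probs[idx])


@dataclass
class MID:
    """Mass isotopologue distribution: fractions m+0 .. m+C."""

    metabolite: str
    fractions: np.ndarray

    def __post_init__(self) -> None:
        self.fractions = np.asarray(self.fractions, dtype=float)
        if self.fractions.ndim != 1 or len(self.fractions) < 1:
            raise ValueError("MID fractions must be a 1-D vector")
        if np.any(self.fractions < -1e-9):
            raise ValueError(f"{self.metabolite}: negative MID fraction")
        total = float(self.fractions.sum())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"{self.metabolite}: MID sums to {total}")

    @property
    def n_carbons(self) -> int:
        return len(self.fractions) - 1

    def __getitem__(self, k: int) -> float:
        return float(self.fractions[k])


@dataclass(frozen=True)
class TracerSpec:
    """Which tracer was infused and how enriched its entry pool is.

    ``enrichment`` is the fraction of entry-pool molecules carrying the
    tracer pattern: acetyl-CoA m+2 for acetate, tissue pyruvate m+3 for
    glucose, alpha-KG m+5 (from glutamine m+5) for glutamine.
    """

    tracer: str
    enrichment: float | None = None

    _ALLOWED = ("glucose_U13C", "acetate_12_13C2", "glutamine_U13C")

    def __post_init__(self) -> None:
        if self.tracer not in self._ALLOWED:
            raise ValueError(f"unknown tracer {self.tracer!r}; choose from {self._ALLOWED}")
        if self.enrichment is not None and not 0.0 <= self.enrichment <= 1.0:
            raise ValueError("enrichment must be in [0, 1]")


#: default entry-pool enrichments per tracer (fraction of molecules labelled)
TRACERS: Mapping[str, float] = {
    "glucose_U13C": 0.20,
    "acetate_12_13C2": 0.25,
    "glutamine_U13C": 0.32,
}


@dataclass(frozen=True)
class TCAParams:
    """Knobs of the discrete-turn TCA model.

    acetyl_enrichment
        Fraction of acetyl-CoA that is m+2 under the acetate tracer
        (used when the TracerSpec does not carry its own enrichment).
    pdh_fraction
        Share of acetyl-CoA produced from (tissue) pyruvate by PDH; the
        remainder is unlabelled (other lipogenic/oxidative sources).
    pc_fraction
        Share of OAA inflow from pyruvate carboxylation.
    anaplerosis_unlabelled
        Share of OAA inflow from unlabelled anaplerotic sources.
        pc_fraction + anaplerosis_unlabelled <= 1; the remainder is
        cycle-derived (malate) OAA.
    turnover
        Per-turn probability that a cycle-derived OAA molecule re-enters
        condensation rather than exiting; gates multi-turn labelling
        (e.g. citrate m+4 from acetate needs turnover > 0).
    reductive_fraction
        Share of the citrate (and downstream malate) pool formed by
        reductive carboxylation of alpha-KG, applied as a terminal mix.
    glu_exchange
        Per-turn glutamate <-> alpha-KG mixing fraction (1 = full
        equilibration).
    n_turns
        Number of discrete cycle turns to run.
    dilution
        Per-turn, per-pool exchange with unlabelled molecules.
    """

    acetyl_enrichment: float = 0.25
    pdh_fraction: float = 0.5
    pc_fraction: float = 0.1
    anaplerosis_unlabelled: float = 0.2
    turnover: float = 0.8
    reductive_fraction: float = 0.1
    glu_exchange: float = 1.0
    n_turns: int = 8
    dilution: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "acetyl_enrichment",
            "pdh_fraction",
            "pc_fraction",
            "anaplerosis_unlabelled",
            "turnover",
            "reductive_fraction",
            "glu_exchange",
            "dilution",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.pc_fraction + self.anaplerosis_unlabelled > 1.0 + 1e-12:
            raise ValueError("pc_fraction + anaplerosis_unlabelled must be <= 1")
        if self.n_turns < 1:
            raise ValueError("n_turns must be >= 1")


# ---------------------------------------------------------------------------
# pattern-vector primitives

def _popcounts(n_bits: int) -> np.ndarray:
    s = np.arange(1 << n_bits)
    counts = np.zeros_like(s)
    for b in range(n_bits):
        counts += (s >> b) & 1
    return counts


def unlabelled(pool_name: str) -> PositionalState:
    pool = POOLS[pool_name]
    probs = np.zeros(pool.n_patterns)
    probs[0] = 1.0
    return PositionalState(pool, probs)


def delta_state(pool_name: str, carbons: tuple[int, ...]) -> PositionalState:
    """State with all mass on the pattern labelling the given 1-based carbons."""
    pool = POOLS[pool_name]
    idx = 0
    for c in carbons:
        if not 1 <= c <= pool.n_carbons:
            raise ValueError(f"carbon {c} outside 1..{pool.n_carbons} for {pool_name}")
        idx |= 1 << (c - 1)
    probs = np.zeros(pool.n_patterns)
    probs[idx] = 1.0
    return PositionalState(pool, probs)


def mix(a: PositionalState, b: PositionalState, weight_a: float) -> PositionalState:
    if a.pool.name != b.pool.name:
        raise ValueError(f"cannot mix pools {a.pool.name} and {b.pool.name}")
    return PositionalState(a.pool, weight_a * a.probs + (1.0 - weight_a) * b.probs)


def _remap(
    probs: np.ndarray,
    n_src: int,
    target_pool: MetabolitePool,
    src_bit_per_target_bit: tuple[int | None, ...],
) -> PositionalState:
    """Linear atom-map transfer between pattern spaces.

    ``src_bit_per_target_bit[i]`` names which source carbon (0-based bit)
    becomes target carbon ``i``; ``None`` means a fresh carbon taken to be
    unlabelled (e.g. the CO2-derived carbon of reductive carboxylation).
    Source bits not listed are marginalised out (lost as CO2).
    """
    if len(src_bit_per_target_bit) != target_pool.n_carbons:
        raise ValueError("atom map length does not match target carbon count")
    s = np.arange(1 << n_src)
    t = np.zeros_like(s)
    for i, b in enumerate(src_bit_per_target_bit):
        if b is not None:
            t |= ((s >> b) & 1) << i
    out = np.bincount(t, weights=probs, minlength=target_pool.n_patterns)
    return PositionalState(target_pool, out)


def _joint(a: PositionalState, b: PositionalState) -> tuple[np.ndarray, int]:
    """Joint pattern distribution of two independent pools.

    Joint index = a_pattern | (b_pattern << a.n_carbons).
    """
    return np.outer(b.probs, a.probs).ravel(), a.pool.n_carbons + b.pool.n_carbons


def _scramble(state: PositionalState) -> PositionalState:
    """50/50 average of a pattern distribution with its carbon reversal."""
    n = state.pool.n_carbons
    s = np.arange(1 << n)
    rev = np.zeros_like(s)
    for b in range(n):
        rev |= ((s >> b) & 1) << (n - 1 - b)
    return PositionalState(state.pool, 0.5 * (state.probs + state.probs[rev]))


def positional_to_mid(state: PositionalState) -> MID:
    """Collapse a positional distribution to its mass isotopologue distribution."""
    counts = _popcounts(state.pool.n_carbons)
    fractions = np.bincount(counts, weights=state.probs, minlength=state.pool.n_carbons + 1)
    return MID(state.pool.name, fractions)


# ---------------------------------------------------------------------------
# atom-mapped reactions

def condense(oaa: PositionalState, acetyl: PositionalState) -> PositionalState:
    """Citrate synthase: OAA (4C) + acetyl-CoA (2C) -> citrate (6C).

    Citrate carbons 1-4 derive from OAA C1-C4; citrate C5 is the acetyl
    methyl (C2) and C6 the acetyl carboxyl (C1).
    """
    if oaa.pool.n_carbons != 4 or acetyl.pool.n_carbons != 2:
        raise ValueError("condense expects a 4-carbon OAA pool and a 2-carbon acetyl pool")
    probs, n = _joint(oaa, acetyl)  # bits 0-3 OAA C1-C4, bit 4 acetyl C1, bit 5 acetyl C2
    return _remap(probs, n, POOLS["citrate"], (0, 1, 2, 3, 5, 4))


def _idh(citrate: PositionalState) -> PositionalState:
    """Oxidative IDH: citrate -> alpha-KG + CO2 (OAA-derived citrate C4).

    alpha-KG C1-C3 <- citrate C1-C3 (OAA-derived);
    alpha-KG C4 <- citrate C5 (acetyl methyl); C5 <- citrate C6 (acetyl carboxyl).
    """
    return _remap(citrate.probs, 6, POOLS["akg"], (0, 1, 2, 4, 5))


def _akgdh(akg: PositionalState) -> PositionalState:
    """alpha-KGDH + succinyl-CoA synthetase: alpha-KG -> succinate + CO2 (alpha-KG C1)."""
    out = _remap(akg.probs, 5, POOLS["succinate"], (1, 2, 3, 4))
    return _scramble(out)


def _pdh(pyruvate: PositionalState) -> PositionalState:
    """PDH: pyruvate -> acetyl-CoA + CO2 (pyruvate C1)."""
    return _remap(pyruvate.probs, 3, POOLS["acetyl"], (1, 2))


def _pc(pyruvate: PositionalState) -> PositionalState:
    """Pyruvate carboxylase: pyruvate + CO2 -> OAA (C4 from unlabelled CO2)."""
    return _remap(pyruvate.probs, 3, POOLS["oaa"], (0, 1, 2, None))


def _as_pool(state: PositionalState, pool_name: str) -> PositionalState:
    return PositionalState(POOLS[pool_name], state.probs.copy())


def _tracer_sources(tracer: TracerSpec, params: TCAParams) -> dict[str, PositionalState]:
    """Entry-pool states implied by a tracer at its enrichment."""
    e = tracer.enrichment
    if tracer.tracer == "acetate_12_13C2":
        if e is None:
            e = params.acetyl_enrichment
        return {"acetyl": mix(delta_state("acetyl", (1, 2)), unlabelled("acetyl"), e)}
    if e is None:
        e = TRACERS[tracer.tracer]
    if tracer.tracer == "glucose_U13C":
        return {"pyruvate": mix(delta_state("pyruvate", (1, 2, 3)), unlabelled("pyruvate"), e)}
    return {"akg": mix(delta_state("akg", (1, 2, 3, 4, 5)), unlabelled("akg"), e)}


def _oaa_inflow(
    malate: PositionalState, pyruvate: PositionalState, params: TCAParams
) -> PositionalState:
    """OAA pool refresh.

    pc_fraction from pyruvate carboxylation, anaplerosis_unlabelled from
    unlabelled sources, remainder cycle-derived malate gated by turnover.
    """
    pc = params.pc_fraction
    ana = params.anaplerosis_unlabelled
    cyc = 1.0 - pc - ana
    from_cycle = mix(_as_pool(malate, "oaa"), unlabelled("oaa"), params.turnover)
    probs = pc * _pc(pyruvate).probs + ana * unlabelled("oaa").probs + cyc * from_cycle.probs
    return PositionalState(POOLS["oaa"], probs)


def _dilute(state: PositionalState, dilution: float) -> PositionalState:
    if dilution == 0.0:
        return state
    return mix(unlabelled(state.pool.name), state, dilution)


def initial_states() -> dict[str, PositionalState]:
    return {name: unlabelled(name) for name in POOLS}


def run_oxidative_turn(
    states: dict[str, PositionalState],
    params: TCAParams,
    tracer: TracerSpec,
) -> dict[str, PositionalState]:
    """Advance every pool through one oxidative turn of the cycle.

    The reaction steps are applied sequentially in cyclic order starting
    just downstream of the tracer's entry point, so that one turn carries
    freshly entered label once around the cycle (acetyl entry: condense
    first; alpha-KG entry: alpha-KGDH first).  Returns a new state dict.
    """
    st = dict(states)
    sources = _tracer_sources(tracer, params)

    if tracer.tracer == "glutamine_U13C":
        # full per-turn replacement of the alpha-KG pool by the glutamine source
        st["akg"] = sources["akg"]
        st["glutamate"] = mix(
            _as_pool(st["akg"], "glutamate"), st["glutamate"], params.glu_exchange
        )
        st["succinate"] = _akgdh(st["akg"])
        st["fumarate"] = _scramble(_as_pool(st["succinate"], "fumarate"))
        st["malate"] = _as_pool(st["fumarate"], "malate")
        st["oaa"] = _oaa_inflow(st["malate"], st["pyruvate"], params)
        st["acetyl"] = mix(_pdh(st["pyruvate"]), unlabelled("acetyl"), params.pdh_fraction)
        st["citrate"] = condense(st["oaa"], st["acetyl"])
    else:
        if tracer.tracer == "glucose_U13C":
            st["pyruvate"] = sources["pyruvate"]
            st["acetyl"] = mix(_pdh(st["pyruvate"]), unlabelled("acetyl"), params.pdh_fraction)
        else:  # acetate
            st["acetyl"] = sources["acetyl"]
        st["oaa"] = _oaa_inflow(st["malate"], st["pyruvate"], params)
        st["citrate"] = condense(st["oaa"], st["acetyl"])
        st["akg"] = _idh(st["citrate"])
        st["glutamate"] = mix(
            _as_pool(st["akg"], "glutamate"), st["glutamate"], params.glu_exchange
        )
        st["succinate"] = _akgdh(st["akg"])
        st["fumarate"] = _scramble(_as_pool(st["succinate"], "fumarate"))
        st["malate"] = _as_pool(st["fumarate"], "malate")

    if params.dilution > 0.0:
        st = {name: _dilute(s, params.dilution) for name, s in st.items()}
    return st


def run_reductive_branch(
    akg: PositionalState, params: TCAParams | None = None
) -> dict[str, PositionalState]:
    """Reductive carboxylation of alpha-KG and citrate cleavage.

    alpha-KG + CO2 -> citrate (reverse IDH; the new citrate C4 is
    unlabelled CO2-derived); ATP-citrate lyase then cleaves citrate into a
    2-carbon acetyl unit (the acetyl-map carbons C6, C5) and 4-carbon OAA
    (citrate C1-C4), which is reduced to malate.  Glutamine m+5 therefore
    yields citrate m+5 and malate m+3.
    """
    if akg.pool.n_carbons != 5:
        raise ValueError("run_reductive_branch expects a 5-carbon alpha-KG pool")
    citrate = _remap(akg.probs, 5, POOLS["citrate"], (0, 1, 2, None, 3, 4))
    acetyl = _remap(citrate.probs, 6, POOLS["acetyl"], (5, 4))
    oaa = _remap(citrate.probs, 6, POOLS["oaa"], (0, 1, 2, 3))
    malate = _as_pool(oaa, "malate")
    return {"citrate": citrate, "acetyl": acetyl, "oaa": oaa, "malate": malate}


def simulate(
    tracer: TracerSpec, params: TCAParams
) -> dict[str, tuple[PositionalState, MID]]:
    """Run ``params.n_turns`` oxidative turns, then mix in the reductive branch.

    Returns ``{metabolite: (PositionalState, MID)}`` for every tracked pool.
    The reductive branch (weight ``reductive_fraction``) is applied as a
    terminal mix into the citrate and malate pools, computed from the
    alpha-KG pool feeding reductive IDH (the glutamine source pool under
    the glutamine tracer, the cycle alpha-KG otherwise).
    """
    st = initial_states()
    for _ in range(params.n_turns):
        st = run_oxidative_turn(st, params, tracer)

    if params.reductive_fraction > 0.0:
        if tracer.tracer == "glutamine_U13C":
            akg_source = _tracer_sources(tracer, params)["akg"]
        else:
            akg_source = st["akg"]
        red = run_reductive_branch(akg_source, params)
        rf = params.reductive_fraction
        st["citrate"] = mix(red["citrate"], st["citrate"], rf)
        st["malate"] = mix(red["malate"], st["malate"], rf)

    return {name: (state, positional_to_mid(state)) for name, state in st.items()}
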