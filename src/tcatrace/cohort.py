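"""Synthetic study generators.

Three generators emulate the statistical structure the analysis modules
assume, so every pipeline stage is testable without patient data:

* :func:`generate_tracing_cohort` — fragment-within-patient MID
  measurements under tissue-specific TCA parameters.  Patient-level
  heterogeneity is log-normal perturbation of the class's TCAParams;
  fragment-level measurement noise is Dirichlet-compositional (keeps MIDs
  on the simplex).  Defaults encode the kidney-vs-tumour contrast: the
  adjacent kidney turns the cycle briskly (turnover 0.9, high PDH use)
  while the clear-cell tumour has suppressed turnover (0.45), lower PDH
  contribution and an enhanced reductive branch (0.3).
* :func:`generate_feature_table` — log-normal intensity tables with QC
  injections at fixed intervals, blanks at a stated fraction of signal,
  and optional multiplicative run-order drift on a metabolite subset.
* :func:`generate_survival_cohort` — expression matrices in which a
  latent per-sample program shifts a gene set, with exponential survival
  whose hazard is multiplied by exp(beta * score) and independent
  censoring.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .metrics import FragmentRecord
from .qc import FeatureTable
from .survival import ExpressionMatrix
from .tca import MID, TCAParams, TracerSpec, TRACERS, delta_state, mix, simulate, unlabelled

__all__ = [
    "CohortSpec",
    "default_cohort_spec",
    "generate_tracing_cohort",
    "generate_feature_table",
    "generate_survival_cohort",
]

#: TCAParams fields perturbed per patient (log-normal on the logit-free scale,
#: clipped to [0, 1])
_PERTURBED = ("pdh_fraction", "pc_fraction", "turnover", "reductive_fraction")


@dataclass(frozen=True)
class CohortSpec:
    """Design of a synthetic tracing cohort.

    ``class_params`` maps tissue class to its prior-mean TCAParams;
    ``patient_sd`` is the log-normal SD of the per-patient parameter
    perturbation; ``kappa`` the Dirichlet concentration of fragment-level
    MID noise (500 gives roughly 2% SD on major fractions).
    """

    class_params: Mapping[str, TCAParams]
    patients_per_class: int = 10
    fragments_per_patient: int = 3
    kappa: float = 500.0
    tracer: str = "glucose_U13C"
    enrichment: float | None = None
    patient_sd: float = 0.2

    def __post_init__(self) -> None:
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.patients_per_class < 1 or self.fragments_per_patient < 1:
            raise ValueError("cohort counts must be >= 1")


def default_cohort_spec(**overrides) -> CohortSpec:
    """Kidney-vs-ccRCC glucose-tracing cohort with study-like contrasts."""
    kidney = TCAParams(
        pdh_fraction=0.7, pc_fraction=0.1, anaplerosis_unlabelled=0.15,
        turnover=0.9, reductive_fraction=0.05,
    )
    tumour = TCAParams(
        pdh_fraction=0.35, pc_fraction=0.1, anaplerosis_unlabelled=0.25,
        turnover=0.45, reductive_fraction=0.3,
    )
    spec = CohortSpec(class_params={"adjacent_kidney": kidney, "ccRCC": tumour})
    return replace(spec, **overrides) if overrides else spec


def _perturb_params(params: TCAParams, rng: np.random.Generator, sd: float) -> TCAParams:
    updates = {}
    for name in _PERTURBED:
        v = getattr(params, name) * float(rng.lognormal(0.0, sd))
        updates[name] = min(max(v, 0.0), 1.0)
    if updates.get("pc_fraction", 0.0) + params.anaplerosis_unlabelled > 1.0:
        updates["pc_fraction"] = 1.0 - params.anaplerosis_unlabelled
    return replace(params, **updates)


def _noisy_mid(mid: MID, kappa: float, rng: np.random.Generator) -> MID:
    if np.isinf(kappa):
        return mid
    alpha = np.clip(mid.fractions, 1e-9, None) * kappa
    return MID(mid.metabolite, rng.dirichlet(alpha))


def _plasma_mids(tracer: TracerSpec) -> dict[str, MID]:
    e = tracer.enrichment if tracer.enrichment is not None else TRACERS[tracer.tracer]
    plasma: dict[str, MID] = {}
    if tracer.tracer == "glucose_U13C":
        glc = np.zeros(7)
        glc[0], glc[6] = 1 - e, e
        pyr = np.zeros(4)
        pyr[0], pyr[3] = 1 - e, e
        plasma["glucose"] = MID("glucose", glc)
        plasma["pyruvate"] = MID("pyruvate", pyr)
    elif tracer.tracer == "glutamine_U13C":
        gln = np.zeros(6)
        gln[0], gln[5] = 1 - e, e
        plasma["glutamine"] = MID("glutamine", gln)
    else:
        ace = np.zeros(3)
        ace[0], ace[2] = 1 - e, e
        plasma["acetate"] = MID("acetate", ace)
    return plasma


def generate_tracing_cohort(spec: CohortSpec, seed: int) -> list[FragmentRecord]:
    """Draw a full fragment-within-patient tracing cohort.

    Per patient: TCAParams perturbed from the class prior; per fragment:
    one noiseless simulation plus Dirichlet measurement noise on each MID.
    Deterministic per (spec, seed).
    """
    rng = np.random.default_rng(seed)
    tracer = TracerSpec(spec.tracer, spec.enrichment)
    records: list[FragmentRecord] = []
    pid = 0
    for tissue, params in spec.class_params.items():
        for _ in range(spec.patients_per_class):
            pid += 1
            patient = f"P{pid:03d}"
            pparams = _perturb_params(params, rng, spec.patient_sd)
            result = simulate(tracer, pparams)
            for f in range(spec.fragments_per_patient):
                mids = {
                    name: _noisy_mid(mid, spec.kappa, rng)
                    for name, (_, mid) in result.items()
                }
                records.append(
                    FragmentRecord(
                        patient=patient,
                        tissue=tissue,
                        fragment=f"{patient}-F{f + 1}",
                        mids=mids,
                        plasma_mids=_plasma_mids(tracer),
                        glutamate_state=result["glutamate"][0],
                    )
                )
    return records


def generate_feature_table(
    n_metabolites: int = 40,
    n_study: int = 80,
    qc_interval: int = 4,
    n_blanks: int = 4,
    drift_factor: float = 1.0,
    drift_fraction: float = 0.25,
    blank_fraction: float = 0.01,
    qc_cv: float = 0.05,
    study_cv: float = 0.4,
    n_modes: int = 1,
    seed: int = 0,
) -> FeatureTable:
    """Synthetic LC-MS feature table with QC/blank structure and drift.

    Study samples are log-normal around a per-metabolite base intensity;
    QC samples are tight replicates of the base (CV ``qc_cv``) injected
    every ``qc_interval`` runs; blanks sit at ``blank_fraction`` of the
    base.  ``drift_factor`` > 1 applies a multiplicative linear run-order
    drift (1 -> factor across the run) to the first
    ``drift_fraction * n_metabolites`` metabolites of every sample type.
    With ``n_modes=2`` each metabolite identity appears in both ionization
    modes with independent base intensities.
    """
    rng = np.random.default_rng(seed)
    n_rows = n_metabolites * n_modes
    base = rng.lognormal(mean=12.0, sigma=1.0, size=n_rows)

    sample_ids, types = [], []
    run = 0
    n_qc = 0
    for i in range(n_study):
        if i % qc_interval == 0:
            n_qc += 1
            sample_ids.append(f"QC{n_qc:02d}")
            types.append("QC")
            run += 1
        sample_ids.append(f"S{i + 1:03d}")
        types.append("study")
        run += 1
    n_qc += 1
    sample_ids.append(f"QC{n_qc:02d}")
    types.append("QC")
    for b in range(n_blanks):
        sample_ids.append(f"B{b + 1:02d}")
        types.append("blank")
    n_samples = len(sample_ids)
    run_order = np.arange(1, n_samples + 1)
    samples = pd.DataFrame(
        {"run_order": run_order, "type": types, "batch": 0}, index=sample_ids
    )

    intens = np.empty((n_rows, n_samples))
    for j, t in enumerate(types):
        if t == "QC":
            intens[:, j] = base * rng.lognormal(0.0, qc_cv, n_rows)
        elif t == "study":
            intens[:, j] = base * rng.lognormal(0.0, study_cv, n_rows)
        else:
            intens[:, j] = base * blank_fraction * rng.lognormal(0.0, qc_cv, n_rows)

    n_drift = int(round(drift_fraction * n_rows))
    if drift_factor != 1.0 and n_drift > 0:
        ramp = 1.0 + (drift_factor - 1.0) * (run_order - 1) / (n_samples - 1)
        intens[:n_drift, :] *= ramp[None, :]

    if n_modes == 2:
        names = [f"M{i + 1:03d}_{m}" for m in ("pos", "neg") for i in range(n_metabolites)]
        identity = [f"M{i + 1:03d}" for _ in range(2) for i in range(n_metabolites)]
        mode = ["positive"] * n_metabolites + ["negative"] * n_metabolites
    else:
        names = [f"M{i + 1:03d}" for i in range(n_rows)]
        identity = names
        mode = ["positive"] * n_rows
    features = pd.DataFrame(
        {
            "identity": identity,
            "mode": mode,
            "hmdb_id": [f"HMDB{i:07d}" for i in range(1, n_rows + 1)],
        },
        index=names,
    )
    intensities = pd.DataFrame(intens, index=names, columns=sample_ids)
    return FeatureTable(intensities, samples, features)


def generate_survival_cohort(
    n: int = 200,
    beta: float = 1.0,
    censoring_rate: float = 0.3,
    n_set_genes: int = 30,
    n_other_genes: int = 70,
    base_hazard: float = 1.0 / 1000.0,
    seed: int = 0,
) -> tuple[ExpressionMatrix, pd.Series]:
    """Expression + survival cohort with a score-dependent hazard.

    A latent standard-normal program ``z`` shifts every set gene by
    ``z`` (in log2 units, SD 1 noise); survival is exponential with
    hazard ``base_hazard * exp(beta * z)``; censoring is independent
    exponential scaled to the requested rate (``censoring_rate=1`` means
    everyone censored at an administrative horizon).  Returns the matrix
    (log scale) and the latent scores.
    """
    if n < 10:
        raise ValueError("n must be >= 10")
    rng = np.random.default_rng(seed)
    z = rng.normal(0.0, 1.0, n)
    samples = [f"T{i + 1:03d}" for i in range(n)]
    set_names = [f"OXP{i + 1:03d}" for i in range(n_set_genes)]
    other_names = [f"G{i + 1:03d}" for i in range(n_other_genes)]
    expr_set = rng.normal(8.0, 1.0, (n_set_genes, n)) + z[None, :]
    expr_other = rng.normal(8.0, 1.0, (n_other_genes, n))
    values = pd.DataFrame(
        np.vstack([expr_set, expr_other]), index=set_names + other_names, columns=samples
    )

    hazard = base_hazard * np.exp(beta * z)
    event_time = rng.exponential(1.0 / hazard)
    if censoring_rate >= 1.0:
        time = np.full(n, float(np.median(event_time)))
        event = np.zeros(n, dtype=int)
    elif censoring_rate <= 0.0:
        time, event = event_time, np.ones(n, dtype=int)
    else:
        # censoring hazard chosen so that P(censor first) ~ censoring_rate
        cens_time = rng.exponential(
            1.0 / (base_hazard * censoring_rate / (1.0 - censoring_rate)), size=n
        )
        time = np.minimum(event_time, cens_time)
        event = (event_time <= cens_time).astype(int)
    clinical = pd.DataFrame(
        {
            "time_days": time,
            "event": event,
            "grade": rng.integers(1, 5, n),
            "stage": rng.integers(1, 5, n),
        },
        index=samples,
    )
    matrix = ExpressionMatrix(values=values, clinical=clinical, log_scale=True)
    return matrix, pd.Series(z, index=samples, name="latent_score")
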