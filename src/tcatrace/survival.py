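"""Gene-set scoring, cohort stratification, survival analysis and the
nested fragment-within-patient comparison.

The OxPhos score is the first principal component of log2-transformed,
mean-centred, z-scaled expression of an oxidative-phosphorylation gene
set (KEGG OxPhos genes plus the PDH complex subunits PDHA1, PDHB, DLAT,
DLD, PDHX), sign-oriented so a high score means high set expression.
Kaplan-Meier estimation and the log-rank (Mantel-Cox) test delegate to
lifelines; the nested comparison tests class differences on equally
weighted patient-level means, which in the balanced case is exactly the
nested ANOVA with patient as the random factor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "ExpressionMatrix",
    "GeneSet",
    "PDH_COMPLEX_GENES",
    "ScoredCohort",
    "KMResult",
    "oxphos_score",
    "stratify",
    "km_estimate",
    "logrank_test",
    "nested_comparison",
    "bh_adjust",
]

log = logging.getLogger(__name__)

#: PDH complex subunits appended to the KEGG OxPhos set for the score
PDH_COMPLEX_GENES = ("PDHA1", "PDHB", "DLAT", "DLD", "PDHX")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression with per-sample clinical annotation.

    ``values`` may be on a linear or log2 scale (``log_scale`` flag);
    ``clinical`` is indexed by sample with columns among
    ``time_days``, ``event``, ``grade``, ``stage``.
    """

    values: pd.DataFrame
    clinical: pd.DataFrame
    log_scale: bool = False

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate gene ids in expression matrix")
        missing = set(self.values.columns) - set(self.clinical.index)
        if missing:
            raise ValueError(f"samples missing clinical rows: {sorted(missing)[:5]}")
        for col, lo, hi in (("grade", 1, 4), ("stage", 1, 4)):
            if col in self.clinical.columns:
                v = self.clinical[col].dropna()
                if ((v < lo) | (v > hi)).any():
                    raise ValueError(f"{col} values outside {lo}..{hi}")


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset[str]

    def __init__(self, name: str, genes: Sequence[str]):
        object.__setattr__(self, "name", name)
        object.__setattr__(self, "genes", frozenset(genes))
        if not self.genes:
            raise ValueError("gene set is empty")


@dataclass
class ScoredCohort:
    scores: pd.Series
    strata: pd.Series
    clinical: pd.DataFrame


@dataclass
class KMResult:
    """Product-limit curve and median survival (nan = not reached)."""

    times: np.ndarray
    survival: np.ndarray
    median: float

    @property
    def median_reached(self) -> bool:
        return not math.isnan(self.median)


def oxphos_score(expr: ExpressionMatrix, gene_set: GeneSet) -> pd.Series:
    """PC1 of log2, per-gene-centred, z-scaled set-gene expression.

    Genes absent from the matrix are ignored; zero-variance genes are
    dropped with a log message.  The sign is fixed so the score correlates
    positively with mean set expression ("high" means high OxPhos).
    """
    present = [g for g in expr.values.index if g in gene_set.genes]
    if len(present) < 2:
        raise ValueError(f"fewer than 2 genes of set {gene_set.name!r} present")
    if expr.values.shape[1] < 2:
        raise ValueError("need at least 2 samples to score")
    X = expr.values.loc[present].astype(float)
    if not expr.log_scale:
        X = np.log2(X + 1.0)
    sd = X.std(axis=1, ddof=1)
    dropped = sd.index[sd == 0]
    if len(dropped):
        log.info("oxphos_score: dropped %d zero-variance genes", len(dropped))
        X = X.drop(index=dropped)
    if X.shape[0] < 2:
        raise ValueError("fewer than 2 set genes with nonzero variance")
    Z = X.sub(X.mean(axis=1), axis=0).div(X.std(axis=1, ddof=1), axis=0)
    # samples x genes; PC1 sample coordinates via SVD
    U, S, Vt = np.linalg.svd(Z.to_numpy().T, full_matrices=False)
    scores = U[:, 0] * S[0]
    mean_expr = Z.mean(axis=0).to_numpy()
    if np.corrcoef(scores, mean_expr)[0, 1] < 0:
        scores = -scores
    return pd.Series(scores, index=expr.values.columns, name="oxphos_score")


def stratify(
    values: pd.Series,
    rule: str = "median",
    clinical: pd.DataFrame | None = None,
    grades: Sequence[int] | None = None,
    stages: Sequence[int] | None = None,
) -> pd.Series:
    """Label samples high/low by median split or a 30/70 quantile rule.

    Optional grade/stage filters restrict the subcohort first; the
    quantile rule leaves the middle 40% unlabelled (absent from the
    result).  Ties at a cut point go to "low" (deterministic, logged).
    """
    idx = values.index
    if grades is not None or stages is not None:
        if clinical is None:
            raise ValueError("grade/stage filtering requires a clinical table")
        keep = pd.Series(True, index=idx)
        if grades is not None:
            keep &= clinical.loc[idx, "grade"].isin(grades)
        if stages is not None:
            keep &= clinical.loc[idx, "stage"].isin(stages)
        idx = idx[keep]
    vals = values.loc[idx]
    if len(vals) == 0:
        raise ValueError("filtered subcohort is empty")
    if vals.nunique() == 1:
        raise ValueError("all values identical; no informative split")
    if rule == "median":
        cut = vals.median()
        labels = pd.Series(np.where(vals <= cut, "low", "high"), index=vals.index)
        if (vals == cut).any():
            log.info("stratify: %d values at the median assigned to 'low'", int((vals == cut).sum()))
        return labels
    if rule == "quantile":
        lo, hi = vals.quantile(0.3), vals.quantile(0.7)
        labels = pd.Series(index=vals.index, dtype=object)
        labels[vals <= lo] = "low"
        labels[vals >= hi] = "high"
        return labels.dropna()
    raise ValueError(f"unknown stratification rule {rule!r}")


def km_estimate(time: Sequence[float], event: Sequence[int]) -> KMResult:
    """Kaplan-Meier product-limit estimate with median survival.

    The median is the first time the curve drops to 0.5 or below;
    ``nan`` when never reached (e.g. all subjects censored).
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    if np.any(time < 0):
        raise ValueError("negative survival times")
    kmf = KaplanMeierFitter()
    kmf.fit(time, event_observed=event)
    sf = kmf.survival_function_
    median = float(kmf.median_survival_time_)
    if math.isinf(median):
        median = float("nan")
    return KMResult(
        times=sf.index.to_numpy(float),
        survival=sf.iloc[:, 0].to_numpy(float),
        median=median,
    )


def logrank_test(
    time_a: Sequence[float],
    event_a: Sequence[int],
    time_b: Sequence[float],
    event_b: Sequence[int],
) -> tuple[float, float]:
    """Log-rank (Mantel-Cox) test: (chi-square statistic, two-sided p)."""
    if len(time_a) == 0 or len(time_b) == 0:
        raise ValueError("both groups must be non-empty")
    res = _ll_logrank(
        np.asarray(time_a, float),
        np.asarray(time_b, float),
        event_observed_A=np.asarray(event_a, int),
        event_observed_B=np.asarray(event_b, int),
    )
    return float(res.test_statistic), float(res.p_value)


@dataclass
class NestedResult:
    """Patient-level summaries and the class-difference test."""

    patient_means: pd.DataFrame  # columns: patient, tissue, mean, sd, n_fragments
    statistic: float
    p_value: float


def nested_comparison(
    values: pd.DataFrame,
    class_a: str,
    class_b: str,
    value_col: str = "value",
    patient_col: str = "patient",
    tissue_col: str = "tissue",
) -> NestedResult:
    """Nested two-sided comparison of fragment values between tissue classes.

    Fragments are nested within patients, so patients are the independent
    units: fragment values are collapsed to equally weighted patient means
    and the classes compared with a pooled-variance two-sided t-test.  In
    the balanced case this equals the two-level nested ANOVA with patient
    as the random factor.  A patient contributing fragments to both
    classes is treated as two independent units (no pairing assumed).
    Returns per-patient mean +/- SD for plotting alongside the test.
    """
    df = values[[patient_col, tissue_col, value_col]].dropna(subset=[value_col])
    df = df[df[tissue_col].isin((class_a, class_b))]
    summ = (
        df.groupby([tissue_col, patient_col])[value_col]
        .agg(mean="mean", sd="std", n_fragments="count")
        .reset_index()
    )
    means_a = summ.loc[summ[tissue_col] == class_a, "mean"].to_numpy()
    means_b = summ.loc[summ[tissue_col] == class_b, "mean"].to_numpy()
    if len(means_a) < 2 or len(means_b) < 2:
        raise ValueError("need >= 2 patients per tissue class")
    t, p = stats.ttest_ind(means_a, means_b, equal_var=True)
    return NestedResult(patient_means=summ, statistic=float(t), p_value=float(p))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p values, capped at 1."""
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p values must be in [0, 1]")
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]
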