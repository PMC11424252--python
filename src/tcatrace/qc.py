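"""LC/GC-MS feature-table QC, drift correction and normalization.

The pipeline order is fixed:

1. ``snr`` — per-metabolite signal-to-noise, median(QC)/median(blank);
2. ``run_order_test`` — Spearman correlation of QC intensity with run
   order, Benjamini-Hochberg adjusted across metabolites;
3. ``loess_drift_correct`` — LOESS of QC intensity on run order, applied
   only to metabolites whose QC trend (restricted to QC points inside the
   metabolite's QC interquartile range) is BH-significant;
4. ``tic_normalize`` — per-sample factor from the median intensity of a
   stable-metabolite subset (low QC CV, high S/N);
5. ``log_transform_and_dedupe`` — log10, then one row per metabolite
   identity keeping the ionization mode with the higher S/N.

Thresholds live in :class:`QCConfig`; conditional branches (skipped
metabolites, imputed zeros, mode ties) are logged for audit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess
from statsmodels.stats.multitest import multipletests

__all__ = [
    "FeatureTable",
    "QCConfig",
    "snr",
    "run_order_test",
    "loess_drift_correct",
    "tic_normalize",
    "log_transform_and_dedupe",
    "cohens_d",
    "effect_sizes_and_crossstudy",
    "run_qc_pipeline",
]

log = logging.getLogger(__name__)


@dataclass
class QCConfig:
    snr_min: float = 3.0
    bh_alpha: float = 0.05
    loess_span: float = 0.75
    stable_cv_max: float = 0.2
    stable_snr_min: float = 10.0
    log_base: float = 10.0

    def __post_init__(self) -> None:
        if not 0 < self.bh_alpha < 1:
            raise ValueError("bh_alpha must be in (0, 1)")
        for name in ("snr_min", "loess_span", "stable_cv_max", "stable_snr_min", "log_base"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class FeatureTable:
    """Intensity matrix (metabolites x samples) plus run metadata.

    ``samples`` must carry columns ``run_order`` (unique within batch) and
    ``type`` in {study, QC, blank}; ``features`` carries ``mode``
    (positive|negative) and optionally ``hmdb_id`` and ``identity`` (the
    metabolite identity shared between modes).
    """

    intensities: pd.DataFrame
    samples: pd.DataFrame
    features: pd.DataFrame

    def __post_init__(self) -> None:
        if list(self.intensities.columns) != list(self.samples.index):
            raise ValueError("intensity columns must match sample-sheet index")
        if list(self.intensities.index) != list(self.features.index):
            raise ValueError("intensity rows must match feature-sheet index")
        if (self.intensities.values < 0).any():
            raise ValueError("intensities must be nonnegative")
        bad = set(self.samples["type"]) - {"study", "QC", "blank"}
        if bad:
            raise ValueError(f"unknown sample types: {sorted(bad)}")
        batch = self.samples.get("batch", pd.Series(0, index=self.samples.index))
        for b, grp in self.samples.groupby(batch):
            if grp["run_order"].duplicated().any():
                raise ValueError(f"duplicate run orders in batch {b}")

    def of_type(self, sample_type: str) -> pd.DataFrame:
        cols = self.samples.index[self.samples["type"] == sample_type]
        return self.intensities[cols]

    def copy_with(self, intensities: pd.DataFrame) -> "FeatureTable":
        return FeatureTable(intensities, self.samples, self.features)


def snr(table: FeatureTable) -> pd.Series:
    """Per-metabolite S/N: median over QC samples / median over blanks.

    A zero blank median gives ``inf`` (flagged, metabolite retained).
    """
    qc = table.of_type("QC")
    blank = table.of_type("blank")
    if qc.shape[1] == 0 or blank.shape[1] == 0:
        raise ValueError("snr requires at least one QC and one blank sample")
    qc_med = qc.median(axis=1)
    blank_med = blank.median(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = qc_med / blank_med
    zero_blank = blank_med == 0
    out[zero_blank & (qc_med > 0)] = np.inf
    out[zero_blank & (qc_med == 0)] = np.nan
    n_inf = int(np.isinf(out).sum())
    if n_inf:
        log.info("snr: %d metabolites with zero blank median flagged as infinite S/N", n_inf)
    return out.rename("snr")


def _qc_trend(values: np.ndarray, order: np.ndarray, restrict_iqr: bool) -> tuple[float, float]:
    """Spearman correlation of QC intensity with run order.

    With ``restrict_iqr`` the test uses only QC points whose intensity lies
    inside the metabolite's QC interquartile range.
    """
    if restrict_iqr:
        q1, q3 = np.percentile(values, [25, 75])
        keep = (values >= q1) & (values <= q3)
        values, order = values[keep], order[keep]
    if len(values) < 3 or np.ptp(values) == 0:
        return np.nan, np.nan
    rho, p = stats.spearmanr(order, values)
    return float(rho), float(p)


def run_order_test(table: FeatureTable, restrict_iqr: bool = True) -> pd.DataFrame:
    """Spearman run-order trend test over QC samples, BH-adjusted.

    Returns a frame with columns ``rho``, ``p`` and ``p_adj``; metabolites
    with a constant QC signal get missing values and are excluded from the
    adjustment.
    """
    qc_cols = table.samples.index[table.samples["type"] == "QC"]
    if len(qc_cols) < 4:
        raise ValueError("run_order_test requires at least 4 QC samples")
    order = table.samples.loc[qc_cols, "run_order"].to_numpy(float)
    res = pd.DataFrame(index=table.intensities.index, columns=["rho", "p", "p_adj"], dtype=float)
    for met in table.intensities.index:
        rho, p = _qc_trend(table.intensities.loc[met, qc_cols].to_numpy(float), order, restrict_iqr)
        res.loc[met, ["rho", "p"]] = rho, p
    ok = res["p"].notna()
    if ok.any():
        res.loc[ok, "p_adj"] = multipletests(res.loc[ok, "p"], method="fdr_bh")[1]
    return res


def loess_drift_correct(
    table: FeatureTable,
    qc_test: pd.DataFrame,
    config: QCConfig | None = None,
) -> FeatureTable:
    """Divide out a LOESS run-order trend for BH-significant metabolites.

    The LOESS model is fit on QC samples only (standard QC-based robust
    LOESS signal correction), evaluated at every sample's run order by
    interpolation, and each corrected trace is rescaled to its QC median.
    Metabolites whose fitted trend is nonpositive anywhere are skipped with
    a logged reason; non-significant metabolites pass through unchanged.
    """
    config = config or QCConfig()
    qc_cols = table.samples.index[table.samples["type"] == "QC"]
    qc_order = table.samples.loc[qc_cols, "run_order"].to_numpy(float)
    all_order = table.samples["run_order"].to_numpy(float)
    out = table.intensities.copy()
    flagged = qc_test.index[(qc_test["p_adj"] < config.bh_alpha).fillna(False)]
    for met in flagged:
        qc_vals = table.intensities.loc[met, qc_cols].to_numpy(float)
        fit = lowess(qc_vals, qc_order, frac=config.loess_span, return_sorted=True)
        trend = np.interp(all_order, fit[:, 0], fit[:, 1])
        if np.any(trend <= 0):
            log.warning("loess: %s skipped, fitted trend nonpositive", met)
            continue
        qc_median = float(np.median(qc_vals))
        out.loc[met] = table.intensities.loc[met].to_numpy(float) / trend * qc_median
    log.info("loess: corrected %d/%d metabolites", len(flagged), len(out))
    return table.copy_with(out)


def _stable_subset(table: FeatureTable, config: QCConfig) -> pd.Index:
    qc = table.of_type("QC")
    cv = qc.std(axis=1, ddof=1) / qc.mean(axis=1)
    s = snr(table)
    stable = table.intensities.index[(cv <= config.stable_cv_max) & (s >= config.stable_snr_min)]
    return stable


def tic_normalize(
    table: FeatureTable, config: QCConfig | None = None
) -> tuple[FeatureTable, pd.Series]:
    """Total-ion-count-style normalization against a stable-metabolite subset.

    Per-sample factor = median intensity of the stable subset in that
    sample / grand median of those medians; study and QC intensities are
    divided by the sample factor.  Blank columns are left untouched (they
    define the noise floor, not sample loading), which also makes the
    operation idempotent.  The stable subset is metabolites with QC CV at
    or below ``stable_cv_max`` and S/N at or above ``stable_snr_min``.
    """
    config = config or QCConfig()
    stable = _stable_subset(table, config)
    if len(stable) == 0:
        raise ValueError(
            f"empty stable subset (stable_cv_max={config.stable_cv_max}, "
            f"stable_snr_min={config.stable_snr_min})"
        )
    loaded = table.samples.index[table.samples["type"] != "blank"]
    sample_medians = table.intensities.loc[stable, loaded].median(axis=0)
    factors = sample_medians / sample_medians.median()
    out = table.intensities.copy()
    out[loaded] = out[loaded].div(factors, axis=1)
    return table.copy_with(out), factors.rename("factor")


def log_transform_and_dedupe(
    table: FeatureTable, config: QCConfig | None = None
) -> FeatureTable:
    """log10 transform, then keep one row per metabolite identity.

    Zeros are imputed as half the minimum positive value of the metabolite
    before the log (logged).  When an identity was measured in both
    ionization modes, the mode with the lower S/N is dropped; equal S/N
    keeps positive mode (tie logged).
    """
    config = config or QCConfig()
    vals = table.intensities.copy().astype(float)
    for met in vals.index:
        row = vals.loc[met]
        if (row == 0).any():
            positives = row[row > 0]
            if positives.empty:
                log.warning("log: %s all-zero, left as zeros pre-imputation floor 1", met)
                vals.loc[met] = 1.0
            else:
                imput = positives.min() / 2.0
                log.info("log: %s imputed %d zeros with %.4g", met, int((row == 0).sum()), imput)
                vals.loc[met] = row.replace(0.0, imput)
    s = snr(table)
    identity = table.features.get("identity", pd.Series(table.features.index, index=table.features.index))
    mode = table.features.get("mode", pd.Series("positive", index=table.features.index))
    keep: list[str] = []
    for ident, grp in table.features.groupby(identity):
        rows = list(grp.index)
        if len(rows) == 1:
            keep.append(rows[0])
            continue
        snrs = s.loc[rows]
        best = snrs.max()
        winners = snrs.index[snrs == best]
        if len(winners) > 1:
            pos = [r for r in winners if mode.loc[r] == "positive"]
            chosen = pos[0] if pos else winners[0]
            log.info("dedupe: %s S/N tie, keeping %s (positive-mode rule)", ident, chosen)
        else:
            chosen = winners[0]
        keep.append(chosen)
    keep = [m for m in vals.index if m in set(keep)]
    logged = np.log10(vals.loc[keep]) / np.log10(config.log_base) * 1.0
    return FeatureTable(logged, table.samples, table.features.loc[keep])


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Cohen's d with pooled SD; nan when the pooled SD is zero."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    na, nb = len(a), len(b)
    if na < 2 or nb < 2:
        raise ValueError("cohens_d requires >= 2 samples per group")
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        return float("nan")
    return float((a.mean() - b.mean()) / pooled)


def effect_sizes_and_crossstudy(
    table: FeatureTable,
    groups: pd.Series,
    external: pd.DataFrame,
    tumour_label: str = "tumour",
    normal_label: str = "normal",
) -> tuple[pd.DataFrame, float]:
    """Per-metabolite Cohen's d (tumour vs normal) and cross-study concordance.

    Intensities are min-normalized (divided by the minimum positive value
    observed across the dataset) and log10-transformed before the effect
    size, mirroring standard cross-study harmonisation.  ``external`` needs
    columns ``hmdb_id`` and ``d``; the returned correlation is Pearson's r
    of effect sizes over the intersection of HMDB identifiers.
    """
    study_cols = table.samples.index[table.samples["type"] == "study"]
    groups = groups.loc[study_cols]
    vals = table.intensities[study_cols].astype(float)
    floor = vals.values[vals.values > 0].min()
    transformed = np.log10(vals.clip(lower=floor / 2.0) / floor)
    a_cols = groups.index[groups == tumour_label]
    b_cols = groups.index[groups == normal_label]
    if len(a_cols) < 2 or len(b_cols) < 2:
        raise ValueError("need >= 2 samples per group for effect sizes")
    rows = []
    hmdb = table.features.get("hmdb_id", pd.Series(index=table.features.index, dtype=object))
    for met in transformed.index:
        d = cohens_d(transformed.loc[met, a_cols].to_numpy(), transformed.loc[met, b_cols].to_numpy())
        rows.append({"metabolite": met, "hmdb_id": hmdb.get(met), "d": d})
    effects = pd.DataFrame(rows).set_index("metabolite")
    merged = effects.dropna(subset=["hmdb_id", "d"]).merge(
        external.dropna(subset=["hmdb_id", "d"]), on="hmdb_id", suffixes=("_study", "_external")
    )
    if len(merged) < 3:
        return effects, float("nan")
    r = float(np.corrcoef(merged["d_study"], merged["d_external"])[0, 1])
    return effects, r


def run_qc_pipeline(
    table: FeatureTable, config: QCConfig | None = None
) -> tuple[FeatureTable, dict]:
    """Full pipeline: snr -> run-order test -> LOESS -> TIC -> log/dedupe.

    When a ``batch`` column with multiple levels is present the pipeline
    runs independently per batch and the deduped tables are concatenated
    column-wise.  Returns the processed table and a report dict (S/N,
    trend tests, factors).
    """
    config = config or QCConfig()
    if "batch" in table.samples.columns and table.samples["batch"].nunique() > 1:
        parts, reports = [], {}
        for b, grp in table.samples.groupby("batch"):
            sub = FeatureTable(table.intensities[grp.index], grp, table.features)
            done, rep = run_qc_pipeline(sub, config)
            parts.append(done)
            reports[str(b)] = rep
        common = parts[0].intensities.index
        for p in parts[1:]:
            common = common.intersection(p.intensities.index)
        merged = pd.concat([p.intensities.loc[common] for p in parts], axis=1)
        samples = pd.concat([p.samples for p in parts])
        return FeatureTable(merged, samples, parts[0].features.loc[common]), {"batches": reports}
    s = snr(table)
    trend = run_order_test(table)
    corrected = loess_drift_correct(table, trend, config)
    normalized, factors = tic_normalize(corrected, config)
    final = log_transform_and_dedupe(normalized, config)
    report = {
        "snr": s.to_dict(),
        "run_order": trend.to_dict(orient="index"),
        "tic_factors": factors.to_dict(),
        "n_metabolites_final": int(final.intensities.shape[0]),
    }
    return final, report
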