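"""Readers, writers and the end-to-end pipeline driver.

Canonical interchange formats: long/tidy CSV for MIDs and metrics, wide
CSV plus a sample sheet for feature tables, GMT for gene sets, JSON for
reports.  All randomness flows from the single seed in :class:`RunConfig`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import metrics as metrics_mod
from .metrics import FragmentRecord, total_labelling, ratio_metric
from .natabund import ElementalFormula, IsotopeTable, correct
from .cohort import CohortSpec, default_cohort_spec, generate_tracing_cohort
from .survival import GeneSet, nested_comparison
from .tca import MID, TCAParams

__all__ = [
    "RunConfig",
    "read_mid_table",
    "write_mid_table",
    "read_feature_table",
    "read_gmt",
    "read_formulas",
    "mid_results_to_frame",
    "metrics_table",
    "run_pipeline",
]

log = logging.getLogger(__name__)

_MID_COLUMNS = ("patient", "fragment", "tissue", "metabolite", "isotopologue", "fraction")


def write_mid_table(records: list[FragmentRecord], path: str | Path) -> None:
    rows = []
    for rec in records:
        for met, mid in rec.mids.items():
            for k, frac in enumerate(mid.fractions):
                rows.append(
                    {
                        "patient": rec.patient,
                        "fragment": rec.fragment,
                        "tissue": rec.tissue,
                        "metabolite": met,
                        "isotopologue": k,
                        "fraction": float(frac),
                    }
                )
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.15g")


def read_mid_table(path: str | Path) -> list[FragmentRecord]:
    """Read a long-format MID CSV into validated FragmentRecords.

    Per-metabolite fractions off the simplex by at most 1e-6 are
    renormalized; larger deviations are rejected naming the fragment and
    metabolite.
    """
    df = pd.read_csv(path)
    missing = set(_MID_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    records: list[FragmentRecord] = []
    for (patient, fragment, tissue), grp in df.groupby(
        ["patient", "fragment", "tissue"], sort=False
    ):
        mids: dict[str, MID] = {}
        for met, sub in grp.groupby("metabolite", sort=False):
            sub = sub.sort_values("isotopologue")
            fracs = sub["fraction"].to_numpy(float)
            if not np.array_equal(sub["isotopologue"].to_numpy(), np.arange(len(fracs))):
                raise ValueError(
                    f"{path}: fragment {fragment} metabolite {met}: "
                    "isotopologues must be contiguous m+0..m+C"
                )
            total = fracs.sum()
            if abs(total - 1.0) > 1e-6:
                rows = ", ".join(str(i) for i in sub.index[:3])
                raise ValueError(
                    f"{path}: fragment {fragment} metabolite {met} fractions sum to "
                    f"{total:.6g} (rows {rows})"
                )
            mids[str(met)] = MID(str(met), fracs / total)
        records.append(
            FragmentRecord(
                patient=str(patient), tissue=str(tissue), fragment=str(fragment), mids=mids
            )
        )
    return records


def read_feature_table(table_path: str | Path, samples_path: str | Path):
    """Wide intensity CSV (metabolite rows) + sample sheet -> FeatureTable."""
    from .qc import FeatureTable

    wide = pd.read_csv(table_path, index_col=0)
    samples = pd.read_csv(samples_path, index_col=0)
    feat_cols = [c for c in ("identity", "mode", "hmdb_id") if c in wide.columns]
    features = wide[feat_cols].copy() if feat_cols else pd.DataFrame(index=wide.index)
    if "identity" not in features:
        features["identity"] = features.index
    if "mode" not in features:
        features["mode"] = "positive"
    intensities = wide.drop(columns=feat_cols)
    return FeatureTable(intensities[samples.index.tolist()], samples, features)


def read_gmt(path: str | Path) -> dict[str, GeneSet]:
    sets: dict[str, GeneSet] = {}
    for line in Path(path).read_text().splitlines():
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            continue
        name, _desc, *genes = parts
        sets[name] = GeneSet(name, [g for g in genes if g])
    return sets


def read_formulas(path: str | Path) -> dict[str, ElementalFormula]:
    """YAML map metabolite -> {backbone_carbons, other: {element: count}}."""
    raw = yaml.safe_load(Path(path).read_text())
    return {
        met: ElementalFormula(
            backbone_carbons=int(spec["backbone_carbons"]),
            other={str(k): int(v) for k, v in (spec.get("other") or {}).items()},
        )
        for met, spec in raw.items()
    }


def mid_results_to_frame(result: dict) -> pd.DataFrame:
    """Simulator output -> long frame (metabolite, isotopologue, fraction)."""
    rows = []
    for met, (_, mid) in result.items():
        for k, frac in enumerate(mid.fractions):
            rows.append({"metabolite": met, "isotopologue": k, "fraction": float(frac)})
    return pd.DataFrame(rows)


def metrics_table(records: list[FragmentRecord]) -> pd.DataFrame:
    """Standard metric suite over a cohort, one row per fragment x metric."""
    rows = []
    for rec in records:
        values = {
            "citrate_m2_over_pyruvate_m3": ratio_metric(("citrate", 2), ("pyruvate", 3), rec),
            "citrate_m4_over_citrate_m2": ratio_metric(("citrate", 4), ("citrate", 2), rec),
        }
        for met in ("citrate", "malate", "succinate", "fumarate", "glutamate"):
            if met in rec.mids:
                values[f"total_labelling_{met}"] = metrics_mod.MetricValue(
                    total_labelling(rec.mids[met])
                )
        if "citrate" in rec.mids:
            values["citrate_m5"] = metrics_mod.MetricValue(
                rec.mids["citrate"][5] if rec.mids["citrate"].n_carbons >= 5 else float("nan")
            )
        if rec.glutamate_state is not None:
            values["glu45_fraction"] = metrics_mod.glu45_fraction(rec.glutamate_state)
        for name, mv in values.items():
            rows.append(
                {
                    "patient": rec.patient,
                    "fragment": rec.fragment,
                    "tissue": rec.tissue,
                    "metric": name,
                    "value": mv.value,
                    "reason": mv.reason,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration."""

    seed: int = 0
    out_dir: str = "tcatrace_out"
    mids_path: str | None = None  # None -> generate the default synthetic cohort
    cohort: CohortSpec | None = None
    compare: tuple[str, str] = ("adjacent_kidney", "ccRCC")
    metric: str = "citrate_m2_over_pyruvate_m3"


def run_pipeline(config: RunConfig) -> dict:
    """correct/load -> metrics -> nested comparison, with a JSON report.

    Stage failures raise with the stage name; the report is written to
    ``<out_dir>/report.json`` and returned.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    if config.mids_path is not None:
        records = read_mid_table(config.mids_path)
    else:
        spec = config.cohort or default_cohort_spec()
        records = generate_tracing_cohort(spec, config.seed)
    if not records:
        raise ValueError("stage cohort: empty cohort, nothing to analyse")

    try:
        table = metrics_table(records)
    except Exception as exc:  # pragma: no cover - defensive
        raise RuntimeError(f"stage metrics failed: {exc}") from exc
    table.to_csv(out_dir / "metrics.csv", index=False)

    report: dict = {
        "seed": config.seed,
        "n_fragments": len(records),
        "n_patients": int(table["patient"].nunique()),
        "comparisons": {},
    }
    sub = table[table["metric"] == config.metric].rename(columns={"value": "value"})
    class_a, class_b = config.compare
    try:
        nested = nested_comparison(sub, class_a, class_b)
        report["comparisons"][config.metric] = {
            "classes": [class_a, class_b],
            "mean_a": float(
                nested.patient_means.loc[
                    nested.patient_means["tissue"] == class_a, "mean"
                ].mean()
            ),
            "mean_b": float(
                nested.patient_means.loc[
                    nested.patient_means["tissue"] == class_b, "mean"
                ].mean()
            ),
            "t": nested.statistic,
            "p": nested.p_value,
        }
    except ValueError as exc:
        raise RuntimeError(f"stage nested_comparison failed: {exc}") from exc

    (out_dir / "report.json").write_text(json.dumps(report, indent=2, sort_keys=True))
    return report
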