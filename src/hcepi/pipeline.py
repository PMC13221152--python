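"""End-to-end pipeline orchestration.

Ties the stages together — prepare -> periods -> classify -> trends ->
diagnosis linkage -> risk — over delimited-text input tables (or a
simulated cohort), writing every output table plus a run manifest with the
configuration hash, package version and row counts.  Deterministic given
inputs and seed.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .catalog import FormulationCatalog, default_catalog
from .classify import classification_table, classify_cohort, cohort_classification_summary, extract_rapid_switch_flows
from .diagnoses import abortion_overlap, pre_initiation_diagnoses, thrombosis_during_use
from .periods import build_periods, censor_by_pregnancy, first_usage_periods
from .prepare import prepare_purchases
from .registry import CodeRegistry, default_registry
from .risk import assess_risk_factors, carrier_thrombosis_association, factor_prevalence_comparison, index_year_groups
from .simulate import SimulatedCohort, SimulationConfig, simulate_cohort
from .trends import annual_prevalence, covered_days_shares, initiator_summary

__all__ = ["PipelineConfig", "run_pipeline", "validate_inputs"]

_ATC_RE = re.compile(r"^[A-Z]\d{2}([A-Z]([A-Z](\d{2}(\(P\))?)?)?)?$")
_ICD_RE = re.compile(r"^[A-Z]\d{2}(\.\d{1,2})?$")


@dataclass
class PipelineConfig:
    """Thresholds of every stage, defaulting to the reference values."""

    gap_days: int = 90
    rapid_gap_days: int = 90
    rapid_pre_days: int = 90
    nonswitcher_days: int = 180
    pre_window_days: int = 90
    post_window_days: int = 90
    lookback_days: int = 730
    dosage_bounds: tuple = (0.3, 6.0)
    age_bounds: tuple = (15, 55)
    bmi_bounds: tuple = (14.0, 43.0)
    bonferroni_m: int = 15
    study_end: str = "2022-12-31"
    risk_index_year: int = 2022
    registry_path: Optional[str] = None
    seed: int = 0
    simulate_n: Optional[int] = None
    input_dir: Optional[str] = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path) -> int:
    out = df.copy()
    for col in out.columns:
        if pd.api.types.is_datetime64_any_dtype(out[col]):
            out[col] = out[col].dt.strftime("%Y-%m-%d")
        elif out[col].dtype == object:
            out[col] = out[col].map(
                lambda v: ";".join(ts.strftime("%Y-%m-%d") for ts in v) if isinstance(v, tuple) else v
            )
    out.to_csv(path, sep="\t", index=False)
    return len(out)


def run_pipeline(
    outdir: str | Path,
    config: Optional[PipelineConfig] = None,
    cohort: Optional[SimulatedCohort] = None,
    catalog: Optional[FormulationCatalog] = None,
) -> dict:
    """Run every stage and write all outputs under ``outdir``.

    Input comes from ``cohort``, from ``config.input_dir`` (tables written
    by :meth:`SimulatedCohort.to_dir` or of the same shape), or — when
    ``config.simulate_n`` is set — from a fresh simulation.
    Returns the manifest dict.
    """
    config = config or PipelineConfig()
    catalog = catalog or default_catalog()
    registry = (
        CodeRegistry.from_path(config.registry_path) if config.registry_path else default_registry()
    )
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if cohort is None:
        if config.simulate_n is not None:
            cohort = simulate_cohort(
                SimulationConfig(n_participants=config.simulate_n, seed=config.seed)
            )
        elif config.input_dir is not None:
            violations = [v for v in validate_inputs(config.input_dir) if not v.startswith("warning:")]
            if violations:
                raise ValueError("input validation failed:\n" + "\n".join(violations))
            cohort = SimulatedCohort.from_dir(config.input_dir)
        else:
            raise ValueError("provide a cohort, an input_dir, or simulate_n")

    study_end = pd.Timestamp(config.study_end)
    counts: dict[str, int] = {}

    prepared = prepare_purchases(
        cohort.purchases, cohort.participants, cohort.bmi,
        catalog=catalog, registry=registry,
        dosage_bounds=tuple(config.dosage_bounds),
        age_bounds=tuple(config.age_bounds),
        bmi_bounds=tuple(config.bmi_bounds),
    )
    counts["purchases_prepared"] = _write(prepared.purchases, outdir / "purchases_prepared.tsv")
    (outdir / "filter_report.json").write_text(prepared.report.to_json())

    raw_periods = build_periods(
        prepared.purchases, catalog, gap_days=config.gap_days,
        study_end=study_end, participants=prepared.participants,
    )
    periods = censor_by_pregnancy(raw_periods, cohort.diagnoses, registry=registry)
    counts["periods"] = _write(periods, outdir / "periods.tsv")

    classifications = classify_cohort(
        periods, cohort.diagnoses, study_end=study_end,
        rapid_gap_days=config.rapid_gap_days,
        rapid_pre_days=config.rapid_pre_days,
        nonswitcher_days=config.nonswitcher_days,
    )
    counts["classifications"] = _write(
        classification_table(classifications), outdir / "classifications.tsv"
    )
    counts["classification_summary"] = _write(
        cohort_classification_summary(classifications), outdir / "classification_summary.tsv"
    )
    counts["rapid_switch_flows"] = _write(
        extract_rapid_switch_flows(classifications), outdir / "rapid_switch_flows.tsv"
    )

    counts["prevalence"] = _write(
        annual_prevalence(periods, prepared.participants, catalog=catalog),
        outdir / "prevalence.tsv",
    )
    counts["covered_days_shares"] = _write(
        covered_days_shares(periods, catalog, participants=prepared.participants),
        outdir / "covered_days_shares.tsv",
    )
    firsts = first_usage_periods(periods)
    init = initiator_summary(firsts, prepared.participants, cohort.bmi, catalog=catalog)
    (outdir / "initiator_summary.json").write_text(
        json.dumps(
            {k: v for k, v in init.items() if k != "hc_type_shares_by_year"}, indent=2, default=str
        )
    )
    counts["initiator_type_shares"] = _write(
        init["hc_type_shares_by_year"], outdir / "initiator_type_shares.tsv"
    )

    dx_by_pid = dict(tuple(cohort.diagnoses.groupby("participant_id"))) if len(cohort.diagnoses) else {}
    pre_rows = []
    for r in firsts.itertuples(index=False):
        codes, no_record = pre_initiation_diagnoses(
            {"start_date": r.start_date},
            dx_by_pid.get(r.participant_id, cohort.diagnoses.iloc[0:0]),
            window_days=config.pre_window_days,
        )
        pre_rows.append(
            {
                "participant_id": r.participant_id,
                "codes": ";".join(sorted(codes)),
                "no_medical_condition_record": no_record,
            }
        )
    counts["pre_initiation"] = _write(pd.DataFrame(pre_rows), outdir / "pre_initiation.tsv")

    counts["abortion_overlap"] = _write(
        abortion_overlap(raw_periods, cohort.diagnoses, registry=registry),
        outdir / "abortion_overlap.tsv",
    )
    counts["thrombosis_during_use"] = _write(
        thrombosis_during_use(periods, cohort.diagnoses, cohort.purchases, registry=registry),
        outdir / "thrombosis_during_use.tsv",
    )

    # risk-factor stage (only meaningful when both groups are populated)
    risk_outputs = {}
    profiles = index_year_groups(prepared.purchases, config.risk_index_year, catalog=catalog)
    if profiles:
        parts = cohort.participants.set_index("participant_id")
        bmi_by_pid = dict(tuple(cohort.bmi.groupby("participant_id"))) if len(cohort.bmi) else {}
        purch_by_pid = dict(tuple(cohort.purchases.groupby("participant_id")))
        rel_map: dict = {}
        for r in cohort.relatives.itertuples(index=False):
            rel_map.setdefault(r.participant_id, []).append(r.relative_id)
        for prof in profiles:
            pid = prof.participant_id
            rel_dx = pd.concat(
                [dx_by_pid.get(rid, cohort.diagnoses.iloc[0:0]) for rid in rel_map.get(pid, [])],
                ignore_index=True,
            ) if rel_map.get(pid) else cohort.diagnoses.iloc[0:0]
            assess_risk_factors(
                prof,
                dx_by_pid.get(pid, cohort.diagnoses.iloc[0:0]),
                purch_by_pid.get(pid, cohort.purchases.iloc[0:0]),
                parts.loc[pid],
                relative_diagnoses=rel_dx,
                bmi_records=bmi_by_pid.get(pid),
                registry=registry,
                lookback_days=config.lookback_days,
            )
        groups = {p.group for p in profiles}
        if {"CHC", "POC"} <= groups:
            counts["risk_factor_table"] = _write(
                factor_prevalence_comparison(profiles, m=config.bonferroni_m),
                outdir / "risk_factor_table.tsv",
            )
        assoc = carrier_thrombosis_association(cohort.participants, cohort.diagnoses, registry=registry)
        risk_outputs["carrier_thrombosis"] = {
            "table": vars(assoc["table"]),
            "odds_ratio": None if assoc["odds_ratio"] is None else list(assoc["odds_ratio"]),
            "carrier_breakdown": assoc["carrier_breakdown"],
        }
        (outdir / "association_tables.json").write_text(json.dumps(risk_outputs, indent=2, default=str))

    manifest = {
        "package_version": __version__,
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "row_counts": counts,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


_EXPECTED_COLUMNS = {
    "participants": ["participant_id", "birth_year"],
    "bmi": ["participant_id", "date", "bmi"],
    "relatives": ["participant_id", "relative_id"],
    "purchases": ["participant_id", "purchase_date", "prescribed_atc", "purchased_atc", "dosage"],
    "diagnoses": ["participant_id", "date", "icd10"],
}


def validate_inputs(input_dir: str | Path) -> list[str]:
    """Schema report: missing tables/columns, unparseable dates, malformed
    ATC or ICD-10 codes (with offending row numbers). Empty list = clean."""
    input_dir = Path(input_dir)
    violations: list[str] = []
    for name, cols in _EXPECTED_COLUMNS.items():
        path = input_dir / f"{name}.tsv"
        if not path.exists():
            violations.append(f"{name}: missing file {path}")
            continue
        df = pd.read_csv(path, sep="\t")
        for col in cols:
            if col not in df.columns:
                violations.append(f"{name}: missing column {col!r}")
        for col in ("date", "purchase_date"):
            if col in df.columns:
                parsed = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
                for idx in df.index[parsed.isna() & df[col].notna()][:10]:
                    violations.append(f"{name}: row {idx}: unparseable {col} {df.loc[idx, col]!r}")
        if name == "purchases":
            for col in ("prescribed_atc", "purchased_atc"):
                if col not in df.columns:
                    continue
                for idx, code in df[col].dropna().items():
                    code_u = str(code).strip().upper()
                    if not _ATC_RE.match(code_u):
                        violations.append(f"purchases: row {idx}: malformed ATC {code!r}")
                    elif len(code_u.replace("(P)", "")) < 7:
                        violations.append(f"warning: purchases: row {idx}: ATC {code!r} is not level 5")
        if name == "diagnoses" and "icd10" in df.columns:
            for idx, code in df["icd10"].dropna().items():
                if not _ICD_RE.match(str(code).strip().upper()):
                    violations.append(f"diagnoses: row {idx}: malformed ICD-10 {code!r}")
    return violations
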