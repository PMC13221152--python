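"""Synthetic cohort generator.

Generates linked participant / BMI / relative / purchase / diagnosis
tables with the statistical structure the analysis pipeline assumes, so
every downstream stage is testable without access-restricted biobank
data.  The generator emulates:

* per-formulation purchase streams realising one of five switching
  archetypes per participant — non-switcher, broad switcher, rapid
  switcher, rapid discontinuer, and an "other" stream that satisfies none
  of the label definitions (a single 91-180-day period).  Streams are
  constructed so the pipeline's classification recovers the sampled
  archetype exactly, including after pregnancy censoring;
* pregnancy interruptions: ICD-10 O-codes planted inside coverage
  intervals (plus a small rate of out-of-coverage abortion codes);
* Hardy-Weinberg genotypes at the Factor V Leiden (rs6025, MAF 0.02) and
  prothrombin G20210A (rs1799963, MAF 0.01) sites, and thromboembolism
  diagnoses whose odds are multiplied for carriers to hit a target odds
  ratio (default 1.6 against a 4.2% non-carrier baseline);
* symmetric first-degree-relative links between cohort members;
* corrupted records mirroring the exclusion classes of the filtering
  cascade (non-HC/emergency codes, prescribed/purchased ATC mismatch,
  out-of-range dosage, out-of-range age at purchase, out-of-range BMI),
  planted as *extra* labelled rows in a side table so the clean streams
  are untouched and the filters must rediscover them.

Default rates echo the reference analysis: the archetype mix
(23.9 / 46.5 / 17.7 / 7.3 / 4.6%), the corruption fractions (1.8% ATC
mismatch, 0.04% dosage, 0.1% age, 1.1% of individuals BMI), a 3.2%
pregnancy-overlap rate, and a 23.1% side-effect-diagnosis rate in the
rapid-switch gap.

One integer seed drives named substreams (demographics, purchases,
genetics, diagnoses, corruption), so adding draws to one stream never
perturbs the others, and identical configurations reproduce byte-identical
tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .catalog import FormulationCatalog, IUD_DOSE_DAYS, default_catalog

__all__ = ["SimulationConfig", "SimulatedCohort", "simulate_cohort", "make_fixture", "FIXTURE_NAMES"]

EPOCH = pd.Timestamp("2004-01-01")
STUDY_END = pd.Timestamp("2022-12-31")
H = (STUDY_END - EPOCH).days  # last valid day offset

ARCHETYPES = ("non_switcher", "broad_switcher", "rapid_switcher", "rapid_discontinuer", "other")

_BENIGN_CODES = ("Z00", "J06", "M54", "K29", "R10", "H52", "Z01")
_PREGNANCY_CODES = ("O02", "O03", "O04", "O20", "O26", "O80")
_VTE_CODES = ("I80", "I80.2", "I26.9", "I80.3", "I82.8")
_VTE_WEIGHTS = np.array([330, 212, 130, 125, 78], dtype=float)
_SIDE_EFFECT_CODES = ("N92", "G43", "L70", "N94", "F32", "F41", "N64.4")
_SIDE_EFFECT_WEIGHTS = np.array([556, 233, 180, 147, 140, 93, 28], dtype=float)
_IUD_LABELS = ("52 mg", "19.5 mg", "13.5 mg")
_IUD_LABEL_P = np.array([0.7, 0.15, 0.15])


@dataclass(frozen=True)
class SimulationConfig:
    n_participants: int = 1000
    seed: int = 0
    archetype_mix: dict = field(
        default_factory=lambda: {
            "non_switcher": 0.239,
            "broad_switcher": 0.465,
            "rapid_switcher": 0.177,
            "rapid_discontinuer": 0.073,
            "other": 0.046,
        }
    )
    fvl_maf: float = 0.02
    ptm_maf: float = 0.01
    carrier_thrombosis_or: float = 1.6
    baseline_thrombosis_risk: float = 0.042
    pregnancy_rate: float = 0.032
    out_of_coverage_abortion_rate: float = 0.01
    side_effect_rate: float = 0.231
    relative_fraction: float = 0.6
    missing_genotype_rate: float = 0.01
    background_dx_rate: float = 1.5       # Poisson mean of unrelated codes
    antithrombotic_rate: float = 0.3      # B01A purchase after a thrombosis event
    # corruption rates (planted violation rows / individuals)
    atc_mismatch_rate: float = 0.018
    bad_dosage_rate: float = 0.0004
    bad_age_rate: float = 0.001
    bad_bmi_rate: float = 0.011
    non_hc_rate: float = 0.004            # non-HC + emergency-contraceptive rows
    study_start: pd.Timestamp = EPOCH
    study_end: pd.Timestamp = STUDY_END

    def validate(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        probs = np.array([self.archetype_mix.get(a, 0.0) for a in ARCHETYPES])
        if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("archetype_mix must be non-negative and sum to 1")
        for maf in (self.fvl_maf, self.ptm_maf):
            if not 0 < maf < 0.5:
                raise ValueError("minor-allele frequencies must be in (0, 0.5)")
        if self.carrier_thrombosis_or <= 0:
            raise ValueError("carrier_thrombosis_or must be positive")
        if not 0 < self.baseline_thrombosis_risk < 1:
            raise ValueError("baseline_thrombosis_risk must be in (0, 1)")


@dataclass
class SimulatedCohort:
    participants: pd.DataFrame
    bmi: pd.DataFrame
    relatives: pd.DataFrame
    purchases: pd.DataFrame
    diagnoses: pd.DataFrame
    corruption: pd.DataFrame
    config: Optional[SimulationConfig] = None

    _TABLES = ("participants", "bmi", "relatives", "purchases", "diagnoses", "corruption")

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in self._TABLES:
            df = getattr(self, name).copy()
            for col in df.columns:
                if pd.api.types.is_datetime64_any_dtype(df[col]):
                    df[col] = df[col].dt.strftime("%Y-%m-%d")
            df.to_csv(path / f"{name}.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, path: str | Path) -> "SimulatedCohort":
        path = Path(path)
        frames = {}
        date_cols = {"purchase_date", "date"}
        for name in cls._TABLES:
            df = pd.read_csv(path / f"{name}.tsv", sep="\t")
            for col in df.columns:
                if col in date_cols:
                    df[col] = pd.to_datetime(df[col])
            frames[name] = df
        return cls(**frames)


def _streams(seed: int) -> dict[str, np.random.Generator]:
    names = ("demographics", "purchases", "genetics", "diagnoses", "corruption")
    return {
        name: np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(i,)))
        for i, name in enumerate(names)
    }


def _pick(rng, pool, weights, size=None, replace=True):
    idx = rng.choice(len(pool), size=size, replace=replace, p=weights)
    if size is None:
        return pool[idx]
    return [pool[i] for i in idx]


def _stream_non_switcher(rng, spec, dpu):
    if spec.duration_class == "long_acting":
        label = _pick(rng, _IUD_LABELS, _IUD_LABEL_P) if spec.atc5 == "G02BA03" else None
        cd = IUD_DOSE_DAYS[label] if label else 1095
        purchases = [(0, spec, 1.0, label)]
        periods = [(0, cd - 1)]
        return purchases, periods
    days, dosages = [0], [int(rng.integers(1, 4))]
    while days[-1] - days[0] <= 185:
        days.append(days[-1] + int(rng.integers(21, 80)))
        dosages.append(int(rng.integers(1, 4)))
    purchases = [(d, spec, float(k), None) for d, k in zip(days, dosages)]
    periods = [(0, days[-1] + dosages[-1] * dpu - 1)]
    return purchases, periods


def _stream_segment(rng, spec, dpu, t0, min_span=None, extra_range=(1, 4)):
    days, dosages = [t0], [int(rng.integers(1, 3))]
    if min_span is not None:
        while days[-1] - days[0] < min_span:
            days.append(days[-1] + int(rng.integers(40, 80)))
            dosages.append(int(rng.integers(1, 3)))
    else:
        for _ in range(int(rng.integers(*extra_range)) - 1):
            days.append(days[-1] + int(rng.integers(30, 80)))
            dosages.append(int(rng.integers(1, 3)))
    purchases = [(d, spec, float(k), None) for d, k in zip(days, dosages)]
    end = days[-1] + dosages[-1] * dpu - 1
    return purchases, (days[0], end), days[-1]


def _stream_broad(rng, specs, dpus):
    purchases, periods = [], []
    t = 0
    for j, (spec, dpu) in enumerate(zip(specs, dpus)):
        final = j == len(specs) - 1
        seg, period, last_day = _stream_segment(
            rng, spec, dpu, t, min_span=None if final else 95
        )
        purchases += seg
        periods.append(period)
        t = last_day + int(rng.integers(100, 161))
    return purchases, periods


def _stream_rapid(rng, specs, dpus):
    (spec_a, spec_b), (dpu_a, dpu_b) = specs, dpus
    dos_a = int(rng.integers(1, 3))
    cd_a = dos_a * dpu_a                       # <= 70 days, always < 90
    g = int(rng.integers(0, 90))               # inter-period gap g + 1 in [1, 90]
    purchases = [(0, spec_a, float(dos_a), None)]
    periods = [(0, cd_a - 1)]
    seg, period, _ = _stream_segment(rng, spec_b, dpu_b, cd_a + g)
    purchases += seg
    periods.append(period)
    return purchases, periods


def _stream_discontinuer(rng, spec, dpu):
    dos = int(rng.integers(1, 4))
    if dos * dpu >= 90:
        dos = 2
    cd = dos * dpu
    return [(0, spec, float(dos), None)], [(0, cd - 1)]


def _stream_other(rng, spec, dpu):
    cd = dpu
    gap = int(rng.integers(91 - cd, 86))       # merged period of 91-120 days
    purchases = [(0, spec, 1.0, None), (gap, spec, 1.0, None)]
    return purchases, [(0, gap + cd - 1)]


def simulate_cohort(config: SimulationConfig, catalog: Optional[FormulationCatalog] = None) -> SimulatedCohort:
    """Generate a full linked synthetic cohort (deterministic given seed)."""
    config.validate()
    catalog = catalog or default_catalog()
    rng = _streams(config.seed)
    n = config.n_participants
    horizon = (pd.Timestamp(config.study_end) - EPOCH).days

    all_pool = list(catalog)
    all_w = np.array([s.n_individuals for s in all_pool], dtype=float)
    all_w /= all_w.sum()
    short_pool = [s for s in all_pool if s.is_short_acting]
    short_w = np.array([s.n_individuals for s in short_pool], dtype=float)
    short_w /= short_w.sum()

    # --- demographics ------------------------------------------------------
    d = rng["demographics"]
    archetypes = [ARCHETYPES[i] for i in d.choice(
        len(ARCHETYPES), size=n, p=[config.archetype_mix.get(a, 0.0) for a in ARCHETYPES]
    )]
    ages_at_first = np.clip(np.round(d.normal(28.0, 9.2, size=n)), 16, 50).astype(int)
    pids = [f"P{i:06d}" for i in range(n)]

    # --- genetics ----------------------------------------------------------
    g = rng["genetics"]
    fvl = g.binomial(2, config.fvl_maf, size=n).astype(float)
    ptm = g.binomial(2, config.ptm_maf, size=n).astype(float)
    missing = g.random(n) < config.missing_genotype_rate
    carrier = (fvl >= 1) | (ptm >= 1)
    fvl[missing] = np.nan
    ptm[missing] = np.nan

    # symmetric first-degree links: disjoint pairs over a shuffled subset
    m_pairs = int(config.relative_fraction * n / 2)
    order = g.permutation(n)
    rel_rows = []
    for k in range(m_pairs):
        i, j = order[2 * k], order[2 * k + 1]
        rel_rows.append({"participant_id": pids[i], "relative_id": pids[j]})
        rel_rows.append({"participant_id": pids[j], "relative_id": pids[i]})

    # --- purchase streams --------------------------------------------------
    p = rng["purchases"]
    purchase_rows: list[dict] = []
    first_day = np.empty(n, dtype=int)
    birth_year = np.empty(n, dtype=int)
    analytic_periods: list[list[tuple[int, int]]] = []
    gap_anchor: list[Optional[tuple[int, int]]] = []  # (pre 1st purchase, post 1st purchase)

    for i in range(n):
        arch = archetypes[i]
        if arch == "non_switcher":
            spec = _pick(p, all_pool, all_w)
            stream, periods = _stream_non_switcher(p, spec, spec.days_per_unit or 0)
        elif arch == "broad_switcher":
            k = int(p.integers(2, 4))
            specs = _pick(p, short_pool, short_w, size=k, replace=False)
            stream, periods = _stream_broad(p, specs, [s.days_per_unit for s in specs])
        elif arch == "rapid_switcher":
            specs = _pick(p, short_pool, short_w, size=2, replace=False)
            stream, periods = _stream_rapid(p, specs, [s.days_per_unit for s in specs])
        elif arch == "rapid_discontinuer":
            spec = _pick(p, short_pool, short_w)
            stream, periods = _stream_discontinuer(p, spec, spec.days_per_unit)
        else:
            spec = _pick(p, short_pool, short_w)
            stream, periods = _stream_other(p, spec, spec.days_per_unit)

        extent = max(end for _, end in periods) + 1
        buffer = max(extent, 130)
        start0 = int(p.integers(0, horizon - buffer + 1))
        first_day[i] = start0
        birth_year[i] = (EPOCH + pd.Timedelta(days=start0)).year - ages_at_first[i]
        analytic_periods.append([(s + start0, e + start0) for s, e in periods])
        if arch == "rapid_switcher":
            gap_anchor.append((stream[0][0] + start0, periods[1][0] + start0))
        else:
            gap_anchor.append(None)
        for day, spec_, dosage, label in stream:
            purchase_rows.append(
                {
                    "participant_id": pids[i],
                    "day": day + start0,
                    "prescribed_atc": spec_.formulation_key,
                    "purchased_atc": spec_.formulation_key,
                    "dosage": dosage,
                    "package_content": 21 if spec_.is_short_acting else 1,
                    "iud_dose_label": label,
                }
            )

    # --- BMI records -------------------------------------------------------
    bmi_rows = []
    for i in range(n):
        for _ in range(int(d.integers(1, 4))):
            day = int(np.clip(first_day[i] + d.integers(-700, 701), 0, horizon))
            value = float(np.clip(np.round(d.normal(24.3, 4.6), 1), 16.0, 40.0))
            bmi_rows.append({"participant_id": pids[i], "day": day, "bmi": value})

    # --- diagnoses ---------------------------------------------------------
    x = rng["diagnoses"]
    dx_rows = []
    for i in range(n):
        arch = archetypes[i]
        # background, unrelated codes (residency evidence; never panel codes)
        for _ in range(int(x.poisson(config.background_dx_rate))):
            dx_rows.append(
                {
                    "participant_id": pids[i],
                    "day": int(x.integers(0, horizon + 1)),
                    "icd10": _BENIGN_CODES[int(x.integers(0, len(_BENIGN_CODES)))],
                }
            )
        if arch == "rapid_discontinuer":
            day = min(first_day[i] + int(x.integers(30, 401)), horizon)
            dx_rows.append({"participant_id": pids[i], "day": day, "icd10": "Z00"})
        # pregnancy interruption inside coverage, placed so the archetype
        # definition survives censoring
        if x.random() < config.pregnancy_rate:
            periods = analytic_periods[i]
            day = None
            if arch == "non_switcher":
                s, e = periods[0]
                lo, hi = s + 181, min(e - 1, s + 1000)
                if hi >= lo:
                    day = int(x.integers(lo, hi + 1))
            elif arch in ("broad_switcher", "rapid_switcher"):
                s, e = periods[-1]
                if e >= s + 1:
                    day = int(x.integers(s + 1, e + 1))
            elif arch == "other":
                s, e = periods[0]
                if e >= s + 92:
                    day = int(x.integers(s + 92, e + 1))
            if day is not None:
                code = _PREGNANCY_CODES[int(x.integers(0, len(_PREGNANCY_CODES)))]
                dx_rows.append({"participant_id": pids[i], "day": day, "icd10": code})
        if x.random() < config.out_of_coverage_abortion_rate and first_day[i] > 10:
            day = max(0, first_day[i] - int(x.integers(10, 200)))
            dx_rows.append({"participant_id": pids[i], "day": day, "icd10": "O04"})
        # side-effect diagnosis inside the rapid-switch gap window
        if gap_anchor[i] is not None and x.random() < config.side_effect_rate:
            lo, hi = gap_anchor[i]
            code = _pick(x, _SIDE_EFFECT_CODES, _SIDE_EFFECT_WEIGHTS / _SIDE_EFFECT_WEIGHTS.sum())
            dx_rows.append(
                {"participant_id": pids[i], "day": int(x.integers(lo, hi + 1)), "icd10": code}
            )

    # thromboembolism with carrier-multiplied odds
    p0 = config.baseline_thrombosis_risk
    odds0 = p0 / (1 - p0)
    odds_c = config.carrier_thrombosis_or * odds0
    p_c = odds_c / (1 + odds_c)
    event_prob = np.where(carrier, p_c, p0)
    has_event = x.random(n) < event_prob
    vte_p = _VTE_WEIGHTS / _VTE_WEIGHTS.sum()
    anti_rows = []
    for i in np.flatnonzero(has_event):
        day = int(x.integers(0, horizon + 1))
        code = _pick(x, _VTE_CODES, vte_p)
        dx_rows.append({"participant_id": pids[i], "day": day, "icd10": code})
        if x.random() < config.antithrombotic_rate:
            aday = min(day + int(x.integers(5, 61)), horizon)
            anti_rows.append(
                {
                    "participant_id": pids[i],
                    "day": aday,
                    "prescribed_atc": "B01AF01",
                    "purchased_atc": "B01AF01",
                    "dosage": 1.0,
                    "package_content": 30,
                    "iud_dose_label": None,
                }
            )
    n_clean = len(purchase_rows)
    corruption_rows = []
    purchase_rows += anti_rows
    for k in range(len(anti_rows)):
        # antithrombotic purchases are legitimate non-HC rows; labelling
        # them lets the cascade tests assert the selection step exactly
        corruption_rows.append(
            {"purchase_id": None, "row_index": n_clean + k,
             "participant_id": anti_rows[k]["participant_id"], "kind": "non_hc_atc"}
        )

    # --- corruption: extra labelled rows -----------------------------------
    c = rng["corruption"]

    def _in_age_day(i) -> int:
        year = int(birth_year[i] + c.integers(20, 51))
        year = min(max(year, EPOCH.year), STUDY_END.year)
        day0 = (pd.Timestamp(year=year, month=1, day=1) - EPOCH).days
        return int(min(day0 + c.integers(0, 365), horizon))

    def _plant(row, kind):
        purchase_rows.append(row)
        corruption_rows.append({"purchase_id": None, "row_index": len(purchase_rows) - 1,
                                "participant_id": row["participant_id"], "kind": kind})

    for _ in range(round(config.non_hc_rate * n_clean)):
        i = int(c.integers(0, n))
        atc = "G03AD01" if c.random() < 0.5 else "N06AB03"
        _plant(
            {
                "participant_id": pids[i], "day": _in_age_day(i),
                "prescribed_atc": atc, "purchased_atc": atc,
                "dosage": 1.0, "package_content": 21, "iud_dose_label": None,
            },
            "non_hc_atc",
        )
    for _ in range(round(config.atc_mismatch_rate * n_clean)):
        i = int(c.integers(0, n))
        s1, s2 = _pick(c, short_pool, short_w, size=2, replace=False)
        _plant(
            {
                "participant_id": pids[i], "day": _in_age_day(i),
                "prescribed_atc": s1.formulation_key, "purchased_atc": s2.formulation_key,
                "dosage": float(c.integers(1, 4)), "package_content": 21, "iud_dose_label": None,
            },
            "atc_mismatch",
        )
    for _ in range(round(config.bad_dosage_rate * n_clean)):
        i = int(c.integers(0, n))
        spec = _pick(c, short_pool, short_w)
        dosage = float(_pick(c, (0.1, 0.2, 6.5, 8.0), np.full(4, 0.25)))
        _plant(
            {
                "participant_id": pids[i], "day": _in_age_day(i),
                "prescribed_atc": spec.formulation_key, "purchased_atc": spec.formulation_key,
                "dosage": dosage, "package_content": 21, "iud_dose_label": None,
            },
            "dosage_out_of_range",
        )
    feasible_young = [i for i in range(n) if birth_year[i] + 14 >= EPOCH.year]
    feasible_old = [i for i in range(n) if birth_year[i] + 56 <= STUDY_END.year]
    for _ in range(round(config.bad_age_rate * n_clean)):
        if feasible_young and (not feasible_old or c.random() < 0.5):
            i = feasible_young[int(c.integers(0, len(feasible_young)))]
            year = max(EPOCH.year, int(birth_year[i]) + int(c.integers(10, 15)))
        elif feasible_old:
            i = feasible_old[int(c.integers(0, len(feasible_old)))]
            year = min(STUDY_END.year, int(birth_year[i]) + 56)
        else:
            break
        spec = _pick(c, short_pool, short_w)
        day0 = (pd.Timestamp(year=year, month=1, day=1) - EPOCH).days
        _plant(
            {
                "participant_id": pids[i], "day": int(min(day0 + c.integers(0, 365), horizon)),
                "prescribed_atc": spec.formulation_key, "purchased_atc": spec.formulation_key,
                "dosage": float(c.integers(1, 4)), "package_content": 21, "iud_dose_label": None,
            },
            "age_out_of_range",
        )
    bmi_bad = c.choice(n, size=round(config.bad_bmi_rate * n), replace=False)
    for i in bmi_bad:
        value = 12.0 if c.random() < 0.5 else 45.0
        bmi_rows.append({"participant_id": pids[i], "day": int(first_day[i]), "bmi": value})
        corruption_rows.append(
            {"purchase_id": None, "row_index": None, "participant_id": pids[i], "kind": "bmi_out_of_range"}
        )

    # --- assemble frames ---------------------------------------------------
    def day_to_date(series):
        return EPOCH + pd.to_timedelta(series, unit="D")

    participants = pd.DataFrame(
        {
            "participant_id": pids,
            "birth_year": birth_year,
            "archetype": archetypes,
            "fvl_copies": fvl,
            "ptm_copies": ptm,
        }
    )
    purchases = pd.DataFrame(purchase_rows)
    purchases.insert(0, "purchase_id", np.arange(len(purchases)))
    purchases["purchase_date"] = day_to_date(purchases.pop("day"))
    purchases = purchases[
        ["purchase_id", "participant_id", "purchase_date", "prescribed_atc",
         "purchased_atc", "dosage", "package_content", "iud_dose_label"]
    ]
    corruption = pd.DataFrame(
        corruption_rows, columns=["purchase_id", "row_index", "participant_id", "kind"]
    )
    if len(corruption):
        with_row = corruption["row_index"].notna()
        corruption.loc[with_row, "purchase_id"] = (
            corruption.loc[with_row, "row_index"].astype(int).to_numpy()
        )
        corruption = corruption.drop(columns=["row_index"])
    else:
        corruption = corruption.drop(columns=["row_index"])

    bmi = pd.DataFrame(bmi_rows)
    bmi["date"] = day_to_date(bmi.pop("day"))
    bmi = bmi[["participant_id", "date", "bmi"]].sort_values(
        ["participant_id", "date"], kind="stable"
    ).reset_index(drop=True)

    diagnoses = pd.DataFrame(dx_rows)
    diagnoses["date"] = day_to_date(diagnoses.pop("day"))
    diagnoses = diagnoses[["participant_id", "date", "icd10"]].sort_values(
        ["participant_id", "date", "icd10"], kind="stable"
    ).reset_index(drop=True)

    relatives = pd.DataFrame(rel_rows, columns=["participant_id", "relative_id"])

    return SimulatedCohort(
        participants=participants,
        bmi=bmi,
        relatives=relatives,
        purchases=purchases,
        diagnoses=diagnoses,
        corruption=corruption,
        config=config,
    )


# ---------------------------------------------------------------------------
# hand-built micro-fixtures with worked-by-hand expectations

FIXTURE_NAMES = (
    "pregnancy_censor",
    "gap_merge_89_days",
    "gap_split_90_days",
    "switch_truncation",
    "mixed_five_users",
)


def _tiny(purchases, diagnoses=None, participants=None, bmi=None):
    purch = pd.DataFrame(
        purchases,
        columns=["participant_id", "purchase_date", "purchased_atc", "dosage", "iud_dose_label"],
    )
    purch["purchase_date"] = pd.to_datetime(purch["purchase_date"])
    purch["prescribed_atc"] = purch["purchased_atc"]
    purch["package_content"] = 21
    purch.insert(0, "purchase_id", np.arange(len(purch)))
    dx = pd.DataFrame(diagnoses or [], columns=["participant_id", "date", "icd10"])
    if len(dx):
        dx["date"] = pd.to_datetime(dx["date"])
    parts = pd.DataFrame(
        participants or [{"participant_id": pid, "birth_year": 1985, "fvl_copies": 0.0, "ptm_copies": 0.0}
                         for pid in purch["participant_id"].unique()]
    )
    bmi_df = pd.DataFrame(bmi or [], columns=["participant_id", "date", "bmi"])
    if len(bmi_df):
        bmi_df["date"] = pd.to_datetime(bmi_df["date"])
    return SimulatedCohort(
        participants=parts,
        bmi=bmi_df,
        relatives=pd.DataFrame(columns=["participant_id", "relative_id"]),
        purchases=purch,
        diagnoses=dx,
        corruption=pd.DataFrame(columns=["purchase_id", "participant_id", "kind"]),
    )


def make_fixture(name: str) -> SimulatedCohort:
    """Hand-built micro-datasets with worked-by-hand expected results."""
    if name == "pregnancy_censor":
        # one 84-day period [2010-01-01, 2010-03-25]; O03 on 2010-02-01
        return _tiny(
            [("F1", "2010-01-01", "G03AA12", 3.0, None)],
            diagnoses=[("F1", "2010-02-01", "O03")],
        )
    if name == "gap_merge_89_days":
        return _tiny(
            [
                ("F1", "2010-01-01", "G03AA12", 1.0, None),
                ("F1", "2010-03-31", "G03AA12", 1.0, None),  # 89 days later
            ]
        )
    if name == "gap_split_90_days":
        return _tiny(
            [
                ("F1", "2010-01-01", "G03AA12", 1.0, None),
                ("F1", "2010-04-01", "G03AA12", 1.0, None),  # 90 days later
            ]
        )
    if name == "switch_truncation":
        # COC then POP 10 days later: COC period truncated to 9 days
        return _tiny(
            [
                ("F1", "2010-01-01", "G03AA12", 3.0, None),
                ("F1", "2010-01-11", "G03AC09", 1.0, None),
            ]
        )
    if name == "mixed_five_users":
        # U1 non-switcher (224 d), U2 broad (two formulations, slow),
        # U3 rapid (28 d pre-period, 11-day gap), U4 rapid discontinuer
        # (28 d, verified), U5 unclassified (112 d single period)
        return _tiny(
            [
                ("U1", "2010-01-01", "G03AA10", 3.0, None),
                ("U1", "2010-03-01", "G03AA10", 5.0, None),
                ("U2", "2011-01-01", "G03AA12", 6.0, None),
                ("U2", "2012-01-01", "G02BB01", 6.0, None),
                ("U3", "2012-01-01", "G03AA16", 1.0, None),
                ("U3", "2012-02-08", "G03AC09", 2.0, None),
                ("U4", "2013-01-01", "G03AA09", 1.0, None),
                ("U5", "2014-01-01", "G03HB01", 1.0, None),
                ("U5", "2014-03-26", "G03HB01", 1.0, None),
            ],
            diagnoses=[("U4", "2013-06-01", "Z00")],
        )
    raise KeyError(f"unknown fixture {name!r}; known: {FIXTURE_NAMES}")
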