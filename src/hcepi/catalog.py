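"""Catalog of prescribed hormonal-contraceptive formulations.

The catalog maps ATC level-5 codes to a formulation's hormonal composition
(progestin-only vs. progestin + estrogen), administration route, duration
class and contraceptive-method type, and carries the per-purchase coverage
rule used to turn pharmacy purchases into covered days:

* short-acting methods (pills, patches, rings) cover ``days_per_unit`` days
  per purchased package unit — 28 days, except the levonorgestrel-only pill
  G03AC03 which covers 35;
* the etonogestrel implant (G03AC08) covers 1,095 days (3 years) per
  insertion regardless of the invoiced dosage;
* the levonorgestrel-releasing IUD (G02BA03) covers 1,095 / 1,835 / 2,190
  days for the 13.5 mg / 19.5 mg / 52 mg products (3, 5, 6 years).

One ATC code, G03AA10 (gestodene/ethinylestradiol), was marketed both as an
oral pill and as a transdermal patch; the catalog is therefore keyed by
``(atc5, route)``, and the conventional suffixed spelling ``"G03AA10(p)"``
is accepted anywhere a code is taken as input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterator, Optional

import pandas as pd

__all__ = [
    "FormulationSpec",
    "FormulationCatalog",
    "CatalogMissError",
    "default_catalog",
    "lookup_formulation",
    "covered_days",
    "coc_generation_group",
    "IUD_ATC",
    "IMPLANT_ATC",
    "IUD_DOSE_DAYS",
    "IMPLANT_DAYS",
    "COC_TYPES",
]

IUD_ATC = "G02BA03"
IMPLANT_ATC = "G03AC08"
IMPLANT_DAYS = 1095
#: LNG-IUD dose label -> covered days (3, 5 or 6 years).
IUD_DOSE_DAYS = {"13.5 mg": 1095, "19.5 mg": 1835, "52 mg": 2190}

COC_TYPES = frozenset(
    {"COC_2nd_gen", "COC_3rd_gen", "COC_4th_gen", "COC_anti_androgenic", "COC_estradiol"}
)

_ROUTES = ("oral", "transdermal", "intravaginal", "intrauterine", "subdermal")
_HC_CLASSES = ("CHC", "POC")


class CatalogMissError(KeyError):
    """Raised when a well-formed ATC code is not in the formulation catalog."""


@dataclass(frozen=True)
class FormulationSpec:
    """One catalog row: a marketed hormonal-contraceptive formulation."""

    atc5: str
    route: str
    abbreviation: str
    formulation_name: str
    components: str          # "progestin_only" | "progestin_estrogen"
    duration_class: str      # "short_acting" | "long_acting"
    hc_type: str
    hc_class: str            # "CHC" | "POC"
    days_per_unit: Optional[int]
    n_individuals: int = 0
    n_purchases: int = 0

    @property
    def formulation_key(self) -> str:
        """Stable identity string; the patch variant is suffixed ``(p)``."""
        if self.atc5 == "G03AA10" and self.route == "transdermal":
            return "G03AA10(p)"
        return self.atc5

    @property
    def is_short_acting(self) -> bool:
        return self.duration_class == "short_acting"

    @property
    def is_coc(self) -> bool:
        return self.hc_type in COC_TYPES


def _normalise_code(atc5: str) -> tuple[str, Optional[str]]:
    """Return (bare code, forced route) handling the ``(p)`` patch suffix."""
    if not isinstance(atc5, str) or not atc5.strip():
        raise ValueError("ATC code must be a non-empty string")
    code = atc5.strip().upper()
    if code.endswith("(P)"):
        return code[:-3], "transdermal"
    return code, None


class FormulationCatalog:
    """The 21-entry formulation catalog, keyed by ``(atc5, route)``.

    A bare ambiguous code (currently only ``G03AA10``) resolves to the oral
    product; the patch is addressed as ``"G03AA10(p)"`` or with an explicit
    ``route``.
    """

    def __init__(self, frame: pd.DataFrame):
        required = {
            "atc5", "route", "abbreviation", "formulation_name", "components",
            "duration_class", "hc_type", "hc_class", "days_per_unit",
        }
        missing = required - set(frame.columns)
        if missing:
            raise ValueError(f"catalog file missing columns: {sorted(missing)}")
        self._frame = frame.reset_index(drop=True)
        self._entries: dict[tuple[str, str], FormulationSpec] = {}
        self._by_code: dict[str, list[FormulationSpec]] = {}
        for row in frame.itertuples(index=False):
            dpu = None if pd.isna(row.days_per_unit) else int(row.days_per_unit)
            spec = FormulationSpec(
                atc5=row.atc5,
                route=row.route,
                abbreviation=row.abbreviation,
                formulation_name=row.formulation_name,
                components=row.components,
                duration_class=row.duration_class,
                hc_type=row.hc_type,
                hc_class=row.hc_class,
                days_per_unit=dpu,
                n_individuals=int(getattr(row, "n_individuals", 0) or 0),
                n_purchases=int(getattr(row, "n_purchases", 0) or 0),
            )
            self._validate(spec)
            key = (spec.atc5, spec.route)
            if key in self._entries:
                raise ValueError(f"duplicate catalog key {key}")
            self._entries[key] = spec
            self._by_code.setdefault(spec.atc5, []).append(spec)

    @staticmethod
    def _validate(spec: FormulationSpec) -> None:
        if spec.route not in _ROUTES:
            raise ValueError(f"unknown route {spec.route!r} for {spec.atc5}")
        if spec.hc_class not in _HC_CLASSES:
            raise ValueError(f"unknown hc_class {spec.hc_class!r} for {spec.atc5}")
        # POC iff progestin-only; long-acting iff intrauterine/subdermal.
        if (spec.hc_class == "POC") != (spec.components == "progestin_only"):
            raise ValueError(f"hc_class/components mismatch for {spec.atc5}")
        long_route = spec.route in ("intrauterine", "subdermal")
        if (spec.duration_class == "long_acting") != long_route:
            raise ValueError(f"duration_class/route mismatch for {spec.atc5}")
        if spec.is_short_acting:
            expected = 35 if spec.atc5 == "G03AC03" else 28
            if spec.days_per_unit != expected:
                raise ValueError(
                    f"short-acting {spec.atc5} must cover {expected} days/unit"
                )

    # -- construction ----------------------------------------------------
    @classmethod
    def default(cls) -> "FormulationCatalog":
        with resources.files("hcepi.data").joinpath("formulations.tsv").open() as fh:
            return cls(pd.read_csv(fh, sep="\t"))

    @classmethod
    def from_path(cls, path: str | Path) -> "FormulationCatalog":
        return cls(pd.read_csv(path, sep="\t"))

    def to_frame(self) -> pd.DataFrame:
        return self._frame.copy()

    # -- queries ---------------------------------------------------------
    def lookup(self, atc5: str, route: Optional[str] = None) -> FormulationSpec:
        code, forced = _normalise_code(atc5)
        route = forced or route
        if route is not None:
            spec = self._entries.get((code, route))
            if spec is None:
                raise CatalogMissError(f"{code} (route={route}) not in catalog")
            return spec
        candidates = self._by_code.get(code)
        if not candidates:
            raise CatalogMissError(f"{code} not in catalog")
        if len(candidates) == 1:
            return candidates[0]
        for spec in candidates:       # ambiguous bare code -> oral product
            if spec.route == "oral":
                return spec
        return candidates[0]

    def __contains__(self, atc5: str) -> bool:
        try:
            self.lookup(atc5)
            return True
        except (CatalogMissError, ValueError):
            return False

    def __len__(self) -> int:
        return len(self._entries)

    def __iter__(self) -> Iterator[FormulationSpec]:
        return iter(self._entries.values())

    def covered_days(
        self,
        atc5: str,
        dosage: float,
        iud_dose_label: Optional[str] = None,
        route: Optional[str] = None,
    ) -> int:
        """Covered days for one purchase.

        Short-acting: ``round(dosage * days_per_unit)`` (half away from
        zero).  Implant: 1,095 days regardless of dosage.  LNG-IUD: mapped
        from the dose label; the label is required for IUD purchases.
        """
        spec = self.lookup(atc5, route=route)
        if not (isinstance(dosage, (int, float)) and dosage > 0):
            raise ValueError(f"dosage must be positive, got {dosage!r}")
        if spec.atc5 == IUD_ATC:
            if iud_dose_label is None:
                raise ValueError("iud_dose_label is required for LNG-IUD purchases")
            try:
                return IUD_DOSE_DAYS[iud_dose_label]
            except KeyError:
                raise ValueError(f"unknown LNG-IUD dose label {iud_dose_label!r}") from None
        if spec.atc5 == IMPLANT_ATC:
            return IMPLANT_DAYS
        return int(math.floor(dosage * spec.days_per_unit + 0.5))

    def coc_generation_group(self, atc5: str, route: Optional[str] = None) -> str:
        """Progestin-generation group of a combined oral contraceptive."""
        spec = self.lookup(atc5, route=route)
        if not spec.is_coc:
            raise ValueError(f"{spec.formulation_key} is not a combined oral contraceptive")
        return spec.hc_type


_DEFAULT: Optional[FormulationCatalog] = None


def default_catalog() -> FormulationCatalog:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = FormulationCatalog.default()
    return _DEFAULT


def lookup_formulation(atc5: str, route: Optional[str] = None) -> FormulationSpec:
    return default_catalog().lookup(atc5, route=route)


def covered_days(
    atc5: str, dosage: float, iud_dose_label: Optional[str] = None, route: Optional[str] = None
) -> int:
    return default_catalog().covered_days(atc5, dosage, iud_dose_label, route=route)


def coc_generation_group(atc5: str, route: Optional[str] = None) -> str:
    return default_catalog().coc_generation_group(atc5, route=route)
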