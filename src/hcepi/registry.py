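"""Named ICD-10 code sets and ATC prefix groups.

Diagnosis phenotyping throughout the pipeline is driven by a
:class:`CodeRegistry`: a collection of named code sets (pregnancy codes,
HC-initiation reasons, the side-effect panel, venous/arterial
thromboembolism codes, thrombosis risk conditions) plus ATC prefix groups
(HC selection, risk-increasing medications, antithrombotics).

Matching semantics: a three-character entry such as ``N92`` matches the
category and every subcode (``N92.0``); a subcategory entry such as
``E28.2`` matches exactly.  Ranges are inclusive over the three-character
category ordering (``O00``–``O99``), with optional excluded sub-ranges
(``O85``–``O92``).  The shipped defaults can be replaced wholesale or per
set from a YAML file of the same shape, which changes only membership
decisions — window logic lives elsewhere.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import yaml

__all__ = ["CodeSet", "CodeRegistry", "default_registry", "normalise_icd10", "atc_matches"]

_ICD_RE = re.compile(r"^[A-Z]\d{2}(\.\d{1,2})?$")


def normalise_icd10(code: str) -> str:
    """Upper-case, strip, and restore the dot of a four-character subcode."""
    c = str(code).strip().upper()
    if len(c) > 3 and c[3] != ".":
        c = c[:3] + "." + c[3:]
    return c


def _category(code: str) -> str:
    return code[:3]


@dataclass(frozen=True)
class CodeSet:
    """One named set of ICD-10 codes with prefix/exact/range semantics."""

    name: str
    exact: frozenset[str] = frozenset()       # dotted subcategory codes
    categories: frozenset[str] = frozenset()  # 3-character categories (prefix match)
    ranges: tuple[tuple[str, str], ...] = ()
    exclude_ranges: tuple[tuple[str, str], ...] = ()

    @classmethod
    def from_entries(
        cls,
        name: str,
        codes: Iterable[str] = (),
        ranges: Iterable[Iterable[str]] = (),
        exclude_ranges: Iterable[Iterable[str]] = (),
    ) -> "CodeSet":
        exact, cats = set(), set()
        for raw in codes:
            code = normalise_icd10(raw)
            if not _ICD_RE.match(code):
                raise ValueError(f"malformed ICD-10 entry {raw!r} in set {name!r}")
            (cats if len(code) == 3 else exact).add(code)
        return cls(
            name=name,
            exact=frozenset(exact),
            categories=frozenset(cats),
            ranges=tuple((lo.upper(), hi.upper()) for lo, hi in ranges),
            exclude_ranges=tuple((lo.upper(), hi.upper()) for lo, hi in exclude_ranges),
        )

    def __contains__(self, code: str) -> bool:
        c = normalise_icd10(code)
        cat = _category(c)
        for lo, hi in self.exclude_ranges:
            if lo <= cat <= hi:
                return False
        if c in self.exact or cat in self.categories:
            return True
        return any(lo <= cat <= hi for lo, hi in self.ranges)


def atc_matches(code: str, prefixes: Iterable[str]) -> bool:
    c = str(code).strip().upper()
    return any(c.startswith(p) for p in prefixes)


@dataclass
class CodeRegistry:
    code_sets: dict[str, CodeSet] = field(default_factory=dict)
    atc_prefixes: dict[str, tuple[str, ...]] = field(default_factory=dict)

    def codeset(self, name: str) -> CodeSet:
        try:
            return self.code_sets[name]
        except KeyError:
            raise KeyError(f"registry has no code set {name!r}") from None

    def contains(self, set_name: str, code: str) -> bool:
        return code in self.codeset(set_name)

    def prefixes(self, group: str) -> tuple[str, ...]:
        try:
            return self.atc_prefixes[group]
        except KeyError:
            raise KeyError(f"registry has no ATC prefix group {group!r}") from None

    def with_set(self, name: str, codeset: CodeSet) -> "CodeRegistry":
        """A copy with one code set replaced (membership-only override)."""
        sets = dict(self.code_sets)
        sets[name] = codeset
        return CodeRegistry(code_sets=sets, atc_prefixes=dict(self.atc_prefixes))

    @classmethod
    def from_mapping(cls, payload: dict) -> "CodeRegistry":
        sets = {
            name: CodeSet.from_entries(
                name,
                codes=entry.get("codes", ()),
                ranges=entry.get("ranges", ()),
                exclude_ranges=entry.get("exclude_ranges", ()),
            )
            for name, entry in payload.get("code_sets", {}).items()
        }
        prefixes = {
            group: tuple(str(p).upper() for p in values)
            for group, values in payload.get("atc_prefixes", {}).items()
        }
        return cls(code_sets=sets, atc_prefixes=prefixes)

    @classmethod
    def from_path(cls, path: str | Path) -> "CodeRegistry":
        with open(path) as fh:
            return cls.from_mapping(yaml.safe_load(fh))

    @classmethod
    def default(cls) -> "CodeRegistry":
        with resources.files("hcepi.data").joinpath("registry.yaml").open() as fh:
            return cls.from_mapping(yaml.safe_load(fh))


_DEFAULT: Optional[CodeRegistry] = None


def default_registry() -> CodeRegistry:
    global _DEFAULT
    if _DEFAULT is None:
        _DEFAULT = CodeRegistry.default()
    return _DEFAULT
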