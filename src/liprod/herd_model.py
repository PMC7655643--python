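"""Per-cow herd data model: domain types, CSV round-trip, breed codes and filters.

One observation is a cow on a sampling date (D1-D4), carrying production
(yield, fat+protein solids), health (somatic cell count, treatment count),
feeding (concentrate and conserved forage offered) and a nine-variable milk
fatty-acid profile. Breed codes follow the field convention for crossbred
dairy cattle: a purebred Jersey is ``JE``, a first cross of Jersey and
Holstein/Friesian is ``HFJE`` regardless of which parent was the sire, and a
trailing ``X`` marks a majority genetic contribution and/or a backcross
(``JEX``).
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "BREED_PRECEDENCE",
    "DATE_CODES",
    "SEASON_OF_DATE",
    "FA_DESIRABLE",
    "FA_UNDESIRABLE",
    "FA_VARIABLES",
    "LIP_VARIABLES",
    "HERD_COLUMNS",
    "FARM_COLUMNS",
    "HerdError",
    "SchemaError",
    "ValidationError",
    "VocabularyError",
    "FattyAcidProfile",
    "CowRecord",
    "BreedCode",
    "FarmInfo",
    "HerdDataset",
    "canonical_breed_code",
    "parse_breed_label",
    "read_herd_csv",
    "write_herd_csv",
    "is_complete",
    "filter_complete_records",
    "apply_inclusion_criteria",
]

# Breed vocabulary, in the fixed precedence used to order compound labels.
# HF Holstein/Friesian, NZF New Zealand Friesian, BF British/unknown Friesian,
# JE Jersey, SR Scandinavian Red, SH Shorthorn, AYR Ayrshire, MO Montbelliarde,
# BS Brown Swiss, MRI Meuse Rhine Issel, XX unknown crossbred composition.
BREED_PRECEDENCE: tuple[str, ...] = (
    "HF", "NZF", "BF", "JE", "SR", "SH", "AYR", "MO", "BS", "MRI", "XX",
)
_BREED_RANK = {b: i for i, b in enumerate(BREED_PRECEDENCE)}

DATE_CODES: tuple[str, ...] = ("D1", "D2", "D3", "D4")
SEASON_OF_DATE: dict[str, str] = {
    "D1": "autumn-2011",
    "D2": "spring-2012",
    "D3": "summer-2012",
    "D4": "autumn-2012",
}

# The nine scored fatty-acid variables (% of total FA except the ratio).
FA_DESIRABLE: tuple[str, ...] = ("oa_pct", "cla9_pct", "n3_pct", "epa_dpa_dha_pct")
FA_UNDESIRABLE: tuple[str, ...] = ("c12_pct", "c14_pct", "c16_pct", "n6_pct", "n6_n3_ratio")
FA_VARIABLES: tuple[str, ...] = FA_DESIRABLE + FA_UNDESIRABLE

#: The 13 variables defining low-input production (LI-P).
LIP_VARIABLES: tuple[str, ...] = (
    "yield_l_day", "solids_kg_day", "scc_kcells_ml", "treatments_n",
) + FA_VARIABLES

HERD_COLUMNS: tuple[str, ...] = (
    "cow_id", "farm_id", "management", "date_code", "breed_code",
    "sire_breed", "dam_breed", "generation", "days_in_milk",
    "yield_l_day", "solids_kg_day", "scc_kcells_ml", "treatments_n",
    "concentrate_kg_day", "forage_kg_day",
    "oa_pct", "cla9_pct", "n3_pct", "epa_dpa_dha_pct",
    "c12_pct", "c14_pct", "c16_pct", "n6_pct", "n6_n3_ratio",
)
FARM_COLUMNS: tuple[str, ...] = (
    "farm_id", "management", "n_cows", "calving_pattern", "breeds",
)


class HerdError(ValueError):
    """Base class for herd data errors."""


class SchemaError(HerdError):
    """CSV header does not match the documented schema."""


class ValidationError(HerdError):
    """A record violates a domain invariant."""


class VocabularyError(HerdError):
    """A breed token outside the recognized vocabulary."""


@dataclass
class FattyAcidProfile:
    """Nine scored fatty-acid variables, as % of total FA plus the n-6/n-3 ratio.

    Four are desirable in human nutrition (oleic acid, cis-9 trans-11 CLA,
    total omega-3, EPA+DPA+DHA); five are undesirable (lauric, myristic,
    palmitic, total omega-6, and the omega-6/omega-3 ratio).
    """

    oa_pct: float
    cla9_pct: float
    n3_pct: float
    epa_dpa_dha_pct: float
    c12_pct: float
    c14_pct: float
    c16_pct: float
    n6_pct: float
    n6_n3_ratio: float

    def validate(self, check_ratio: bool = False, ratio_rtol: float = 0.05) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if v is None or not math.isfinite(v) or v < 0:
                raise ValidationError(f"fatty-acid field {f.name!r} must be finite and >= 0, got {v!r}")
        pct_sum = (self.oa_pct + self.cla9_pct + self.n3_pct + self.c12_pct
                   + self.c14_pct + self.c16_pct + self.n6_pct)
        if pct_sum >= 100:
            raise ValidationError(f"non-overlapping FA percentages sum to {pct_sum:.3f} >= 100")
        if self.epa_dpa_dha_pct > self.n3_pct + 1e-9:
            raise ValidationError("epa_dpa_dha_pct cannot exceed total n3_pct")
        if check_ratio and self.n3_pct > 0:
            implied = self.n6_pct / self.n3_pct
            if not math.isclose(self.n6_n3_ratio, implied, rel_tol=ratio_rtol):
                raise ValidationError(
                    f"n6_n3_ratio {self.n6_n3_ratio:.4f} inconsistent with "
                    f"n6/n3 = {implied:.4f}"
                )

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass
class CowRecord:
    """One cow x sampling-date observation."""

    cow_id: str
    farm_id: int
    management: str            # "organic" | "low_input"
    date_code: str             # D1..D4
    breed_code: str            # canonical label, e.g. JE, HFJE, NZFX
    sire_breed: Optional[str] = None
    dam_breed: Optional[str] = None
    generation: Optional[str] = None   # purebred | F1 | F2plus
    days_in_milk: Optional[float] = None
    yield_l_day: Optional[float] = None
    solids_kg_day: Optional[float] = None
    scc_kcells_ml: Optional[float] = None
    treatments_n: Optional[int] = None
    concentrate_kg_day: Optional[float] = None
    forage_kg_day: Optional[float] = None
    fa: Optional[FattyAcidProfile] = None

    @property
    def season(self) -> str:
        return SEASON_OF_DATE[self.date_code]

    def validate(self, row: Optional[int] = None) -> None:
        where = f" (row {row})" if row is not None else ""
        if self.date_code not in DATE_CODES:
            raise ValidationError(f"unknown date_code {self.date_code!r}{where}")
        nonneg = ("days_in_milk", "yield_l_day", "solids_kg_day", "scc_kcells_ml",
                  "treatments_n", "concentrate_kg_day", "forage_kg_day")
        for name in nonneg:
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}{where}")
        if self.yield_l_day is not None and self.solids_kg_day is not None:
            # fat+protein mass cannot exceed total milk mass at ~1 kg/L
            if self.solids_kg_day > self.yield_l_day + 1e-9:
                raise ValidationError(
                    f"solids_kg_day {self.solids_kg_day} exceeds yield_l_day "
                    f"{self.yield_l_day}{where}"
                )
        if self.fa is not None:
            self.fa.validate()


@dataclass(frozen=True)
class BreedCode:
    """Canonical, parent-sex-symmetric breed label."""

    canonical_label: str
    component_breeds: tuple[str, ...]
    is_backcross_or_majority: bool = False


@dataclass
class FarmInfo:
    """One row of the farm roster (mirrors the printed background table)."""

    farm_id: int
    management: str
    n_cows: int
    calving_pattern: str
    breeds: tuple[str, ...] = ()


@dataclass
class HerdDataset:
    """A collection of cow x date records plus the farm roster."""

    records: list[CowRecord] = field(default_factory=list)
    farm_table: dict[int, FarmInfo] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.records)

    def validate(self) -> None:
        seen: set[tuple[str, str]] = set()
        for i, rec in enumerate(self.records):
            key = (rec.cow_id, rec.date_code)
            if key in seen:
                raise ValidationError(f"duplicate (cow_id, date_code) {key}")
            seen.add(key)
            rec.validate(row=i + 2)
            if self.farm_table and rec.farm_id not in self.farm_table:
                raise ValidationError(
                    f"farm_id {rec.farm_id} of cow {rec.cow_id} not in farm table"
                )

    def to_frame(self) -> pd.DataFrame:
        """Long-format DataFrame with one row per record (herd CSV schema)."""
        rows = []
        for rec in self.records:
            row = {
                "cow_id": rec.cow_id, "farm_id": rec.farm_id,
                "management": rec.management, "date_code": rec.date_code,
                "breed_code": rec.breed_code, "sire_breed": rec.sire_breed,
                "dam_breed": rec.dam_breed, "generation": rec.generation,
                "days_in_milk": rec.days_in_milk,
                "yield_l_day": rec.yield_l_day,
                "solids_kg_day": rec.solids_kg_day,
                "scc_kcells_ml": rec.scc_kcells_ml,
                "treatments_n": rec.treatments_n,
                "concentrate_kg_day": rec.concentrate_kg_day,
                "forage_kg_day": rec.forage_kg_day,
            }
            if rec.fa is not None:
                row.update(rec.fa.as_dict())
            else:
                row.update({name: None for name in FA_VARIABLES})
            rows.append(row)
        df = pd.DataFrame(rows, columns=list(HERD_COLUMNS))
        df["season"] = df["date_code"].map(SEASON_OF_DATE)
        return df

    def subset(self, records: Iterable[CowRecord]) -> "HerdDataset":
        return HerdDataset(records=list(records), farm_table=dict(self.farm_table))


# ---------------------------------------------------------------------------
# Breed codes
# ---------------------------------------------------------------------------

def _parse_parent_tokens(label: str) -> tuple[str, ...]:
    """Split a raw pedigree label like ``JExSH`` into vocabulary tokens."""
    raw = label.replace("×", "x").strip()
    tokens = tuple(t.strip().upper() for t in raw.split("x") if t.strip())
    if not tokens:
        raise VocabularyError(f"empty breed label {label!r}")
    for t in tokens:
        if t not in _BREED_RANK:
            raise VocabularyError(f"unrecognized breed token {t!r} in {label!r}")
    return tokens


def parse_breed_label(label: str) -> BreedCode:
    """Parse a canonical label (``HFJE``, ``NZFX``, ``SH``) back into a BreedCode.

    Concatenated labels are decoded by greedy longest-token matching against
    the breed vocabulary; a trailing single ``X`` (not part of the ``XX``
    token) marks a majority contribution / backcross.
    """
    s = label.strip().upper()
    if not s:
        raise VocabularyError("empty breed label")
    tokens: list[str] = []
    i = 0
    by_len = sorted(_BREED_RANK, key=len, reverse=True)
    while i < len(s):
        for tok in by_len:
            if s.startswith(tok, i):
                # a trailing lone "X" is the backcross marker, not a token
                tokens.append(tok)
                i += len(tok)
                break
        else:
            if s[i:] == "X":
                return BreedCode(s, tuple(tokens), is_backcross_or_majority=True)
            raise VocabularyError(f"cannot parse breed label {label!r} at {s[i:]!r}")
    return BreedCode(s, tuple(tokens), is_backcross_or_majority=False)


def canonical_breed_code(sire: str, dam: str) -> BreedCode:
    """Combine sire and dam pedigree labels into a canonical breed code.

    The label is invariant under swapping sire and dam. Purebred parents of
    one breed give the pure label (JE x JE -> JE); two distinct purebred
    parents give the concatenated pair ordered by breed precedence
    (JE x HF -> HFJE, JE x AYR -> JEAYR); crosses involving compound parents
    take the single strictly-majority breed with a trailing X
    (JExSH x JExAYR -> JEX), or XX when no single breed dominates.
    """
    sire_toks = _parse_parent_tokens(sire)
    dam_toks = _parse_parent_tokens(dam)
    if len(sire_toks) == 1 and len(dam_toks) == 1:
        a, b = sire_toks[0], dam_toks[0]
        if a == b:
            return BreedCode(a, (a,), False)
        first, second = sorted((a, b), key=_BREED_RANK.__getitem__)
        return BreedCode(first + second, (first, second), False)
    frac: Counter[str] = Counter()
    for toks in (sire_toks, dam_toks):
        for t in toks:
            frac[t] += 0.5 / len(toks)
    ordered = sorted(frac.items(), key=lambda kv: (-kv[1], _BREED_RANK[kv[0]]))
    if len(ordered) == 1:
        return BreedCode(ordered[0][0], (ordered[0][0],), False)
    if ordered[0][1] > ordered[1][1] + 1e-12:
        major = ordered[0][0]
        comps = tuple(sorted(frac, key=_BREED_RANK.__getitem__))
        return BreedCode(major + "X", comps, True)
    comps = tuple(sorted(frac, key=_BREED_RANK.__getitem__))
    return BreedCode("XX", comps, False)


# ---------------------------------------------------------------------------
# CSV reading and writing
# ---------------------------------------------------------------------------

_INT_FIELDS = {"farm_id", "treatments_n"}


def _fmt(value) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    if isinstance(value, float):
        if value == int(value) and abs(value) < 1e15:
            return repr(value) if abs(value) >= 1e6 else f"{value:g}"
        return f"{value:.6g}"
    return str(value)


def _parse_cell(name: str, cell: str, row: int):
    cell = cell.strip()
    if cell == "":
        return None
    if name in ("cow_id", "management", "date_code", "breed_code",
                "sire_breed", "dam_breed", "generation"):
        return cell
    try:
        if name in _INT_FIELDS:
            return int(float(cell))
        return float(cell)
    except ValueError as exc:
        raise ValidationError(f"cannot parse {name}={cell!r} at row {row}") from exc


def read_herd_csv(path, farm_path=None) -> HerdDataset:
    """Read a long-format herd CSV (one row = cow x date) into a HerdDataset.

    Missing optional cells (empty strings) become absent values, never zeros.
    A fatty-acid profile is attached only when all nine FA cells are present.
    The farm table is read from ``farm_path`` when given, otherwise derived
    from the records themselves.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in HERD_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"herd CSV missing column(s): {', '.join(missing)}")
    records: list[CowRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, raw in enumerate(df.itertuples(index=False)):
        row = i + 2  # 1-based with header
        cells = dict(zip(df.columns, raw))
        parsed = {c: _parse_cell(c, cells[c], row) for c in HERD_COLUMNS}
        fa_vals = {name: parsed[name] for name in FA_VARIABLES}
        fa = FattyAcidProfile(**fa_vals) if all(v is not None for v in fa_vals.values()) else None
        rec = CowRecord(
            cow_id=parsed["cow_id"], farm_id=parsed["farm_id"],
            management=parsed["management"], date_code=parsed["date_code"],
            breed_code=parsed["breed_code"], sire_breed=parsed["sire_breed"],
            dam_breed=parsed["dam_breed"], generation=parsed["generation"],
            days_in_milk=parsed["days_in_milk"],
            yield_l_day=parsed["yield_l_day"],
            solids_kg_day=parsed["solids_kg_day"],
            scc_kcells_ml=parsed["scc_kcells_ml"],
            treatments_n=parsed["treatments_n"],
            concentrate_kg_day=parsed["concentrate_kg_day"],
            forage_kg_day=parsed["forage_kg_day"],
            fa=fa,
        )
        key = (rec.cow_id, rec.date_code)
        if key in seen:
            raise ValidationError(f"duplicate (cow_id, date_code) {key} at row {row}")
        seen.add(key)
        rec.validate(row=row)
        records.append(rec)

    farm_table: dict[int, FarmInfo] = {}
    if farm_path is not None:
        fdf = pd.read_csv(farm_path, dtype=str, keep_default_na=False)
        fmissing = [c for c in FARM_COLUMNS if c not in fdf.columns]
        if fmissing:
            raise SchemaError(f"farm CSV missing column(s): {', '.join(fmissing)}")
        for t in fdf.itertuples(index=False):
            cells = dict(zip(fdf.columns, t))
            farm_table[int(cells["farm_id"])] = FarmInfo(
                farm_id=int(cells["farm_id"]),
                management=cells["management"],
                n_cows=int(cells["n_cows"]),
                calving_pattern=cells["calving_pattern"],
                breeds=tuple(b for b in cells["breeds"].split(";") if b),
            )
    else:
        for rec in records:
            info = farm_table.setdefault(rec.farm_id, FarmInfo(
                farm_id=rec.farm_id, management=rec.management, n_cows=0,
                calving_pattern="unknown", breeds=()))
            if rec.breed_code not in info.breeds:
                info.breeds = info.breeds + (rec.breed_code,)
        for fid, info in farm_table.items():
            info.n_cows = len({r.cow_id for r in records if r.farm_id == fid})
    ds = HerdDataset(records=records, farm_table=farm_table)
    ds.validate()
    return ds


def write_herd_csv(dataset: HerdDataset, path, farm_path=None) -> None:
    """Write the herd CSV (floats at 6 significant digits) and, optionally,
    the companion farm roster CSV."""
    lines = [",".join(HERD_COLUMNS)]
    for rec in dataset.records:
        fa = rec.fa.as_dict() if rec.fa is not None else {n: None for n in FA_VARIABLES}
        vals = {
            "cow_id": rec.cow_id, "farm_id": rec.farm_id,
            "management": rec.management, "date_code": rec.date_code,
            "breed_code": rec.breed_code, "sire_breed": rec.sire_breed,
            "dam_breed": rec.dam_breed, "generation": rec.generation,
            "days_in_milk": rec.days_in_milk, "yield_l_day": rec.yield_l_day,
            "solids_kg_day": rec.solids_kg_day,
            "scc_kcells_ml": rec.scc_kcells_ml, "treatments_n": rec.treatments_n,
            "concentrate_kg_day": rec.concentrate_kg_day,
            "forage_kg_day": rec.forage_kg_day, **fa,
        }
        lines.append(",".join(_fmt(vals[c]) for c in HERD_COLUMNS))
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
    if farm_path is not None:
        flines = [",".join(FARM_COLUMNS)]
        for fid in sorted(dataset.farm_table):
            info = dataset.farm_table[fid]
            flines.append(",".join([
                str(info.farm_id), info.management, str(info.n_cows),
                info.calving_pattern, ";".join(info.breeds)]))
        Path(farm_path).write_text("\n".join(flines) + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# Filters
# ---------------------------------------------------------------------------

def is_complete(rec: CowRecord) -> bool:
    """A record is analyzable when production, health and the full FA profile
    are all present."""
    return (rec.yield_l_day is not None and rec.solids_kg_day is not None
            and rec.scc_kcells_ml is not None and rec.treatments_n is not None
            and rec.fa is not None)


def filter_complete_records(dataset: HerdDataset, date: str) -> HerdDataset:
    """Retain only records of the given sampling date that are complete for
    production, health and fatty-acid composition."""
    if date not in DATE_CODES:
        raise ValidationError(f"unknown date_code {date!r}")
    keep = [r for r in dataset.records if r.date_code == date and is_complete(r)]
    return dataset.subset(keep)


def apply_inclusion_criteria(
    dataset: HerdDataset, min_cows: int = 6, min_farms: int = 3,
) -> tuple[frozenset[str], HerdDataset]:
    """Apply the breed-group inclusion rule.

    A breed group is retained iff, on at least one sampling date, it has
    complete records for at least ``min_cows`` distinct cows drawn from at
    least ``min_farms`` distinct farms. Returns the retained group labels and
    a dataset holding only those groups' records.
    """
    cows: dict[tuple[str, str], set[str]] = {}
    farms: dict[tuple[str, str], set[int]] = {}
    for rec in dataset.records:
        if not is_complete(rec):
            continue
        key = (rec.breed_code, rec.date_code)
        cows.setdefault(key, set()).add(rec.cow_id)
        farms.setdefault(key, set()).add(rec.farm_id)
    retained = frozenset(
        group for (group, date) in cows
        if len(cows[(group, date)]) >= min_cows and len(farms[(group, date)]) >= min_farms
    )
    kept = [r for r in dataset.records if r.breed_code in retained]
    return retained, dataset.subset(kept)
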