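"""Drug-panel data model and delimited-text I/O.

A panel couples per-drug clinical annotations (pharmacological class,
CTCAE severity grade, incidence category, peak plasma concentration
C_max) with per drug x epithelium-model x assay summaries of the in
vitro dose-response experiments: IC15, IC50 (both right-censorable at
the highest tested concentration) and the percent reduction of the
readout at the top dose.
"""

from __future__ import annotations

import enum
import math
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Union

import pandas as pd

__all__ = [
    "Model",
    "Assay",
    "DrugClass",
    "IncidenceCategory",
    "Route",
    "CensorableConc",
    "DrugRecord",
    "AssaySummary",
    "DrugPanel",
    "PanelSchemaError",
    "PanelParseError",
    "PanelIntegrityError",
    "load_panel",
    "write_panel",
    "bundled_panel",
]

PANEL_COLUMNS = [
    "drug", "class", "severity_grade", "incidence", "cmax_uM", "route",
    "model", "assay", "ic15_uM", "ic50_uM", "pct_reduction",
]

#: highest tested concentration; ICs that never cross within (0, this]
#: are reported right-censored as ">100 uM"
DEFAULT_CENSOR_LIMIT_UM = 100.0

# accepts ">100", "> 100 uM", ">100 μM" and the Cyrillic-glyph variant
# ">100 μм" that appears in typeset tables
_CENSOR_RE = re.compile(r"^>\s*(\d+(?:\.\d+)?)\s*(?:u|µ|μ)?(?:m|м)?\s*$", re.IGNORECASE)


class PanelSchemaError(ValueError):
    """Required column missing or file structurally unreadable."""


class PanelParseError(ValueError):
    """A cell could not be interpreted (reported with its row number)."""


class PanelIntegrityError(ValueError):
    """Cross-row consistency violated (duplicates, dangling references)."""


class Model(str, enum.Enum):
    """Epithelium model used for the monolayer."""

    HIEC = "hIEC"
    CACO2 = "Caco-2"


class Assay(str, enum.Enum):
    """Readout: barrier integrity (TEER) or viability (ATP luminescence)."""

    TEER = "TEER"
    ATP = "ATP"


class DrugClass(str, enum.Enum):
    CELL_CYCLE_INHIBITOR = "cell-cycle inhibitor"
    TKI = "TKI"
    NSAID = "NSAID"


class IncidenceCategory(str, enum.Enum):
    UNCOMMON = "uncommon"
    COMMON = "common"
    VERY_COMMON = "very common"


class Route(str, enum.Enum):
    ORAL = "oral"
    INTRAVENOUS = "intravenous"
    UNSPECIFIED = "unspecified"


@dataclass(frozen=True)
class CensorableConc:
    """A concentration that may be right-censored at the assay limit.

    Exactly one of ``value_uM`` / ``censored`` carries information: an
    uncensored concentration has a numeric ``value_uM``; a censored one
    was reported only as exceeding ``limit_uM`` (the drug never produced
    the required decrement within the tested range).
    """

    value_uM: Optional[float] = None
    censored: bool = False
    limit_uM: float = DEFAULT_CENSOR_LIMIT_UM

    def __post_init__(self) -> None:
        if self.censored:
            if self.value_uM is not None:
                raise ValueError("censored concentration cannot carry a value")
        else:
            if self.value_uM is None:
                raise ValueError("uncensored concentration requires a value")
            if not math.isfinite(self.value_uM) or self.value_uM <= 0:
                raise ValueError(f"concentration must be positive, got {self.value_uM}")
        if self.limit_uM <= 0:
            raise ValueError("censor limit must be positive")

    @classmethod
    def parse(cls, token: Union[str, float, int]) -> "CensorableConc":
        """Parse a table cell: a number, or a censoring token like '>100 uM'."""
        if isinstance(token, (int, float)):
            return cls(value_uM=float(token))
        text = str(token).strip()
        m = _CENSOR_RE.match(text)
        if m:
            return cls(censored=True, limit_uM=float(m.group(1)))
        try:
            return cls(value_uM=float(text))
        except ValueError:
            raise PanelParseError(f"cannot parse concentration {token!r}") from None

    def format(self) -> str:
        if self.censored:
            limit = self.limit_uM
            return f">{limit:g}"
        return f"{self.value_uM:g}"


@dataclass(frozen=True)
class DrugRecord:
    """One drug's identity and clinical context."""

    name: str
    drug_class: DrugClass
    severity_grade: int
    incidence_category: IncidenceCategory
    cmax_uM: float
    route: Route = Route.UNSPECIFIED

    def __post_init__(self) -> None:
        if self.severity_grade not in (1, 2, 3, 4):
            raise ValueError(f"severity grade must be 1-4, got {self.severity_grade}")
        if not math.isfinite(self.cmax_uM) or self.cmax_uM <= 0:
            raise ValueError(f"cmax_uM must be positive, got {self.cmax_uM}")


@dataclass(frozen=True)
class AssaySummary:
    """Per drug x model x assay dose-response summary."""

    drug: str
    model: Model
    assay: Assay
    ic15: CensorableConc
    ic50: CensorableConc
    pct_reduction: float

    def __post_init__(self) -> None:
        if self.pct_reduction > 100:
            raise ValueError(
                f"percent reduction cannot exceed 100, got {self.pct_reduction}"
            )


@dataclass
class DrugPanel:
    """An ordered drug panel with its assay summaries."""

    records: list[DrugRecord] = field(default_factory=list)
    summaries: list[AssaySummary] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise PanelIntegrityError(f"duplicate drug names: {dup}")
        known = set(names)
        keys: set[tuple[str, Model, Assay]] = set()
        for s in self.summaries:
            if s.drug not in known:
                raise PanelIntegrityError(f"summary refers to unknown drug {s.drug!r}")
            key = (s.drug, s.model, s.assay)
            if key in keys:
                raise PanelIntegrityError(f"duplicate summary for {key}")
            keys.add(key)

    # -- lookups ----------------------------------------------------------
    def record(self, name: str) -> DrugRecord:
        for r in self.records:
            if r.name == name:
                return r
        raise KeyError(name)

    def summary(self, drug: str, model: Union[Model, str], assay: Union[Assay, str]) -> AssaySummary:
        model, assay = Model(model), Assay(assay)
        for s in self.summaries:
            if s.drug == drug and s.model == model and s.assay == assay:
                return s
        raise KeyError((drug, model.value, assay.value))

    def summaries_for(self, model: Union[Model, str], assay: Union[Assay, str]) -> list[AssaySummary]:
        """Summaries for one model/assay combination, in panel drug order."""
        model, assay = Model(model), Assay(assay)
        by_drug = {s.drug: s for s in self.summaries if s.model == model and s.assay == assay}
        return [by_drug[r.name] for r in self.records if r.name in by_drug]

    def __len__(self) -> int:
        return len(self.records)

    # -- tabular views ----------------------------------------------------
    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per drug x model x assay summary."""
        rows = []
        by_name = {r.name: r for r in self.records}
        for s in self.summaries:
            r = by_name[s.drug]
            rows.append({
                "drug": r.name,
                "class": r.drug_class.value,
                "severity_grade": r.severity_grade,
                "incidence": r.incidence_category.value,
                "cmax_uM": r.cmax_uM,
                "route": r.route.value,
                "model": s.model.value,
                "assay": s.assay.value,
                "ic15_uM": s.ic15.format(),
                "ic50_uM": s.ic50.format(),
                "pct_reduction": s.pct_reduction,
            })
        return pd.DataFrame(rows, columns=PANEL_COLUMNS)


def _normalize_incidence(token: str) -> IncidenceCategory:
    return IncidenceCategory(str(token).strip().lower())


def load_panel(path: Union[str, Path], *, sep: str = ",") -> DrugPanel:
    """Read a long-format delimited panel table.

    Censored IC cells are encoded as ``>limit`` tokens (e.g. ``>100``,
    ``>100 µM``); malformed cells raise :class:`PanelParseError` naming
    the offending row.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=sep, dtype=str, skipinitialspace=True)
    except pd.errors.EmptyDataError:
        raise PanelSchemaError(f"{path}: file is empty") from None
    missing = [c for c in PANEL_COLUMNS if c not in df.columns and c != "route"]
    if missing:
        raise PanelSchemaError(f"{path}: missing required columns {missing}")

    records: dict[str, DrugRecord] = {}
    summaries: list[AssaySummary] = []
    for idx, row in df.iterrows():
        rowno = idx + 2  # header is line 1
        name = str(row["drug"]).strip()
        try:
            cmax = float(row["cmax_uM"])
        except (TypeError, ValueError):
            raise PanelParseError(
                f"{path} row {rowno}: non-numeric cmax_uM {row['cmax_uM']!r}"
            ) from None
        try:
            rec = DrugRecord(
                name=name,
                drug_class=DrugClass(str(row["class"]).strip()),
                severity_grade=int(row["severity_grade"]),
                incidence_category=_normalize_incidence(row["incidence"]),
                cmax_uM=cmax,
                route=Route(str(row.get("route", "unspecified")).strip()),
            )
        except ValueError as exc:
            raise PanelParseError(f"{path} row {rowno}: {exc}") from None
        prev = records.setdefault(name, rec)
        if prev != rec:
            raise PanelIntegrityError(
                f"{path} row {rowno}: conflicting annotations for drug {name!r}"
            )
        try:
            summaries.append(AssaySummary(
                drug=name,
                model=Model(str(row["model"]).strip()),
                assay=Assay(str(row["assay"]).strip()),
                ic15=CensorableConc.parse(row["ic15_uM"]),
                ic50=CensorableConc.parse(row["ic50_uM"]),
                pct_reduction=float(row["pct_reduction"]),
            ))
        except PanelParseError as exc:
            raise PanelParseError(f"{path} row {rowno}: {exc}") from None
        except ValueError as exc:
            raise PanelParseError(f"{path} row {rowno}: {exc}") from None
    return DrugPanel(records=list(records.values()), summaries=summaries)


def write_panel(panel: DrugPanel, path: Union[str, Path], *, sep: str = ",") -> Path:
    """Write a panel in the long delimited format read by :func:`load_panel`.

    Numeric fields round-trip bit-identically at stored precision;
    censored ICs keep their ``>limit`` token.
    """
    path = Path(path)
    df = panel.to_frame()
    # repr-precision floats so a reload compares equal
    df["cmax_uM"] = [f"{v:g}" for v in df["cmax_uM"]]
    df["pct_reduction"] = [repr(float(v)) for v in df["pct_reduction"]]
    df.to_csv(path, sep=sep, index=False)
    return path


def bundled_panel() -> DrugPanel:
    """The built-in 17-drug reference panel.

    Seventeen clinically characterized compounds (seven cell-cycle
    inhibitors, five tyrosine kinase inhibitors, five NSAIDs) with CTCAE
    severity grades, incidence categories, clinical C_max values, and
    IC15/IC50/percent-reduction summaries for all four model x assay
    combinations (hIEC/Caco-2 x TEER/ATP); 68 summaries in total. Six
    drug x model x assay cells are right-censored at 100 uM.
    """
    ref = resources.files("barriertox.data").joinpath("panel.csv")
    with resources.as_file(ref) as p:
        return load_panel(p)
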