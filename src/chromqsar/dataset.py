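"""Compound/retention data model, delimited-text I/O and the bundled dataset.

The central container is :class:`CompoundTable`: a list of
:class:`CompoundRecord` (identity, structural/electronic descriptors and
pharmacokinetic responses), the raw chromatographic
:class:`RetentionSeries`, and any *derived* lipophilicity descriptors
(``log_km``, ``log_k01``, ``log_kw_iam``, ``log_kw_ods``) produced by the
fitting modules or supplied directly.

The packaged dataset covers 19 fused azaisocytosine-containing congeners
from three structural classes (I: 2-isopropyl, II: 2-trifluoromethyl,
III: the third congener set), with micellar (Brij 35) retention factors at
four surfactant molarities and published log k_w values on IAM and
end-capped ODS phases.
"""

from __future__ import annotations

import csv
import io
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import DataValidationError, SchemaError

#: Pharmacokinetic response names. ``caco2_e06`` is kept on the printed
#: 1e-6 cm/s scale (values like 187); the others are base-10 logs except
#: ``fu_brain`` which is a fraction in [0, 1].
RESPONSE_NAMES = ("log_Kp", "log_KaHSA", "log_BB", "caco2_e06", "fu_brain")

#: Structural/electronic descriptors carried by every record.
STRUCTURAL_DESCRIPTORS = ("mw", "tpsa", "alpha")

#: Lipophilicity descriptors derived from chromatographic data.
DERIVED_DESCRIPTORS = ("log_km", "log_k01", "log_kw_iam", "log_kw_ods")

RETENTION_SYSTEMS = ("MLC", "IAM", "ODS")
X_KINDS = ("surfactant_molarity", "modifier_volume_fraction")

_COMPOUND_COLUMNS = (
    ("compound_id",) + ("series", "substituent") + STRUCTURAL_DESCRIPTORS
    + ("log_p",) + RESPONSE_NAMES
)
_REQUIRED_COMPOUND_COLUMNS = ("compound_id", "mw", "tpsa", "alpha")
_RETENTION_COLUMNS = ("compound_id", "system", "x_kind", "x", "k")


def _parse_number(text: str, *, column: str, row: str) -> float:
    """Parse one numeric cell; '.' decimal only, thousands separators rejected."""
    s = text.strip()
    if s == "":
        return math.nan
    # a comma anywhere is either a thousands separator or a decimal comma;
    # both are rejected so silent magnitude errors cannot slip through
    if "," in s:
        raise DataValidationError(
            f"column {column!r}, compound {row!r}: {text!r} contains a comma; "
            "use '.' as the decimal separator and no digit grouping"
        )
    # strip unicode minus
    s = s.replace("−", "-")
    try:
        return float(s)
    except ValueError as exc:
        raise DataValidationError(
            f"column {column!r}, compound {row!r}: cannot parse {text!r} as a number"
        ) from exc


@dataclass
class CompoundRecord:
    """One compound: identity, descriptors and pharmacokinetic responses."""

    compound_id: str
    substituent: str = ""
    series: str = ""
    mw: float = math.nan          # molecular weight, g/mol
    tpsa: float = math.nan        # topological polar surface area, A^2
    alpha: float = math.nan       # polarizability, A^3
    log_p: float = math.nan       # in-silico n-octanol/water log P
    responses: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if not (self.mw > 0):
            raise DataValidationError(f"compound {self.compound_id}: mw must be > 0, got {self.mw}")
        if not (self.tpsa >= 0):
            raise DataValidationError(f"compound {self.compound_id}: tpsa must be >= 0, got {self.tpsa}")
        if not (self.alpha > 0):
            raise DataValidationError(f"compound {self.compound_id}: alpha must be > 0, got {self.alpha}")
        fu = self.responses.get("fu_brain", math.nan)
        if not math.isnan(fu) and not (0.0 <= fu <= 1.0):
            raise DataValidationError(
                f"compound {self.compound_id}: fu_brain must lie in [0, 1], got {fu}"
            )


@dataclass
class RetentionSeries:
    """(concentration, retention factor) measurements for one compound/system.

    ``x`` is surfactant molarity (mol/L) for micellar series or the organic
    modifier volume fraction (phi, dimensionless) for isocratic
    reversed-phase series. Points are stored sorted by ``x``.
    """

    compound_id: str
    system: str                   # one of RETENTION_SYSTEMS
    x_kind: str                   # one of X_KINDS
    x: np.ndarray
    k: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.k = np.asarray(self.k, dtype=float)
        if self.system not in RETENTION_SYSTEMS:
            raise DataValidationError(f"unknown retention system {self.system!r}")
        if self.x_kind not in X_KINDS:
            raise DataValidationError(f"unknown x_kind {self.x_kind!r}")
        if self.x.shape != self.k.shape or self.x.ndim != 1:
            raise DataValidationError("x and k must be 1-d arrays of equal length")
        order = np.argsort(self.x)
        self.x = self.x[order]
        self.k = self.k[order]
        if np.any(self.k <= 0):
            bad = self.x[self.k <= 0][0]
            raise DataValidationError(
                f"compound {self.compound_id} ({self.system}): retention factor "
                f"k must be > 0 (offending point at x={bad:g})"
            )
        if np.any(self.x < 0):
            raise DataValidationError(
                f"compound {self.compound_id} ({self.system}): concentrations must be >= 0"
            )
        if np.any(np.diff(self.x) == 0):
            raise DataValidationError(
                f"compound {self.compound_id} ({self.system}): duplicate x values"
            )

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class CompoundTable:
    """Records + retention series + derived descriptor vectors."""

    records: list[CompoundRecord] = field(default_factory=list)
    retention: list[RetentionSeries] = field(default_factory=list)
    #: descriptor name -> {compound_id -> value}
    derived_descriptors: dict[str, dict[str, float]] = field(default_factory=dict)

    def validate(self) -> None:
        ids = [r.compound_id for r in self.records]
        seen: set[str] = set()
        for cid in ids:
            if cid in seen:
                raise DataValidationError(f"duplicated compound_id {cid!r}")
            seen.add(cid)
        for rec in self.records:
            rec.validate()
        for series in self.retention:
            if series.compound_id not in seen:
                raise DataValidationError(
                    f"retention series references unknown compound_id {series.compound_id!r}"
                )
        for name, values in self.derived_descriptors.items():
            unknown = set(values) - seen
            if unknown:
                raise DataValidationError(
                    f"derived descriptor {name!r} has values for unknown compounds {sorted(unknown)}"
                )

    @property
    def compound_ids(self) -> list[str]:
        return [r.compound_id for r in self.records]

    def get_series(self, compound_id: str, system: str = "MLC") -> RetentionSeries | None:
        for s in self.retention:
            if s.compound_id == compound_id and s.system == system:
                return s
        return None

    def set_derived(self, name: str, values: Mapping[str, float]) -> None:
        self.derived_descriptors[name] = dict(values)

    def to_frame(self) -> pd.DataFrame:
        """All descriptors and responses as one DataFrame indexed by compound_id."""
        rows = {}
        for rec in self.records:
            row = {
                "series": rec.series,
                "substituent": rec.substituent,
                "mw": rec.mw,
                "tpsa": rec.tpsa,
                "alpha": rec.alpha,
                "log_p": rec.log_p,
            }
            row.update(rec.responses)
            rows[rec.compound_id] = row
        frame = pd.DataFrame.from_dict(rows, orient="index")
        frame.index.name = "compound_id"
        for name, values in self.derived_descriptors.items():
            frame[name] = pd.Series(values)
        return frame


def _detect_delimiter(sample: str) -> str:
    header = sample.splitlines()[0] if sample else ""
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_compound_table(
    path: str | Path,
    *,
    retention_path: str | Path | None = None,
    delimiter: str | None = None,
) -> CompoundTable:
    """Read a compound table (and optionally a long-format retention table).

    The compound file needs a header row with at least ``compound_id``,
    ``mw``, ``tpsa`` and ``alpha``; response columns and derived descriptor
    columns (``log_km``, ``log_k01``, ``log_kw_iam``, ``log_kw_ods``) are
    picked up when present. The delimiter is auto-detected between comma
    and tab unless given.
    """
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    table = parse_compound_csv(text, delimiter=delimiter)
    if retention_path is not None:
        table.retention = read_retention_table(retention_path, delimiter=delimiter)
    table.validate()
    return table


def parse_compound_csv(text: str, *, delimiter: str | None = None) -> CompoundTable:
    delim = delimiter or _detect_delimiter(text)
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    if reader.fieldnames is None:
        raise SchemaError("compound table is empty (no header row)")
    cols = [c.strip() for c in reader.fieldnames]
    missing = [c for c in _REQUIRED_COMPOUND_COLUMNS if c not in cols]
    if missing:
        raise SchemaError(f"compound table is missing required column(s): {missing}")
    records: list[CompoundRecord] = []
    derived: dict[str, dict[str, float]] = {}
    derived_cols = [c for c in cols if c in DERIVED_DESCRIPTORS]
    for raw in reader:
        if None in raw:
            raise SchemaError(
                f"row {raw.get('compound_id')!r} has more fields than the header; "
                "check delimiters and digit-grouping commas"
            )
        row = {k.strip(): (v if v is not None else "") for k, v in raw.items()}
        cid = row["compound_id"].strip()
        rec = CompoundRecord(
            compound_id=cid,
            substituent=row.get("substituent", "").strip(),
            series=row.get("series", "").strip(),
            mw=_parse_number(row["mw"], column="mw", row=cid),
            tpsa=_parse_number(row["tpsa"], column="tpsa", row=cid),
            alpha=_parse_number(row["alpha"], column="alpha", row=cid),
            log_p=_parse_number(row.get("log_p", ""), column="log_p", row=cid),
            responses={
                name: _parse_number(row.get(name, ""), column=name, row=cid)
                for name in RESPONSE_NAMES
                if name in cols
            },
        )
        records.append(rec)
        for dcol in derived_cols:
            val = _parse_number(row.get(dcol, ""), column=dcol, row=cid)
            if not math.isnan(val):
                derived.setdefault(dcol, {})[cid] = val
    table = CompoundTable(records=records, derived_descriptors=derived)
    table.validate()
    return table


def read_retention_table(path: str | Path, *, delimiter: str | None = None) -> list[RetentionSeries]:
    """Read a long-format retention table (compound_id, system, x_kind, x, k)."""
    return parse_retention_csv(Path(path).read_text(encoding="utf-8"), delimiter=delimiter)


def parse_retention_csv(text: str, *, delimiter: str | None = None) -> list[RetentionSeries]:
    delim = delimiter or _detect_delimiter(text)
    reader = csv.DictReader(io.StringIO(text), delimiter=delim)
    if reader.fieldnames is None:
        raise SchemaError("retention table is empty (no header row)")
    cols = [c.strip() for c in reader.fieldnames]
    missing = [c for c in _RETENTION_COLUMNS if c not in cols]
    if missing:
        raise SchemaError(f"retention table is missing required column(s): {missing}")
    groups: dict[tuple[str, str, str], list[tuple[float, float]]] = {}
    for raw in reader:
        row = {k.strip(): (v if v is not None else "") for k, v in raw.items()}
        cid = row["compound_id"].strip()
        key = (cid, row["system"].strip(), row["x_kind"].strip())
        x = _parse_number(row["x"], column="x", row=cid)
        k = _parse_number(row["k"], column="k", row=cid)
        if k <= 0 or math.isnan(k):
            raise DataValidationError(
                f"compound {cid}: retention factor must be > 0, got {row['k']!r} at x={row['x']}"
            )
        groups.setdefault(key, []).append((x, k))
    out = []
    for (cid, system, x_kind), pts in groups.items():
        xs, ks = zip(*pts)
        out.append(RetentionSeries(cid, system, x_kind, np.array(xs), np.array(ks)))
    return out


def _format_value(v: float | str) -> str:
    if isinstance(v, str):
        return v
    v = float(v)
    if math.isnan(v):
        return ""
    return repr(v)  # repr round-trips doubles exactly


def write_compound_table(
    table: CompoundTable,
    path: str | Path,
    *,
    retention_path: str | Path | None = None,
    delimiter: str = ",",
) -> None:
    """Write a CompoundTable back to delimited text, losslessly.

    Floats are written with ``repr`` so ``read(write(t))`` reproduces ``t``
    at full double precision.
    """
    table.validate()
    derived_cols = sorted(table.derived_descriptors)
    cols = list(_COMPOUND_COLUMNS) + derived_cols
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(cols)
        for rec in table.records:
            row = [
                rec.compound_id, rec.series, rec.substituent,
                _format_value(rec.mw), _format_value(rec.tpsa),
                _format_value(rec.alpha), _format_value(rec.log_p),
            ]
            row += [_format_value(rec.responses.get(name, math.nan)) for name in RESPONSE_NAMES]
            row += [
                _format_value(table.derived_descriptors[d].get(rec.compound_id, math.nan))
                for d in derived_cols
            ]
            writer.writerow(row)
    if retention_path is not None:
        with open(retention_path, "w", newline="", encoding="utf-8") as fh:
            writer = csv.writer(fh, delimiter=delimiter)
            writer.writerow(_RETENTION_COLUMNS)
            for s in table.retention:
                for xv, kv in zip(s.x, s.k):
                    writer.writerow([s.compound_id, s.system, s.x_kind,
                                     _format_value(float(xv)), _format_value(float(kv))])


def load_bundled_dataset() -> CompoundTable:
    """The packaged 19-congener dataset.

    Returns all structural/electronic descriptors, the five pharmacokinetic
    responses, micellar retention factors at 0.075/0.100/0.125/0.150 mol/L
    Brij 35, and the published log k_w values on IAM and ODS phases (stored
    as derived descriptors ``log_kw_iam`` / ``log_kw_ods``).
    """
    pkg = resources.files("chromqsar.data")
    table = parse_compound_csv(pkg.joinpath("congener_compounds.csv").read_text(encoding="utf-8"))
    table.retention = parse_retention_csv(
        pkg.joinpath("congener_retention.csv").read_text(encoding="utf-8")
    )
    table.validate()
    return table
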