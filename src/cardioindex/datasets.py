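"""Cohort I/O: UCI heart-disease raw dialect, plain CSV, cleaning rules.

A :class:`Cohort` is a labelled subject table (pandas DataFrame) plus a
variable registry mapping V-codes (``V1``..``V76``) and indicator names
to human-readable descriptions.  The binary response ``Y`` encodes
presence of coronary artery disease (the raw multi-level severity field
is dichotomised 0 -> 0, {1,2,3,4} -> 1).

The UCI raw dialect is whitespace-separated numeric tokens, one subject
spanning several physical lines, each record closed by the literal
token ``name`` (the anonymised 76th attribute): 75 numeric tokens +
``name`` per record.  The sentinel ``-9`` means missing throughout; 0
is additionally treated as missing for pressure/rate fields only, where
it is physiologically impossible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class SchemaError(ValueError):
    """A required column or registry code is absent."""


class ParseError(ValueError):
    """A file does not conform to the declared dialect."""


@dataclass(frozen=True)
class Variable:
    code: str
    name: str
    kind: str = "numeric"  # numeric | categorical | binary


# Standard 76-attribute registry of the UCI heart-disease raw files.
_UCI_RAW_NAMES = [
    "id", "ccf", "age", "sex", "painloc", "painexer", "relrest", "pncaden",
    "cp", "trestbps", "htn", "chol", "smoke", "cigs", "years", "fbs", "dm",
    "famhist", "restecg", "ekgmo", "ekgday", "ekgyr", "dig", "prop", "nitr",
    "pro", "diuretic", "proto", "thaldur", "thaltime", "met", "thalach",
    "thalrest", "tpeakbps", "tpeakbpd", "dummy", "trestbpd", "exang",
    "xhypo", "oldpeak", "slope", "rldv5", "rldv5e", "ca", "restckm",
    "exerckm", "restef", "restwm", "exeref", "exerwm", "thal", "thalsev",
    "thalpul", "earlobe", "cmo", "cday", "cyr", "num", "lmt", "ladprox",
    "laddist", "diag", "cxmain", "ramus", "om1", "om2", "rcaprox",
    "rcadist", "lvx1", "lvx2", "lvx3", "lvx4", "lvf", "cathef", "junk",
    "name",
]
_UCI_KINDS = {
    "V4": "binary", "V5": "binary", "V6": "binary", "V7": "binary",
    "V11": "binary", "V16": "binary", "V17": "binary", "V18": "binary",
    "V23": "binary", "V24": "binary", "V25": "binary", "V26": "binary",
    "V27": "binary", "V38": "binary", "V39": "binary",
    "V9": "categorical", "V19": "categorical", "V41": "categorical",
    "V51": "categorical",
}


def uci_registry() -> dict[str, Variable]:
    """The standard V1..V76 registry of the UCI raw heart-disease files."""
    reg = {}
    for i, name in enumerate(_UCI_RAW_NAMES, start=1):
        code = f"V{i}"
        reg[code] = Variable(code, name, _UCI_KINDS.get(code, "numeric"))
    return reg


#: Registry codes that identify rather than describe a subject.
UCI_IDENTIFIER_CODES = ("V1", "V2", "V76")
#: Raw disease-severity field, dichotomised to Y.
UCI_DISEASE_CODE = "V58"
#: Vitals columns of the raw dialect: resting systolic/diastolic
#: pressure and resting heart rate (the triple on the RC ~ 0.03 scale).
UCI_VITALS_CODES = {"sbp": "V10", "dbp": "V37", "hr": "V33"}
#: Fields for which 0 is physiologically impossible, hence a missing code.
ZERO_MISSING_CODES = ("V10", "V37", "V33", "V32", "V34", "V35", "V12")


@dataclass
class Cohort:
    """A labelled subject table with its variable registry.

    ``data`` holds one row per subject; ``Y`` is the binary label.
    ``registry`` covers every non-Y column of ``data``.
    """

    data: pd.DataFrame
    registry: dict[str, Variable] = field(default_factory=dict)
    provenance: str = ""

    def __post_init__(self) -> None:
        if "Y" not in self.data.columns:
            raise SchemaError("cohort table lacks the response column Y")
        y = self.data["Y"].dropna()
        if not y.isin([0, 1]).all():
            raise SchemaError("response Y must be binary 0/1")
        missing = [c for c in self.data.columns if c != "Y" and c not in self.registry]
        for c in missing:
            self.registry[c] = Variable(c, c)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def y(self) -> pd.Series:
        return self.data["Y"]

    def with_data(self, data: pd.DataFrame) -> "Cohort":
        return Cohort(data, dict(self.registry), self.provenance)


def dichotomize(severity) -> np.ndarray:
    """Map the 0-4 disease-severity field to binary Y (0 -> 0, 1..4 -> 1)."""
    sev = np.asarray(severity, dtype=float)
    out = np.where(np.isfinite(sev), (sev > 0).astype(float), np.nan)
    return out


def read_uci_raw(path, registry: dict[str, Variable] | None = None) -> Cohort:
    """Parse a UCI heart-disease raw file into a Cohort.

    Records are split on the literal terminator token ``name``; each
    must carry exactly 75 numeric tokens.  ``-9`` becomes NaN
    everywhere; 0 becomes NaN in pressure/rate fields.  The severity
    field V58 is dichotomised into ``Y`` and vitals are copied into
    ``sbp``/``dbp``/``hr`` convenience columns.
    """
    registry = dict(registry or uci_registry())
    with open(path, encoding="utf-8") as fh:
        tokens = fh.read().split()
    records: list[list[float]] = []
    current: list[float] = []
    for tok in tokens:
        if tok == "name":
            if len(current) != 75:
                raise ParseError(
                    f"record {len(records)}: expected 75 numeric tokens before "
                    f"'name', got {len(current)}"
                )
            records.append(current)
            current = []
        else:
            try:
                current.append(float(tok))
            except ValueError as exc:
                raise ParseError(
                    f"record {len(records)}: non-numeric token {tok!r}"
                ) from exc
    if current:
        raise ParseError(
            f"record {len(records)}: trailing {len(current)} token(s) without "
            "a 'name' terminator"
        )
    cols = [f"V{i}" for i in range(1, 76)]
    df = pd.DataFrame(records, columns=cols)
    df = df.mask(df == -9)
    for code in ZERO_MISSING_CODES:
        df[code] = df[code].mask(df[code] == 0)
    df["Y"] = dichotomize(df[UCI_DISEASE_CODE])
    for role, code in UCI_VITALS_CODES.items():
        df[role] = df[code]
    for role in UCI_VITALS_CODES:
        registry.setdefault(role, Variable(role, role))
    return Cohort(df, registry, provenance=str(path))


def read_csv_cohort(path, column_map: dict[str, str] | None = None) -> Cohort:
    """Read a delimited cohort table with header.

    ``column_map`` maps the roles ``sbp``/``dbp``/``hr``/``y`` to column
    names in the file (defaults to those same names, case-insensitive).
    Mapped columns are renamed to the canonical roles; every other
    column is retained and registered under its own name.
    """
    df = pd.read_csv(path)
    column_map = dict(column_map or {})
    lower = {c.lower(): c for c in df.columns}
    rename = {}
    absent = []
    for role in ("sbp", "dbp", "hr", "y"):
        source = column_map.get(role, role)
        if source in df.columns:
            rename[source] = role.upper() if role == "y" else role
        elif source.lower() in lower:
            rename[lower[source.lower()]] = role.upper() if role == "y" else role
        else:
            absent.append(source)
    if absent:
        raise SchemaError(f"missing mapped column(s): {', '.join(absent)}")
    df = df.rename(columns=rename)
    registry = {c: Variable(c, c) for c in df.columns if c != "Y"}
    return Cohort(df, registry, provenance=str(path))


def write_csv_cohort(cohort: Cohort, path) -> None:
    """Write the cohort table as UTF-8 CSV, missing values as empty fields."""
    cohort.data.to_csv(path, index=False, na_rep="")


@dataclass(frozen=True)
class CleaningPolicy:
    """List-wise exclusion rules applied before analysis.

    ``require_valid_vitals`` drops rows whose SBP/DBP/HR cannot support
    the indicator math (missing, non-positive, or SBP <= DBP).
    ``required_columns`` drops rows with a missing value in any listed
    column (the na.omit analogue).
    """

    require_valid_vitals: bool = True
    required_columns: tuple[str, ...] = ()
    sbp: str = "sbp"
    dbp: str = "dbp"
    hr: str = "hr"


def clean_cohort(cohort: Cohort, policy: CleaningPolicy) -> tuple[Cohort, dict[str, int]]:
    """Filter a cohort per ``policy``; returns (cohort, exclusion report).

    Pure filtration: retained rows are unaltered.  An empty result is
    legal and logged.
    """
    df = cohort.data
    keep = pd.Series(True, index=df.index)
    report: dict[str, int] = {}
    if policy.require_valid_vitals:
        s, d, h = (df.get(c) for c in (policy.sbp, policy.dbp, policy.hr))
        if s is None or d is None or h is None:
            raise SchemaError("vitals columns absent; cannot apply vitals rule")
        ok = s.notna() & d.notna() & h.notna() & (d > 0) & (s > d) & (h > 0)
        report["invalid_vitals"] = int((keep & ~ok).sum())
        keep &= ok
    for col in policy.required_columns:
        if col not in df.columns:
            raise SchemaError(f"required column {col!r} absent")
        ok = df[col].notna()
        report[f"missing_{col}"] = int((keep & ~ok).sum())
        keep &= ok
    out = df.loc[keep].copy()
    if out.empty:
        logger.warning("cleaning excluded every record (%d rules)", len(report))
    return cohort.with_data(out), report
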