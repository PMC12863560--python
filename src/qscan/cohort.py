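"""Subject × dose response tables and derived-variable tables.

The raw input to every analysis in this package is a small rectangular
table: one row per subject, one column per unit dose, each cell holding the
subject's mean number of self-administered infusions per session component
at that dose.  Downstream stages produce a second rectangular table of
derived per-subject variables (curve amplitude, demand intensity, ...).
Both live here, together with CSV readers/writers and the embedded
reference cohort used throughout the test-suite and documentation.
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "VariableTable",
    "CohortParseError",
    "read_cohort",
    "read_variables",
    "write_report",
    "fixture_table1",
    "fixture_table2",
]

#: Derived-variable columns that must be strictly positive when present.
POSITIVE_VARIABLES = frozenset({"amplitude", "width", "auc", "q0", "evalue"})


class CohortParseError(ValueError):
    """Raised when a cohort or variable CSV violates the format contract."""


@dataclass
class CohortTable:
    """Per-subject mean infusion counts at each unit dose.

    Parameters
    ----------
    subjects : list of str
        Subject identifiers, unique.
    doses : ndarray
        Unit doses in mg/kg/infusion, nonnegative, strictly increasing.
        At most one zero dose is allowed (a saline / no-drug component).
    responses : ndarray, shape (n_subjects, n_doses)
        Mean infusions earned per session component; all nonnegative.
    fixed_ratio : int
        Operant price ratio (lever presses per infusion), shared by the
        cohort.  Default 5 (an FR5 schedule).
    """

    subjects: list[str]
    doses: np.ndarray
    responses: np.ndarray
    fixed_ratio: int = 5

    def __post_init__(self) -> None:
        self.subjects = [str(s) for s in self.subjects]
        self.doses = np.asarray(self.doses, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if len(set(self.subjects)) != len(self.subjects):
            raise CohortParseError("duplicate subject identifiers")
        if self.doses.ndim != 1 or self.responses.shape != (
            len(self.subjects),
            self.doses.size,
        ):
            raise CohortParseError(
                f"responses shape {self.responses.shape} does not match "
                f"{len(self.subjects)} subjects x {self.doses.size} doses"
            )
        if np.any(self.doses < 0):
            raise CohortParseError("doses must be nonnegative")
        if np.any(np.diff(self.doses) <= 0):
            raise CohortParseError("doses must be strictly increasing")
        if np.sum(self.doses == 0) > 1:
            raise CohortParseError("at most one zero dose allowed")
        if np.any(~np.isfinite(self.responses)) or np.any(self.responses < 0):
            raise CohortParseError("responses must be finite and nonnegative")
        if not (isinstance(self.fixed_ratio, (int, np.integer)) and self.fixed_ratio > 0):
            raise CohortParseError("fixed_ratio must be a positive integer")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_doses(self) -> int:
        return int(self.doses.size)

    @property
    def nonzero_doses(self) -> np.ndarray:
        return self.doses[self.doses > 0]

    def row(self, subject: str) -> np.ndarray:
        """Responses for one subject, in dose order."""
        return self.responses[self.subjects.index(subject)]

    def nonzero_row(self, subject: str) -> np.ndarray:
        return self.row(subject)[self.doses > 0]

    def subset(self, keep: list[str]) -> "CohortTable":
        """Restrict to ``keep`` subjects (original cohort order preserved)."""
        idx = [i for i, s in enumerate(self.subjects) if s in set(keep)]
        return CohortTable(
            [self.subjects[i] for i in idx],
            self.doses.copy(),
            self.responses[idx].copy(),
            self.fixed_ratio,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.responses, index=self.subjects,
                          columns=[_dose_label(d) for d in self.doses])
        df.index.name = "subject"
        return df

    def write_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("subject," + ",".join(_dose_label(d) for d in self.doses) + "\n")
            for s, row in zip(self.subjects, self.responses):
                fh.write(s + "," + ",".join(_fmt(v) for v in row) + "\n")


@dataclass
class VariableTable:
    """Subject × variable matrix of derived real-valued measures."""

    subjects: list[str]
    variables: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.subjects = [str(s) for s in self.subjects]
        self.variables = [str(v) for v in self.variables]
        self.values = np.asarray(self.values, dtype=float).reshape(
            len(self.subjects), len(self.variables)
        )
        if len(set(self.variables)) != len(self.variables):
            raise CohortParseError("duplicate variable names")
        if len(set(self.subjects)) != len(self.subjects):
            raise CohortParseError("duplicate subject identifiers")
        for j, name in enumerate(self.variables):
            col = self.values[:, j]
            if name in POSITIVE_VARIABLES and np.any(col[np.isfinite(col)] <= 0):
                raise CohortParseError(f"variable {name!r} must be strictly positive")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def column(self, name: str) -> np.ndarray:
        return self.values[:, self.variables.index(name)]

    def entry(self, subject: str, variable: str) -> float:
        return float(self.values[self.subjects.index(subject),
                                 self.variables.index(variable)])

    def as_mapping(self, variable: str) -> dict[str, float]:
        return dict(zip(self.subjects, self.column(variable)))

    def select(self, variables: list[str]) -> "VariableTable":
        idx = [self.variables.index(v) for v in variables]
        return VariableTable(list(self.subjects), list(variables), self.values[:, idx])

    def drop_subjects(self, drop) -> "VariableTable":
        drop = set(drop)
        idx = [i for i, s in enumerate(self.subjects) if s not in drop]
        return VariableTable([self.subjects[i] for i in idx],
                             list(self.variables), self.values[idx])

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.subjects, columns=self.variables)
        df.index.name = "subject"
        return df

    def write_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("subject," + ",".join(self.variables) + "\n")
            for s, row in zip(self.subjects, self.values):
                fh.write(s + "," + ",".join(_fmt(v) for v in row) + "\n")


def _dose_label(d: float) -> str:
    return "d" + _fmt(d)


def _fmt(v: float) -> str:
    # repr of a float is its shortest exactly-round-tripping decimal form
    return repr(float(v))


def _parse_float(cell: str, where: str) -> float:
    try:
        return float(cell)
    except ValueError:
        raise CohortParseError(f"non-numeric cell {cell!r} in {where}") from None


def read_cohort(path, fixed_ratio: int = 5) -> CohortTable:
    """Read a subject × dose CSV into a validated :class:`CohortTable`.

    The header row is ``subject,<dose>,<dose>,...`` where each dose is a
    plain numeral, optionally prefixed with ``d`` (``d0.032``).  Dose
    columns are sorted ascending on read.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise CohortParseError("empty file")
    header = lines[0].split(",")
    if len(header) < 2 or header[0].strip().lower() not in {"subject", "ratid", "id"}:
        raise CohortParseError(
            "malformed header: expected 'subject' followed by dose columns"
        )
    doses = np.array(
        [_parse_float(h.strip().lstrip("dD"), "header") for h in header[1:]]
    )
    subjects, rows = [], []
    for ln in lines[1:]:
        cells = ln.split(",")
        if len(cells) != len(header):
            raise CohortParseError(f"row {cells[0]!r} has {len(cells) - 1} cells, "
                                   f"expected {len(header) - 1}")
        subjects.append(cells[0].strip())
        rows.append([_parse_float(c, f"row {cells[0]!r}") for c in cells[1:]])
    order = np.argsort(doses)
    return CohortTable(subjects, doses[order],
                       np.asarray(rows, dtype=float)[:, order], fixed_ratio)


def read_variables(path) -> VariableTable:
    """Read a subject × variable CSV written by :meth:`VariableTable.write_csv`."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        raise CohortParseError("empty file")
    header = lines[0].split(",")
    variables = [h.strip() for h in header[1:]]
    subjects, rows = [], []
    for ln in lines[1:]:
        cells = ln.split(",")
        if len(cells) != len(header):
            raise CohortParseError(f"row {cells[0]!r} has wrong cell count")
        subjects.append(cells[0].strip())
        rows.append([_parse_float(c, f"row {cells[0]!r}") for c in cells[1:]])
    values = (np.asarray(rows, dtype=float)
              if rows else np.empty((0, len(variables))))
    return VariableTable(subjects, variables, values)


def write_report(obj, path) -> None:
    """Write a table as CSV or any report object as JSON.

    Tables (:class:`CohortTable`, :class:`VariableTable`) go to CSV and
    round-trip losslessly through the matching reader.  Anything exposing
    ``to_dict()`` — the comparison/report objects elsewhere in the package —
    is serialised as sorted-key JSON so that identical reports are
    byte-identical on disk.
    """
    if isinstance(obj, (CohortTable, VariableTable)):
        obj.write_csv(path)
        return
    if hasattr(obj, "to_dict"):
        payload = obj.to_dict()
    elif isinstance(obj, dict):
        payload = obj
    else:
        raise TypeError(f"cannot serialise {type(obj).__name__}")
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(_jsonify(payload), fh, indent=1, sort_keys=True)
        fh.write("\n")


def _jsonify(x):
    if isinstance(x, dict):
        return {str(k): _jsonify(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonify(v) for v in x]
    if isinstance(x, np.ndarray):
        return _jsonify(x.tolist())
    if isinstance(x, (np.floating, float)):
        v = float(x)
        return v if math.isfinite(v) else None
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.bool_, bool)):
        return bool(x)
    return x


# ---------------------------------------------------------------------------
# Embedded reference cohort
# ---------------------------------------------------------------------------
# A 12-subject cocaine self-administration cohort on an FR5 schedule, seven
# unit doses (mg/kg/infusion), mean infusions per 20-min session component.
# Values are carried to the full printed precision of the source table and
# are used as the canonical worked example and as ground truth in tests.

_TABLE1_CSV = """\
subject,d0,d0.01,d0.032,d0.1,d0.32,d0.56,d1
A,5.363636,7.272727,13.7619,24.09524,7.52381,4.1,2
B,5.545455,7.818182,24.66667,27.2381,8.238095,4.8,3.1
C,3.727273,6.181818,15.80952,27.66667,11,5.6,3
D,7.727273,9,30.04762,16,5.142857,3.2,1.5
E,9.636364,9.818182,15.33333,28.28571,11.2381,6.1,4.3
F,2.444444,2,5.5,14.61111,6,4.111111,2.777778
G,5,6.272727,17,16.04762,7,3.8,1.5
H,5,8.363636,15.71429,19,6.714286,3.5,1.7
I,8.545455,19.45455,24.7619,19.61905,6.142857,3.3,1.8
J,7.181818,8.363636,20.57143,22.7619,9.238095,4.4,2.4
K,8.454545,7.363636,13.57143,33.42857,22.19048,11.9,5.9
L,6.363636,7.909091,12.42857,29.42857,9.047619,5.9,3.4
"""

# Derived curve variables for the 11 retained subjects (the Grubbs screen
# removes subject K): Gaussian amplitude (infusions), mean dose at peak
# (mg/kg/infusion), width (log10-dose units), area under the fitted curve,
# demand intensity Q0 (mg/kg) and essential value.
_TABLE2_CSV = """\
subject,amplitude,mean,width,auc,q0,evalue
A,22.54239,0.061376,0.7562,42.73391,2.700,3.373096
B,29.64831,0.059979,0.7878,58.55338,3.500,4.287834
C,26.30268,0.075683,0.776,51.16791,4.000,3.892034
D,27.86121,0.043053,0.7192,50.2326,2.000,3.614032
E,23.87811,0.065917,0.9318,55.77745,4.300,4.599677
F,12.61828,0.112099,0.6497,20.55175,3.100,1.946017
G,20.55891,0.056364,0.7349,37.87601,2.200,3.011693
H,21.28139,0.051168,0.7708,41.12233,2.200,3.328713
I,29.51209,0.031117,0.8713,64.46199,2.100,4.960436
J,26.18183,0.057544,0.7961,52.25208,3.100,4.015591
L,22.59436,0.070795,0.8479,48.02646,3.900,3.952847
"""


def _read_cohort_string(text: str, fixed_ratio: int = 5) -> CohortTable:
    lines = [ln for ln in text.splitlines() if ln.strip()]
    header = lines[0].split(",")
    doses = np.array([float(h.lstrip("dD")) for h in header[1:]])
    subjects, rows = [], []
    for ln in lines[1:]:
        cells = ln.split(",")
        subjects.append(cells[0])
        rows.append([float(c) for c in cells[1:]])
    return CohortTable(subjects, doses, np.asarray(rows), fixed_ratio)


def fixture_table1() -> CohortTable:
    """The embedded 12-subject × 7-dose reference cohort (FR5)."""
    return _read_cohort_string(_TABLE1_CSV)


def fixture_table2() -> VariableTable:
    """Published derived variables for the 11 retained reference subjects."""
    lines = [ln for ln in _TABLE2_CSV.splitlines() if ln.strip()]
    variables = lines[0].split(",")[1:]
    subjects, rows = [], []
    for ln in lines[1:]:
        cells = ln.split(",")
        subjects.append(cells[0])
        rows.append([float(c) for c in cells[1:]])
    return VariableTable(subjects, variables, np.asarray(rows))
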