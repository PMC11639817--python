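"""Spreadsheet prior knowledge: parsing, validation, and parameter compilation.

Prior knowledge for AMARES fitting is a small table with peaks in columns and
the five model fields (``amplitude``, ``chemicalshift``, ``linewidth``,
``phase``, ``g``) in rows, split into an "Initial Values" block and a
"Bounds" block.  Cells in the initial-value block hold either a number or a
constraint expression tying the field to an earlier peak (e.g. ``BATP/2`` for
an amplitude ratio, ``BATP-15Hz`` for a J-coupling splitting); cells in the
bounds block hold bracketed ranges such as ``(-180, 180)``, one-sided bounds
such as ``(0,`` and ``, 180)``, or a bare number that fixes the parameter.

Multiplets are named by suffixing the primary peak name with digits
(``BATP``, ``BATP2``, ``BATP3``); digits are not permitted elsewhere in a
name.  The table is parsed left to right, so a peak may only reference peaks
to its left.  Rows (and individual cells) starting with ``#`` are comments.

A field whose initial value is an expression is *tied* (the constraint holds
exactly throughout the fit); a bare number with a range bound is *free*; a
bare number with a bare-number bound, or with no bounds entry at all, is
*fixed*.  :func:`compile_parameters` lowers a validated table onto an
:class:`lmfit.Parameters` object whose constraint expressions enforce the
ties at every objective evaluation.
"""

from __future__ import annotations

import copy
import csv
import re
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np

from .signal_model import (
    PeakParameters,
    linewidth_to_damping,
    ppm_to_hz,
)

__all__ = [
    "FIELDS",
    "Bound",
    "ConstraintExpr",
    "PeakSpec",
    "PriorKnowledge",
    "PriorKnowledgeError",
    "parse_bound",
    "parse_expression",
    "parse_prior_knowledge",
    "load_prior_table",
    "prior_to_rows",
    "save_prior_knowledge",
    "compile_parameters",
    "CompiledParams",
    "params_to_peaks",
    "example_prior_path",
]

FIELDS = ("amplitude", "chemicalshift", "linewidth", "phase", "g")

#: lmfit-parameter suffix for each spreadsheet field
FIELD_SUFFIX = {
    "amplitude": "amp",
    "chemicalshift": "cs",
    "linewidth": "lw",
    "phase": "phase",
    "g": "g",
}

_NAME_RE = re.compile(r"^[A-Za-z]+[0-9]*$")
_EXPR_RE = re.compile(
    r"^(?P<name>[A-Za-z][A-Za-z0-9]*)"
    r"(?:\s*(?P<op>[*/+-])\s*(?P<operand>[0-9]*\.?[0-9]+(?:[eE][+-]?[0-9]+)?)"
    r"\s*(?P<unit>[Hh][Zz])?)?$"
)


class PriorKnowledgeError(ValueError):
    """Raised for malformed or inconsistent prior-knowledge tables."""


def _normalize_cell(text: str) -> str:
    # XLSX exports vary: Unicode minus / non-breaking spaces are normalized
    return (
        str(text)
        .replace("−", "-")
        .replace("–", "-")
        .replace("\xa0", " ")
        .strip()
    )


def _parse_number(text: str, context: str = "") -> float:
    try:
        return float(text)
    except ValueError:
        where = f" in {context}" if context else ""
        raise PriorKnowledgeError(f"cannot parse {text!r} as a number{where}") from None


def _format_number(x: float) -> str:
    return repr(float(x)) if float(x) != int(x) else str(int(x))


@dataclass(frozen=True)
class Bound:
    """A box constraint: either a (possibly one-sided) range or a fixed value."""

    lower: float | None = None
    upper: float | None = None
    fixed: float | None = None

    def __post_init__(self) -> None:
        has_range = self.lower is not None or self.upper is not None
        if self.fixed is not None and has_range:
            raise PriorKnowledgeError("bound cannot be both fixed and a range")
        if (
            self.lower is not None
            and self.upper is not None
            and not self.lower < self.upper
        ):
            raise PriorKnowledgeError(
                f"lower bound {self.lower} must be < upper bound {self.upper}"
            )

    @property
    def is_fixed(self) -> bool:
        return self.fixed is not None

    def clip(self, value: float) -> float:
        if self.fixed is not None:
            return self.fixed
        lo = -np.inf if self.lower is None else self.lower
        hi = np.inf if self.upper is None else self.upper
        return float(min(max(value, lo), hi))

    def to_cell(self) -> str:
        if self.fixed is not None:
            return _format_number(self.fixed)
        if self.lower is not None and self.upper is not None:
            return f"({_format_number(self.lower)}, {_format_number(self.upper)})"
        if self.lower is not None:
            return f"({_format_number(self.lower)},"
        return f", {_format_number(self.upper)})"


def parse_bound(cell_text: str) -> Bound:
    """Parse one bounds-block cell.

    ``(x, y)`` is a range, ``(x,`` a lower bound only, ``x)`` or ``, y)`` an
    upper bound only, and a bare number fixes the parameter at that value.
    """
    text = _normalize_cell(cell_text)
    if not text:
        raise PriorKnowledgeError("empty bound cell")
    if re.search(r"[A-DF-Za-df-z]", text):
        raise PriorKnowledgeError(
            f"expressions are not supported inside the Bounds block: {text!r}"
        )
    if "(" not in text and ")" not in text:
        return Bound(fixed=_parse_number(text, "bound cell"))
    if text.startswith("(") and text.endswith(")"):
        inner = text[1:-1]
        parts = [p.strip() for p in inner.split(",")]
        if len(parts) != 2:
            raise PriorKnowledgeError(f"malformed bound cell {text!r}")
        lower = _parse_number(parts[0], "bound cell") if parts[0] else None
        upper = _parse_number(parts[1], "bound cell") if parts[1] else None
        if lower is None and upper is None:
            raise PriorKnowledgeError(f"malformed bound cell {text!r}")
        return Bound(lower=lower, upper=upper)
    if text.startswith("("):
        inner = text[1:].rstrip(",").strip()
        if not inner or "," in inner:
            raise PriorKnowledgeError(f"malformed bound cell {text!r}")
        return Bound(lower=_parse_number(inner, "bound cell"))
    if text.endswith(")"):
        inner = text[:-1].lstrip(",").strip()
        if not inner or "," in inner:
            raise PriorKnowledgeError(f"malformed bound cell {text!r}")
        return Bound(upper=_parse_number(inner, "bound cell"))
    raise PriorKnowledgeError(f"malformed bound cell {text!r}")


@dataclass(frozen=True)
class ConstraintExpr:
    """A tie of one field to the same field of an earlier peak.

    ``operation`` is one of ``identity`` (same value), ``scale``
    (ratio via ``*`` or ``/``), ``offset_hz`` (chemical-shift offset given in
    Hz, converted to ppm through the carrier frequency at compile time) or
    ``offset_ppm`` (bare chemical-shift offset).  ``operand`` is the number as
    written (signed for offsets), and ``op_symbol`` preserves the spelled
    operator for lossless serialization.
    """

    referenced_peak: str
    referenced_field: str
    operation: str = "identity"
    operand: float | None = None
    op_symbol: str | None = None

    def evaluate(self, source_value: float, carrier_mhz: float | None = None) -> float:
        if self.operation == "identity":
            return source_value
        if self.operation == "scale":
            factor = (
                1.0 / self.operand if self.op_symbol == "/" else float(self.operand)
            )
            return source_value * factor
        if self.operation == "offset_hz":
            if carrier_mhz is None or not carrier_mhz > 0:
                raise ValueError("offset_hz ties need a positive carrier_mhz")
            return source_value + self.operand / carrier_mhz
        if self.operation == "offset_ppm":
            return source_value + self.operand
        raise ValueError(f"unknown tie operation {self.operation!r}")

    def to_cell(self) -> str:
        if self.operation == "identity":
            return self.referenced_peak
        operand = abs(self.operand)
        if self.operation == "scale":
            return f"{self.referenced_peak}{self.op_symbol}{_format_number(operand)}"
        sign = "-" if self.operand < 0 else "+"
        unit = "Hz" if self.operation == "offset_hz" else ""
        return f"{self.referenced_peak}{sign}{_format_number(operand)}{unit}"


def parse_expression(
    cell_text: str, column_field: str, known_peaks
) -> ConstraintExpr | float:
    """Parse one initial-value cell: a numeric literal or a tie expression.

    ``known_peaks`` are the names already parsed (to the left); referencing
    any other name is a dependency error.
    """
    text = _normalize_cell(cell_text)
    if not text:
        raise PriorKnowledgeError("empty initial-value cell")
    try:
        return float(text)
    except ValueError:
        pass
    match = _EXPR_RE.match(text)
    if match is None:
        if re.match(r"^[A-Za-z0-9]*[0-9][A-Za-z]+", text):
            raise PriorKnowledgeError(
                f"invalid peak name in {text!r}: digits are only permitted as a "
                "trailing multiplet index"
            )
        raise PriorKnowledgeError(f"cannot parse expression {text!r}")
    name = match.group("name")
    if not _NAME_RE.match(name):
        raise PriorKnowledgeError(
            f"invalid peak name {name!r}: digits are only permitted as a "
            "trailing multiplet index"
        )
    if name not in known_peaks:
        raise PriorKnowledgeError(
            f"expression {text!r} references {name!r}, which must precede the "
            "dependent peak in the spreadsheet"
        )
    op = match.group("op")
    if op is None:
        return ConstraintExpr(referenced_peak=name, referenced_field=column_field)
    operand = float(match.group("operand"))
    has_hz = match.group("unit") is not None
    if op in "*/":
        if has_hz:
            raise PriorKnowledgeError(f"unit suffix not allowed in ratio {text!r}")
        return ConstraintExpr(
            referenced_peak=name,
            referenced_field=column_field,
            operation="scale",
            operand=operand,
            op_symbol=op,
        )
    # additive offsets are only meaningful for chemical shifts
    if column_field != "chemicalshift":
        raise PriorKnowledgeError(
            f"offset expression {text!r} is only supported in the chemicalshift row"
        )
    signed = operand if op == "+" else -operand
    return ConstraintExpr(
        referenced_peak=name,
        referenced_field=column_field,
        operation="offset_hz" if has_hz else "offset_ppm",
        operand=signed,
        op_symbol=op,
    )


@dataclass(frozen=True)
class PeakSpec:
    """One peak's five fields, each an initial value (or tie) plus a bound."""

    name: str
    initial: dict
    bounds: dict

    def __post_init__(self) -> None:
        if not _NAME_RE.match(self.name):
            raise PriorKnowledgeError(
                f"invalid peak name {self.name!r}: letters with an optional "
                "trailing multiplet index only"
            )


def _multiplet_root(name: str) -> str:
    return re.sub(r"[0-9]+$", "", name)


@dataclass(frozen=True)
class PriorKnowledge:
    """Ordered, validated collection of peaks with acquisition context."""

    peaks: tuple
    carrier_mhz: float
    ref_ppm: float = 0.0

    def __post_init__(self) -> None:
        if not self.carrier_mhz > 0:
            raise PriorKnowledgeError("carrier_mhz must be > 0")
        names = [p.name for p in self.peaks]
        if len(set(names)) != len(names):
            raise PriorKnowledgeError("duplicate peak names in prior knowledge")

    @property
    def names(self) -> list:
        return [p.name for p in self.peaks]

    @property
    def multiplet_groups(self) -> dict:
        """Partition of all peaks by stripping the trailing multiplet index."""
        groups: dict = {}
        for name in self.names:
            groups.setdefault(_multiplet_root(name), []).append(name)
        return groups


def load_prior_table(path) -> list:
    """Read a CSV or XLSX prior-knowledge file into rows of cell strings."""
    path = Path(path)
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        import openpyxl

        book = openpyxl.load_workbook(path, read_only=True, data_only=True)
        sheet = book.worksheets[0]
        rows = [
            ["" if c is None else str(c) for c in row]
            for row in sheet.iter_rows(values_only=True)
        ]
        book.close()
        return rows
    with open(path, newline="") as handle:
        return [list(row) for row in csv.reader(handle)]


def parse_prior_knowledge(table, carrier_mhz: float, ref_ppm: float = 0.0) -> PriorKnowledge:
    """Parse a prior-knowledge table into a validated :class:`PriorKnowledge`.

    ``table`` may be a path to a CSV/XLSX file or rows of cell strings.
    """
    if isinstance(table, (str, Path)):
        table = load_prior_table(table)
    rows = []
    for raw in table:
        cells = [_normalize_cell(c) for c in raw]
        if not any(cells):
            continue
        first = next(c for c in cells if c)
        if first.startswith("#"):
            continue
        rows.append(["" if c.startswith("#") else c for c in cells])

    peak_names: list | None = None
    blocks: dict = {"initial": {}, "bounds": {}}
    seen_blocks: set = set()
    current: str | None = None
    for row in rows:
        head = row[0].lower()
        if head == "index":
            peak_names = [c for c in row[1:] if c]
            continue
        if head == "initial values":
            current = "initial"
            seen_blocks.add("initial")
            continue
        if head == "bounds":
            current = "bounds"
            seen_blocks.add("bounds")
            continue
        if head in FIELDS:
            if current is None:
                raise PriorKnowledgeError(
                    f"field row {row[0]!r} appears before any block header"
                )
            if head in blocks[current]:
                raise PriorKnowledgeError(f"duplicate {row[0]!r} row in {current} block")
            blocks[current][head] = row[1:]
            continue
        raise PriorKnowledgeError(f"unrecognized row header {row[0]!r}")

    if peak_names is None:
        raise PriorKnowledgeError("missing 'Index' row naming the peaks")
    if len(set(peak_names)) != len(peak_names):
        raise PriorKnowledgeError("duplicate peak name in Index row")
    for name in peak_names:
        if not _NAME_RE.match(name):
            raise PriorKnowledgeError(
                f"invalid peak name {name!r}: digits are only permitted as a "
                "trailing multiplet index"
            )
    if "initial" not in seen_blocks:
        raise PriorKnowledgeError("missing 'Initial Values' block")
    if "bounds" not in seen_blocks:
        raise PriorKnowledgeError("missing 'Bounds' block")
    missing = [f for f in FIELDS if f not in blocks["initial"]]
    if missing:
        raise PriorKnowledgeError(f"Initial Values block is missing rows: {missing}")

    peaks = []
    for j, name in enumerate(peak_names):
        known = peak_names[:j]
        initial: dict = {}
        bounds: dict = {}
        for fieldname in FIELDS:
            cells = blocks["initial"][fieldname]
            cell = cells[j] if j < len(cells) else ""
            bcells = blocks["bounds"].get(fieldname, [])
            bcell = bcells[j] if j < len(bcells) else ""
            context = f"peak {name!r}, row {fieldname!r}"
            if not cell and not bcell:
                raise PriorKnowledgeError(f"missing initial value for {context}")
            try:
                initial[fieldname] = (
                    parse_expression(cell, fieldname, known) if cell else None
                )
                bounds[fieldname] = parse_bound(bcell) if bcell else None
            except PriorKnowledgeError as err:
                raise PriorKnowledgeError(f"{err} ({context})") from None
            if initial[fieldname] is None:
                initial[fieldname] = bounds[fieldname].fixed
                if initial[fieldname] is None:
                    raise PriorKnowledgeError(
                        f"missing initial value for {context}"
                    )
        peaks.append(PeakSpec(name=name, initial=initial, bounds=bounds))
    return PriorKnowledge(peaks=tuple(peaks), carrier_mhz=carrier_mhz, ref_ppm=ref_ppm)


def prior_to_rows(pk: PriorKnowledge) -> list:
    """Serialize a :class:`PriorKnowledge` back to the spreadsheet dialect."""
    rows = [["Index"] + pk.names, ["Initial Values"]]
    for fieldname in FIELDS:
        row = [fieldname]
        for peak in pk.peaks:
            value = peak.initial[fieldname]
            row.append(
                value.to_cell()
                if isinstance(value, ConstraintExpr)
                else _format_number(value)
            )
        rows.append(row)
    rows.append(["Bounds"])
    for fieldname in FIELDS:
        row = [fieldname]
        for peak in pk.peaks:
            bound = peak.bounds[fieldname]
            row.append("" if bound is None else bound.to_cell())
        rows.append(row)
    return rows


def save_prior_knowledge(pk: PriorKnowledge, path) -> None:
    with open(path, "w", newline="") as handle:
        csv.writer(handle).writerows(prior_to_rows(pk))


def param_name(peak: str, fieldname: str) -> str:
    return f"{peak}_{FIELD_SUFFIX[fieldname]}"


@dataclass
class CompiledParams:
    """Prior knowledge lowered onto an :class:`lmfit.Parameters` object.

    ``classification`` maps each parameter name to ``"free"``, ``"tied"`` or
    ``"fixed"``; ``ties`` holds the originating :class:`ConstraintExpr` for
    tied parameters.  ``fresh()`` hands out an independent copy for a fit.
    """

    params: "object"
    peak_names: list
    classification: dict
    ties: dict
    carrier_mhz: float
    ref_ppm: float
    multiplet_groups: dict = dataclass_field(default_factory=dict)

    @property
    def free_names(self) -> list:
        return [n for n, c in self.classification.items() if c == "free"]

    @property
    def n_free(self) -> int:
        return len(self.free_names)

    def fresh(self):
        return copy.deepcopy(self.params)

    def evaluate_tie(self, name: str, values: dict) -> float:
        """Pure tie evaluator: value of a tied parameter from a value map."""
        expr = self.ties[name]
        source = values[param_name(expr.referenced_peak, expr.referenced_field)]
        return expr.evaluate(source, carrier_mhz=self.carrier_mhz)


def compile_parameters(pk: PriorKnowledge) -> CompiledParams:
    """Classify every (peak, field) as free/tied/fixed and build lmfit params.

    Ties become lmfit constraint expressions evaluated exactly at every step;
    Hz offsets on chemical shifts are converted to ppm through the carrier.
    """
    import lmfit

    params = lmfit.Parameters()
    classification: dict = {}
    ties: dict = {}
    seen: set = set()
    for peak in pk.peaks:
        for fieldname in FIELDS:
            name = param_name(peak.name, fieldname)
            init = peak.initial[fieldname]
            bound = peak.bounds[fieldname]
            if isinstance(init, ConstraintExpr):
                source = param_name(init.referenced_peak, init.referenced_field)
                if source not in seen:  # impossible under left-to-right parsing
                    raise PriorKnowledgeError(
                        f"tie of {name} references unknown parameter {source}"
                    )
                if init.operation == "identity":
                    expr = source
                elif init.operation == "scale":
                    expr = f"{source}{init.op_symbol}{init.operand!r}"
                elif init.operation == "offset_hz":
                    expr = f"{source} + ({init.operand / pk.carrier_mhz!r})"
                else:
                    expr = f"{source} + ({init.operand!r})"
                params.add(name, expr=expr)
                classification[name] = "tied"
                ties[name] = init
            elif bound is not None and not bound.is_fixed:
                lo = -np.inf if bound.lower is None else bound.lower
                hi = np.inf if bound.upper is None else bound.upper
                params.add(name, value=bound.clip(init), min=lo, max=hi, vary=True)
                classification[name] = "free"
            else:
                params.add(name, value=float(init), vary=False)
                classification[name] = "fixed"
            seen.add(name)
    params.update_constraints()
    return CompiledParams(
        params=params,
        peak_names=list(pk.names),
        classification=classification,
        ties=ties,
        carrier_mhz=pk.carrier_mhz,
        ref_ppm=pk.ref_ppm,
        multiplet_groups=pk.multiplet_groups,
    )


def params_to_peaks(params, peak_names, carrier_mhz: float, ref_ppm: float) -> dict:
    """Convert user-unit lmfit parameters to model-unit :class:`PeakParameters`."""
    peaks = {}
    for name in peak_names:
        cs = params[param_name(name, "chemicalshift")].value
        lw = params[param_name(name, "linewidth")].value
        g = params[param_name(name, "g")].value
        peaks[name] = PeakParameters(
            amplitude=params[param_name(name, "amplitude")].value,
            frequency_hz=float(ppm_to_hz(cs, carrier_mhz, ref_ppm)),
            damping=linewidth_to_damping(max(lw, 0.0), min(max(g, 0.0), 1.0)),
            phase_deg=params[param_name(name, "phase")].value,
            g=min(max(g, 0.0), 1.0),
        )
    return peaks


def example_prior_path() -> Path:
    """Packaged example prior table: 31P human brain ATP multiplets at 7 T."""
    return Path(__file__).parent / "data" / "prior_31p_brain_7t.csv"
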