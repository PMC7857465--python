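"""Table renderers with publication-style rounding.

Stored results always keep full precision; formatting only happens
here.  Conventions: dimensionless quantities (CMC, a1, R^2) round to 2
decimals, degree quantities to 1 decimal, rounding half away from zero;
a CMC above 0.995 renders as ">0.99" and an undefined CMC as an
en-dash.  CSV output keeps a parallel full-precision column per
formatted one so rendered files re-parse losslessly.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["round_half_up", "format_cmc", "format_table", "render_report"]

UNDEFINED_MARK = "–"  # en-dash

#: columns rounded to 2 decimals (dimensionless)
_DIMLESS = ("cmc", "a1", "r2")
#: columns kept as-is
_VERBATIM = ("case", "level", "factor", "joint", "mode", "n_sim",
             "n_undefined_cmc", "cmc_defined")


def round_half_up(value: float, decimals: int) -> float:
    """Round with ties away from zero (publication convention)."""
    q = Decimal(10) ** -decimals
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def format_cmc(value: float | None, defined: bool = True) -> str:
    """Render a CMC cell: '–' if undefined, '>0.99' above 0.995."""
    if not defined or value is None or (isinstance(value, float) and np.isnan(value)):
        return UNDEFINED_MARK
    if value > 0.995:
        return ">0.99"
    return f"{round_half_up(value, 2):.2f}"


def _format_cell(column: str, value) -> str:
    if column.startswith(_VERBATIM) or isinstance(value, (str, bool, np.bool_)):
        return str(value)
    if column == "cmc" or column.startswith("cmc_"):
        return format_cmc(value)
    if column.startswith(_DIMLESS):
        return f"{round_half_up(value, 2):.2f}"
    return f"{round_half_up(value, 1):.1f}"  # degree-scale quantity


def format_table(table: pd.DataFrame) -> pd.DataFrame:
    """Format every cell of a results table as a rendered string."""
    out = {}
    for column in table.columns:
        out[column] = [_format_cell(column, v) for v in table[column]]
    return pd.DataFrame(out, index=table.index)


def render_report(
    table: pd.DataFrame,
    path: str | Path,
    style: str = "csv",
) -> None:
    """Write a results table as CSV or markdown.

    CSV keeps the full-precision value of every formatted numeric
    column in a parallel ``raw_<name>`` column; markdown shows only the
    formatted cells.
    """
    formatted = format_table(table)
    path = Path(path)
    if style == "csv":
        merged = formatted.copy()
        for column in table.columns:
            if not formatted[column].equals(
                table[column].astype(str)
            ) and pd.api.types.is_numeric_dtype(table[column]):
                merged[f"raw_{column}"] = table[column]
        merged.to_csv(path, index=False)
    elif style == "markdown":
        header = "| " + " | ".join(formatted.columns) + " |"
        rule = "| " + " | ".join("---" for _ in formatted.columns) + " |"
        lines = [header, rule]
        for _, row in formatted.iterrows():
            lines.append("| " + " | ".join(row) + " |")
        path.write_text("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown style {style!r}")
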