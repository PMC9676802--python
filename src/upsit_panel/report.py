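"""Rendering of the four-column classifier comparison table.

Rows: Sensitivity, Specificity, Positive/Negative likelihood ratio,
Negative/Positive predictive value, Accuracy.  Columns: PLS-DA and decision
tree, each on the selected panel and the full battery.  Display conventions:
proportions as estimate ± SE at 2 dp, likelihood ratios at 2 dp, accuracy at
3 dp; an infinite LR+ renders as "inf (fp=0)".
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .metrics import DiagnosticReport

ROW_ORDER = (
    "Sensitivity",
    "Specificity",
    "Positive likelihood ratio",
    "Negative likelihood ratio",
    "Negative predictive value",
    "Positive predictive value",
    "Accuracy",
)


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal half-up rounding (the convention of printed clinical tables)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def _pm(p: float, se: float) -> str:
    return f"{round_half_up(p, 2):.2f} ± {round_half_up(se, 2):.2f}"


def _column(report: DiagnosticReport) -> dict[str, str]:
    lr_pos = "inf (fp=0)" if report.lr_pos_infinite else f"{round_half_up(report.lr_pos, 2):.2f}"
    return {
        "Sensitivity": _pm(report.sensitivity, report.sensitivity_se),
        "Specificity": _pm(report.specificity, report.specificity_se),
        "Positive likelihood ratio": lr_pos,
        "Negative likelihood ratio": f"{round_half_up(report.lr_neg, 2):.2f}",
        "Negative predictive value": (
            _pm(report.npv, report.npv_se) if report.npv is not None else "undefined"
        ),
        "Positive predictive value": (
            _pm(report.ppv, report.ppv_se) if report.ppv is not None else "undefined"
        ),
        "Accuracy": f"{round_half_up(report.accuracy, 3):.3f}",
    }


def render_table(reports: dict[str, DiagnosticReport]) -> pd.DataFrame:
    """Metric table, one column per (classifier × item set) report.

    ``reports`` maps column names (e.g. "PLS-DA 8-item") to DiagnosticReports.
    All reports must describe cohorts of the same class sizes.
    """
    sizes = {(r.cm.n_pd, r.cm.n_hs) for r in reports.values()}
    if len(sizes) > 1:
        raise ValueError(f"reports describe different cohorts: {sorted(sizes)}")
    df = pd.DataFrame({name: _column(r) for name, r in reports.items()})
    return df.loc[list(ROW_ORDER)]


def render_markdown(table: pd.DataFrame) -> str:
    return table.to_markdown()
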