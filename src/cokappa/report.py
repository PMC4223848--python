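"""Display rounding and text rendering of association results.

Rounding mirrors the conventional presentation of such tables: CLQs and
observed/expected percentages to two significant figures, kappa as an
integer percent (one decimal below 10%), with full precision preserved in
the machine-readable long format.
"""

from __future__ import annotations

from math import floor, isnan, log10

import numpy as np
import pandas as pd

from .association import AssociationMatrix
from .errors import InvalidInputError

__all__ = [
    "format_sig2",
    "format_kappa_pct",
    "results_long",
    "render_from_long",
    "render_matrix",
]


def format_sig2(x: float) -> str:
    """Two significant figures, keeping a trailing decimal (1.0 not 1)."""
    if isnan(x):
        return "NA"
    if x == 0:
        return "0.0"
    decimals = max(1 - floor(log10(abs(x))), 0)
    return f"{x:.{decimals}f}"


def format_kappa_pct(kappa: float) -> str:
    """Kappa in percent: integer above 10%, one decimal below."""
    if isnan(kappa):
        return "NA"
    pct = 100.0 * kappa
    if abs(pct) < 9.95:
        return f"{pct:.1f}"
    return f"{pct:.0f}"


def results_long(matrix: AssociationMatrix, item: str = "") -> pd.DataFrame:
    """Full-precision long-format results for one item."""
    return matrix.to_dataframe(item=item)


def _cell_text(row) -> str:
    if isnan(row["clq"]) and isnan(row["kappa_exact"]):
        return "NA"
    return (
        f"{format_sig2(row['obs_pct'])}/{format_sig2(row['exp_pct'])} "
        f"{format_sig2(row['clq'])} ({format_kappa_pct(row['kappa_exact'])}){row['stars']}"
    )


def render_from_long(df: pd.DataFrame, upper_triangle: bool = True) -> str:
    """Render the long format as an index-by-neighbor text table.

    Each cell shows ``obs/exp CLQ (kappa %)stars``; the second column is
    the index raters' relative frequency, recovered from the diagonal
    chance expectation (``exp = 100 p_a^2``).  With ``upper_triangle``
    only cells on or above the diagonal are shown, matching the
    symmetric presentation convention.
    """
    if df.empty:
        raise InvalidInputError("no results to render")
    df = df.copy()
    df["stars"] = df["stars"].fillna("")
    cats = sorted(df["index_cat"].unique())
    item = str(df["item"].iloc[0])
    cells = {(int(r["index_cat"]), int(r["neighbor_cat"])): r for _, r in df.iterrows()}
    missing = [(a, b) for a in cats for b in cats if (a, b) not in cells]
    if missing:
        raise InvalidInputError(f"long format is missing pairs {missing[:4]}...")

    rel_freq = {a: float(np.sqrt(max(cells[(a, a)]["exp_pct"], 0.0) / 100.0)) for a in cats}
    header = ["index cat", "rel freq %"] + [f"nb {c}" for c in cats]
    rows = [header]
    for a in cats:
        row = [str(a), format_sig2(100.0 * rel_freq[a])]
        for b in cats:
            if upper_triangle and cats.index(b) < cats.index(a):
                row.append("")
            else:
                row.append(_cell_text(cells[(a, b)]))
        rows.append(row)

    widths = [max(len(r[i]) for r in rows) for i in range(len(header))]
    lines = [f"# {item}: index - nearest neighbor agreement, obs/exp %  CLQ (kappa %)"]
    for ri, r in enumerate(rows):
        lines.append("  ".join(s.ljust(w) for s, w in zip(r, widths)).rstrip())
        if ri == 0:
            lines.append("-" * (sum(widths) + 2 * (len(widths) - 1)))
    lines.append("stars: * 0.01<=p<0.05; ** p<0.01; *** p<0.001")
    return "\n".join(lines) + "\n"


def render_matrix(matrix: AssociationMatrix, item: str = "", upper_triangle: bool = True) -> str:
    return render_from_long(results_long(matrix, item=item), upper_triangle=upper_triangle)
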