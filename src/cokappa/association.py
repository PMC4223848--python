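"""Kappa, colocation quotient (CLQ), and their interconversion.

For index category *a* and neighbor category *b* with observed colocation
proportion ``o_ab`` and index relative counts ``p_a``, ``p_b``:

* ``CLQ(a, b) = o_ab / (p_a p_b)`` — how many times more likely than
  chance the colocation is (with-replacement convention: the index rating
  is part of the chance expectation, so no finite-population correction).
* ``CLQ_max = (p_a + p_b) / (2 p_a p_b)`` — the largest CLQ attainable
  conditioning on the total share ``p_a + p_b`` and assuming equal
  occurrence of the two categories; for ``a == b`` it reduces to ``1/p_a``.
* ``kappa(a, b) = (P_O - P_E) / (1 - P_E)`` on the dichotomized 2×2 with
  ``P_E = p_a p_b + (1 - p_a)(1 - p_b)`` — excess agreement as a fraction
  of the maximum attainable excess.
* ``kappa ≈ (CLQ - 1) / (CLQ_max - 1)``, exactly so when neighbor and
  index margins coincide.

The null standard error is the large-sample no-agreement variance for
kappa between two raters (Fleiss–Cohen–Everitt) applied to the
dichotomized table with n equal to the number of matched sets.  Because
matched sets share raters (mutual nearest neighbors appear twice), this SE
understates the true sampling variability; :func:`permutation_null`
provides the empirical reference distribution for calibrated inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import isnan, sqrt

import numpy as np
import pandas as pd
from scipy.stats import norm

from .contingency import WeightedContingencyTable, dichotomize
from .dataset import RatingDataset
from .errors import InvalidInputError, UndefinedStatisticError
from .geometry import MatchedSet

__all__ = [
    "AssociationResult",
    "AssociationMatrix",
    "PermutationNull",
    "clq",
    "clq_max",
    "kappa_exact",
    "overall_kappa",
    "kappa_from_clq",
    "null_se",
    "p_value",
    "significance_stars",
    "permutation_null",
    "association_matrix",
    "pair_association",
]

_MARGIN_EPS = 1e-15


def _index_margin_pair(table: WeightedContingencyTable, a, b) -> tuple[float, float]:
    if not table.is_square:
        raise InvalidInputError("pairwise statistics require a square table")
    return table.index_margin(a), table.index_margin(b)


def clq(table: WeightedContingencyTable, a, b) -> float:
    """Observed over chance-expected colocation, ``o_ab / (p_a p_b)``."""
    p_a, p_b = _index_margin_pair(table, a, b)
    if p_a <= _MARGIN_EPS or p_b <= _MARGIN_EPS:
        raise UndefinedStatisticError(f"CLQ undefined: zero margin for pair ({a}, {b})")
    return table.cell(a, b) / (p_a * p_b)


def clq_max(p_a: float, p_b: float, *, same_category: bool = False) -> float:
    """Theoretical maximum of the CLQ given the two relative counts.

    ``(p_a + p_b) / (2 p_a p_b)``; for a same-category pair pass
    ``same_category=True`` (the constraint ``p_a + p_b <= 1`` does not
    apply and the expression reduces to ``1/p_a``).
    """
    if p_a <= _MARGIN_EPS or p_b <= _MARGIN_EPS:
        raise UndefinedStatisticError("CLQ maximum undefined for a zero margin")
    if not same_category and p_a + p_b > 1.0 + 1e-9:
        raise InvalidInputError("cross-category margins must satisfy p_a + p_b <= 1")
    if same_category and p_a >= 1.0 - _MARGIN_EPS:
        raise UndefinedStatisticError("CLQ maximum degenerate when a category has share 1")
    return (p_a + p_b) / (2.0 * p_a * p_b)


def kappa_exact(table: WeightedContingencyTable, a, b) -> float:
    """Chance-corrected agreement on the dichotomized {a,¬a}×{b,¬b} table.

    ``P_O`` sums the two agreement cells of the 2×2; ``P_E`` uses the
    index margins of the parent table.  For ``a == b`` this equals the
    overall kappa of the a / not-a table.
    """
    p_a, p_b = _index_margin_pair(table, a, b)
    d = dichotomize(table, a, b)
    p_o = d.cells[0, 0] + d.cells[1, 1]
    p_e = p_a * p_b + (1.0 - p_a) * (1.0 - p_b)
    if p_e >= 1.0 - _MARGIN_EPS:
        raise UndefinedStatisticError(f"kappa undefined: degenerate margins for ({a}, {b})")
    return (p_o - p_e) / (1.0 - p_e)


def overall_kappa(table: WeightedContingencyTable) -> float:
    """Overall kappa of a square table, chance expectation from index margins."""
    if not table.is_square:
        raise InvalidInputError("overall kappa requires a square table")
    p = table.index_margins
    p_o = float(np.trace(table.cells))
    p_e = float(p @ p)
    if p_e >= 1.0 - _MARGIN_EPS:
        raise UndefinedStatisticError("overall kappa undefined: degenerate margins")
    return (p_o - p_e) / (1.0 - p_e)


def kappa_from_clq(clq_value: float, p_a: float, p_b: float, *, same_category: bool = False) -> float:
    """Normalize a CLQ onto the kappa scale: ``(CLQ - 1)/(CLQ_max - 1)``.

    Algebraically ``2 p_a p_b (CLQ - 1) / (p_a + p_b - 2 p_a p_b)``; equals
    the exact kappa whenever neighbor and index margins coincide.
    """
    if clq_value < 0:
        raise InvalidInputError("CLQ cannot be negative")
    cmax = clq_max(p_a, p_b, same_category=same_category)
    if cmax <= 1.0 + _MARGIN_EPS:
        raise UndefinedStatisticError("CLQ maximum of 1 leaves no room for agreement")
    return (clq_value - 1.0) / (cmax - 1.0)


def null_se(table: WeightedContingencyTable, a, b) -> float:
    """Approximate SE of kappa under the no-agreement null.

    Fleiss–Cohen–Everitt large-sample null variance on the dichotomized
    2×2 with row margins r (index) and column margins s (weighted
    neighbor), n = number of matched sets::

        SE0 = sqrt( (P_E + P_E^2 - sum_i r_i s_i (r_i + s_i))
                    / (n (1 - P_E)^2) )
    """
    if table.n_sets < 2:
        raise InvalidInputError("null SE requires at least 2 matched sets")
    d = dichotomize(table, a, b)
    r = d.index_margins
    s = d.neighbor_margins
    p_e = float(r @ s)
    if p_e >= 1.0 - _MARGIN_EPS:
        raise UndefinedStatisticError(f"null SE undefined: degenerate margins for ({a}, {b})")
    num = p_e + p_e**2 - float(np.sum(r * s * (r + s)))
    return sqrt(max(num, 0.0) / (table.n_sets * (1.0 - p_e) ** 2))


def p_value(kappa: float, se: float) -> float:
    """Two-sided normal p-value for kappa / SE."""
    if not se > 0:
        raise InvalidInputError("standard error must be positive")
    return float(2.0 * norm.sf(abs(kappa) / se))


def significance_stars(p: float) -> str:
    """Footnote bands: * 0.01<=p<0.05, ** p<0.01, *** p<0.001."""
    if not 0.0 <= p <= 1.0:
        raise InvalidInputError("p must lie in [0, 1]")
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class AssociationResult:
    """CLQ, kappa and inferential quantities for one ordered category pair.

    Undefined statistics (zero margins) are NaN; ``stars`` renders the
    significance band of the exact kappa.
    """

    a: int
    b: int
    obs: float
    exp_clq: float
    clq: float
    clq_max: float
    kappa_exact: float
    kappa_from_clq: float
    se_null: float
    p_value: float
    n_sets: int

    @property
    def same_category(self) -> bool:
        return self.a == self.b

    @property
    def defined(self) -> bool:
        return not (isnan(self.clq) or isnan(self.kappa_exact))

    @property
    def stars(self) -> str:
        if isnan(self.p_value):
            return ""
        return significance_stars(self.p_value)


def pair_association(table: WeightedContingencyTable, a, b) -> AssociationResult:
    """All association statistics for the ordered pair (a, b).

    Statistics that are undefined for the table's margins come back as
    NaN rather than raising, so full matrices can always be assembled.
    """
    a, b = int(a), int(b)
    p_a, p_b = _index_margin_pair(table, a, b)
    obs = table.cell(a, b)
    nan = float("nan")
    try:
        clq_v = clq(table, a, b)
        cmax = clq_max(p_a, p_b, same_category=a == b)
        k_clq = kappa_from_clq(clq_v, p_a, p_b, same_category=a == b)
    except (UndefinedStatisticError, InvalidInputError):
        clq_v = cmax = k_clq = nan
    try:
        k_exact = kappa_exact(table, a, b)
        se = null_se(table, a, b)
        p = p_value(k_exact, se) if se > 0 else nan
    except (UndefinedStatisticError, InvalidInputError):
        k_exact = se = p = nan
    return AssociationResult(
        a=a,
        b=b,
        obs=obs,
        exp_clq=p_a * p_b,
        clq=clq_v,
        clq_max=cmax,
        kappa_exact=k_exact,
        kappa_from_clq=k_clq,
        se_null=se,
        p_value=p,
        n_sets=table.n_sets,
    )


@dataclass(frozen=True)
class AssociationMatrix:
    """Association results for every ordered category pair of a table."""

    scheme_codes: tuple
    results: dict = field(repr=False)
    n_sets: int

    def get(self, a, b) -> AssociationResult:
        return self.results[(int(a), int(b))]

    @property
    def max_asymmetry(self) -> float:
        """Symmetry diagnostic max |CLQ(a,b) − CLQ(b,a)| over defined pairs."""
        worst = 0.0
        for a in self.scheme_codes:
            for b in self.scheme_codes:
                if a >= b:
                    continue
                x, y = self.get(a, b).clq, self.get(b, a).clq
                if not (isnan(x) or isnan(y)):
                    worst = max(worst, abs(x - y))
        return worst

    def to_dataframe(self, item: str = "") -> pd.DataFrame:
        """Long-format results, one row per ordered pair."""
        rows = []
        for a in self.scheme_codes:
            for b in self.scheme_codes:
                r = self.get(a, b)
                rows.append(
                    {
                        "item": item,
                        "index_cat": r.a,
                        "neighbor_cat": r.b,
                        "obs_pct": 100.0 * r.obs,
                        "exp_pct": 100.0 * r.exp_clq,
                        "clq": r.clq,
                        "clq_max": r.clq_max,
                        "kappa_exact": r.kappa_exact,
                        "kappa_from_clq": r.kappa_from_clq,
                        "se": r.se_null,
                        "p": r.p_value,
                        "stars": r.stars,
                    }
                )
        return pd.DataFrame.from_records(rows)


def association_matrix(table: WeightedContingencyTable) -> AssociationMatrix:
    """Compute both (a, b) and (b, a) for all pairs; no averaging."""
    if not table.is_square:
        raise InvalidInputError("association matrices require a square table")
    codes = table.scheme.codes
    results = {
        (int(a), int(b)): pair_association(table, a, b) for a in codes for b in codes
    }
    return AssociationMatrix(scheme_codes=codes, results=results, n_sets=table.n_sets)


@dataclass(frozen=True)
class PermutationNull:
    """Empirical null distribution of (CLQ, kappa) under random labeling."""

    clq: np.ndarray
    kappa: np.ndarray
    seed: int
    a: int
    b: int

    @property
    def n_perm(self) -> int:
        return self.clq.size

    @property
    def kappa_sd(self) -> float:
        return float(np.nanstd(self.kappa))


def permutation_null(
    data: RatingDataset,
    sets: list[MatchedSet] | tuple[MatchedSet, ...],
    item: str,
    a,
    b,
    n_perm: int,
    seed: int,
) -> PermutationNull:
    """Random-labeling reference distribution for the pair (a, b).

    Ratings are permuted across all rater locations (overall margins
    preserved) and CLQ plus the exact kappa are recomputed for each
    permutation on the fixed matched-set geometry.  Reproducible given
    ``seed``.
    """
    if n_perm < 1:
        raise InvalidInputError("n_perm must be >= 1")
    if not sets:
        raise InvalidInputError("permutation null requires matched sets")
    a, b = int(a), int(b)
    values = data.rating_values(item)
    n_sets = len(sets)
    index_pos = np.fromiter((s.index_pos for s in sets), dtype=np.int64, count=n_sets)
    m = np.fromiter((s.m for s in sets), dtype=np.int64, count=n_sets)
    nb_pos = np.concatenate([np.asarray(s.neighbor_pos, dtype=np.int64) for s in sets])
    weights = np.repeat(1.0 / m, m)
    idx_of_flat = index_pos[np.repeat(np.arange(n_sets), m)]

    rng = np.random.default_rng(seed)
    clqs = np.empty(n_perm)
    kappas = np.empty(n_perm)
    for t in range(n_perm):
        v = values[rng.permutation(data.n)]
        is_a_idx = v[index_pos] == a
        p_a = is_a_idx.mean()
        p_b = (v[index_pos] == b).mean()
        nb_is_b = v[nb_pos] == b
        o_ab = float(weights @ ((v[idx_of_flat] == a) & nb_is_b)) / n_sets
        q_b = float(weights @ nb_is_b) / n_sets
        if p_a <= _MARGIN_EPS or p_b <= _MARGIN_EPS:
            clqs[t] = kappas[t] = float("nan")
            continue
        clqs[t] = o_ab / (p_a * p_b)
        p_o = 1.0 - p_a - q_b + 2.0 * o_ab
        p_e = p_a * p_b + (1.0 - p_a) * (1.0 - p_b)
        kappas[t] = (p_o - p_e) / (1.0 - p_e) if p_e < 1.0 - _MARGIN_EPS else float("nan")
    return PermutationNull(clq=clqs, kappa=kappas, seed=seed, a=a, b=b)
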