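"""Collapsing rating categories and testing whether a merge is warranted.

Two categories may be combined without loss of reliability when

i.   they cluster spatially (cross-category CLQ > 1 and kappa > 0);
ii.  the cross-category CLQ is of the same magnitude as the smaller of the
     two same-category CLQs (operationalized as
     ``cross >= (1 - tau) * min(same_a, same_b)``, default ``tau = 0.15``);
iii. the same-category kappa of the merged category exceeds both original
     same-category kappas.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import isnan

import numpy as np

from .association import kappa_exact, clq
from .contingency import CategoryScheme, WeightedContingencyTable
from .errors import InvalidInputError, UndefinedStatisticError

__all__ = ["CollapseSpec", "CollapseReport", "collapse_table", "evaluate_collapse"]

DEFAULT_TAU = 0.15


@dataclass(frozen=True)
class CollapseSpec:
    """A partition of category codes into labeled super-categories."""

    groups: tuple  # of (label, tuple-of-codes)

    def __post_init__(self) -> None:
        groups = tuple((str(label), tuple(int(c) for c in codes)) for label, codes in self.groups)
        object.__setattr__(self, "groups", groups)
        seen: set = set()
        for _, codes in groups:
            if not codes:
                raise InvalidInputError("collapse groups must be non-empty")
            if seen & set(codes):
                raise InvalidInputError("collapse groups must be disjoint")
            seen |= set(codes)

    @property
    def all_codes(self) -> frozenset:
        return frozenset(c for _, codes in self.groups for c in codes)

    @classmethod
    def parse(cls, text: str) -> "CollapseSpec":
        """Parse the ``"1+2,3+4,5+6"`` syntax into a spec."""
        groups = []
        for part in text.split(","):
            part = part.strip()
            if not part:
                raise InvalidInputError(f"empty group in collapse spec {text!r}")
            try:
                codes = tuple(int(tok) for tok in part.split("+"))
            except ValueError:
                raise InvalidInputError(f"cannot parse collapse group {part!r}") from None
            label = "-".join(str(c) for c in codes) if len(codes) > 1 else str(codes[0])
            groups.append((label, codes))
        return cls(groups=tuple(groups))

    def validate_against(self, scheme: CategoryScheme) -> None:
        missing = set(scheme.codes) - self.all_codes
        extra = self.all_codes - set(scheme.codes)
        if missing:
            raise InvalidInputError(f"collapse spec does not cover codes {sorted(missing)}")
        if extra:
            raise InvalidInputError(f"collapse spec names unknown codes {sorted(extra)}")


def collapsed_scheme(spec: CollapseSpec, parent: CategoryScheme) -> CategoryScheme:
    """New scheme with codes 1..g; a group is informative iff all members are."""
    labels = tuple(label for label, _ in spec.groups)
    codes = tuple(range(1, len(spec.groups) + 1))
    informative = frozenset(
        code
        for code, (_, members) in zip(codes, spec.groups)
        if all(c in parent.informative for c in members)
    )
    return CategoryScheme(codes=codes, labels=labels, informative=informative)


def collapse_table(table: WeightedContingencyTable, spec: CollapseSpec) -> WeightedContingencyTable:
    """Sum cells and margins over the groups of a partition."""
    if not table.is_square:
        raise InvalidInputError("collapse requires a square table")
    spec.validate_against(table.scheme)
    g = len(spec.groups)
    masks = [
        np.array([c in set(codes) for c in table.scheme.codes]) for _, codes in spec.groups
    ]
    cells = np.zeros((g, g))
    for i, mi in enumerate(masks):
        for j, mj in enumerate(masks):
            cells[i, j] = table.cells[mi][:, mj].sum()
    scheme = collapsed_scheme(spec, table.scheme)
    return WeightedContingencyTable(
        cells=cells, row_scheme=scheme, col_scheme=scheme, n_sets=table.n_sets
    )


@dataclass(frozen=True)
class CollapseReport:
    """Evaluation of the three merge criteria for one candidate pair."""

    a: int
    b: int
    clq_cross: float
    kappa_cross: float
    clq_a: float
    clq_b: float
    kappa_a: float
    kappa_b: float
    kappa_collapsed: float
    tau: float
    criterion_i: bool
    criterion_ii: bool
    criterion_iii: bool

    @property
    def verdict(self) -> bool:
        return self.criterion_i and self.criterion_ii and self.criterion_iii

    def summary(self) -> str:
        mark = {True: "pass", False: "fail"}
        return (
            f"collapse {self.a}+{self.b}: "
            f"i) cross CLQ {self.clq_cross:.3g}, kappa {100 * self.kappa_cross:.2g}% "
            f"[{mark[self.criterion_i]}]; "
            f"ii) cross CLQ vs min same-category CLQ {min(self.clq_a, self.clq_b):.3g} "
            f"(tau={self.tau}) [{mark[self.criterion_ii]}]; "
            f"iii) collapsed kappa {100 * self.kappa_collapsed:.3g}% vs "
            f"{100 * self.kappa_a:.3g}%/{100 * self.kappa_b:.3g}% [{mark[self.criterion_iii]}]; "
            f"verdict: {'collapse supported' if self.verdict else 'not supported'}"
        )


def evaluate_collapse(
    table: WeightedContingencyTable, a, b, tau: float = DEFAULT_TAU
) -> CollapseReport:
    """Evaluate criteria i–iii for merging categories ``a`` and ``b``.

    The merged table keeps all other categories as singletons; statistics
    that are undefined on either table raise ``InvalidInputError``.
    """
    a, b = int(a), int(b)
    if a == b:
        raise InvalidInputError("a collapse candidate needs two distinct categories")
    scheme = table.scheme
    merged_label = f"{scheme.label(a)}-{scheme.label(b)}"
    groups = [(merged_label, (a, b))]
    groups += [(scheme.label(c), (c,)) for c in scheme.codes if c not in (a, b)]
    spec = CollapseSpec(groups=tuple(groups))
    collapsed = collapse_table(table, spec)
    merged_code = 1  # groups are coded 1..g in listed order

    try:
        clq_cross = clq(table, a, b)
        kappa_cross = kappa_exact(table, a, b)
        clq_a = clq(table, a, a)
        clq_b = clq(table, b, b)
        kappa_a = kappa_exact(table, a, a)
        kappa_b = kappa_exact(table, b, b)
        kappa_merged = kappa_exact(collapsed, merged_code, merged_code)
    except UndefinedStatisticError as exc:
        raise InvalidInputError(f"cannot evaluate collapse of ({a}, {b}): {exc}") from exc
    stats = [clq_cross, kappa_cross, clq_a, clq_b, kappa_a, kappa_b, kappa_merged]
    if any(isnan(s) for s in stats):
        raise InvalidInputError(f"missing statistics for collapse candidate ({a}, {b})")

    return CollapseReport(
        a=a,
        b=b,
        clq_cross=clq_cross,
        kappa_cross=kappa_cross,
        clq_a=clq_a,
        clq_b=clq_b,
        kappa_a=kappa_a,
        kappa_b=kappa_b,
        kappa_collapsed=kappa_merged,
        tau=tau,
        criterion_i=bool(clq_cross > 1.0 and kappa_cross > 0.0),
        criterion_ii=bool(clq_cross >= (1.0 - tau) * min(clq_a, clq_b)),
        criterion_iii=bool(kappa_merged > max(kappa_a, kappa_b)),
    )
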