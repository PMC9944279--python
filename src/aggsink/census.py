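"""Infection-census accounting and the study's statistical decision tree.

Host cells are classified into five stages: non-infected, early-infected
(encysted zoospore), maturely-infected (mature sporangium), post-infected
(empty sporangium after zoospore discharge), and decaying (no chlorophyll,
no infection signs — counted as uninfected). Infection prevalence is the
percentage of cells in the three infected stages, decaying cells included
in the denominator only.

Pairwise comparisons follow the decision tree: Shapiro–Wilk on each group;
if either rejects normality → Mann–Whitney; otherwise an F-test on the
variances routes to Welch (unequal) or Student's t (equal). Multi-group
comparisons use Kruskal–Wallis with Bonferroni-corrected pairwise
Mann–Whitney post-hocs and a compact-letter display. All tests two-sided
at α = 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "CellCensus",
    "ComparisonResult",
    "INFECTED_STAGES",
    "STAGES",
    "bacteria_per_aggregate",
    "enrichment",
    "multi_group_compare",
    "pairwise_compare",
    "prevalence",
    "propagate_uncertainty",
]

STAGES = ("non", "early", "mature", "post", "decaying")
INFECTED_STAGES = ("early", "mature", "post")


@dataclass
class CellCensus:
    """Counts by infection stage, with optional per-cell bacterial loads.

    ``bacteria`` maps stage → array of bacteria counted on individual cells
    of that stage. ``compartment`` is ``'aggregate'`` or ``'ambient'``.
    """

    counts: dict
    bacteria: dict = field(default_factory=dict)
    compartment: str = "aggregate"

    def __post_init__(self) -> None:
        unknown = set(self.counts) - set(STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        if any(v < 0 for v in self.counts.values()):
            raise ValueError("stage counts must be non-negative")

    @property
    def total(self) -> int:
        return int(sum(self.counts.get(s, 0) for s in STAGES))


def prevalence(census: CellCensus | Mapping[str, int]) -> float:
    """Infection prevalence in percent.

    100 · (early + mature + post) / total, where the total includes all
    five stages (decaying cells count as uninfected).
    """
    counts = census.counts if isinstance(census, CellCensus) else census
    total = sum(counts.get(s, 0) for s in STAGES)
    if total <= 0:
        raise ValueError("census contains no cells")
    infected = sum(counts.get(s, 0) for s in INFECTED_STAGES)
    return 100.0 * infected / total


def enrichment(prevalence_aggregate: float, prevalence_ambient: float) -> float:
    """Fold-enrichment of infected cells in aggregates vs. the ambient water.

    Plain prevalence ratio; rounding happens only at reporting time.
    """
    if prevalence_ambient <= 0:
        raise ValueError("ambient prevalence must be positive for a fold-enrichment")
    if prevalence_aggregate < 0:
        raise ValueError("prevalence cannot be negative")
    return prevalence_aggregate / prevalence_ambient


def bacteria_per_aggregate(
    stage_fractions: Mapping[str, float],
    mean_bacteria: Mapping[str, float],
    cells_per_aggregate: float = 20_000,
) -> float:
    """Bacteria per aggregate from the stage composition and per-cell loads.

    cells_per_aggregate · Σ_stage fraction · mean bacteria per cell. The
    default cell count is the study's assumed 20,000 host cells per
    aggregate.
    """
    if cells_per_aggregate < 0:
        raise ValueError("cells_per_aggregate must be non-negative")
    total = 0.0
    for stage, frac in stage_fractions.items():
        if frac == 0:
            continue
        if stage not in mean_bacteria:
            raise ValueError(f"missing mean bacterial load for stage {stage!r}")
        total += frac * mean_bacteria[stage]
    return cells_per_aggregate * total


# ---------------------------------------------------------------------------
# statistical decision tree


@dataclass(frozen=True)
class ComparisonResult:
    test_name: str
    statistic: float
    p_value: float
    group_letters: tuple = ()
    posthoc_p: tuple = ()

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0) and not np.isnan(self.p_value):
            raise ValueError("p-value out of [0, 1]")


class DegenerateDataError(ValueError):
    """Raised when the samples admit no meaningful test (e.g. zero variance)."""


def _variance_f_test(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided F-test p-value for equality of variances."""
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    f = vx / vy
    p_one = stats.f.sf(f, len(x) - 1, len(y) - 1)
    return float(min(2.0 * min(p_one, 1.0 - p_one), 1.0))


def pairwise_compare(x: Sequence[float], y: Sequence[float], alpha: float = 0.05) -> ComparisonResult:
    """Two-sample comparison following the normality/variance decision tree.

    Shapiro–Wilk on each group; either rejection (p < α) routes to the
    Mann–Whitney U test. Otherwise an F-test on the variances chooses
    Welch's t (unequal variances) or Student's t. Two-sided throughout.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("each sample needs at least 3 observations")
    if np.var(x) == 0 and np.var(y) == 0:
        raise DegenerateDataError("both samples are constant; no test is meaningful")
    if np.var(x) == 0 or np.var(y) == 0:
        # Shapiro is undefined for a constant sample; a constant sample is
        # maximally non-normal, so route to the rank test.
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        return ComparisonResult("mann_whitney", float(stat), float(p))
    sw_x = stats.shapiro(x).pvalue
    sw_y = stats.shapiro(y).pvalue
    if sw_x < alpha or sw_y < alpha:
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
        return ComparisonResult("mann_whitney", float(stat), float(p))
    if _variance_f_test(x, y) < alpha:
        stat, p = stats.ttest_ind(x, y, equal_var=False)
        return ComparisonResult("welch", float(stat), float(p))
    stat, p = stats.ttest_ind(x, y, equal_var=True)
    return ComparisonResult("t", float(stat), float(p))


def _compact_letters(n_groups: int, order: np.ndarray, distinct: set) -> tuple:
    """Insert-and-absorb compact-letter display.

    Groups are processed in mean order; each gets the first existing letter
    shared with no significantly different group, else a new letter.
    ``distinct`` holds index pairs that differ significantly.
    """
    letters: list[set] = [set() for _ in range(n_groups)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    next_letter = 0
    for gi in order:
        placed = False
        for li in range(next_letter):
            letter = alphabet[li]
            members = [j for j in range(n_groups) if letter in letters[j]]
            if all((min(gi, j), max(gi, j)) not in distinct for j in members):
                letters[gi].add(letter)
                placed = True
        if not placed:
            letters[gi].add(alphabet[next_letter])
            next_letter += 1
    return tuple("".join(sorted(s)) for s in letters)


def multi_group_compare(groups: Sequence[Sequence[float]], alpha: float = 0.05) -> ComparisonResult:
    """Kruskal–Wallis omnibus with Bonferroni-corrected pairwise post-hocs.

    Pairwise Mann–Whitney p-values are multiplied by the number of pairs
    (capped at 1); groups sharing no compact-display letter differ at α.
    """
    if len(groups) < 3:
        raise ValueError("multi-group comparison needs at least 3 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(len(a) < 3 for a in arrays):
        raise ValueError("each group needs at least 3 observations")
    stat, p = stats.kruskal(*arrays)
    k = len(arrays)
    m = k * (k - 1) // 2
    distinct: set = set()
    adj_p = []
    for i in range(k):
        for j in range(i + 1, k):
            _, p_ij = stats.mannwhitneyu(arrays[i], arrays[j], alternative="two-sided")
            p_adj = min(1.0, m * p_ij)
            adj_p.append(((i, j), p_adj))
            if p < alpha and p_adj < alpha:
                distinct.add((i, j))
    order = np.argsort([-np.mean(a) for a in arrays])
    letters = _compact_letters(k, order, distinct)
    return ComparisonResult(
        "kruskal_wallis", float(stat), float(p), group_letters=letters, posthoc_p=tuple(adj_p)
    )


# ---------------------------------------------------------------------------
# error propagation


def propagate_uncertainty(
    values: Sequence[float],
    sds: Sequence[float],
    expression: str | tuple,
) -> float:
    """First-order Gaussian error propagation; returns the sd of the result.

    ``'sum'``/``'difference'``: absolute sds add in quadrature.
    ``'product'``/``'quotient'``: relative sds add in quadrature.
    ``('power', k)``: single value, relative sd multiplied by \\|k\\|.
    """
    values = np.asarray(values, dtype=float)
    sds = np.asarray(sds, dtype=float)
    if values.shape != sds.shape:
        raise ValueError("values and sds must have equal length")
    if np.any(sds < 0):
        raise ValueError("standard deviations must be non-negative")
    if isinstance(expression, tuple):
        op, *args = expression
    else:
        op, args = expression, []
    if op in ("sum", "difference"):
        return float(np.sqrt(np.sum(sds**2)))
    if op in ("product", "quotient"):
        if np.any(values == 0):
            raise ValueError(f"{op} propagation requires non-zero values")
        result = np.prod(values) if op == "product" else values[0] / np.prod(values[1:])
        rel = np.sqrt(np.sum((sds / values) ** 2))
        return float(abs(result) * rel)
    if op == "power":
        if len(args) != 1:
            raise ValueError("power expression requires an exponent: ('power', k)")
        if values.size != 1:
            raise ValueError("power propagation takes a single value")
        (k,) = args
        v, s = float(values[0]), float(sds[0])
        if v == 0:
            raise ValueError("power propagation requires a non-zero value")
        return float(abs(v**k) * abs(k) * (s / abs(v)))
    raise ValueError(f"unknown expression {expression!r}")
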