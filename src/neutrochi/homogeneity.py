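"""The neutrosophic chi-square test for several multinomial samples.

Classical background: with ``h`` independent multinomial samples over
``k`` categories, the Pearson statistic

    Q = sum_j sum_i (Y_ij - n_j p_i)^2 / (n_j p_i)

is referred to a chi-square distribution with ``h(k-1)`` degrees of
freedom when the category probabilities ``p_i`` are specified in advance
(goodness-of-fit regime), or ``(h-1)(k-1)`` when they are estimated by
pooling all groups under the null of homogeneity.

The neutrosophic extension attaches an indeterminacy measure
``I in [I_L, I_U]`` to the statistic, turning it into an interval
``Q_N in [Q_L, Q_U]`` with ``Q_U = (1 + I_U) Q_L`` in the simplified
multiplicative form, or — for genuinely interval-valued counts — the
two-sum form where the determinate part is the Pearson sum over the lower
table and the indeterminate coefficient the Pearson sum over the upper
table.  Because the statistic is an interval, the decision is
trichotomous: *do not reject* when the whole interval is below the
critical value, *reject* when it is entirely above, *indeterminate* when
it straddles it.  At ``I = [0, 0]`` everything collapses to the classical
test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .core import IndeterminacyInterval, NeutrosophicValue, make_neutrosophic
from .counts import CountTable, NeutrosophicCountTable

__all__ = [
    "PooledEstimates",
    "TestConfig",
    "TestResult",
    "estimate_pooled_probabilities",
    "expected_counts",
    "pearson_statistic",
    "neutrosophic_statistic",
    "general_interval_statistic",
    "degrees_of_freedom",
    "critical_value",
    "run_test",
    "MIN_EXPECTED_WARN",
    "PROB_SUM_TOL",
]

Mode = Literal["goodness_of_fit", "homogeneity"]
Decision = Literal["reject", "do_not_reject", "indeterminate"]

#: classical adequacy heuristic: warn when any expected cell is below this
MIN_EXPECTED_WARN = 5.0
#: absolute tolerance on sum(p) == 1
PROB_SUM_TOL = 1e-9


@dataclass(frozen=True)
class PooledEstimates:
    """Pooled category-probability estimates under the homogeneity null.

    Each probability is an interval ``[p_L, p_U]``: the lower endpoint is
    estimated from the lower count table, the upper endpoint from the
    upper table.  For determinate data the interval is degenerate.
    """

    probabilities: tuple[NeutrosophicValue, ...]
    source_totals: tuple[int, ...]  # pooled category totals of the lower table

    @property
    def lower(self) -> np.ndarray:
        return np.array([p.lower for p in self.probabilities])

    @property
    def upper(self) -> np.ndarray:
        return np.array([p.upper for p in self.probabilities])


@dataclass(frozen=True)
class TestConfig:
    """Configuration for one run of the test."""

    __test__ = False  # not a pytest collection target

    alpha: float = 0.05
    indeterminacy: IndeterminacyInterval = field(
        default_factory=IndeterminacyInterval.classical
    )
    mode: Mode = "homogeneity"
    critical_value_override: float | None = None
    probabilities: tuple[float, ...] | None = None  # goodness-of-fit regime only

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError(f"alpha must lie in (0, 1), got {self.alpha}")
        if self.mode not in ("goodness_of_fit", "homogeneity"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.mode == "goodness_of_fit" and self.probabilities is None:
            raise ValueError("goodness_of_fit mode requires specified probabilities")
        if self.probabilities is not None:
            object.__setattr__(
                self, "probabilities", tuple(float(p) for p in self.probabilities)
            )


@dataclass(frozen=True)
class TestResult:
    """Outcome of the neutrosophic chi-square test."""

    __test__ = False  # not a pytest collection target

    statistic: NeutrosophicValue
    cell_contributions: np.ndarray  # h x k, lower-endpoint evaluation
    degrees_of_freedom: int
    critical_value: float
    decision: Decision
    alpha: float
    group_labels: tuple[str, ...] = ()
    category_labels: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "statistic": {
                "lower": self.statistic.lower,
                "upper": self.statistic.upper,
                "determinate_part": self.statistic.determinate_part,
                "indeterminate_coefficient": self.statistic.indeterminate_coefficient,
                "indeterminacy": [
                    self.statistic.indeterminacy.lower,
                    self.statistic.indeterminacy.upper,
                ],
            },
            "degrees_of_freedom": self.degrees_of_freedom,
            "alpha": self.alpha,
            "critical_value": self.critical_value,
            "decision": self.decision,
            "cell_contributions": self.cell_contributions.tolist(),
            "group_labels": list(self.group_labels),
            "category_labels": list(self.category_labels),
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def to_text(self) -> str:
        """Render the four-step report: hypotheses, threshold, statistic, decision."""
        s = self.statistic
        lines = [
            "Step 1: H0: all groups share one category-probability vector",
            "        H1: at least one group differs",
            f"Step 2: alpha = {self.alpha:g}, df = {self.degrees_of_freedom}, "
            f"critical value = {self.critical_value:g}",
            f"Step 3: Q_N = {s.determinate_part:.6g} + "
            f"{s.indeterminate_coefficient:.6g} * I, "
            f"I in [{s.indeterminacy.lower:g}, {s.indeterminacy.upper:g}]"
            f"  =>  Q in [{s.lower:.6f}, {s.upper:.6f}]",
            f"Step 4: decision: {self.decision.replace('_', ' ')}",
        ]
        return "\n".join(lines)


def estimate_pooled_probabilities(data: NeutrosophicCountTable) -> PooledEstimates:
    """Estimate category probabilities by pooling all groups, per endpoint.

    ``p_i,L = sum_j Y_ij,L / sum_j n_j,L`` from the lower table and
    likewise for the upper table; each endpoint vector sums to 1 because
    it is a vector of proportions of its own table.
    """
    lo, up = data.lower, data.upper
    grand_lo, grand_up = lo.grand_total, up.grand_total
    if grand_lo <= 0 or grand_up <= 0:
        raise ValueError("cannot estimate probabilities from an all-zero table")
    pooled_lo = lo.category_totals / grand_lo
    pooled_up = up.category_totals / grand_up
    if np.any((lo.category_totals == 0) & (up.category_totals == 0)):
        raise ValueError(
            "a category has zero pooled count in both endpoint tables; "
            "its expected counts would be degenerate"
        )
    # each endpoint vector comes from its own table so each sums to 1;
    # for a single category p_up may fall below p_lo when the upper table
    # shifts composition, hence the direct additive construction
    probs = tuple(
        NeutrosophicValue(a, b - a, IndeterminacyInterval(0.0, 1.0))
        if b != a
        else NeutrosophicValue(a, 0.0, IndeterminacyInterval.classical())
        for a, b in zip(pooled_lo, pooled_up)
    )
    return PooledEstimates(probs, tuple(int(t) for t in lo.category_totals))


def expected_counts(data: CountTable, probabilities: Sequence[float]) -> np.ndarray:
    """Expected cell counts ``E[j, i] = n_j * p_i`` under the null.

    Row sums equal the observed group totals.  A zero expected cell makes
    the Pearson statistic undefined and raises; expected cells below
    :data:`MIN_EXPECTED_WARN` trigger the classical adequacy warning.
    """
    p = np.asarray(probabilities, dtype=float)
    if p.ndim != 1 or p.size != data.n_categories:
        raise ValueError(
            f"expected {data.n_categories} probabilities, got shape {p.shape}"
        )
    if abs(p.sum() - 1.0) > PROB_SUM_TOL:
        raise ValueError(f"probabilities sum to {p.sum()!r}, not 1")
    if (p < 0).any():
        raise ValueError("probabilities must be nonnegative")
    expected = np.outer(data.group_totals, p)
    if (expected <= 0).any():
        raise ValueError(
            "degenerate expectation: some expected cell counts are zero "
            "(zero probability or empty group); the statistic is undefined"
        )
    if (expected < MIN_EXPECTED_WARN).any():
        warnings.warn(
            f"{int((expected < MIN_EXPECTED_WARN).sum())} expected cell(s) below "
            f"{MIN_EXPECTED_WARN}; the chi-square approximation may be poor",
            stacklevel=2,
        )
    return expected


def pearson_statistic(
    data: CountTable, probabilities: Sequence[float]
) -> tuple[float, np.ndarray]:
    """Pearson chi-square statistic and its per-cell contributions.

    ``Q = sum_j sum_i (Y_ij - n_j p_i)^2 / (n_j p_i)``; the returned
    contribution matrix has one term per cell, in table (row-major) order.
    """
    expected = expected_counts(data, probabilities)
    contributions = (data.counts - expected) ** 2 / expected
    return float(contributions.sum()), contributions


def neutrosophic_statistic(
    q_lower: float, indeterminacy: IndeterminacyInterval
) -> NeutrosophicValue:
    """Simplified multiplicative form ``Q_N = (1 + I) * Q_L``.

    The classical statistic is the determinate part; the upper endpoint is
    ``(1 + I_U) * Q_L``.
    """
    return make_neutrosophic(q_lower, indeterminacy)


def general_interval_statistic(
    data: NeutrosophicCountTable,
    estimates: PooledEstimates,
    indeterminacy: IndeterminacyInterval,
) -> NeutrosophicValue:
    """Two-sum interval form for genuinely interval-valued counts.

    The determinate part is the Pearson sum over the lower table with the
    lower estimates; the indeterminate coefficient is the Pearson sum over
    the upper table with the upper estimates, so
    ``Q_U = Q(lower) + Q(upper) * I_U``.  With degenerate data this does
    NOT coincide with the multiplicative form unless the coefficient
    equals the determinate part, which it does exactly then.
    """
    q_lo, _ = pearson_statistic(data.lower, estimates.lower)
    q_up, _ = pearson_statistic(data.upper, estimates.upper)
    return NeutrosophicValue(q_lo, q_up, indeterminacy)


def degrees_of_freedom(h: int, k: int, mode: Mode) -> int:
    """``h(k-1)`` with specified probabilities; ``(h-1)(k-1)`` with estimated."""
    if h < 1 or k < 2:
        raise ValueError(f"need h >= 1 and k >= 2, got h={h}, k={k}")
    if mode == "goodness_of_fit":
        return h * (k - 1)
    if mode == "homogeneity":
        if h < 2:
            raise ValueError(
                "homogeneity mode needs at least 2 groups (df would be 0)"
            )
        return (h - 1) * (k - 1)
    raise ValueError(f"unknown mode {mode!r}")


def critical_value(alpha: float, df: int, override: float | None = None) -> float:
    """Upper-tail chi-square critical value, or a caller-supplied override.

    The default is the ``1 - alpha`` quantile of the chi-square
    distribution with ``df`` degrees of freedom.  The override exists so a
    tabulated value from a specific published analysis can be reproduced
    exactly without changing the default behaviour.
    """
    if override is not None:
        if override <= 0:
            raise ValueError(f"critical value override must be > 0, got {override}")
        return float(override)
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if df < 1:
        raise ValueError(f"degrees of freedom must be >= 1, got {df}")
    return float(stats.chi2.ppf(1.0 - alpha, df))


def _decide(statistic: NeutrosophicValue, crit: float) -> Decision:
    if statistic.upper <= crit:
        return "do_not_reject"
    if statistic.lower > crit:
        return "reject"
    return "indeterminate"


def run_test(
    data: CountTable | NeutrosophicCountTable, config: TestConfig | None = None
) -> TestResult:
    """Run the neutrosophic chi-square test end to end.

    Homogeneity mode pools the groups for the probability estimates;
    goodness-of-fit mode uses the probabilities specified in ``config``.
    Determinate input (a plain :class:`CountTable`, or a degenerate
    interval table) uses the simplified multiplicative statistic; a
    genuinely interval-valued table uses the two-sum form.

    The decision is trichotomous: ``do_not_reject`` when
    ``Q_U <= critical value``, ``reject`` when ``Q_L > critical value``,
    ``indeterminate`` when the interval straddles it.
    """
    config = config or TestConfig()
    if isinstance(data, CountTable):
        interval_data = NeutrosophicCountTable.degenerate(data)
    else:
        interval_data = data
    lower_table = interval_data.lower
    h, k = lower_table.n_groups, lower_table.n_categories

    if config.mode == "homogeneity":
        estimates = estimate_pooled_probabilities(interval_data)
        p_lower, p_upper = estimates.lower, estimates.upper
    else:
        p = np.asarray(config.probabilities, dtype=float)
        p_lower = p_upper = p

    q_lower, contributions = pearson_statistic(lower_table, p_lower)
    if interval_data.is_degenerate:
        statistic = neutrosophic_statistic(q_lower, config.indeterminacy)
    else:
        q_upper, _ = pearson_statistic(interval_data.upper, p_upper)
        statistic = NeutrosophicValue(q_lower, q_upper, config.indeterminacy)

    df = degrees_of_freedom(h, k, config.mode)
    crit = critical_value(config.alpha, df, config.critical_value_override)
    return TestResult(
        statistic=statistic,
        cell_contributions=contributions,
        degrees_of_freedom=df,
        critical_value=crit,
        decision=_decide(statistic, crit),
        alpha=config.alpha,
        group_labels=lower_table.group_labels,
        category_labels=lower_table.category_labels,
    )
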