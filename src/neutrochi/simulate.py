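"""Indeterminacy sweeps, synthetic data, and Monte Carlo calibration.

Three validation surfaces for the neutrosophic homogeneity test:

* :func:`indeterminacy_sweep` — a deterministic rescaling study: fix the
  data, vary the upper indeterminacy endpoint ``I_U``, and record the
  statistic interval and the decision at each level.
* :func:`generate_null_table` / :func:`generate_synthetic_fasta` — seeded
  multinomial fixture generators, at the count-table and FASTA level.
* :func:`estimate_type_I_error` / :func:`estimate_power` — Monte Carlo
  operating characteristics.  Because the decision is trichotomous, both
  a rejection rate and an indeterminate rate are reported.

Randomness protocol: a single root seed spawns one independent substream
per replicate (``numpy.random.SeedSequence``), so results do not depend
on replicate execution order and are bit-reproducible given the seed.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from math import sqrt
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqIO import write as seqio_write
from Bio.SeqRecord import SeqRecord

from .core import IndeterminacyInterval, NeutrosophicValue, make_neutrosophic
from .counts import NUCLEOTIDES, CountTable
from .homogeneity import Decision, TestConfig, run_test

__all__ = [
    "SweepRow",
    "MonteCarloConfig",
    "MonteCarloResult",
    "TABLE2_GRID",
    "DEFAULT_SWEEP_GRID",
    "indeterminacy_sweep",
    "sweep_to_csv",
    "generate_null_table",
    "estimate_type_I_error",
    "estimate_power",
    "generate_synthetic_fasta",
]

#: default sweep grid for the upper indeterminacy endpoint:
#: 0, 0.01..0.09 step 0.01, then 0.1..1.0 step 0.1 (20 points)
DEFAULT_SWEEP_GRID: tuple[float, ...] = tuple(
    round(0.01 * i, 2) for i in range(10)
) + tuple(round(0.1 * i, 1) for i in range(1, 11))
TABLE2_GRID = DEFAULT_SWEEP_GRID  # historical alias


@dataclass(frozen=True)
class SweepRow:
    """One point of an indeterminacy sweep."""

    indeterminacy: IndeterminacyInterval
    statistic: NeutrosophicValue
    decision: Decision


@dataclass(frozen=True)
class MonteCarloConfig:
    """Configuration of a Monte Carlo calibration experiment.

    ``null_probabilities`` is the shared category vector under the
    homogeneity null; ``alternative_probabilities`` (h x k), when given,
    replaces it with per-group vectors.  ``group_sizes`` has one entry per
    group.
    """

    replicates: int
    seed: int
    group_sizes: tuple[int, ...]
    null_probabilities: tuple[float, ...]
    alternative_probabilities: tuple[tuple[float, ...], ...] | None = None
    alpha: float = 0.05
    indeterminacy: IndeterminacyInterval = IndeterminacyInterval(0.0, 0.0)

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if len(self.group_sizes) < 1 or any(n < 1 for n in self.group_sizes):
            raise ValueError("group sizes must be positive")
        _check_prob_vector(self.null_probabilities)
        if self.alternative_probabilities is not None:
            if len(self.alternative_probabilities) != len(self.group_sizes):
                raise ValueError("need one alternative probability row per group")
            for row in self.alternative_probabilities:
                if len(row) != len(self.null_probabilities):
                    raise ValueError("alternative rows must have k entries")
                _check_prob_vector(row)

    @property
    def h(self) -> int:
        return len(self.group_sizes)

    @property
    def k(self) -> int:
        return len(self.null_probabilities)


@dataclass(frozen=True)
class MonteCarloResult:
    """Estimated operating characteristics of the test."""

    rejection_rate: float
    indeterminate_rate: float
    standard_error: float
    replicates_run: int

    def to_dict(self) -> dict:
        return {
            "rejection_rate": self.rejection_rate,
            "indeterminate_rate": self.indeterminate_rate,
            "standard_error": self.standard_error,
            "replicates_run": self.replicates_run,
        }


def _check_prob_vector(p: Sequence[float]) -> None:
    arr = np.asarray(p, dtype=float)
    if arr.ndim != 1 or arr.size < 2:
        raise ValueError("probability vector needs at least 2 entries")
    if (arr < 0).any():
        raise ValueError("probabilities must be nonnegative")
    if abs(arr.sum() - 1.0) > 1e-9:
        raise ValueError(f"probabilities sum to {arr.sum()!r}, not 1")


def indeterminacy_sweep(
    data: CountTable,
    i_uppers: Sequence[float] = DEFAULT_SWEEP_GRID,
    config: TestConfig | None = None,
    round_q_to: int | None = None,
) -> list[SweepRow]:
    """Run the test at each upper indeterminacy level, lower fixed at 0.

    The determinate statistic ``Q_L`` is constant across the sweep; the
    upper endpoint ``(1 + I_U) Q_L`` is nondecreasing in ``I_U``, so a
    sweep shows at which indeterminacy level (if any) the decision leaves
    the do-not-reject region.

    ``round_q_to`` rounds ``Q_L`` to that many decimal places before the
    interval is formed.  Published sweep tables typically rescale the
    *reported* statistic rather than the full-precision one; rounding at
    reporting precision reproduces such tables digit for digit.  The
    default (``None``) keeps full precision.
    """
    i_uppers = [float(i) for i in i_uppers]
    if any(i < 0 for i in i_uppers):
        raise ValueError("indeterminacy levels must be >= 0")
    if any(b < a for a, b in zip(i_uppers, i_uppers[1:])):
        raise ValueError("indeterminacy levels must be sorted ascending")
    base = config or TestConfig()
    rows = []
    for i_u in i_uppers:
        cfg = TestConfig(
            alpha=base.alpha,
            indeterminacy=IndeterminacyInterval(0.0, i_u),
            mode=base.mode,
            critical_value_override=base.critical_value_override,
            probabilities=base.probabilities,
        )
        result = run_test(data, cfg)
        statistic = result.statistic
        if round_q_to is not None:
            statistic = make_neutrosophic(
                round(statistic.determinate_part, round_q_to), cfg.indeterminacy
            )
        decision: Decision = (
            "do_not_reject" if statistic.upper <= result.critical_value
            else "reject" if statistic.lower > result.critical_value
            else "indeterminate"
        )
        rows.append(SweepRow(cfg.indeterminacy, statistic, decision))
    return rows


def sweep_to_csv(rows: Sequence[SweepRow], path: str | Path) -> None:
    """Serialize a sweep as CSV: i_lower, i_upper, q_lower, q_upper, decision."""
    with open(Path(path), "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["i_lower", "i_upper", "q_lower", "q_upper", "decision"])
        for row in rows:
            writer.writerow(
                [
                    row.indeterminacy.lower,
                    row.indeterminacy.upper,
                    f"{row.statistic.lower:.6f}",
                    f"{row.statistic.upper:.6f}",
                    row.decision,
                ]
            )


def _draw_table(
    rng: np.random.Generator,
    group_sizes: Sequence[int],
    prob_rows: np.ndarray,
) -> CountTable:
    k = prob_rows.shape[1]
    counts = np.vstack(
        [rng.multinomial(n, prob_rows[j]) for j, n in enumerate(group_sizes)]
    )
    return CountTable(
        tuple(f"group{j + 1}" for j in range(len(group_sizes))),
        tuple(f"cat{i + 1}" for i in range(k)),
        counts,
    )


def generate_null_table(
    config: MonteCarloConfig, rng: np.random.Generator | None = None
) -> CountTable:
    """Draw one table under the homogeneity null: every row multinomial
    with the shared ``null_probabilities``.  Reproducible under the
    config seed."""
    rng = rng or np.random.default_rng(config.seed)
    p = np.tile(np.asarray(config.null_probabilities, float), (config.h, 1))
    return _draw_table(rng, config.group_sizes, p)


def _monte_carlo(config: MonteCarloConfig, prob_rows: np.ndarray) -> MonteCarloResult:
    streams = np.random.SeedSequence(config.seed).spawn(config.replicates)
    test_cfg = TestConfig(alpha=config.alpha, indeterminacy=config.indeterminacy)
    rejections = 0
    indeterminates = 0
    for stream in streams:
        rng = np.random.default_rng(stream)
        table = _draw_table(rng, config.group_sizes, prob_rows)
        decision = run_test(table, test_cfg).decision
        if decision == "reject":
            rejections += 1
        elif decision == "indeterminate":
            indeterminates += 1
    r = rejections / config.replicates
    return MonteCarloResult(
        rejection_rate=r,
        indeterminate_rate=indeterminates / config.replicates,
        standard_error=sqrt(r * (1.0 - r) / config.replicates),
        replicates_run=config.replicates,
    )


def estimate_type_I_error(config: MonteCarloConfig) -> MonteCarloResult:
    """Empirical type-I error under the homogeneity null.

    With ``I = [0, 0]`` and the default chi-square critical value the
    rejection rate should sit near ``alpha``; widening the indeterminacy
    interval moves borderline rejections into the indeterminate state and
    can only lower the rejection rate on identical seeds.
    """
    if config.alternative_probabilities is not None:
        raise ValueError("type-I error is estimated under the null; drop alt probs")
    p = np.tile(np.asarray(config.null_probabilities, float), (config.h, 1))
    return _monte_carlo(config, p)


def estimate_power(config: MonteCarloConfig) -> MonteCarloResult:
    """Empirical rejection rate under the specified alternative."""
    if config.alternative_probabilities is None:
        raise ValueError("power estimation requires alternative_probabilities")
    p = np.asarray(config.alternative_probabilities, float)
    return _monte_carlo(config, p)


def generate_synthetic_fasta(
    records: int,
    length: int,
    probabilities: Sequence[float],
    seed: int,
    path: str | Path,
) -> CountTable:
    """Write a synthetic FASTA with multinomial base composition.

    Each record's A/C/G/T counts are drawn once from
    ``multinomial(length, probabilities)`` and the sequence is a seeded
    permutation of exactly those bases, so counting the file recovers the
    generating totals exactly.  Returns the generating count table (one
    row per record; rows may differ in countable length only if a
    probability is 0 — they never do here, the row totals all equal
    ``length``).
    """
    if records < 1:
        raise ValueError("need at least one record")
    if length <= 0:
        raise ValueError(f"sequence length must be positive, got {length}")
    p = np.asarray(probabilities, dtype=float)
    if p.size != 4:
        raise ValueError("need exactly 4 probabilities, one per base A,C,G,T")
    _check_prob_vector(p)

    rng = np.random.default_rng(seed)
    bases = np.array(list(NUCLEOTIDES))
    rows = []
    seq_records = []
    for r in range(records):
        counts = rng.multinomial(length, p)
        letters = np.repeat(bases, counts)
        rng.shuffle(letters)
        rows.append(counts)
        seq_records.append(
            SeqRecord(Seq("".join(letters)), id=f"synthetic_{r + 1}", description="")
        )
    seqio_write(seq_records, str(Path(path)), "fasta")
    return CountTable(
        tuple(f"synthetic_{r + 1}" for r in range(records)),
        NUCLEOTIDES,
        np.vstack(rows),
    )
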