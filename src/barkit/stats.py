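"""Library-design mathematics: coverage, required size, expected class
counts and barcode uniqueness.

The sampling model: each of N independent insertion mutants lands uniformly
in a genome, so a gene occupying fraction f of the genome is hit at least
once with probability P = 1 - (1-f)^N.  Uniqueness of barcodes drawn from a
pool of K clones is a birthday problem; both the per-mutant reading (the
bound a library designer quotes per strain) and the stricter library-wide
reading are reported, because they differ by orders of magnitude at
realistic N.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "LibraryDesign",
    "coverage_probability",
    "required_mutants",
    "expected_class_count",
    "uniqueness_probability",
    "UnreachableTargetError",
]


class UnreachableTargetError(ValueError):
    pass


@dataclass(frozen=True)
class LibraryDesign:
    """Operating point of a barcode-tagged insertion library.

    f: gene fraction of the genome (gene size / genome size);
    N: number of insertion mutants;
    K: barcode clones per bacterial sub-library;
    coding_fraction: fraction of the genome inside protein-coding genes.
    """

    f: float = 2 / 14_000
    N: int = 10_000
    K: float = 1.86e5
    coding_fraction: float = 0.57

    def __post_init__(self) -> None:
        if not 0 < self.f < 1:
            raise ValueError("f must be in (0, 1)")
        if self.N < 0:
            raise ValueError("N must be >= 0")
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if not 0 <= self.coding_fraction <= 1:
            raise ValueError("coding_fraction must be in [0, 1]")


def coverage_probability(f: float, N: int) -> float:
    """P = 1 - (1-f)^N: chance that a gene of genome-fraction f is hit at
    least once by N uniform insertions."""
    if not 0 < f <= 1:
        raise ValueError("f must be in (0, 1]")
    if N < 0:
        raise ValueError("N must be >= 0")
    return -math.expm1(N * math.log1p(-f)) if f < 1 else (0.0 if N == 0 else 1.0)


def required_mutants(f: float, P_target: float) -> int:
    """Smallest N with coverage_probability(f, N) >= P_target."""
    if not 0 < f < 1:
        raise ValueError("f must be in (0, 1)")
    if not 0 <= P_target < 1:
        if P_target == 1:
            raise UnreachableTargetError("P = 1 is unreachable for f < 1")
        raise ValueError("P_target must be in [0, 1)")
    if P_target == 0:
        return 0
    n = math.ceil(math.log1p(-P_target) / math.log1p(-f))
    # guard the boundary against floating-point round-off
    while n > 0 and coverage_probability(f, n - 1) >= P_target:
        n -= 1
    while coverage_probability(f, n) < P_target:
        n += 1
    return n


def expected_class_count(
    N: int, k_class: int, k_total: int, coding_fraction: float
) -> tuple[float, int]:
    """Expected number of mutants in a phenotype class.

    With k_class of k_total annotated genes in the class and only the coding
    fraction of the genome mutable to a visible phenotype, the expectation
    among N assayed mutants is N * (k_class/k_total) * coding_fraction.
    Returns (real value, half-up-rounded integer).
    """
    if k_total < 1:
        raise ValueError("k_total must be >= 1")
    if not 0 <= k_class <= k_total:
        raise ValueError("require 0 <= k_class <= k_total")
    value = N * (k_class / k_total) * coding_fraction
    rounded = int(Decimal(value).quantize(Decimal("1"), rounding=ROUND_HALF_UP))
    return value, rounded


def uniqueness_probability(K: float, N: int) -> tuple[float, float]:
    """(per_mutant, all_unique) barcode-uniqueness probabilities.

    per_mutant: probability that a given mutant's barcode was drawn by none
    of the other N-1 mutants, (1 - 1/K)^(N-1).
    all_unique: probability that all N draws differ, prod_{i<N} (1 - i/K),
    computed in log space; 0 by pigeonhole when N > K.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    if N < 1:
        raise ValueError("N must be >= 1")
    per_mutant = math.exp((N - 1) * math.log1p(-1 / K)) if K > 1 else (1.0 if N == 1 else 0.0)
    if N > K:
        return per_mutant, 0.0
    log_all = 0.0
    for i in range(1, N):
        log_all += math.log1p(-i / K)
    return per_mutant, math.exp(log_all)
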