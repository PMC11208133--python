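"""Closed-form library sizes and bounds.

All arithmetic is exact integer arithmetic; nothing in this module touches
floating point.  The central identity: a library built by partitioning a
Hamiltonian path on the k-mer graph into blocks of L-k+1 nodes has exactly

    N = floor(m**k / (L - k + 1))

sequences, and no SSM-satisfying library can be larger, because the design
already uses every one of the m**k k-mers and a larger library would have
to repeat one (pigeonhole).

Downstream filters shrink the library by a bounded amount: since no k-mer
occurs in two sequences, each forbidden k-mer can knock out at most one
sequence, which yields the pattern bound K_p <= (k-p+1) * m**(k-p), the
post-filter size N_p >= N - K_p, and — for three-letter (A/C/T) libraries
with odd k — the reverse-complement bound N_rc >= N - 2**(k-1), because
only the 2**(k-1) A/T-only k-mers with the discarded middle base can cost
a sequence.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ContractError, InfeasibleDesignError, ParameterError

__all__ = [
    "SizeBound",
    "library_size",
    "max_orthogonality",
    "pattern_kmer_bound",
    "pattern_filtered_bound",
    "rc_filtered_bound",
]


@dataclass(frozen=True)
class SizeBound:
    """An exact integer size statement about a library.

    ``kind`` records the direction of the statement: the maximal-size
    formula is exact, the pattern k-mer count is an upper bound, the
    post-filter sizes are lower bounds.
    """

    value: int
    kind: str        # "exact" | "upper_bound" | "lower_bound"
    formula_id: str  # "eq1" | "eq2" | "eq3" | "eq4"

    def __post_init__(self) -> None:
        if self.value < 0:
            raise ParameterError("a size bound cannot be negative")
        if self.kind not in ("exact", "upper_bound", "lower_bound"):
            raise ParameterError(f"unknown bound kind {self.kind!r}")

    def __int__(self) -> int:
        return self.value


def _check_mkL(m: int, k: int, L: int) -> None:
    if not 2 <= m <= 4:
        raise ParameterError(f"alphabet size m must be in [2, 4], got {m}")
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if k > L:
        raise ParameterError(f"k={k} exceeds L={L}")


def library_size(m: int, k: int, L: int) -> SizeBound:
    """Maximal SSM library size: floor(m**k / (L - k + 1)).

    This is exact — the partitioned-Hamiltonian-path design achieves it,
    and no SSM-for-k library of length-L sequences can exceed it.
    """
    _check_mkL(m, k, L)
    return SizeBound(m ** k // (L - k + 1), "exact", "eq1")


def max_orthogonality(N_d: int, L: int, m: int = 4) -> int:
    """Smallest SSM order k whose maximal library reaches a desired size.

    Scans k = 1, 2, ... and returns the first k with
    ``library_size(m, k, L) >= N_d``.  Smaller k is a stronger
    orthogonality constraint, so this is the most orthogonal design able
    to deliver N_d barcodes of length L.

    Raises
    ------
    InfeasibleDesignError
        If even k = L (all m**L sequences) cannot reach N_d.
    """
    if N_d < 1:
        raise ParameterError(f"desired library size must be >= 1, got {N_d}")
    _check_mkL(m, 1, L)
    for k in range(1, L + 1):
        if library_size(m, k, L).value >= N_d:
            return k
    raise InfeasibleDesignError(
        f"no SSM order k <= L={L} yields {N_d} sequences over an "
        f"m={m} alphabet (maximum is {m**L} at k=L)"
    )


def pattern_kmer_bound(k: int, p: int, m: int) -> SizeBound:
    """Upper bound on the number of k-mers containing a fixed length-p
    pattern: (k - p + 1) * m**(k - p).

    Position-times-context counting; over-counts k-mers containing the
    pattern more than once, hence an upper bound.
    """
    if not 2 <= m <= 4:
        raise ParameterError(f"alphabet size m must be in [2, 4], got {m}")
    if p < 1:
        raise ParameterError(f"pattern length p must be >= 1, got {p}")
    if p > k:
        raise ParameterError(f"pattern length p={p} exceeds k={k}")
    return SizeBound((k - p + 1) * m ** (k - p), "upper_bound", "eq2")


def pattern_filtered_bound(N: int, K_p: int) -> SizeBound:
    """Lower bound on library size after removing one pattern: N - K_p.

    Valid for full SSM designs with pattern length p <= k: every removed
    sequence must contain at least one of the <= K_p pattern-bearing
    k-mers, and no k-mer is in two sequences.
    """
    if N < 0 or K_p < 0:
        raise ParameterError("N and K_p must be non-negative")
    return SizeBound(max(N - K_p, 0), "lower_bound", "eq3")


def rc_filtered_bound(N: int, k: int) -> SizeBound:
    """Lower bound on a three-letter, odd-k library after
    reverse-complement filtering: N - 2**(k-1).

    Only A/T-only k-mers can collide with a reverse complement inside an
    A/C/T library (any C maps to an absent G); there are 2**k of those,
    the middle-base partition discards half, and each discarded k-mer
    costs at most one sequence.  Proven only for odd k, where the middle
    base exists and no k-mer is its own reverse complement.
    """
    if N < 0:
        raise ParameterError("N must be non-negative")
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    if k % 2 == 0:
        raise ContractError(
            f"the reverse-complement bound is proven only for odd k "
            f"(three-letter middle-base partition); got k={k}"
        )
    return SizeBound(max(N - 2 ** (k - 1), 0), "lower_bound", "eq4")
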