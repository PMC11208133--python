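"""Alphabets and design parameters.

A design is fully specified by an ordered DNA alphabet (2-4 of the bases
A, C, G, T), the SSM order ``k`` (no length-k subsequence may appear more
than once anywhere in the library) and the barcode length ``L``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

from .errors import AlphabetError, ParameterError

#: Watson-Crick complement over the full DNA alphabet.
DNA_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

_DNA = ("A", "C", "G", "T")


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of DNA symbols.

    Symbols are normalised to uppercase and sorted lexicographically
    (A < C < G < T), which fixes the traversal order of every graph
    algorithm in this package and hence makes designs deterministic.

    The complement map is always defined over the full four-letter
    alphabet: for a three-letter A/C/T alphabet the complement of C is G,
    which lies *outside* the alphabet — that asymmetry is precisely what
    makes three-letter libraries easy to protect against
    reverse-complement crosstalk.
    """

    symbols: tuple[str, ...]

    def __init__(self, symbols) -> None:
        syms = tuple(str(s).upper() for s in symbols)
        if len(set(syms)) != len(syms):
            raise AlphabetError(f"duplicate symbols in alphabet {syms!r}")
        for s in syms:
            if s not in _DNA:
                raise AlphabetError(
                    f"symbol {s!r} is not one of A, C, G, T "
                    "(IUPAC ambiguity codes are not supported)"
                )
        if not 2 <= len(syms) <= 4:
            raise AlphabetError(
                f"alphabet must have 2-4 symbols, got {len(syms)}"
            )
        object.__setattr__(self, "symbols", tuple(sorted(syms)))

    # -- basic protocol ------------------------------------------------
    @property
    def m(self) -> int:
        """Alphabet size."""
        return len(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __iter__(self) -> Iterator[str]:
        return iter(self.symbols)

    def __contains__(self, s: str) -> bool:
        return s in self.symbols

    def __str__(self) -> str:
        return "".join(self.symbols)

    def index(self, symbol: str) -> int:
        """Rank of a single symbol (its base-m digit)."""
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise AlphabetError(
                f"symbol {symbol!r} not in alphabet {self}"
            ) from None

    def complement(self, symbol: str) -> str:
        """Watson-Crick complement (may fall outside the alphabet)."""
        try:
            return DNA_COMPLEMENT[symbol]
        except KeyError:
            raise AlphabetError(f"{symbol!r} has no DNA complement") from None

    # -- constructors --------------------------------------------------
    @classmethod
    def dna(cls) -> "Alphabet":
        """The full four-letter alphabet ACGT."""
        return cls(_DNA)

    @classmethod
    def three_letter(cls) -> "Alphabet":
        """The A/C/T alphabet used for reverse-complement-safe designs."""
        return cls(("A", "C", "T"))

    @classmethod
    def from_string(cls, s: str) -> "Alphabet":
        return cls(tuple(s))

    def is_three_letter_act(self) -> bool:
        return self.symbols == ("A", "C", "T")


@dataclass(frozen=True)
class DesignParams:
    """Parameters of one library design run.

    Parameters
    ----------
    alphabet
        The allowed alphabet (size m).
    k
        SSM order in nt: no k-mer may occur twice across the library.
        Smaller k is a stronger orthogonality constraint.
    L
        Barcode length in nt.
    """

    alphabet: Alphabet
    k: int
    L: int

    def __post_init__(self) -> None:
        if not isinstance(self.k, int) or not isinstance(self.L, int):
            raise ParameterError("k and L must be integers")
        if self.k < 1:
            raise ParameterError(f"k must be >= 1, got {self.k}")
        if self.k > self.L:
            raise ParameterError(
                f"SSM order k={self.k} exceeds barcode length L={self.L}"
            )

    @property
    def m(self) -> int:
        return self.alphabet.m

    @property
    def n_kmers(self) -> int:
        """Number of nodes in the k-mer graph, m**k (exact integer)."""
        return self.m ** self.k

    @property
    def nodes_per_sequence(self) -> int:
        """Path length representing one barcode: L - k + 1."""
        return self.L - self.k + 1

    def to_dict(self) -> dict:
        return {"alphabet": str(self.alphabet), "k": self.k, "L": self.L}

    @classmethod
    def from_dict(cls, d: dict) -> "DesignParams":
        return cls(Alphabet.from_string(d["alphabet"]), int(d["k"]), int(d["L"]))
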