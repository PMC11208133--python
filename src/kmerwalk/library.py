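"""Containers: sequence libraries, filter reports, audit reports."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

from .alphabet import Alphabet, DesignParams
from .errors import AlphabetError


@dataclass
class SequenceLibrary:
    """An ordered collection of equal-purpose barcode sequences.

    ``provenance`` is an append-only list of dicts, one per operation
    (design, each filter, ...), carrying the counts needed to reconcile
    ``designed - sum(removed) == len(sequences)``.

    The container itself does not enforce uniqueness or SSM — random
    fixture libraries are deliberately allowed to violate both so that
    the audits have something to find.  Libraries produced by
    :func:`kmerwalk.graph.design_library` are unique by construction.
    """

    sequences: list[str]
    params: Optional[DesignParams] = None
    provenance: list[dict] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self) -> Iterator[str]:
        return iter(self.sequences)

    def __getitem__(self, i):
        return self.sequences[i]

    @property
    def alphabet(self) -> Alphabet:
        """Declared alphabet, or the one inferred from the sequences."""
        if self.params is not None:
            return self.params.alphabet
        used = sorted(set().union(*map(set, self.sequences)) if self.sequences else ())
        if not used:
            return Alphabet.dna()
        if len(used) < 2:  # Alphabet requires >= 2 symbols
            used = sorted(set(used) | {"A" if "A" not in used else "T"})
        return Alphabet(used)

    def symbol_check(self) -> None:
        """Raise if any sequence uses a symbol outside the alphabet."""
        allowed = set(self.alphabet.symbols)
        for i, seq in enumerate(self.sequences):
            bad = set(seq) - allowed
            if bad:
                raise AlphabetError(
                    f"sequence {i} uses symbols {sorted(bad)} outside alphabet "
                    f"{self.alphabet}"
                )

    def replace(self, sequences: Sequence[str], provenance_entry: dict | None = None
                ) -> "SequenceLibrary":
        """New library with the same params and extended provenance."""
        prov = list(self.provenance)
        if provenance_entry is not None:
            prov.append(provenance_entry)
        return SequenceLibrary(list(sequences), self.params, prov)

    def reconcile(self) -> bool:
        """True iff provenance counts add up to the current size."""
        designed = None
        removed = 0
        for entry in self.provenance:
            if "sequences_designed" in entry:
                designed = entry["sequences_designed"]
            removed += entry.get("removed", 0)
        if designed is None:
            return True
        return designed - removed == len(self.sequences)


@dataclass
class FilterReport:
    """Outcome of one per-sequence filter pass."""

    rule: str
    n_input: int
    n_removed: int
    n_kept: int
    removed_examples: list[str] = field(default_factory=list)
    details: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "n_input": self.n_input,
            "n_removed": self.n_removed,
            "n_kept": self.n_kept,
            "removed_examples": self.removed_examples,
            "details": self.details,
        }


@dataclass
class AuditReport:
    """Outcome of an SSM or reverse-complement audit.

    ``violations`` is a (possibly truncated) list of dicts; ``n_violations``
    is always the full count, so ``ok`` is exact even when the listing is
    truncated for very large libraries.
    """

    kind: str                       # "ssm" or "rc"
    k: int
    n_sequences: int
    n_kmers_scanned: int
    n_violations: int
    violations: list[dict] = field(default_factory=list)
    truncated: bool = False

    @property
    def ok(self) -> bool:
        return self.n_violations == 0

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "k": self.k,
            "n_sequences": self.n_sequences,
            "n_kmers_scanned": self.n_kmers_scanned,
            "n_violations": self.n_violations,
            "ok": self.ok,
            "violations": self.violations,
            "truncated": self.truncated,
        }


def as_sequences(library) -> list[str]:
    """Accept a SequenceLibrary or any iterable of strings."""
    if isinstance(library, SequenceLibrary):
        return library.sequences
    return list(library)
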