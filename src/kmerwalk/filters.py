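"""Downstream constraint filters and library QC metrics.

Every filter is a pure, order-preserving per-sequence predicate: survivors
are a subset of the input in input order, and the report reconciles
(kept + removed == input).  Because each filter looks at one sequence at a
time, any two filters commute set-wise.

The melting-temperature filter offers the Wallace rule (2 °C per A/T,
4 °C per G/C — the usual quick rule for short primers) and the
SantaLucia nearest-neighbor model via Biopython, with pinned salt and
strand-concentration defaults recorded in the report.

The secondary-structure screen is a longest-intramolecular-reverse-
complement-match heuristic, not an energy model: it returns the largest s
for which some length-s substring and its reverse complement both occur
in the sequence (a proxy for hairpin-forming self-complementarity).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .audit import _rc, ssm_audit
from .errors import ParameterError
from .library import FilterReport, SequenceLibrary, as_sequences
from .rc import _apply_predicate

__all__ = [
    "ConstraintSet",
    "pattern_filter",
    "homopolymer_filter",
    "max_homopolymer_run",
    "gc_content",
    "gc_filter",
    "melting_temp",
    "tm_filter",
    "selfcomp_screen",
    "structure_filter",
    "apply_constraints",
    "hamming_matrix",
    "qc_report",
    "qc_table",
    "NN_DEFAULTS",
]

#: Nearest-neighbor Tm conditions (SantaLucia & Hicks 2004 parameter table,
#: Biopython DNA_NN4), recorded in every nn-based FilterReport.
NN_DEFAULTS = {
    "nn_table": "SantaLucia & Hicks (2004), Biopython DNA_NN4",
    "Na_mM": 50.0,
    "dnac1_nM": 25.0,
    "dnac2_nM": 25.0,
}


@dataclass
class ConstraintSet:
    """Bundle of downstream constraints; ``None`` disables a constraint.

    GC bounds are fractions (0..1), inclusive on both ends; Tm bounds are
    in °C; ``structure_max_selfcomp`` is the longest allowed intramolecular
    reverse-complement match in nt.
    """

    forbidden_patterns: list[str] = field(default_factory=list)
    max_homopolymer: Optional[int] = None
    gc_window: Optional[tuple[float, float]] = None
    tm_window: Optional[tuple[float, float]] = None
    tm_method: str = "wallace"
    structure_max_selfcomp: Optional[int] = None

    def __post_init__(self) -> None:
        if self.gc_window is not None:
            lo, hi = self.gc_window
            if not 0 <= lo <= hi <= 1:
                raise ParameterError(f"bad GC window [{lo}, {hi}]")
        if self.tm_window is not None:
            lo, hi = self.tm_window
            if lo > hi:
                raise ParameterError(f"bad Tm window [{lo}, {hi}]")
        if self.max_homopolymer is not None and self.max_homopolymer < 1:
            raise ParameterError("max_homopolymer must be >= 1")
        if self.tm_method not in ("wallace", "nn_santalucia"):
            raise ParameterError(f"unknown Tm method {self.tm_method!r}")

    def is_empty(self) -> bool:
        return (not self.forbidden_patterns and self.max_homopolymer is None
                and self.gc_window is None and self.tm_window is None
                and self.structure_max_selfcomp is None)


# ---------------------------------------------------------------------------
# pattern / homopolymer
# ---------------------------------------------------------------------------

def pattern_filter(library, patterns) -> tuple[SequenceLibrary, FilterReport]:
    """Remove every sequence containing any of the patterns as a substring.

    Overlapping occurrences count; one occurrence suffices for removal.
    On a full SSM design with pattern length p <= k, survivors number at
    least N - (k-p+1)*m**(k-p) per pattern.
    """
    pats = [str(p).upper() for p in patterns]
    if any(not p for p in pats):
        raise ParameterError("empty pattern")
    return _apply_predicate(
        library, lambda s: not any(p in s for p in pats),
        rule="pattern", details={"patterns": pats},
    )


def max_homopolymer_run(seq: str) -> int:
    """Length of the longest run of one repeated base."""
    best = run = 0
    prev = ""
    for ch in seq:
        run = run + 1 if ch == prev else 1
        prev = ch
        if run > best:
            best = run
    return best


def homopolymer_filter(library, max_run: int
                       ) -> tuple[SequenceLibrary, FilterReport]:
    """Remove sequences with any base repeated more than ``max_run`` times.

    Equivalent to :func:`pattern_filter` with the m patterns
    "X * (max_run+1)"; implemented as a direct run-length scan.
    """
    if max_run < 1:
        raise ParameterError("max_run must be >= 1")
    return _apply_predicate(
        library, lambda s: max_homopolymer_run(s) <= max_run,
        rule="homopolymer", details={"max_run": max_run},
    )


# ---------------------------------------------------------------------------
# GC content
# ---------------------------------------------------------------------------

def gc_content(seq: str) -> float:
    """Fraction of G or C bases: (#G + #C) / len."""
    if not seq:
        raise ParameterError("empty sequence")
    return (seq.count("G") + seq.count("C")) / len(seq)


def gc_filter(library, lo: float, hi: float
              ) -> tuple[SequenceLibrary, FilterReport]:
    """Keep sequences with lo <= GC fraction <= hi (inclusive)."""
    if not 0 <= lo <= hi <= 1:
        raise ParameterError(f"bad GC window [{lo}, {hi}]")
    return _apply_predicate(
        library, lambda s: lo <= gc_content(s) <= hi,
        rule="gc", details={"lo": lo, "hi": hi},
    )


# ---------------------------------------------------------------------------
# melting temperature
# ---------------------------------------------------------------------------

def melting_temp(seq: str, method: str = "wallace") -> float:
    """Melting temperature in °C.

    ``wallace``: 2*(#A + #T) + 4*(#G + #C) — the quick additive rule,
    reasonable for oligos under ~14 nt.  ``nn_santalucia``: SantaLucia
    nearest-neighbor thermodynamics via Biopython under the
    :data:`NN_DEFAULTS` conditions; requires at least 2 nt.
    """
    if method == "wallace":
        at = seq.count("A") + seq.count("T")
        gc = seq.count("G") + seq.count("C")
        return float(2 * at + 4 * gc)
    if method == "nn_santalucia":
        if len(seq) < 2:
            raise ParameterError(
                "nearest-neighbor Tm needs at least 2 nt"
            )
        from Bio.SeqUtils import MeltingTemp as mt

        return float(
            mt.Tm_NN(
                seq, nn_table=mt.DNA_NN4, Na=NN_DEFAULTS["Na_mM"],
                dnac1=NN_DEFAULTS["dnac1_nM"], dnac2=NN_DEFAULTS["dnac2_nM"],
            )
        )
    raise ParameterError(f"unknown Tm method {method!r}")


def tm_filter(library, lo: float, hi: float, method: str = "wallace"
              ) -> tuple[SequenceLibrary, FilterReport]:
    """Keep sequences with lo <= Tm <= hi (°C, inclusive)."""
    if lo > hi:
        raise ParameterError(f"bad Tm window [{lo}, {hi}]")
    details = {"lo": lo, "hi": hi, "method": method}
    if method == "nn_santalucia":
        details.update(NN_DEFAULTS)
    return _apply_predicate(
        library, lambda s: lo <= melting_temp(s, method) <= hi,
        rule="tm", details=details,
    )


# ---------------------------------------------------------------------------
# secondary-structure heuristic
# ---------------------------------------------------------------------------

def selfcomp_screen(seq: str, max_len: Optional[int] = None) -> int:
    """Longest intramolecular reverse-complement match, in nt.

    Returns the largest s such that some length-s substring of ``seq``
    has its reverse complement also occurring in ``seq`` (the two may
    overlap); 0 if no base pairs with any other.  A sequence that is its
    own reverse complement scores its full length.
    """
    n = len(seq)
    cap = n if max_len is None else min(max_len, n)
    for s in range(cap, 0, -1):
        windows = {seq[i : i + s] for i in range(n - s + 1)}
        if any(_rc(w) in windows for w in windows):
            return s
    return 0


def structure_filter(library, threshold: int
                     ) -> tuple[SequenceLibrary, FilterReport]:
    """Keep sequences whose longest self-complementary match <= threshold."""
    if threshold < 0:
        raise ParameterError("threshold must be >= 0")
    return _apply_predicate(
        library, lambda s: selfcomp_screen(s, threshold + 1) <= threshold,
        rule="structure", details={"max_selfcomp": threshold},
    )


# ---------------------------------------------------------------------------
# constraint pipeline
# ---------------------------------------------------------------------------

def apply_constraints(library, constraints: ConstraintSet
                      ) -> tuple[SequenceLibrary, list[FilterReport]]:
    """Apply every active constraint in a fixed order, collecting reports.

    Order (patterns, homopolymer, GC, Tm, structure) affects only the
    intermediate reports — the surviving set is order-independent because
    each filter is a per-sequence predicate.
    """
    reports: list[FilterReport] = []
    lib = library if isinstance(library, SequenceLibrary) else SequenceLibrary(
        as_sequences(library))
    if constraints.forbidden_patterns:
        lib, r = pattern_filter(lib, constraints.forbidden_patterns)
        reports.append(r)
    if constraints.max_homopolymer is not None:
        lib, r = homopolymer_filter(lib, constraints.max_homopolymer)
        reports.append(r)
    if constraints.gc_window is not None:
        lib, r = gc_filter(lib, *constraints.gc_window)
        reports.append(r)
    if constraints.tm_window is not None:
        lo, hi = constraints.tm_window
        lib, r = tm_filter(lib, lo, hi, constraints.tm_method)
        reports.append(r)
    if constraints.structure_max_selfcomp is not None:
        lib, r = structure_filter(lib, constraints.structure_max_selfcomp)
        reports.append(r)
    return lib, reports


# ---------------------------------------------------------------------------
# QC metrics
# ---------------------------------------------------------------------------

def hamming_matrix(library) -> np.ndarray:
    """Symmetric matrix of pairwise Hamming distances.

    Requires equal-length sequences.  O(n^2 * L) — intended for the
    small-to-medium libraries one actually inspects pairwise.
    """
    seqs = as_sequences(library)
    if not seqs:
        return np.zeros((0, 0), dtype=np.int64)
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ParameterError("hamming_matrix requires equal-length sequences")
    codes = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    codes = codes.reshape(len(seqs), L)
    # chunk rows to bound the (n, n, L) broadcast
    n = len(seqs)
    out = np.zeros((n, n), dtype=np.int64)
    chunk = max(1, 10_000_000 // max(n * L, 1))
    for i0 in range(0, n, chunk):
        block = codes[i0 : i0 + chunk]
        out[i0 : i0 + chunk] = (block[:, None, :] != codes[None, :, :]).sum(
            axis=2)
    return out

def qc_table(library) -> pd.DataFrame:
    """Per-sequence QC table: GC fraction, longest homopolymer, Wallace Tm."""
    seqs = as_sequences(library)
    return pd.DataFrame(
        {
            "index": range(len(seqs)),
            "sequence": seqs,
            "gc_fraction": [gc_content(s) for s in seqs],
            "max_homopolymer": [max_homopolymer_run(s) for s in seqs],
            "tm_wallace": [melting_temp(s, "wallace") for s in seqs],
        }
    )


def qc_report(library, k: Optional[int] = None, pairwise_sample: int = 1000,
              seed: int = 0) -> dict:
    """Library-level QC summary.

    Reports GC mean/sd, homopolymer statistics, duplicate-k-mer count at
    ``k`` (0 means the library satisfies SSM for that k) and the
    min/mean pairwise Hamming distance.  For libraries larger than
    ``pairwise_sample``, the Hamming statistics are computed on a seeded
    random subsample of that size (noted in the output).
    """
    seqs = as_sequences(library)
    out: dict = {"n_sequences": len(seqs)}
    if not seqs:
        return out
    lengths = {len(s) for s in seqs}
    out["length"] = lengths.pop() if len(lengths) == 1 else sorted(lengths)
    gc = np.array([gc_content(s) for s in seqs])
    out["gc_mean"] = float(gc.mean())
    out["gc_sd"] = float(gc.std(ddof=1)) if len(seqs) > 1 else 0.0
    runs = np.array([max_homopolymer_run(s) for s in seqs])
    out["max_homopolymer_max"] = int(runs.max())
    out["max_homopolymer_mean"] = float(runs.mean())
    if k is not None:
        out["k"] = k
        out["duplicate_kmers"] = ssm_audit(seqs, k, detailed=False).n_violations
    if len({len(s) for s in seqs}) == 1 and len(seqs) >= 2:
        if len(seqs) > pairwise_sample:
            rng = np.random.default_rng(seed)
            idx = rng.choice(len(seqs), size=pairwise_sample, replace=False)
            sub = [seqs[i] for i in sorted(idx)]
            out["hamming_sampled"] = pairwise_sample
        else:
            sub = seqs
            out["hamming_sampled"] = None
        H = hamming_matrix(sub)
        iu = np.triu_indices(len(sub), k=1)
        out["hamming_min"] = int(H[iu].min())
        out["hamming_mean"] = float(H[iu].mean())
    return out
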