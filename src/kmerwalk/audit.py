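"""Brute-force audit oracles for SSM and reverse-complement orthogonality.

These are deliberately independent of the designers in :mod:`kmerwalk.graph`
and :mod:`kmerwalk.rc`: they look only at the final sequences, so a bug in a
construction cannot hide from them.
"""

from __future__ import annotations

import numpy as np

from .alphabet import DNA_COMPLEMENT
from .errors import ParameterError
from .library import AuditReport, as_sequences

_MAX_LISTED = 100  # cap on violations listed in a report (count stays exact)

_RC_TABLE = str.maketrans("ACGT", "TGCA")


def _rc(seq: str) -> str:
    return seq.translate(_RC_TABLE)[::-1]


def _check_k(seqs: list[str], k: int) -> None:
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    for i, s in enumerate(seqs):
        if len(s) < k:
            raise ParameterError(
                f"sequence {i} has length {len(s)} < k={k}; audit undefined"
            )


# ---------------------------------------------------------------------------
# SSM audit
# ---------------------------------------------------------------------------

def ssm_audit(library, k: int, detailed: bool = True) -> AuditReport:
    """Report every k-mer that occurs more than once across the library.

    A library satisfies SSM for length k iff the report is empty.  Both
    across-sequence and within-sequence repeats count; each violation lists
    the k-mer and all its (sequence index, offset) occurrences.

    With ``detailed=False`` the audit runs a vectorised count-only pass
    (base-4 integer encoding of every window, sort, count duplicates):
    it requires equal-length sequences, uses a few bytes per window, and
    handles multi-million-k-mer libraries in seconds.  ``n_violations``
    is exact either way.
    """
    seqs = as_sequences(library)
    _check_k(seqs, k)
    n_kmers = sum(len(s) - k + 1 for s in seqs)

    if not detailed:
        dup = _count_duplicate_windows(seqs, k)
        return AuditReport(
            kind="ssm", k=k, n_sequences=len(seqs), n_kmers_scanned=n_kmers,
            n_violations=dup, violations=[], truncated=dup > 0,
        )

    occurrences: dict[str, list[tuple[int, int]]] = {}
    for i, s in enumerate(seqs):
        for j in range(len(s) - k + 1):
            occurrences.setdefault(s[j : j + k], []).append((i, j))
    violations = []
    n_viol = 0
    for kmer, locs in occurrences.items():
        if len(locs) > 1:
            n_viol += 1
            if len(violations) < _MAX_LISTED:
                violations.append(
                    {"kmer": kmer, "count": len(locs),
                     "locations": [list(t) for t in locs]}
                )
    return AuditReport(
        kind="ssm", k=k, n_sequences=len(seqs), n_kmers_scanned=n_kmers,
        n_violations=n_viol, violations=violations,
        truncated=n_viol > len(violations),
    )


def _encode_matrix(seqs: list[str], k: int) -> np.ndarray:
    """(n, L) uint8 base-4 codes; requires equal lengths and ACGT symbols."""
    L = len(seqs[0])
    if any(len(s) != L for s in seqs):
        raise ParameterError("count-only audit requires equal-length sequences")
    table = np.full(256, 255, dtype=np.uint8)
    for i, b in enumerate(b"ACGT"):
        table[b] = i
    flat = np.frombuffer("".join(seqs).encode("ascii"), dtype=np.uint8)
    codes = table[flat]
    if codes.max(initial=0) == 255:
        raise ParameterError("non-ACGT symbol in library")
    return codes.reshape(len(seqs), L)


def _window_ranks(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer rank of every length-k window, flattened."""
    n, L = codes.shape
    W = L - k + 1
    ranks = np.zeros((n, W), dtype=np.int64)
    for t in range(k):
        ranks += codes[:, t : t + W].astype(np.int64) << (2 * (k - 1 - t))
    return ranks.ravel()


def _count_duplicate_windows(seqs: list[str], k: int) -> int:
    """Number of distinct k-mers occurring more than once (exact)."""
    if not seqs:
        return 0
    if k > 31:
        raise ParameterError("count-only audit supports k <= 31")
    ranks = _window_ranks(_encode_matrix(seqs, k), k)
    ranks.sort()
    dup_mask = ranks[1:] == ranks[:-1]
    if not dup_mask.any():
        return 0
    # count distinct duplicated values, not duplicated slots
    dup_vals = np.unique(ranks[1:][dup_mask])
    return int(dup_vals.size)


# ---------------------------------------------------------------------------
# RC audit
# ---------------------------------------------------------------------------

def rc_audit(library, k: int) -> AuditReport:
    """Report reverse-complement crosstalk at the k-mer level.

    A violation is (a) a k-mer and its reverse complement both occurring
    anywhere in the library (including within one sequence), or (b) any
    occurrence of an RC-palindromic k-mer (its own reverse complement;
    exists only for even k).  An empty report means no library k-mer can
    hybridise with the reverse complement of any library sequence.

    Two passes: collect the k-mer set, then locate occurrences of the
    offending k-mers only, so clean multi-million-k-mer libraries stay
    cheap.
    """
    seqs = as_sequences(library)
    _check_k(seqs, k)
    n_kmers = 0
    present: set[str] = set()
    for s in seqs:
        n_kmers += len(s) - k + 1
        for j in range(len(s) - k + 1):
            present.add(s[j : j + k])

    palindromic = set()
    pairs = set()  # canonical (min, max) pairs
    for kmer in present:
        rc = _rc(kmer)
        if rc == kmer:
            palindromic.add(kmer)
        elif rc in present:
            pairs.add((min(kmer, rc), max(kmer, rc)))

    offenders = palindromic | {a for a, _ in pairs} | {b for _, b in pairs}
    locations: dict[str, list[list[int]]] = {km: [] for km in offenders}
    if offenders:
        for i, s in enumerate(seqs):
            for j in range(len(s) - k + 1):
                w = s[j : j + k]
                if w in locations:
                    locations[w].append([i, j])

    violations = []
    for kmer in sorted(palindromic):
        violations.append(
            {"type": "palindrome", "kmer": kmer, "locations": locations[kmer]}
        )
    for a, b in sorted(pairs):
        violations.append(
            {"type": "rc_pair", "kmer": a, "rc": b,
             "locations": locations[a], "rc_locations": locations[b]}
        )
    n_viol = len(violations)
    return AuditReport(
        kind="rc", k=k, n_sequences=len(seqs), n_kmers_scanned=n_kmers,
        n_violations=n_viol, violations=violations[:_MAX_LISTED],
        truncated=n_viol > _MAX_LISTED,
    )
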