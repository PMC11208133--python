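"""Reverse-complement orthogonality strategies.

SSM alone stops barcodes sharing k-mers with each other; applications that
mix a library with the reverse complements of its members (multiplexed PCR,
probe/target pools) additionally need no k-mer of the library to be the
reverse complement of another library k-mer.  Three strategies deliver
that, each suited to a different parameter regime:

``three_letter_odd``
    A/C/T libraries, odd k.  Any k-mer containing C is automatically safe
    (its reverse complement contains G, which the library cannot contain),
    so only A/T-only k-mers matter.  For odd k the middle base of a k-mer
    always differs from the middle base of its reverse complement, so the
    2**k A/T-only k-mers split into two RC-conjugate halves by middle
    base; discarding every sequence containing a middle-base-A k-mer
    removes one half and with it all possible collisions.  Costs at most
    2**(k-1) sequences.
``adapted_hierholzer``
    Four-letter libraries, odd k.  A greedy graph traversal that marks
    both each visited k-mer and its reverse complement as used, emitting
    self-avoiding trails; odd k guarantees no k-mer is its own reverse
    complement, so the pairing is clean.
``hash_filter``
    Any alphabet, the only option for even k.  A single greedy pass over
    an SSM library keeping a sequence iff none of its k-mers collides
    (as an RC) with the k-mers of sequences already kept, with itself, or
    is an RC palindrome.
"""

from __future__ import annotations

from .alphabet import Alphabet, DesignParams
from .audit import _rc
from .errors import ContractError, ParameterError
from .graph import assemble_sequence, rank_kmer, unrank_kmer
from .library import FilterReport, SequenceLibrary, as_sequences

RC_MODES = ("none", "three_letter_odd", "adapted_hierholzer", "hash_filter")

__all__ = [
    "RC_MODES",
    "reverse_complement",
    "middle_base_partition",
    "filter_three_letter_odd",
    "adapted_hierholzer",
    "rc_hash_filter",
]

_ACGT = set("ACGT")


def reverse_complement(seq: str) -> str:
    """Watson-Crick reverse complement (an involution on ACGT strings)."""
    bad = set(seq) - _ACGT
    if bad:
        raise ParameterError(
            f"cannot reverse-complement symbols {sorted(bad)} (ACGT only)"
        )
    return _rc(seq)


# ---------------------------------------------------------------------------
# three-letter / odd-k partition filter
# ---------------------------------------------------------------------------

def middle_base_partition(k: int) -> tuple[frozenset, frozenset]:
    """Split the 2**k A/T-only k-mers by middle base, for odd k.

    Returns ``(discard, keep)``: the middle-base-A half and the
    middle-base-T half.  Reverse complementation maps each half onto the
    other, so removing every sequence containing a member of one half
    leaves a library in which no A/T-only k-mer co-occurs with its
    reverse complement.
    """
    if k % 2 == 0:
        raise ContractError(f"middle-base partition needs odd k, got {k}")
    mid = k // 2
    at_kmers = []
    for r in range(2 ** k):
        bits = format(r, f"0{k}b")
        at_kmers.append(bits.translate(str.maketrans("01", "AT")))
    discard = frozenset(w for w in at_kmers if w[mid] == "A")
    keep = frozenset(w for w in at_kmers if w[mid] == "T")
    return discard, keep


def filter_three_letter_odd(library, k: int
                            ) -> tuple[SequenceLibrary, FilterReport]:
    """Remove sequences containing any A/T-only k-mer with middle base A.

    Requires an A/C/T library and odd k.  On a full SSM design this costs
    at most 2**(k-1) sequences and the survivors pass the RC audit.
    """
    if k % 2 == 0:
        raise ContractError(
            f"three-letter RC filtering requires odd k, got {k}"
        )
    seqs = as_sequences(library)
    used = set().union(*map(set, seqs)) if seqs else set()
    if "G" in used:
        raise ContractError(
            "three-letter RC filtering requires an A/C/T library; found G"
        )
    mid = k // 2

    def clean(seq: str) -> bool:
        for j in range(len(seq) - k + 1):
            w = seq[j : j + k]
            if w[mid] == "A" and set(w) <= {"A", "T"}:
                return False
        return True

    return _apply_predicate(
        library, clean, rule="rc_three_letter_odd",
        details={"k": k, "discarded_partition": "AT-only, middle base A",
                 "max_removable": 2 ** (k - 1)},
    )


# ---------------------------------------------------------------------------
# adapted Hierholzer traversal (four-letter, odd k)
# ---------------------------------------------------------------------------

def _rc_rank(r: int, k: int) -> int:
    """Rank of the reverse complement of the rank-r k-mer over ACGT.

    With A<C<G<T coded 0..3, complement is 3 - digit; reversal reverses
    digit order.
    """
    out = 0
    for _ in range(k):
        r, d = divmod(r, 4)
        out = out * 4 + (3 - d)
    return out


def adapted_hierholzer(params: DesignParams) -> SequenceLibrary:
    """Design a four-letter, odd-k library free of RC crosstalk by
    construction.

    Greedy trail-growing on the k-mer graph: every time a node is taken,
    both it and its reverse complement are marked used, so no trail can
    ever visit the reverse complement of any visited k-mer.  When a trail
    dead-ends, a new one starts from the lexicographically smallest
    unmarked node, until all nodes are marked.  Trails are partitioned
    into (L-k+1)-node fragments; short leftovers are discarded.

    At most half the k-mer graph is usable (nodes pair with their RCs),
    so the library is smaller than the unconstrained design; no size
    guarantee is made beyond non-emptiness for sane parameters.
    """
    if params.m != 4:
        raise ContractError(
            f"adapted Hierholzer requires the four-letter alphabet, m={params.m}"
        )
    if params.k % 2 == 0:
        raise ContractError(
            "adapted Hierholzer requires odd k (even k admits k-mers that "
            f"are their own reverse complement); got k={params.k}"
        )
    k, L = params.k, params.L
    alphabet = params.alphabet
    M = 4 ** k
    suffix_mod = 4 ** (k - 1)
    visited = bytearray(M)
    trails: list[list[int]] = []
    scan = 0  # lex-smallest possibly-unvisited node; only ever increases
    while True:
        while scan < M and visited[scan]:
            scan += 1
        if scan == M:
            break
        u = scan
        visited[u] = 1
        visited[_rc_rank(u, k)] = 1
        trail = [u]
        while True:
            base = (u % suffix_mod) * 4
            for s in range(4):
                v = base + s
                if not visited[v]:
                    visited[v] = 1
                    visited[_rc_rank(v, k)] = 1
                    trail.append(v)
                    u = v
                    break
            else:
                break
        trails.append(trail)

    step = params.nodes_per_sequence
    sequences: list[str] = []
    used_nodes = 0
    for trail in trails:
        used_nodes += len(trail)
        for j in range(len(trail) // step):
            frag = [unrank_kmer(r, k, alphabet) for r in
                    trail[j * step : (j + 1) * step]]
            sequences.append(assemble_sequence(frag))
    prov = {
        "operation": "design",
        "backend": "adapted_hierholzer",
        "params": params.to_dict(),
        "nodes_total": M,
        "nodes_visited": used_nodes,
        "n_trails": len(trails),
        "nodes_discarded": used_nodes - len(sequences) * step,
        "sequences_designed": len(sequences),
    }
    return SequenceLibrary(sequences, params, [prov])


# ---------------------------------------------------------------------------
# hashing filter (even k, or generic fallback)
# ---------------------------------------------------------------------------

def rc_hash_filter(library, k: int) -> tuple[SequenceLibrary, FilterReport]:
    """Greedy single-pass RC filter over an SSM library.

    In library order, a sequence is kept iff none of its k-mers
    (a) is its own reverse complement (possible only for even k),
    (b) is the reverse complement of an earlier k-mer in the same
    sequence, or (c) is the reverse complement of any k-mer of an
    already-kept sequence.  The kept set passes the RC audit.
    """
    kept_kmers: set[str] = set()

    def clean(seq: str) -> bool:
        own: list[str] = []
        for j in range(len(seq) - k + 1):
            w = seq[j : j + k]
            rc = _rc(w)
            if rc == w:
                return False
            if rc in kept_kmers:
                return False
            if any(rc == prev for prev in own):
                return False
            own.append(w)
        kept_kmers.update(own)
        return True

    return _apply_predicate(
        library, clean, rule="rc_hash_filter", details={"k": k},
    )


# ---------------------------------------------------------------------------
# shared predicate-filter plumbing
# ---------------------------------------------------------------------------

def _apply_predicate(library, keep, rule: str, details: dict | None = None
                     ) -> tuple[SequenceLibrary, FilterReport]:
    """Order-preserving subset filter with a reconciling report."""
    seqs = as_sequences(library)
    kept, removed = [], []
    for s in seqs:
        (kept if keep(s) else removed).append(s)
    report = FilterReport(
        rule=rule, n_input=len(seqs), n_removed=len(removed),
        n_kept=len(kept), removed_examples=removed[:10],
        details=details or {},
    )
    entry = {"operation": "filter", "rule": rule,
             "removed": len(removed), "kept": len(kept)}
    if isinstance(library, SequenceLibrary):
        out = library.replace(kept, entry)
    else:
        out = SequenceLibrary(kept, None, [entry])
    return out, report
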