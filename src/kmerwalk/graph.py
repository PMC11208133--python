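"""Hamiltonian paths on k-mer graphs and their partition into barcodes.

The k-mer (de Bruijn) graph has all m**k k-mers as nodes and a directed
edge u -> v whenever dropping u's first symbol and appending one symbol
yields v (overlap k-1).  A Hamiltonian path visits every k-mer exactly
once; chopping it into consecutive blocks of L-k+1 nodes and reading each
block off as a sequence yields a library in which no k-mer occurs twice —
the sequence-symmetry-minimisation (SSM) property — and, because every
k-mer in sequence space is used, no larger SSM library exists.

Two interchangeable backends construct the underlying de Bruijn cycle:

``shift_rule``
    Streaming necklace construction (Fredricksen-Kessler-Maiorana /
    Duval): emits the lexicographically least de Bruijn cycle by
    concatenating the Lyndon words whose length divides k, in lexicographic
    order.  Amortised O(1) work and O(k) working state per symbol — memory
    does not grow with m**k.
``hierholzer``
    Iterative Hierholzer Eulerian circuit on the (k-1)-mer graph, whose
    edges are exactly the k-mers.  Uses O(m**k) visit marks; simpler, and
    shares machinery with the reverse-complement-aware traversal in
    :mod:`kmerwalk.rc`.

Both are deterministic; they differ in the order k-mers are visited, so
set-level properties (exhaustiveness, overlap validity, library size) are
the contract, not byte-level agreement between backends.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

from .alphabet import Alphabet, DesignParams
from .errors import AlphabetError, ContractError, ParameterError
from .library import SequenceLibrary

BACKENDS = ("shift_rule", "hierholzer")

__all__ = [
    "BACKENDS",
    "KmerPath",
    "rank_kmer",
    "unrank_kmer",
    "debruijn_symbol_stream",
    "hamiltonian_path",
    "assemble_sequence",
    "partition_path",
    "design_library",
]


# ---------------------------------------------------------------------------
# k-mer ranking (base-m positional encoding)
# ---------------------------------------------------------------------------

def rank_kmer(kmer: str, alphabet: Alphabet) -> int:
    """Rank of a k-mer in lexicographic order, in [0, m**k).

    The base-m positional encoding: lexicographic order of k-mers equals
    numeric order of ranks, and :func:`unrank_kmer` inverts it exactly.
    """
    m = alphabet.m
    r = 0
    for pos, sym in enumerate(kmer):
        try:
            d = alphabet.symbols.index(sym)
        except ValueError:
            raise AlphabetError(
                f"symbol {sym!r} at position {pos} of {kmer!r} is outside "
                f"alphabet {alphabet}"
            ) from None
        r = r * m + d
    return r


def unrank_kmer(rank: int, k: int, alphabet: Alphabet) -> str:
    """Inverse of :func:`rank_kmer` for length-k k-mers."""
    m = alphabet.m
    if not 0 <= rank < m ** k:
        raise ParameterError(f"rank {rank} outside [0, {m}**{k})")
    out = []
    for _ in range(k):
        rank, d = divmod(rank, m)
        out.append(alphabet.symbols[d])
    return "".join(reversed(out))


# ---------------------------------------------------------------------------
# de Bruijn cycle backends (symbol codes 0..m-1)
# ---------------------------------------------------------------------------

def _fkm_symbol_codes(m: int, k: int) -> Iterator[int]:
    """Stream the lexicographically least de Bruijn cycle B(m, k).

    Iterative Lyndon-word concatenation: every Lyndon word over
    {0..m-1} whose length divides k, in lexicographic order.  O(k) state.
    """
    w = [0]
    while True:
        if k % len(w) == 0:
            yield from w
        r = len(w)
        w = [w[i % r] for i in range(k)]
        while w and w[-1] == m - 1:
            w.pop()
        if not w:
            return
        w[-1] += 1


def _fkm_codes(m: int, k: int) -> bytearray:
    """Materialised B(m, k) — same loop as the stream, bulk appends."""
    out = bytearray()
    w = [0]
    while True:
        if k % len(w) == 0:
            out.extend(w)
        r = len(w)
        w = [w[i % r] for i in range(k)]
        while w and w[-1] == m - 1:
            w.pop()
        if not w:
            return out
        w[-1] += 1


def _edge_orders(m: int, n_tables: int = 64) -> list[tuple[int, ...]]:
    """Fixed table of symbol permutations (Knuth multiplicative hash).

    Node u consumes its out-edges in ``orders[u % n_tables]`` order; the
    low base-m digits of u churn with every step of the walk, so
    successive edge choices look composition-neutral while remaining
    fully deterministic.
    """
    return [
        tuple(sorted(range(m),
                     key=lambda s: ((t * 7 + s + 1) * 2654435761) & 0xFFFFFFFF))
        for t in range(n_tables)
    ]


def _hierholzer_codes(m: int, k: int) -> bytearray:
    """De Bruijn cycle via an Eulerian circuit on the (k-1)-mer graph.

    Nodes are the m**(k-1) (k-1)-mers (as ranks); each node has one
    out-edge per symbol, and edge (u, s) *is* the k-mer u*m + s.  The
    iterative stack formulation of Hierholzer's algorithm consumes each
    node's edges in a fixed multiplicative-hash order — deterministic,
    but decorrelating base composition along the cycle (lexicographic
    orders cluster composition, which skews per-barcode GC).  The edge
    sequence is a Hamiltonian cycle on the k-mer graph, rotated so the
    all-first-symbol k-mer leads.
    """
    if k == 1:
        return bytearray(range(m))
    n_nodes = m ** (k - 1)
    orders = _edge_orders(m)
    next_sym = bytearray(n_nodes)  # per-node count of consumed out-edges
    stack = [0]
    circuit: list[int] = []
    while stack:
        u = stack[-1]
        if next_sym[u] < m:
            s = orders[u % len(orders)][next_sym[u]]
            next_sym[u] += 1
            stack.append((u * m + s) % n_nodes)
        else:
            circuit.append(stack.pop())
    circuit.reverse()
    # edge i runs circuit[i] -> circuit[i+1]; its k-mer's leading symbol is
    # the leading symbol of circuit[i]
    lead = n_nodes // m
    symbols = bytearray(circuit[i] // lead for i in range(len(circuit) - 1))
    # rotate so the cycle starts at the all-0 k-mer (a run of k zeros,
    # possibly straddling the cycle boundary)
    run = 0
    for i, c in enumerate(symbols + symbols[: k - 1]):
        run = run + 1 if c == 0 else 0
        if run == k:
            start = (i - k + 1) % len(symbols)
            return symbols[start:] + symbols[:start]
    raise AssertionError("de Bruijn cycle lacks the all-zero k-mer")


def _cycle_codes(params: DesignParams, backend: str) -> bytearray:
    if backend == "shift_rule":
        return _fkm_codes(params.m, params.k)
    if backend == "hierholzer":
        return _hierholzer_codes(params.m, params.k)
    raise ParameterError(f"unknown backend {backend!r}; choose from {BACKENDS}")


def debruijn_symbol_stream(params: DesignParams) -> Iterator[str]:
    """Stream the symbols of the de Bruijn cycle as characters (O(k) memory)."""
    syms = params.alphabet.symbols
    for c in _fkm_symbol_codes(params.m, params.k):
        yield syms[c]


# ---------------------------------------------------------------------------
# paths
# ---------------------------------------------------------------------------

@dataclass
class KmerPath:
    """An ordered, self-avoiding walk over k-mers.

    Consecutive nodes must overlap by k-1 symbols and no node may repeat.
    Validation is optional because generator output is correct by
    construction and may be large.
    """

    nodes: list[str]
    k: int

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ParameterError("k must be >= 1")

    def validate(self) -> None:
        seen = set()
        prev = None
        for i, node in enumerate(self.nodes):
            if len(node) != self.k:
                raise ContractError(f"node {i} has length {len(node)}, not k={self.k}")
            if node in seen:
                raise ContractError(f"node {node!r} repeats (position {i})")
            seen.add(node)
            if prev is not None and prev[1:] != node[:-1]:
                raise ContractError(
                    f"nodes {i-1} -> {i} ({prev!r} -> {node!r}) violate the "
                    f"(k-1)-overlap edge rule"
                )
            prev = node

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self) -> Iterator[str]:
        return iter(self.nodes)


def hamiltonian_path(params: DesignParams, backend: str = "shift_rule"
                     ) -> Iterator[str]:
    """Yield every k-mer exactly once, respecting the overlap edge rule.

    The path is the sequence of m**k sliding windows of the backend's
    de Bruijn cycle.  With the ``shift_rule`` backend this streams: working
    memory is O(k), independent of m**k.  Deterministic for fixed params.
    """
    m, k = params.m, params.k
    syms = params.alphabet.symbols
    if backend == "shift_rule":
        window: list[str] = []
        head: list[str] = []  # first k-1 symbols, for the wrap-around windows
        for c in _fkm_symbol_codes(m, k):
            ch = syms[c]
            if len(head) < k - 1:
                head.append(ch)
            window.append(ch)
            if len(window) == k:
                yield "".join(window)
                del window[0]
        for ch in head:
            window.append(ch)
            yield "".join(window)
            del window[0]
    elif backend == "hierholzer":
        codes = _hierholzer_codes(m, k)
        s = _codes_to_str(codes, params.alphabet)
        ext = s + s[: k - 1]
        for i in range(len(s)):
            yield ext[i : i + k]
    else:
        raise ParameterError(f"unknown backend {backend!r}; choose from {BACKENDS}")


def _codes_to_str(codes: bytearray, alphabet: Alphabet) -> str:
    table = bytes.maketrans(
        bytes(range(alphabet.m)), "".join(alphabet.symbols).encode()
    )
    return bytes(codes).translate(table).decode("ascii")


# ---------------------------------------------------------------------------
# partition + assembly
# ---------------------------------------------------------------------------

def assemble_sequence(fragment: list[str]) -> str:
    """Map a path fragment to its sequence.

    The sequence is the first k-mer extended by the last symbol of each
    subsequent node; length is k + (len(fragment) - 1).
    """
    if not fragment:
        raise ParameterError("empty fragment")
    first = fragment[0]
    out = [first]
    prev = first
    for i, node in enumerate(fragment[1:], start=1):
        if prev[1:] != node[:-1]:
            raise ContractError(
                f"fragment nodes {i-1} -> {i} ({prev!r} -> {node!r}) do not "
                f"overlap by k-1 symbols"
            )
        out.append(node[-1])
        prev = node
    return "".join(out)


def partition_path(path, L: int, params: DesignParams | None = None
                   ) -> SequenceLibrary:
    """Partition a k-mer path into consecutive fragments of L-k+1 nodes.

    Fragments are non-overlapping and consumed in path order; a trailing
    remainder shorter than L-k+1 nodes is discarded (and counted in
    provenance).  Accepts a :class:`KmerPath` or any iterable of k-mers.
    """
    if isinstance(path, KmerPath):
        nodes_iter: Iterable[str] = path.nodes
        k = path.k
    else:
        nodes_iter = iter(path)
        try:
            first = next(nodes_iter)
        except StopIteration:
            return SequenceLibrary([], params, [_design_prov(None, 0, 0, 0)])
        k = len(first)
        import itertools

        nodes_iter = itertools.chain([first], nodes_iter)
    if L < k:
        raise ParameterError(f"L={L} must be >= k={k}")
    step = L - k + 1
    sequences: list[str] = []
    frag: list[str] = []
    n_nodes = 0
    for node in nodes_iter:
        n_nodes += 1
        frag.append(node)
        if len(frag) == step:
            sequences.append(assemble_sequence(frag))
            frag = []
    discarded = len(frag)
    prov = _design_prov(None, n_nodes, discarded, len(sequences))
    return SequenceLibrary(sequences, params, [prov])


def _design_prov(backend, n_nodes, discarded, n_seqs) -> dict:
    entry = {
        "operation": "design",
        "nodes_total": n_nodes,
        "nodes_discarded": discarded,
        "sequences_designed": n_seqs,
    }
    if backend is not None:
        entry["backend"] = backend
    return entry


# ---------------------------------------------------------------------------
# full design
# ---------------------------------------------------------------------------

def design_library(params: DesignParams, backend: str = "shift_rule"
                   ) -> SequenceLibrary:
    """Design the maximally sized SSM library for the given parameters.

    Equivalent to ``partition_path(hamiltonian_path(params), params.L)``
    but assembled directly from the de Bruijn cycle's symbol string, which
    avoids materialising m**k k-mer strings: barcode j is the L-symbol
    window starting at offset j*(L-k+1).

    The result has exactly floor(m**k / (L-k+1)) sequences, satisfies SSM
    for k, and is byte-identical across runs with identical parameters.
    """
    codes = _cycle_codes(params, backend)
    s = _codes_to_str(codes, params.alphabet)
    k, L = params.k, params.L
    step = params.nodes_per_sequence
    n_nodes = len(s)  # == m**k
    n_seqs = n_nodes // step
    ext = s + s[: k - 1]
    sequences = [ext[j * step : j * step + L] for j in range(n_seqs)]
    prov = _design_prov(backend, n_nodes, n_nodes - n_seqs * step, n_seqs)
    prov["params"] = params.to_dict()
    return SequenceLibrary(sequences, params, [prov])
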