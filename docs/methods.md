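# Methods

## Model

A barcode library is a set of length-*L* strings over an ordered DNA
alphabet of size *m* ∈ {2, 3, 4}. The orthogonality criterion is sequence
symmetry minimization (SSM) of order *k*: no length-*k* subsequence may
occur more than once across the entire library, counting occurrences both
within and between sequences. SSM is combinatorial — it bounds shared
subsequence content, not hybridization free energy — and is used here
exactly as that: a scalable screen, typically upstream of
application-specific (thermodynamic, genomic-homology) filtering.

The design space is the de Bruijn graph **G(m, k)**: nodes are all *m*ᵏ
k-mers, with an edge u→v iff v = u[1:] + s for some symbol s. A
length-*L* sequence is a walk over *L* − *k* + 1 nodes; libraries whose
walks are pairwise node-disjoint satisfy SSM. The designer takes a single
Hamiltonian path and partitions it into consecutive, non-overlapping
blocks of *L* − *k* + 1 nodes; the trailing remainder of
*m*ᵏ mod (*L* − *k* + 1) nodes is discarded (and recorded in provenance).
The resulting size, ⌊*m*ᵏ/(*L* − *k* + 1)⌋, is maximal: the library uses
every k-mer, and a larger SSM library would need more than *m*ᵏ distinct
k-mers.

Fragment boundaries share k−1 symbols of graph context but zero k-mers,
so no boundary trimming is needed; SSM-k holds exactly as defined.

## Path construction

Hamiltonian paths in arbitrary graphs are hard, but de Bruijn graphs are
the line-graph iterates of a complete graph and admit linear-time
constructions. Two deterministic backends are provided; their contract is
set-level (every k-mer exactly once, valid overlaps, fixed output for
fixed parameters), not any particular visiting order.

- **`shift_rule`** (default): the Fredricksen–Kessler–Maiorana /
  Duval iteration, concatenating every Lyndon word over the ordered
  alphabet whose length divides *k*. It emits the lexicographically least
  de Bruijn cycle with O(*k*) working state and amortized O(1) work per
  symbol, so generation streams: memory does not grow with *m*ᵏ. The
  Hamiltonian path is the sequence of *m*ᵏ sliding windows of the cycle.
- **`hierholzer`**: an iterative (stack-based) Hierholzer Eulerian
  circuit on G(m, k−1), whose edges are exactly the k-mers. It keeps
  O(*m*ᵏ) edge marks. Each node consumes its out-edges in a fixed
  multiplicative-hash order rather than lexicographically: any edge order
  yields a valid Eulerian circuit, and the hashed order decorrelates base
  composition along the cycle (see *GC behaviour* below).

Symbol order is fixed at A < C < G < T (A < C < T for three-letter
alphabets) and every cycle is rotated to start at the all-first-symbol
k-mer, making designs byte-identical across runs. Designs are seed-free;
the only seeded component in the package is the random fixture generator.

## Reverse-complement orthogonality

Applications that expose a library to the reverse complements of its own
members additionally require that no library k-mer be the reverse
complement of another library k-mer. Three strategies cover the parameter
space:

1. **Three-letter, odd k** (`filter_three_letter_odd`). Over {A, C, T},
   any k-mer containing C is safe: its reverse complement contains G,
   which the library cannot contain. Only the 2ᵏ A/T-only k-mers can
   collide. For odd *k* the middle base of a k-mer always differs from
   the middle base of its reverse complement, so the A/T-only k-mers
   split into two RC-conjugate halves of 2ᵏ⁻¹ by middle base. Discarding
   every sequence containing a middle-base-A k-mer removes one half;
   because no k-mer occurs in two sequences, at most 2ᵏ⁻¹ sequences are
   lost, giving N_rc ≥ N − 2ᵏ⁻¹. The middle-base-A half is the discarded
   one by convention (either choice works; one is fixed for determinism).
2. **Four-letter, odd k** (`adapted_hierholzer`). Greedy trail-growing on
   G(m, k) that marks both every visited node and its reverse complement
   as used; odd *k* guarantees no k-mer is its own reverse complement, so
   nodes pair cleanly and at most half the graph is usable. Successors
   are tried in lexicographic order; when a trail dead-ends, a new one
   starts at the lexicographically smallest unmarked node. Loop-splicing
   (the step that makes Hierholzer's algorithm produce a single circuit)
   is deliberately omitted: it is never required for correctness here,
   the RC-marking invariant is easiest to reason about on plain greedy
   trails, and no maximality guarantee is claimed for this strategy —
   its contract is that the output passes both audits.
3. **Even k, any alphabet** (`rc_hash_filter`). A single greedy pass over
   an SSM library keeping a sequence iff none of its k-mers is an RC
   palindrome, the reverse complement of an earlier k-mer in the same
   sequence, or the reverse complement of a k-mer of an already-kept
   sequence. Palindromic k-mers (possible only for even *k*) are treated
   as violations so that the kept set passes the audit unconditionally.

All three outputs are verified against the brute-force `rc_audit`, which
flags any k-mer/reverse-complement co-occurrence (including within one
sequence) and any RC-palindrome occurrence.

## Size theory

All bounds use exact integer arithmetic throughout (floating-point floors
would corrupt sizes around m^k for k ≥ 12):

| quantity | formula | direction |
|---|---|---|
| maximal SSM size | N = ⌊mᵏ/(L−k+1)⌋ | exact |
| k-mers containing a length-p pattern | K_p ≤ (k−p+1)·mᵏ⁻ᵖ | upper |
| size after one pattern filter | N_p ≥ N − K_p | lower |
| three-letter odd-k RC-filtered size | N_rc ≥ N − 2ᵏ⁻¹ | lower |

The pattern bounds hold on full SSM designs with p ≤ k because each
pattern-bearing k-mer occurs in at most one sequence. `max_orthogonality`
scans k = 1, 2, …, L and returns the first k with N ≥ N_d, i.e. the
strongest SSM constraint able to deliver the demanded library size; an
infeasible demand raises a typed error rather than returning a sentinel,
since silently under-sizing an experiment is the worse failure mode.
GC-filtered sizes have no comparable closed form and are reported
empirically by the QC module.

## Downstream filters

Every filter is a pure per-sequence predicate: survivors are an ordered
subset of the input, reports reconcile (kept + removed = input), and any
two filters commute set-wise. Defaults and conventions:

- GC windows are fractions in [0, 1], inclusive on both ends.
- Melting temperature: Wallace rule 2(#A+#T) + 4(#G+#C) °C, adequate for
  oligos under ~14 nt; or SantaLucia nearest-neighbor thermodynamics
  (Biopython, SantaLucia & Hicks 2004 table, 50 mM Na⁺, 25 nM strand
  concentrations — pinned in `NN_DEFAULTS` and recorded in reports).
- Homopolymer filtering is a run-length scan, equivalent to pattern
  filtering on the m runs of length max_run+1 (the equivalence is
  asserted in tests).
- The secondary-structure screen returns the longest length s such that
  some length-s substring and its reverse complement both occur in the
  sequence — a self-complementarity proxy chosen because SSM itself makes
  no thermodynamic claim; it is not a folding energy model, and sequences
  needing guaranteed low hairpin stability should go through a dedicated
  folder downstream.

## GC behaviour of the two backends

The lexicographically least de Bruijn cycle sorts composition along the
path (it opens with poly-A and closes with poly-T territory), so
consecutive blocks — the barcodes — have a wider GC distribution than
uniform random sequences (sd ≈ 0.165 vs 0.112 at L = 20). The
hash-ordered Hierholzer backend decorrelates composition; its per-barcode
GC closely tracks the Binomial(L, 1/2) expectation (observed survivor
fraction of a [0.4, 0.6] window at m = 4, k = 8, L = 20: 0.753 vs 0.737
predicted). When GC-window filtering matters, prefer
`backend="hierholzer"` or widen the window; both backends give identical
library sizes and identical SSM guarantees.

## Random fixtures

`make_fixture_library(n, L, alphabet, seed)` draws n i.i.d. uniform
sequences — the classical candidate-pool approach to barcode design, and
deliberately *not* SSM-satisfying: once n·(L−k+1) approaches mᵏ the
pigeonhole principle forces repeated k-mers, which is what the audit and
filter tests need to exercise. Uniform fixtures share the real-data
features relevant here (alphabet, length, composition) but none of the
structure of designed libraries; tests that pass on fixtures validate the
audits and filter algebra, not the designer — the designer is validated
against the brute-force audits and exhaustive small-graph enumeration.

## Problem sizes used in the test suite

Exhaustive graph checks run for all m ∈ {2, 3, 4} up to k = 6 (4,096
nodes), partition structure up to k = 9, self-RC exclusion up to k = 7.
The two published-scale runs execute in full: the m = 4, k = 12, L = 25
design (1,198,372 sequences; audited count-only over all 16.8 M windows)
and the m = 3, k = 13, L = 25 reverse-complement pipeline (121,495
survivors ≥ the 118,544 bound; audited in full). Pattern-removal bounds
are verified over all 256 length-4 patterns on the m = 4, k = 4, L = 10
design.

## Known limitations

- SSM bounds subsequence sharing, not ΔG; neither the audits nor the
  structure screen certify thermodynamic orthogonality.
- `adapted_hierholzer` makes no size-maximality claim; greedy trails can
  strand usable nodes (at k = 5, L = 20 the usable half of the graph
  yields few full fragments).
- Byte-level agreement with other SSM designers is out of scope: any
  correct Hamiltonian partition is a valid library, and only set-level
  properties are guaranteed.
- Genomic-homology screening (e.g. BLAST against a host genome) is
  downstream of this package.
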