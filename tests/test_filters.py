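"""Constraint filters, QC metrics, and their algebraic invariants."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import kmerwalk as kw
from kmerwalk import (Alphabet, DesignParams, SequenceLibrary,
                      design_library, gc_content, gc_filter, hamming_matrix,
                      homopolymer_filter, make_fixture_library,
                      max_homopolymer_run, melting_temp, pattern_filter,
                      pattern_kmer_bound, qc_report, qc_table,
                      selfcomp_screen, structure_filter, tm_filter)
from kmerwalk.errors import ParameterError
from kmerwalk.rc import _rc

ACGT = Alphabet.dna()


# ---------------------------------------------------------------------------
# pattern / homopolymer
# ---------------------------------------------------------------------------

def test_pattern_filter_substring():
    out, rep = pattern_filter(["AAT", "TTA"], ["TT"])
    assert out.sequences == ["AAT"]
    assert rep.n_removed == 1


def test_pattern_filter_empty_constraint_is_identity(small_design):
    out, rep = pattern_filter(small_design, [])
    assert out.sequences == small_design.sequences
    assert rep.n_removed == 0


def test_pattern_filter_rejects_empty_pattern():
    with pytest.raises(ParameterError):
        pattern_filter(["ACGT"], [""])


def test_length_k_pattern_removes_at_most_one(medium_design):
    for pat in ("ACGT", "AAAA", "CTAG"):
        _, rep = pattern_filter(medium_design, [pat])
        assert rep.n_removed <= 1


def test_homopolymer_filter_examples():
    out, _ = homopolymer_filter(["AAAT", "ACAC"], 2)
    assert out.sequences == ["ACAC"]
    out, _ = homopolymer_filter(["ACGT"], 1)
    assert out.sequences == ["ACGT"]


def test_homopolymer_equals_pattern_filter_reduction():
    lib = make_fixture_library(300, 15, seed=3)
    max_run = 3
    direct, _ = homopolymer_filter(lib, max_run)
    runs = [b * (max_run + 1) for b in "ACGT"]
    reduced, _ = pattern_filter(lib, runs)
    assert direct.sequences == reduced.sequences


def test_homopolymer_survivors_respect_pattern_bound(medium_design):
    """max_run=3 forbids the four length-4 homopolymers; each costs at
    most K_p sequences on a full SSM design."""
    N = len(medium_design)
    out, _ = homopolymer_filter(medium_design, 3)
    total_bound = 4 * pattern_kmer_bound(4, 4, 4).value
    assert len(out) >= N - total_bound


# ---------------------------------------------------------------------------
# GC
# ---------------------------------------------------------------------------

def test_gc_content_examples():
    assert gc_content("ACT") == pytest.approx(1 / 3)
    assert gc_content("GGCC") == 1.0


def test_three_letter_gc_is_c_fraction():
    seq = "ACTACTTCA"
    assert gc_content(seq) == pytest.approx(seq.count("C") / len(seq))


def test_gc_filter_inclusive_window():
    out, _ = gc_filter(["ACGT", "AAAA"], 0.5, 0.5)
    assert out.sequences == ["ACGT"]


def test_gc_distribution_resembles_binomial():
    """Survivor fraction of a [0.4, 0.6] GC window on the m=4, k=8, L=20
    design (hash-mixed traversal) is within 0.05 of the Binomial(20, 1/2)
    mass on 8..12 GC bases, as expected if design GC behaves like uniform
    random bases.  The necklace traversal clusters composition along the
    path and is checked only for the direction of its deviation."""
    scipy_stats = pytest.importorskip("scipy.stats")
    expected = float(sum(scipy_stats.binom.pmf(i, 20, 0.5) for i in range(8, 13)))
    lib = design_library(DesignParams(ACGT, 8, 20), backend="hierholzer")
    out, _ = gc_filter(lib, 0.4, 0.6)
    assert len(out) / len(lib) == pytest.approx(expected, abs=0.05)
    lex = design_library(DesignParams(ACGT, 8, 20), backend="shift_rule")
    out_lex, _ = gc_filter(lex, 0.4, 0.6)
    assert len(out_lex) / len(lex) <= expected  # broader GC spread


# ---------------------------------------------------------------------------
# melting temperature
# ---------------------------------------------------------------------------

def test_wallace_examples():
    assert melting_temp("AAAA", "wallace") == 8
    assert melting_temp("GGGG", "wallace") == 16


@given(st.text(alphabet="ACGT", min_size=1, max_size=30))
def test_wallace_monotone_in_appended_G(seq):
    assert melting_temp(seq + "G", "wallace") > melting_temp(seq, "wallace")


def test_nn_method_returns_plausible_value():
    tm = melting_temp("ACGTACGTACGTACGTACGT", "nn_santalucia")
    assert 20 < tm < 90


def test_nn_method_rejects_single_base():
    with pytest.raises(ParameterError):
        melting_temp("A", "nn_santalucia")


def test_tm_filter_wallace_window():
    out, rep = tm_filter(["AAAA", "GGGG"], 10, 20, "wallace")
    assert out.sequences == ["GGGG"]
    assert rep.details["method"] == "wallace"


# ---------------------------------------------------------------------------
# secondary-structure screen
# ---------------------------------------------------------------------------

def _selfcomp_oracle(seq: str) -> int:
    """All-pairs brute force: longest substring whose RC also occurs."""
    best = 0
    n = len(seq)
    for i in range(n):
        for j in range(i + 1, n + 1):
            if _rc(seq[i:j]) in seq:
                best = max(best, j - i)
    return best


def test_selfcomp_examples():
    assert selfcomp_screen("ACGT") >= 2
    assert selfcomp_screen("AAAA") == 0


def test_selfcomp_agrees_with_bruteforce_oracle():
    rng = np.random.default_rng(11)
    for _ in range(200):
        seq = "".join("ACGT"[d] for d in rng.integers(0, 4, size=25))
        assert selfcomp_screen(seq) == _selfcomp_oracle(seq)


def test_structure_filter_threshold():
    out, _ = structure_filter(["ACGT", "AAAA"], 1)
    assert out.sequences == ["AAAA"]


# ---------------------------------------------------------------------------
# QC metrics
# ---------------------------------------------------------------------------

def test_hamming_examples():
    H = hamming_matrix(["AAA", "AAA"])
    assert H[0, 1] == 0
    H = hamming_matrix(["AAA", "TTT"])
    assert H[0, 1] == 3


def test_hamming_symmetry_zero_diagonal():
    lib = make_fixture_library(30, 10, seed=5)
    H = hamming_matrix(lib)
    assert (H == H.T).all()
    assert (np.diag(H) == 0).all()


def test_hamming_rejects_ragged():
    with pytest.raises(ParameterError):
        hamming_matrix(["AAA", "AAAA"])


def test_qc_report_fields(small_design):
    rep = qc_report(small_design, k=3)
    assert rep["n_sequences"] == 10
    assert rep["duplicate_kmers"] == 0
    assert 0 <= rep["gc_mean"] <= 1
    assert rep["hamming_min"] >= 1  # unique sequences differ somewhere


def test_qc_table_columns(small_design):
    df = qc_table(small_design)
    assert list(df.columns) == ["index", "sequence", "gc_fraction",
                                "max_homopolymer", "tm_wallace"]
    assert len(df) == len(small_design)
    assert (df["max_homopolymer"] >= 1).all()


def test_max_homopolymer_run():
    assert max_homopolymer_run("AACCCT") == 3
    assert max_homopolymer_run("ACGT") == 1


# ---------------------------------------------------------------------------
# algebraic invariants
# ---------------------------------------------------------------------------

_FILTERS = {
    "pattern": lambda lib: pattern_filter(lib, ["GG", "TTT"]),
    "homopolymer": lambda lib: homopolymer_filter(lib, 2),
    "gc": lambda lib: gc_filter(lib, 0.3, 0.7),
    "tm": lambda lib: tm_filter(lib, 20, 40, "wallace"),
    "structure": lambda lib: structure_filter(lib, 3),
}


@pytest.mark.parametrize("name", sorted(_FILTERS))
def test_filters_are_order_preserving_subsets(name):
    lib = make_fixture_library(120, 14, seed=23)
    out, rep = _FILTERS[name](lib)
    assert rep.n_kept + rep.n_removed == rep.n_input == len(lib)
    assert rep.n_kept == len(out)
    # order-preserving subset
    it = iter(lib.sequences)
    assert all(any(s == t for t in it) for s in out.sequences)


@pytest.mark.parametrize(
    "name_a, name_b",
    list(itertools.combinations(sorted(_FILTERS), 2)),
)
def test_filters_commute_setwise(name_a, name_b):
    lib = make_fixture_library(100, 12, seed=42)
    ab, _ = _FILTERS[name_b](_FILTERS[name_a](lib)[0])
    ba, _ = _FILTERS[name_a](_FILTERS[name_b](lib)[0])
    assert ab.sequences == ba.sequences


def test_filter_reports_reconcile_through_pipeline(small_design):
    cs = kw.ConstraintSet(forbidden_patterns=["GGG"], max_homopolymer=3,
                          gc_window=(0.2, 0.8))
    out, reports = kw.apply_constraints(small_design, cs)
    removed = sum(r.n_removed for r in reports)
    assert len(out) == len(small_design) - removed
    assert out.reconcile()
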