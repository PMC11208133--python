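"""Readers, writers, metadata sidecars and the random fixture generator.

Formats: plain text (one uppercase sequence per line), FASTA (headers
``seq_<index>``, 0-based, wrapped at 80 columns, via Biopython), and CSV
(``sequence,index,gc_fraction``).  All writers end the file with a
newline; readers normalise case and validate symbols.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np

from . import __version__
from .alphabet import Alphabet
from .errors import FormatError, ParameterError
from .filters import gc_content
from .library import SequenceLibrary, as_sequences

logger = logging.getLogger("kmerwalk")

_ACGT = set("ACGT")

FORMATS = ("txt", "fasta", "csv")


def _sniff_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in FORMATS:
            raise ParameterError(f"unknown format {fmt!r}; choose from {FORMATS}")
        return fmt
    suffix = path.suffix.lower().lstrip(".")
    if suffix in ("fa", "fasta", "fna"):
        return "fasta"
    if suffix == "csv":
        return "csv"
    return "txt"


def read_library(path, fmt: Optional[str] = None) -> SequenceLibrary:
    """Read a barcode library from plain text, FASTA or CSV.

    Sequences are uppercased (with a log notice) and must be ACGT-only.
    Round-trips with :func:`write_library` byte-exactly, modulo header
    regeneration in FASTA.
    """
    path = Path(path)
    fmt = _sniff_format(path, fmt)
    raw: list[str] = []
    if fmt == "fasta":
        from Bio import SeqIO

        try:
            for record in SeqIO.parse(str(path), "fasta"):
                raw.append(str(record.seq))
        except ValueError as e:
            raise FormatError(f"malformed FASTA {path}: {e}") from e
    elif fmt == "csv":
        import csv as _csv

        with open(path, newline="") as fh:
            reader = _csv.DictReader(fh)
            if reader.fieldnames is None or "sequence" not in reader.fieldnames:
                raise FormatError(f"{path}: CSV lacks a 'sequence' column")
            for row in reader:
                raw.append(row["sequence"])
    else:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if line:
                    if line.startswith(">"):
                        raise FormatError(
                            f"{path}: looks like FASTA, not plain text"
                        )
                    raw.append(line)

    if not raw:
        logger.warning("read empty library from %s", path)
    seqs = []
    lowered = 0
    for i, s in enumerate(raw):
        up = s.upper()
        if up != s:
            lowered += 1
        bad = set(up) - _ACGT
        if bad:
            raise FormatError(
                f"{path}: sequence {i} contains non-ACGT symbols {sorted(bad)}"
            )
        seqs.append(up)
    if lowered:
        logger.info("uppercased %d sequences from %s", lowered, path)
    prov = [{"operation": "read", "path": str(path), "format": fmt,
             "sequences": len(seqs)}]
    return SequenceLibrary(seqs, None, prov)


def write_library(library, path, fmt: Optional[str] = None) -> None:
    """Write a library as plain text, FASTA (80-column wrap) or CSV."""
    path = Path(path)
    fmt = _sniff_format(path, fmt)
    seqs = as_sequences(library)
    if fmt == "fasta":
        from Bio.Seq import Seq
        from Bio.SeqIO.FastaIO import FastaWriter
        from Bio.SeqRecord import SeqRecord

        records = (
            SeqRecord(Seq(s), id=f"seq_{i}", description="")
            for i, s in enumerate(seqs)
        )
        with open(path, "w") as fh:
            FastaWriter(fh, wrap=80).write_file(records)
    elif fmt == "csv":
        with open(path, "w") as fh:
            fh.write("sequence,index,gc_fraction\n")
            for i, s in enumerate(seqs):
                fh.write(f"{s},{i},{gc_content(s):.6g}\n")
    else:
        with open(path, "w") as fh:
            for s in seqs:
                fh.write(s + "\n")


def write_metadata(library: SequenceLibrary, path) -> None:
    """JSON sidecar: params, provenance counts, tool version."""
    meta = {
        "tool": "kmerwalk",
        "version": __version__,
        "params": library.params.to_dict() if library.params else None,
        "n_sequences": len(library),
        "provenance": library.provenance,
    }
    with open(path, "w") as fh:
        json.dump(meta, fh, indent=2)
        fh.write("\n")


def make_fixture_library(n: int, L: int, alphabet: Optional[Alphabet] = None,
                         seed: int = 0) -> SequenceLibrary:
    """Uniform random (non-SSM) library, reproducible by seed.

    Exercises audits and filters on input that, unlike designed
    libraries, does violate SSM whenever n*(L-k+1) crowds m**k
    (pigeonhole).  Sequences may even duplicate; that is intended.
    """
    if n < 1 or L < 1:
        raise ParameterError("n and L must be >= 1")
    alphabet = alphabet or Alphabet.dna()
    rng = np.random.default_rng(seed)
    draws = rng.integers(0, alphabet.m, size=(n, L))
    syms = alphabet.symbols
    seqs = ["".join(syms[d] for d in row) for row in draws]
    prov = [{"operation": "fixture", "n": n, "L": L,
             "alphabet": str(alphabet), "seed": seed, "sequences": n}]
    return SequenceLibrary(seqs, None, prov)
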