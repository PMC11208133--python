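"""End-to-end design pipeline: design -> RC strategy -> constraint filters.

The design itself is seed-free and fully deterministic: rerunning an
identical :class:`RunConfig` reproduces byte-identical outputs.  A seed
exists only for random fixture generation in :mod:`kmerwalk.io`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .alphabet import DesignParams
from .errors import ParameterError
from .filters import ConstraintSet, apply_constraints
from .graph import BACKENDS, design_library
from .io import write_library, write_metadata
from .library import SequenceLibrary
from .rc import (RC_MODES, adapted_hierholzer, filter_three_letter_odd,
                 rc_hash_filter)

logger = logging.getLogger("kmerwalk")

__all__ = ["RunConfig", "run_design"]


@dataclass
class RunConfig:
    """Everything needed for one reproducible design run."""

    params: DesignParams
    rc_mode: str = "none"
    constraints: ConstraintSet = field(default_factory=ConstraintSet)
    backend: str = "shift_rule"
    output: Optional[Path] = None
    fmt: str = "txt"
    metadata: Optional[Path] = None

    def __post_init__(self) -> None:
        if self.rc_mode not in RC_MODES:
            raise ParameterError(
                f"unknown rc_mode {self.rc_mode!r}; choose from {RC_MODES}"
            )
        if self.backend not in BACKENDS:
            raise ParameterError(
                f"unknown backend {self.backend!r}; choose from {BACKENDS}"
            )


def run_design(config: RunConfig) -> SequenceLibrary:
    """Design, apply the RC strategy, apply constraint filters, write output.

    Each stage logs its counts to the ``kmerwalk`` logger; the returned
    library's provenance reconciles designed - removed == written.
    """
    params = config.params

    if config.rc_mode == "adapted_hierholzer":
        library = adapted_hierholzer(params)
    else:
        library = design_library(params, backend=config.backend)
    logger.info(
        "designed %d sequences (m=%d, k=%d, L=%d, %s)",
        len(library), params.m, params.k, params.L,
        "adapted_hierholzer" if config.rc_mode == "adapted_hierholzer"
        else config.backend,
    )

    if config.rc_mode == "three_letter_odd":
        library, report = filter_three_letter_odd(library, params.k)
        logger.info("RC three-letter filter removed %d, kept %d",
                    report.n_removed, report.n_kept)
    elif config.rc_mode == "hash_filter":
        library, report = rc_hash_filter(library, params.k)
        logger.info("RC hash filter removed %d, kept %d",
                    report.n_removed, report.n_kept)

    if not config.constraints.is_empty():
        library, reports = apply_constraints(library, config.constraints)
        for r in reports:
            logger.info("%s filter removed %d, kept %d",
                        r.rule, r.n_removed, r.n_kept)

    if config.output is not None:
        write_library(library, config.output, config.fmt)
        meta_path = config.metadata or Path(str(config.output) + ".meta.json")
        write_metadata(library, meta_path)
        logger.info("wrote %d sequences to %s", len(library), config.output)

    assert library.reconcile(), "provenance counts do not reconcile"
    return library
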