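"""Terrace-aware bootstrap support.

Each bootstrap replicate tree sits on its own terrace: trees the replicate's
coverage pattern cannot distinguish from it.  Ordinary majority-rule
consensus credits a replicate with every split it shows, including splits
that are arbitrary within its terrace.  The terrace-aware procedure instead
takes the strict consensus of each replicate's terrace — keeping only splits
present in 100% of the terrace — and builds the majority-rule tree from
those.  A split absent from some terrace member can only lose support, so
terrace-aware support is bounded above by plain support, split by split, and
the consensus resolution rho can only drop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from . import trees as _t
from .coverage import CoverageMatrix
from .errors import ResolutionLimitError
from .terrace import count_parent_trees, terrace_strict_consensus

log = logging.getLogger(__name__)

__all__ = ["BootstrapReport", "terrace_aware_bootstrap"]


@dataclass
class BootstrapReport:
    """Plain vs terrace-aware majority-rule summaries of one replicate set."""

    n_replicates: int
    plain_majority: _t.Tree
    aware_majority: _t.Tree
    rho_plain: float
    rho_aware: float
    plain_support: dict   # Bipartition -> fraction of replicates
    aware_support: dict   # Bipartition -> fraction of terrace consensuses
    terrace_sizes: list | None = None
    n_excluded: int = 0   # replicates whose terrace computation was capped


def terrace_aware_bootstrap(
    replicates: Sequence[_t.Tree],
    matrix: CoverageMatrix,
    threshold: float = 0.5,
    include_sizes: bool = False,
    work_cap: int | None = None,
) -> BootstrapReport:
    """Run the plain and terrace-aware majority-rule pipelines side by side.

    ``threshold`` is the (strict) majority cutoff for both consensus trees.
    Replicates whose terrace computation exceeds ``work_cap`` are excluded
    from the aware tally (a lower-bound consensus is not defined) and
    counted in ``n_excluded``.
    """
    if not replicates:
        raise ValueError("need at least one replicate tree")
    aware_inputs = []
    sizes: list = []
    excluded = 0
    for rep in replicates:
        try:
            if work_cap is not None:
                size, capped = count_parent_trees(rep, matrix, work_cap=work_cap)
                if capped:
                    excluded += 1
                    continue
                if include_sizes:
                    sizes.append(size)
            elif include_sizes:
                size, _ = count_parent_trees(rep, matrix)
                sizes.append(size)
            aware_inputs.append(terrace_strict_consensus(rep, matrix))
        except ResolutionLimitError:
            excluded += 1
    if excluded:
        log.warning("excluded %d replicates with capped terraces", excluded)
    if not aware_inputs:
        raise ValueError("every replicate's terrace computation was capped")
    plain = _t.majority_rule_consensus(replicates, threshold)
    aware = _t.majority_rule_consensus(aware_inputs, threshold)
    return BootstrapReport(
        n_replicates=len(replicates),
        plain_majority=plain,
        aware_majority=aware,
        rho_plain=_t.resolution_rho(plain),
        rho_aware=_t.resolution_rho(aware),
        plain_support=_t.split_support(list(replicates)),
        aware_support=_t.split_support(aware_inputs),
        terrace_sizes=sizes if include_sizes else None,
        n_excluded=excluded,
    )
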