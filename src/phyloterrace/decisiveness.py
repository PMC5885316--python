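"""Data-decisiveness diagnostics and edge-length model comparison arithmetic.

A coverage pattern is *decisive* for a tree when the tree is the only parent
tree of its induced subtrees — the terrace has one member.  Under uniform
random taxon sampling at density d, the minimum number of loci needed for a
pattern on n taxa to be decisive for a random tree with confidence p is

    k_min = ln(C(n,3)/p) / -ln(1 - d^4)        (exact form)
          ~ ln(n^3/(6 p)) / -ln(1 - d^4)       (approximation)

Gene sampling sufficiency compares the sampled locus count k to that bound
on a log scale:

    zeta = ln(k / k_min)

so zeta >= 0 marks sufficient gene sampling and zeta < 0 insufficient.

The module also carries the two exact coverage conditions (a fully sampled
locus is sufficient; full taxon-triple coverage is necessary) and plain AIC
arithmetic for comparing edge-linked (EL: one shared branch-length set) and
edge-unlinked (EUL: independent branch lengths per partition) likelihood
models from externally supplied log-likelihoods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .coverage import CoverageMatrix, comprehensive_taxa, triple_coverage_fraction

__all__ = [
    "kmin",
    "gene_sampling_sufficiency",
    "decisiveness_conditions",
    "DecisivenessReport",
    "decisiveness_report",
    "ModelScore",
    "aic",
    "delta_aic",
]


def kmin(
    n: int, d: float, p: float = 0.05, mode: str = "approx"
) -> tuple[float, int]:
    """Minimum locus count for decisiveness with confidence ``p``.

    Returns ``(raw, ceil)``.  ``mode="exact"`` uses ln(C(n,3)/p);
    ``mode="approx"`` (the form used for survey comparisons) uses
    ln(n^3/(6p)).  At d = 1 any single locus is decisive and the bound is 0.
    """
    if n < 3:
        raise ValueError(f"need n >= 3 taxa, got {n}")
    if not 0 < d <= 1:
        raise ValueError(f"density must be in (0, 1], got {d}")
    if not 0 < p < 1:
        raise ValueError(f"confidence p must be in (0, 1), got {p}")
    if d == 1:
        return 0.0, 0
    denom = -math.log(1 - d**4)
    if mode == "exact":
        numer = math.log(math.comb(n, 3) / p)
    elif mode == "approx":
        numer = math.log(n**3 / (6 * p))
    else:
        raise ValueError(f"unknown mode: {mode!r}")
    raw = numer / denom
    return raw, math.ceil(raw)


def gene_sampling_sufficiency(k: int, kmin_raw: float) -> float:
    """zeta = ln(k / k_min); >= 0 iff the sampled locus count reaches the
    decisiveness bound."""
    if k < 1:
        raise ValueError(f"need k >= 1 sampled loci, got {k}")
    if kmin_raw <= 0:
        raise ValueError(f"need a positive k_min, got {kmin_raw}")
    return math.log(k / kmin_raw)


def decisiveness_conditions(matrix: CoverageMatrix) -> tuple[bool, bool]:
    """(sufficient, necessary) coverage conditions for decisiveness.

    Sufficient: some locus samples every taxon.  Necessary: every taxon
    triple occurs in at least one locus subset.  Sufficiency implies
    necessity; neither alone settles the general case, which depends on the
    tree shape as well.
    """
    if matrix.n < 3:
        raise ValueError("decisiveness conditions need at least 3 taxa")
    sufficient = bool(matrix.presence.all(axis=0).any())
    if sufficient:
        return True, True
    necessary = triple_coverage_fraction(matrix, mode="exact").fraction == 1.0
    return False, necessary


@dataclass(frozen=True)
class DecisivenessReport:
    """Bundle of decisiveness diagnostics for one coverage matrix."""

    n: int
    k: int
    d: float
    p: float
    kmin_exact_raw: float
    kmin_approx_raw: float
    kmin: int  # ceiling of the approximate form
    zeta: float
    has_full_locus: bool
    triples_necessary: bool
    triple_fraction: float
    has_comprehensive_taxon: bool


def decisiveness_report(
    matrix: CoverageMatrix,
    p: float = 0.05,
    use_integer_kmin: bool = False,
) -> DecisivenessReport:
    """Compute every decisiveness diagnostic from a coverage matrix.

    ``zeta`` is computed from the raw (unrounded) approximate k_min by
    default; ``use_integer_kmin`` switches to the printed-integer
    convention.
    """
    n, k, d = matrix.n, matrix.k, matrix.density
    exact_raw, _ = kmin(n, d, p, mode="exact")
    approx_raw, approx_ceil = kmin(n, d, p, mode="approx")
    basis = approx_ceil if use_integer_kmin else approx_raw
    zeta = gene_sampling_sufficiency(k, basis) if basis > 0 else math.inf
    sufficient, necessary = decisiveness_conditions(matrix)
    frac = triple_coverage_fraction(matrix, mode="exact").fraction
    return DecisivenessReport(
        n=n,
        k=k,
        d=d,
        p=p,
        kmin_exact_raw=exact_raw,
        kmin_approx_raw=approx_raw,
        kmin=approx_ceil,
        zeta=zeta,
        has_full_locus=sufficient,
        triples_necessary=necessary,
        triple_fraction=frac,
        has_comprehensive_taxon=bool(comprehensive_taxa(matrix)),
    )


# ---------------------------------------------------------------------------
# AIC arithmetic for EL vs EUL model choice


@dataclass(frozen=True)
class ModelScore:
    """A fitted model's tag, parameter count, and log-likelihood."""

    model: str  # "EL" or "EUL"
    parameters: int
    log_likelihood: float

    @property
    def aic(self) -> float:
        return aic(self.parameters, self.log_likelihood)


def aic(parameter_count: int, log_likelihood: float) -> float:
    """Akaike information criterion: 2*params - 2*lnL."""
    if parameter_count < 0:
        raise ValueError("parameter count cannot be negative")
    return 2 * parameter_count - 2 * log_likelihood


def delta_aic(el: ModelScore, eul: ModelScore) -> float:
    """AIC[EL] - AIC[EUL]: positive favors the edge-unlinked model."""
    return el.aic - eul.aic
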