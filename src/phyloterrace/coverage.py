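"""Taxon-by-locus coverage matrices.

A coverage matrix records, for each taxon and each locus of a partitioned
alignment, whether *any* data are present: a locus counts as sampled for a
taxon as soon as one site in the locus holds a non-missing character.  The
matrix — not the sequences — is what terrace theory consumes: the taxon
subsets Y_1..Y_k (one per locus), the coverage density d, and the fraction
of taxon triples jointly sampled by some locus.

Matrices are built from FASTA / relaxed-PHYLIP alignments plus a RAxML-style
partition definition, or read and written as plain 0/1 CSV.
"""

from __future__ import annotations

import itertools
import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import AlignIO

from .errors import CoverageFormatError

log = logging.getLogger(__name__)

#: Default missing-data characters.  "Any data present" marks a locus as
#: sampled, so fully ambiguous characters are treated as absent by default
#: (an all-N stretch carries no signal); override ``missing_chars`` to change
#: the boundary.
MISSING_NUCLEOTIDE = frozenset("-?Nn")
MISSING_AMINO_ACID = frozenset("-?Xx")

__all__ = [
    "PartitionScheme",
    "CoverageMatrix",
    "MISSING_NUCLEOTIDE",
    "MISSING_AMINO_ACID",
    "parse_raxml_partitions",
    "read_alignment",
    "coverage_from_alignment",
    "coverage_from_csv",
    "coverage_to_csv",
    "density",
    "comprehensive_taxa",
    "triple_coverage_fraction",
    "TripleCoverage",
]


@dataclass(frozen=True)
class PartitionScheme:
    """Ordered loci, each a list of 1-based inclusive (start, end, step) ranges."""

    loci: tuple  # tuple[(name, tuple[(start, end, step), ...]), ...]

    def __post_init__(self):
        names = [name for name, _ in self.loci]
        if len(names) != len(set(names)):
            raise CoverageFormatError("duplicate locus names in partition scheme")
        seen: dict = {}
        for name, ranges in self.loci:
            for start, end, step in ranges:
                if start < 1 or end < start or step < 1:
                    raise CoverageFormatError(
                        f"bad range {start}-{end} (step {step}) in locus {name!r}"
                    )
                for site in range(start, end + 1, step):
                    if site in seen:
                        raise CoverageFormatError(
                            f"site {site} assigned to both {seen[site]!r} and {name!r}"
                        )
                    seen[site] = name

    @property
    def names(self) -> tuple:
        return tuple(name for name, _ in self.loci)

    def sites(self, name: str) -> list[int]:
        """0-based site indices of a locus."""
        for nm, ranges in self.loci:
            if nm == name:
                return [
                    s - 1
                    for start, end, step in ranges
                    for s in range(start, end + 1, step)
                ]
        raise KeyError(name)

    @property
    def max_site(self) -> int:
        return max(end for _, ranges in self.loci for _, end, _ in ranges)


_PARTITION_LINE = re.compile(
    r"^(?:[A-Za-z][\w.+-]*\s*,\s*)?"  # optional data-type prefix ("DNA,", "WAG,")
    r"(?P<name>[^=]+?)\s*=\s*(?P<ranges>.+)$"
)


def parse_raxml_partitions(text: str) -> PartitionScheme:
    """Parse a RAxML-style partition file.

    Lines look like ``DNA, gene1 = 1-500, 603-707`` with optional codon-step
    suffixes (``1-500\\3``); coordinates are 1-based inclusive.
    """
    loci = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        m = _PARTITION_LINE.match(line)
        if not m:
            raise CoverageFormatError(
                f"unparseable partition line {lineno}: {raw!r}"
            )
        name = m.group("name").strip()
        ranges = []
        for chunk in m.group("ranges").split(","):
            chunk = chunk.strip()
            if not chunk:
                continue
            step = 1
            if "\\" in chunk:
                chunk, step_s = chunk.split("\\", 1)
                step = int(step_s)
            if "-" in chunk:
                start_s, end_s = chunk.split("-", 1)
                start, end = int(start_s), int(end_s)
            else:
                start = end = int(chunk)
            ranges.append((start, end, step))
        if not ranges:
            raise CoverageFormatError(f"locus {name!r} has no site ranges")
        loci.append((name, tuple(ranges)))
    if not loci:
        raise CoverageFormatError("no partitions found")
    return PartitionScheme(tuple(loci))


@dataclass
class CoverageMatrix:
    """Boolean taxa x loci presence pattern.

    ``subsets()`` gives the taxon subsets Y_j; ``density`` is the fraction of
    present cells.  All-absent rows or columns are reported (``empty_taxa``,
    ``empty_loci``) and may be dropped at construction.
    """

    taxa: tuple
    loci: tuple
    presence: np.ndarray  # bool, shape (n, k)
    empty_taxa: tuple = field(default=(), compare=False)
    empty_loci: tuple = field(default=(), compare=False)

    def __post_init__(self):
        self.taxa = tuple(self.taxa)
        self.loci = tuple(self.loci)
        self.presence = np.asarray(self.presence, dtype=bool)
        if self.presence.shape != (len(self.taxa), len(self.loci)):
            raise CoverageFormatError(
                f"presence shape {self.presence.shape} does not match "
                f"{len(self.taxa)} taxa x {len(self.loci)} loci"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise CoverageFormatError("duplicate taxon labels")
        if len(set(self.loci)) != len(self.loci):
            raise CoverageFormatError("duplicate locus names")
        self.empty_taxa = tuple(
            t for t, row in zip(self.taxa, self.presence) if not row.any()
        )
        self.empty_loci = tuple(
            l for j, l in enumerate(self.loci) if not self.presence[:, j].any()
        )

    @classmethod
    def from_rows(cls, taxa, loci, rows, drop_empty=False) -> "CoverageMatrix":
        m = cls(tuple(taxa), tuple(loci), np.asarray(rows, dtype=bool))
        if drop_empty and (m.empty_taxa or m.empty_loci):
            keep_r = [i for i, t in enumerate(m.taxa) if t not in set(m.empty_taxa)]
            keep_c = [j for j, l in enumerate(m.loci) if l not in set(m.empty_loci)]
            log.warning(
                "dropping %d all-absent taxa and %d all-absent loci",
                len(m.empty_taxa), len(m.empty_loci),
            )
            m = cls(
                tuple(m.taxa[i] for i in keep_r),
                tuple(m.loci[j] for j in keep_c),
                m.presence[np.ix_(keep_r, keep_c)],
            )
        return m

    @property
    def n(self) -> int:
        return len(self.taxa)

    @property
    def k(self) -> int:
        return len(self.loci)

    @property
    def density(self) -> float:
        return float(self.presence.sum()) / (self.n * self.k)

    def subsets(self) -> list[frozenset]:
        """Y_j: the set of taxa sampled for each locus, in locus order."""
        return [
            frozenset(t for t, p in zip(self.taxa, self.presence[:, j]) if p)
            for j in range(self.k)
        ]

    def restricted_to_taxa(self, taxa: Iterable[str]) -> "CoverageMatrix":
        keep = [i for i, t in enumerate(self.taxa) if t in set(taxa)]
        return CoverageMatrix(
            tuple(self.taxa[i] for i in keep), self.loci, self.presence[keep]
        )


# ---------------------------------------------------------------------------
# construction


def read_alignment(path, schema: str = "fasta") -> dict:
    """Read an alignment into an ordered {taxon: sequence} mapping.

    ``schema`` is "fasta" or "phylip-relaxed" (Biopython formats).
    """
    fmt = {"fasta": "fasta", "phylip-relaxed": "phylip-relaxed", "phylip": "phylip-relaxed"}
    if schema not in fmt:
        raise CoverageFormatError(f"unsupported alignment format: {schema!r}")
    try:
        aln = AlignIO.read(path, fmt[schema])
    except Exception as exc:
        raise CoverageFormatError(f"could not read alignment: {exc}") from exc
    seqs = {}
    for rec in aln:
        if rec.id in seqs:
            raise CoverageFormatError(f"duplicate taxon in alignment: {rec.id}")
        seqs[rec.id] = str(rec.seq)
    return seqs


def coverage_from_alignment(
    alignment: Mapping[str, str],
    scheme: PartitionScheme,
    missing_chars: Iterable[str] = MISSING_NUCLEOTIDE,
    drop_empty: bool = False,
) -> CoverageMatrix:
    """presence[i][j] is True iff taxon i has >= 1 non-missing character in
    locus j's sites."""
    missing = frozenset(missing_chars)
    lengths = {len(s) for s in alignment.values()}
    if len(lengths) > 1:
        raise CoverageFormatError(
            f"ragged alignment: sequence lengths {sorted(lengths)}"
        )
    length = lengths.pop() if lengths else 0
    if scheme.max_site > length:
        raise CoverageFormatError(
            f"partition range extends to site {scheme.max_site}, "
            f"but the alignment has {length} sites"
        )
    taxa = tuple(alignment)
    site_lists = [scheme.sites(name) for name in scheme.names]
    rows = np.zeros((len(taxa), len(scheme.names)), dtype=bool)
    for i, taxon in enumerate(taxa):
        seq = alignment[taxon]
        for j, sites in enumerate(site_lists):
            rows[i, j] = any(seq[s] not in missing for s in sites)
    m = CoverageMatrix.from_rows(taxa, scheme.names, rows, drop_empty=drop_empty)
    for t in m.empty_taxa:
        log.warning("taxon %r has no data in any locus", t)
    return m


def coverage_from_csv(path) -> CoverageMatrix:
    """Read a 0/1 coverage CSV (taxon labels in the first column)."""
    df = pd.read_csv(path, index_col=0, dtype=str)
    values = df.to_numpy()
    bad = [v for v in np.unique(values) if v not in ("0", "1")]
    if bad:
        raise CoverageFormatError(f"non-binary coverage cells: {bad}")
    return CoverageMatrix(
        tuple(str(t) for t in df.index),
        tuple(str(c) for c in df.columns),
        values == "1",
    )


def coverage_to_csv(matrix: CoverageMatrix, path) -> None:
    df = pd.DataFrame(
        matrix.presence.astype(int), index=list(matrix.taxa), columns=list(matrix.loci)
    )
    df.to_csv(path)


# ---------------------------------------------------------------------------
# diagnostics


def density(matrix: CoverageMatrix) -> float:
    return matrix.density


def comprehensive_taxa(matrix: CoverageMatrix) -> list[str]:
    """Taxa sampled in every locus, in input order.

    A comprehensive taxon anchors the rooted-triplet machinery: every
    locus-induced subtree can be rooted at it.
    """
    return [t for t, row in zip(matrix.taxa, matrix.presence) if row.all()]


@dataclass(frozen=True)
class TripleCoverage:
    fraction: float
    stderr: float | None  # None in exact mode
    mode: str
    samples: int | None = None


def triple_coverage_fraction(
    matrix: CoverageMatrix,
    mode: str = "exact",
    samples: int = 100_000,
    seed: int | None = None,
    exact_ceiling: int = 2000,
) -> TripleCoverage:
    """Fraction of the C(n,3) taxon triples contained in >= 1 subset Y_j.

    Full triple coverage is the necessary condition for decisiveness; a
    single fully sampled locus makes it 1.0 trivially.  Exact mode walks all
    triples with per-taxon locus bitsets (O(n^3), refused above
    ``exact_ceiling`` taxa); Monte-Carlo mode samples triples uniformly and
    reports a binomial standard error.
    """
    n = matrix.n
    if n < 3:
        raise ValueError("triple coverage needs at least 3 taxa")
    if mode == "exact":
        if n > exact_ceiling:
            raise ValueError(
                f"exact mode refused for n={n} > {exact_ceiling}; "
                "use mode='montecarlo'"
            )
        masks = [
            int.from_bytes(np.packbits(row).tobytes(), "big")
            for row in matrix.presence
        ]
        covered = sum(
            1
            for i, j, l in itertools.combinations(range(n), 3)
            if masks[i] & masks[j] & masks[l]
        )
        total = math.comb(n, 3)
        return TripleCoverage(covered / total, None, "exact")
    if mode in ("montecarlo", "mc"):
        rng = np.random.default_rng(seed)
        P = matrix.presence
        remaining = samples
        hits = 0
        while remaining > 0:
            batch = min(remaining, 500_000)
            idx = rng.integers(0, n, size=(int(batch * 1.2) + 8, 3))
            distinct = (
                (idx[:, 0] != idx[:, 1])
                & (idx[:, 0] != idx[:, 2])
                & (idx[:, 1] != idx[:, 2])
            )
            idx = idx[distinct][:batch]
            if idx.shape[0] == 0:
                continue
            joint = P[idx[:, 0]] & P[idx[:, 1]] & P[idx[:, 2]]
            hits += int(joint.any(axis=1).sum())
            remaining -= idx.shape[0]
        drawn = samples
        p = hits / drawn
        se = math.sqrt(p * (1 - p) / drawn)
        return TripleCoverage(p, se, "montecarlo", drawn)
    raise ValueError(f"unknown mode: {mode!r}")
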