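"""Small-RNA read processing and the 5'-window counting rule.

The stage contract, in pipeline order:

1. :func:`trim_3p_adapter` -- remove a 3' sequencing adapter (prefix match,
   minimum overlap, optional error tolerance).
2. :func:`length_filter` -- keep trimmed reads of 15-27 nt (inclusive).
3. :func:`align_exact` -- report every exact full-length occurrence of the
   read on both strands of the reference (no mismatches).
4. :func:`assign_counts` -- a hit is attributed to a mature miRNA iff its
   5' end lies within +/- `window` nt of the annotated mature 5' start on
   the same contig and strand.  Hits to multiple loci of one miRNA collapse
   to a single count; a read matching k distinct miRNAs contributes 1/k to
   each (exact rational arithmetic).
5. :func:`compute_rpm`, :func:`presence_filter`, :func:`library_qc_gate` --
   normalization to reads-per-million and the sample/feature filters.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, QCGateError
from .seq import as_dna, check_alphabet, revcomp

logger = logging.getLogger(__name__)

MIN_READ_LEN = 15
MAX_READ_LEN = 27
MIRNA_LIBRARY_MIN_MAPPABLE = 1_000_000
MRNA_LIBRARY_MIN_MAPPABLE = 30_000_000


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Read:
    """A (possibly trimmed) sequencing read; U is accepted and equals T."""

    id: str
    sequence: str

    def __post_init__(self):
        check_alphabet(self.sequence, f"read {self.id!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AdapterSpec:
    adapter: str
    min_overlap: int = 7
    max_error_rate: float = 0.0

    def __post_init__(self):
        check_alphabet(self.adapter, "adapter")
        if not (1 <= self.min_overlap <= len(self.adapter)):
            raise ConfigurationError(
                f"min_overlap must satisfy 1 <= min_overlap <= len(adapter); "
                f"got {self.min_overlap} for a {len(self.adapter)} nt adapter"
            )
        if not (0.0 <= self.max_error_rate < 1.0):
            raise ConfigurationError("max_error_rate must be in [0, 1)")


@dataclass(frozen=True)
class Locus:
    """Genomic anchor of a mature miRNA: the annotated 5'-start position.

    ``five_prime_start`` is 1-based; on the minus strand it is the
    *rightmost* genomic base of the mature sequence.
    """

    seqid: str
    strand: str
    five_prime_start: int

    def __post_init__(self):
        if self.strand not in "+-":
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if self.five_prime_start < 1:
            raise ValueError("five_prime_start is 1-based and must be >= 1")


@dataclass(frozen=True)
class MatureMiRNAAnnotation:
    name: str
    sequence: str
    loci: tuple[Locus, ...]

    def __post_init__(self):
        check_alphabet(self.sequence, f"mature sequence of {self.name!r}")
        if not self.loci:
            raise ValueError(f"miRNA {self.name!r} must have at least one locus")


@dataclass(frozen=True)
class AlignmentHit:
    """Exact full-length placement of a read; ``five_prime`` is the 1-based
    genomic position of the read's 5' end (rightmost base on '-')."""

    seqid: str
    strand: str
    five_prime: int


@dataclass
class AssignmentResult:
    counts: dict[str, Fraction]
    n_assigned_reads: int
    n_mappable_reads: int
    audit: dict[str, tuple[tuple[str, ...], Fraction]] = field(repr=False, default_factory=dict)

    def as_series(self, features: Sequence[str] | None = None) -> pd.Series:
        feats = list(features) if features is not None else sorted(self.counts)
        return pd.Series({f: float(self.counts.get(f, 0)) for f in feats}, dtype=float)


@dataclass
class CountTable:
    """Feature x sample matrix with per-sample library sizes.

    ``counts`` may hold fractional values (apportioned miRNA reads).
    ``library_sizes`` is the per-sample mappable-read total used as the
    RPM denominator and by the QC gate.
    """

    counts: pd.DataFrame
    library_sizes: pd.Series
    kind: str = "miRNA"

    def __post_init__(self):
        if self.kind not in ("miRNA", "mRNA"):
            raise ValueError(f"kind must be 'miRNA' or 'mRNA', got {self.kind!r}")
        self.library_sizes = self.library_sizes.reindex(self.counts.columns)
        if self.library_sizes.isna().any():
            missing = list(self.library_sizes.index[self.library_sizes.isna()])
            raise ValueError(f"missing library sizes for samples {missing}")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def features(self) -> list[str]:
        return list(self.counts.index)

    def subset_samples(self, samples: Sequence[str]) -> "CountTable":
        return CountTable(self.counts[list(samples)], self.library_sizes[list(samples)], self.kind)


# ---------------------------------------------------------------------------
# trimming and filtering
# ---------------------------------------------------------------------------

def trim_3p_adapter(read: Read, spec: AdapterSpec) -> Read:
    """Remove the 3' adapter: the leftmost position where a prefix of the
    adapter matches the read up to its end with >= ``min_overlap`` aligned
    bases and a mismatch fraction <= ``max_error_rate``.

    A full internal adapter occurrence removes everything from the match
    onward.  With no qualifying match the read is returned unchanged, so
    trimming is idempotent.
    """
    seq = as_dna(read.sequence)
    adapter = as_dna(spec.adapter)
    n, m = len(seq), len(adapter)
    for start in range(0, n - spec.min_overlap + 1):
        overlap = min(n - start, m)
        errors = sum(1 for a, b in zip(seq[start:start + overlap], adapter[:overlap]) if a != b)
        if errors <= spec.max_error_rate * overlap:
            return Read(read.id, seq[:start]) if start else _empty_read(read)
    return read


def _empty_read(read: Read) -> Read:
    # Read forbids empty sequences by construction; an adapter-only read is
    # represented with an explicit sentinel object instead.
    return EmptyRead(read.id)


class EmptyRead(Read):
    """Zero-length read produced when trimming consumed the whole insert."""

    def __init__(self, id: str):  # noqa: A002 - mirrors Read field name
        object.__setattr__(self, "id", id)
        object.__setattr__(self, "sequence", "")

    def __len__(self) -> int:
        return 0


def length_filter(reads: Iterable[Read],
                  min_len: int = MIN_READ_LEN,
                  max_len: int = MAX_READ_LEN) -> list[Read]:
    """Keep reads with min_len <= length <= max_len (bounds inclusive)."""
    return [r for r in reads if min_len <= len(r) <= max_len]


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _find_all(haystack: str, needle: str) -> list[int]:
    out, i = [], haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def align_exact(read: Read, reference: Mapping[str, str]) -> list[AlignmentHit]:
    """All exact full-length occurrences of the read on both strands.

    ``reference`` maps seqid -> sequence.  Plus-strand hits report the
    leftmost base as the 5' end; minus-strand hits (the read matches the
    reverse complement) report the rightmost base.
    """
    if len(read) == 0:
        return []
    fwd = as_dna(read.sequence)
    rev = revcomp(fwd)
    hits: list[AlignmentHit] = []
    for seqid, contig in reference.items():
        contig = as_dna(contig)
        for i in _find_all(contig, fwd):
            hits.append(AlignmentHit(seqid, "+", i + 1))
        for i in _find_all(contig, rev):
            hits.append(AlignmentHit(seqid, "-", i + len(rev)))
    return hits


# ---------------------------------------------------------------------------
# counting rule
# ---------------------------------------------------------------------------

def assign_counts(hits_per_read: Mapping[str, Sequence[AlignmentHit]],
                  annotations: Sequence[MatureMiRNAAnnotation],
                  window: int = 5) -> AssignmentResult:
    """Apply the +/-window counting rule with collapsing and apportionment.

    A hit matches a mature miRNA iff it shares seqid and strand with one of
    the miRNA's loci and |hit 5' - annotated 5' start| <= window.  Per read
    the matched miRNA *names* are deduplicated (multi-locus collapsing);
    the read then contributes 1/k to each of the k matched miRNAs.  Reads
    with >= 1 genomic hit count toward ``n_mappable_reads`` whether or not
    any annotation matched.
    """
    if window < 0:
        raise ConfigurationError(f"window must be >= 0, got {window}")
    if not annotations:
        raise ConfigurationError("annotations must be nonempty")

    by_key: dict[tuple[str, str], list[tuple[int, str]]] = {}
    for ann in annotations:
        for locus in ann.loci:
            by_key.setdefault((locus.seqid, locus.strand), []).append(
                (locus.five_prime_start, ann.name))

    counts: dict[str, Fraction] = {ann.name: Fraction(0) for ann in annotations}
    audit: dict[str, tuple[tuple[str, ...], Fraction]] = {}
    n_mappable = 0
    n_assigned = 0
    for read_id, hits in hits_per_read.items():
        if not hits:
            continue
        n_mappable += 1
        matched: set[str] = set()
        for hit in hits:
            for start, name in by_key.get((hit.seqid, hit.strand), ()):
                if abs(hit.five_prime - start) <= window:
                    matched.add(name)
        if not matched:
            continue
        n_assigned += 1
        share = Fraction(1, len(matched))
        for name in matched:
            counts[name] += share
        audit[read_id] = (tuple(sorted(matched)), share)

    result = AssignmentResult(counts, n_assigned, n_mappable, audit)
    assert sum(counts.values()) == n_assigned  # exact rational conservation
    return result


# ---------------------------------------------------------------------------
# normalization and filters
# ---------------------------------------------------------------------------

def compute_rpm(table: CountTable) -> pd.DataFrame:
    """RPM(f, s) = count(f, s) / library_size(s) * 1e6."""
    if (table.library_sizes <= 0).any():
        zero = list(table.library_sizes.index[table.library_sizes <= 0])
        raise ValueError(f"non-positive library size for samples {zero}")
    return table.counts.div(table.library_sizes, axis=1) * 1e6


def presence_filter(table: CountTable, design: Mapping[str, str],
                    groups: Sequence[str] | None = None) -> CountTable:
    """Keep a feature iff it is nonzero in >= ceil(n/2) replicates of every
    group under comparison (equivalently: drop features that are zero in
    more than half the replicates of any group)."""
    unknown = [s for s in table.samples if s not in design]
    if unknown:
        raise ValueError(f"samples without a group label: {unknown}")
    wanted = set(groups) if groups is not None else set(design[s] for s in table.samples)
    keep = pd.Series(True, index=table.counts.index)
    for group in sorted(wanted):
        members = [s for s in table.samples if design[s] == group]
        if not members:
            raise ValueError(f"unknown or empty group {group!r}")
        need = math.ceil(len(members) / 2)
        keep &= (table.counts[members] > 0).sum(axis=1) >= need
    return CountTable(table.counts.loc[keep], table.library_sizes, table.kind)


def library_qc_gate(table: CountTable,
                    design: Mapping[str, str] | None = None) -> CountTable:
    """Drop samples at or below the mappable-read threshold for the table's
    kind (miRNA: 1e6, mRNA: 3e7; samples must be *strictly above* the
    threshold to be kept).  Raises QCGateError if a design group (or the
    whole table) is left empty."""
    threshold = MIRNA_LIBRARY_MIN_MAPPABLE if table.kind == "miRNA" else MRNA_LIBRARY_MIN_MAPPABLE
    kept = [s for s in table.samples if table.library_sizes[s] > threshold]
    dropped = [s for s in table.samples if s not in kept]
    if dropped:
        logger.warning("library QC gate (%s, >%d mappable): dropped %s",
                       table.kind, threshold, dropped)
    if design is not None:
        for group in sorted(set(design[s] for s in table.samples if s in design)):
            if not any(design.get(s) == group for s in kept):
                raise QCGateError(
                    f"QC gate removed every sample of group {group!r}; comparison impossible")
    if not kept:
        raise QCGateError("QC gate removed every sample")
    return table.subset_samples(kept)


def quantify_reads(reads: Iterable[Read],
                   reference: Mapping[str, str],
                   annotations: Sequence[MatureMiRNAAnnotation],
                   adapter: AdapterSpec | None = None,
                   window: int = 5) -> AssignmentResult:
    """Convenience driver: trim -> length filter -> align -> assign."""
    processed = list(reads)
    if adapter is not None:
        processed = [trim_3p_adapter(r, adapter) for r in processed]
    processed = length_filter(processed)
    hits = {r.id: align_exact(r, reference) for r in processed}
    return assign_counts(hits, annotations, window=window)
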