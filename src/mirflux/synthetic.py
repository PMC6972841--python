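"""Simulators for every pipeline input, plus the packaged printed-pair-table
fixtures.

Everything is deterministic given the config seed: generators draw from a
single ``numpy.random.default_rng(seed)`` stream in a fixed order, so equal
configs give byte-identical FASTA/FASTQ/TSV payloads.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, TableParseError
from .quant import CountTable, Locus, MatureMiRNAAnnotation
from .seq import as_dna, revcomp

NUCLEOTIDES = np.array(list("ACGT"))

SEED_TYPES = ("8mer", "7mer-m8", "7mer-A1")

_DEFAULT_OFFSET_PROBS = {0: 0.5, -1: 0.1, 1: 0.1, -2: 0.05, 2: 0.05,
                         -3: 0.04, 3: 0.04, -4: 0.03, 4: 0.03, -5: 0.03, 5: 0.03}


@dataclass
class SimulationConfig:
    """Knobs for all generators; ``seed`` is mandatory."""

    seed: int
    n_mirnas: int = 20
    n_genes: int = 500
    n_samples_per_group: int = 5
    groups: tuple[str, ...] = ("TA", "NAWD")
    adapter: str = "TGGAATTCTCGGGTGCCAAGG"
    read_5p_offset_probs: dict[int, float] = field(
        default_factory=lambda: dict(_DEFAULT_OFFSET_PROBS))
    nb_dispersion: float = 0.05
    effect_fold_changes: dict[str, float] = field(default_factory=dict)
    k_unwanted: int = 3
    factor_loadings_scale: float = 0.0
    baseline_mean: float = 200.0
    read_length: int = 75

    def __post_init__(self):
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigurationError(f"seed must be an integer, got {self.seed!r}")
        if self.n_mirnas < 1 or self.n_genes < 1:
            raise ConfigurationError("n_mirnas and n_genes must be >= 1")
        if self.n_samples_per_group < 2:
            raise ConfigurationError("n_samples_per_group must be >= 2")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.k_unwanted < 0:
            raise ConfigurationError("k_unwanted must be >= 0")
        total = sum(self.read_5p_offset_probs.values())
        if not math.isclose(total, 1.0, abs_tol=1e-9):
            raise ConfigurationError(
                f"read_5p_offset_probs must sum to 1, got {total}")
        if any(p < 0 for p in self.read_5p_offset_probs.values()):
            raise ConfigurationError("offset probabilities must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


# ---------------------------------------------------------------------------
# miRNA reference
# ---------------------------------------------------------------------------

@dataclass
class MiRNAReference:
    """Synthetic genome plus mature annotations."""

    genome: dict[str, str]
    annotations: list[MatureMiRNAAnnotation]

    def mature_fasta(self) -> str:
        return "".join(f">{a.name}\n{a.sequence}\n" for a in self.annotations)

    def genome_fasta(self) -> str:
        return "".join(f">{sid}\n{seq}\n" for sid, seq in self.genome.items())

    def annotation_gff3(self) -> str:
        lines = ["##gff-version 3"]
        for a in self.annotations:
            for loc in a.loci:
                # point feature anchored at the mature 5' start
                lines.append("\t".join([
                    loc.seqid, "mirflux_sim", "miRNA",
                    str(loc.five_prime_start), str(loc.five_prime_start),
                    ".", loc.strand, ".",
                    f"Name={a.name};sequence={a.sequence}",
                ]))
        return "\n".join(lines) + "\n"


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(NUCLEOTIDES, size=length))


def make_mirna_reference(config: SimulationConfig, flank: int = 30) -> MiRNAReference:
    """Build a synthetic genome embedding ``n_mirnas`` mature miRNAs.

    Guarantees (for n_mirnas >= 3): miRNA #0 is annotated at two loci with
    identical sequence *and* identical +/-flank context; miRNAs #1 and #2
    are paralogs -- distinct names, identical mature sequence and context --
    so reads from either apportion 1/2 to each.
    """
    rng = config.rng()
    n = config.n_mirnas
    lengths = rng.integers(19, 24, size=n)
    matures: list[str] = []
    for i in range(n):
        while True:
            seq = _random_seq(rng, int(lengths[i]))
            if seq not in matures:
                break
        matures.append(seq)
    if n >= 3:
        matures[2] = matures[1]  # paralog pair shares the full mature sequence

    # cassette = left flank + mature + right flank; paralogs and duplicate
    # loci reuse the cassette so +/-5 nt shifted reads stay ambiguous.
    cassettes: list[tuple[str, str]] = []  # (mirna name, cassette sequence)
    contexts: dict[int, tuple[str, str]] = {}
    for i, mat in enumerate(matures):
        if i == 2 and n >= 3:
            left, right = contexts[1]
        else:
            left, right = _random_seq(rng, flank), _random_seq(rng, flank)
        contexts[i] = (left, right)
        cassettes.append((f"mir-{i:03d}", left + mat + right))
    if n >= 2:
        # second locus for miRNA #0 (multi-locus collapsing); omitted for the
        # minimal single-miRNA reference, which has exactly one locus
        cassettes.append(("mir-000", contexts[0][0] + matures[0] + contexts[0][1]))

    spacer = lambda: _random_seq(rng, 20)  # noqa: E731
    parts: list[str] = []
    loci_by_name: dict[str, list[Locus]] = {}
    pos = 0
    for name, cassette in cassettes:
        gap = spacer()
        parts.append(gap)
        pos += len(gap)
        idx = int(name.split("-")[1])
        left = contexts[idx][0]
        start = pos + len(left) + 1  # 1-based 5' start of the mature
        parts.append(cassette)
        pos += len(cassette)
        loci_by_name.setdefault(name, []).append(Locus("chrS", "+", start))
    parts.append(spacer())
    genome = {"chrS": "".join(parts)}

    annotations = [
        MatureMiRNAAnnotation(f"mir-{i:03d}", matures[i],
                              tuple(loci_by_name[f"mir-{i:03d}"]))
        for i in range(n)
    ]
    return MiRNAReference(genome, annotations)


# ---------------------------------------------------------------------------
# small-RNA reads
# ---------------------------------------------------------------------------

@dataclass
class SimulatedReads:
    reads: list[tuple[str, str]]          # (read id, sequence)
    truth: pd.DataFrame                   # read_id, source, offset

    def fastq(self) -> str:
        return "".join(f"@{rid}\n{seq}\n+\n{'I' * len(seq)}\n"
                       for rid, seq in self.reads)


def simulate_small_rna_reads(config: SimulationConfig,
                             reference: MiRNAReference,
                             n_reads: int = 1000,
                             decoy_fraction: float = 0.0) -> SimulatedReads:
    """Emit reads as genome subsequences starting ``offset`` nt from an
    annotated mature 5' start, with the 3' adapter appended, plus a
    ``decoy_fraction`` of unmappable random reads."""
    if not reference.annotations:
        raise ConfigurationError("reference has no annotations")
    if len(config.adapter) < 7:
        raise ConfigurationError(
            "adapter must be >= 7 nt to satisfy the trimming overlap")
    if not (0.0 <= decoy_fraction <= 1.0):
        raise ConfigurationError("decoy_fraction must be in [0, 1]")

    rng = config.rng()
    adapter = as_dna(config.adapter)
    offsets = sorted(config.read_5p_offset_probs)
    probs = np.array([config.read_5p_offset_probs[o] for o in offsets])
    anns = reference.annotations
    genome = {sid: as_dna(seq) for sid, seq in reference.genome.items()}

    reads: list[tuple[str, str]] = []
    truth_rows: list[tuple[str, str, float]] = []
    for i in range(n_reads):
        rid = f"read{i:06d}"
        if rng.random() < decoy_fraction:
            seq = _decoy_sequence(rng, genome, 20)
            insert = seq
            truth_rows.append((rid, "decoy", float("nan")))
        else:
            ann = anns[int(rng.integers(len(anns)))]
            locus = ann.loci[int(rng.integers(len(ann.loci)))]
            off = int(offsets[int(rng.choice(len(offsets), p=probs))])
            contig = genome[locus.seqid]
            length = len(ann.sequence)
            if locus.strand == "+":
                start0 = locus.five_prime_start - 1 + off
                insert = contig[start0:start0 + length]
            else:
                end0 = locus.five_prime_start - 1 - off
                insert = revcomp(contig[end0 - length + 1:end0 + 1])
            if len(insert) != length:
                raise ConfigurationError(
                    f"offset {off} at locus {locus} runs off the contig; "
                    "increase the reference flank")
            truth_rows.append((rid, ann.name, float(off)))
        full = (insert + adapter)[:config.read_length]
        reads.append((rid, full))

    truth = pd.DataFrame(truth_rows, columns=["read_id", "source", "offset"])
    return SimulatedReads(reads, truth)


def _decoy_sequence(rng: np.random.Generator, genome: Mapping[str, str],
                    length: int) -> str:
    for _ in range(100):
        seq = _random_seq(rng, length)
        rc = revcomp(seq)
        if not any(seq in contig or rc in contig for contig in genome.values()):
            return seq
    raise ConfigurationError("could not draw an unmappable decoy sequence")


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

@dataclass
class SimulatedCounts:
    table: CountTable
    design: dict[str, str]
    truth: dict


def simulate_count_matrix(config: SimulationConfig,
                          kind: str = "mRNA",
                          feature_prefix: str = "gene") -> SimulatedCounts:
    """NB counts with planted group fold changes, ``k_unwanted`` latent
    factors and lognormal size factors.

    mean(f, s) = baseline_f * FC_f(group_s) * exp(loadings_f . scores_s)
                 * size_factor_s;   counts ~ NB(mean, config.nb_dispersion)

    ``effect_fold_changes`` maps feature id -> linear FC applied to every
    non-reference group (reference = ``groups[0]``).
    """
    if len(config.groups) < 2:
        raise ConfigurationError("need at least two groups")
    if config.baseline_mean <= 0:
        raise ConfigurationError("baseline_mean must be > 0")

    rng = config.rng()
    n_feat = config.n_genes
    features = [f"{feature_prefix}{i:05d}" for i in range(n_feat)]
    unknown = set(config.effect_fold_changes) - set(features)
    if unknown:
        raise ConfigurationError(f"effect_fold_changes for unknown features: {sorted(unknown)}")

    samples, sample_group = [], {}
    for g in config.groups:
        for r in range(config.n_samples_per_group):
            s = f"{g}_{r + 1}"
            samples.append(s)
            sample_group[s] = g
    n_samp = len(samples)

    baseline = rng.lognormal(mean=math.log(config.baseline_mean), sigma=0.7, size=n_feat)
    k = config.k_unwanted
    loadings = rng.normal(0.0, config.factor_loadings_scale, size=(n_feat, k))
    scores = rng.normal(0.0, 1.0, size=(n_samp, k))
    size_f = rng.lognormal(mean=0.0, sigma=0.15, size=n_samp)
    size_f /= np.exp(np.mean(np.log(size_f)))

    fc = np.ones(n_feat)
    for i, f in enumerate(features):
        fc[i] = config.effect_fold_changes.get(f, 1.0)
    if (fc <= 0).any():
        raise ConfigurationError("planted fold changes must be > 0")
    treated = np.array([sample_group[s] != config.groups[0] for s in samples])

    mean = baseline[:, None] * np.exp(loadings @ scores.T) * size_f[None, :]
    mean = mean * np.where(treated[None, :], fc[:, None], 1.0)

    alpha = config.nb_dispersion
    lam = rng.gamma(shape=1.0 / alpha, scale=alpha * mean)
    counts = rng.poisson(lam).astype(float)

    df = pd.DataFrame(counts, index=features, columns=samples)
    lib = df.sum(axis=0)
    lib[lib == 0] = 1.0  # degenerate all-zero sample; keep table valid
    table = CountTable(df, lib, kind=kind)
    truth = {
        "baseline": pd.Series(baseline, index=features),
        "fold_change": pd.Series(fc, index=features),
        "factor_scores": pd.DataFrame(scores, index=samples,
                                      columns=[f"W{j + 1}" for j in range(k)]),
        "loadings": pd.DataFrame(loadings, index=features,
                                 columns=[f"W{j + 1}" for j in range(k)]),
        "size_factors": pd.Series(size_f, index=samples),
    }
    return SimulatedCounts(table, sample_group, truth)


# ---------------------------------------------------------------------------
# planted MRE sites
# ---------------------------------------------------------------------------

def _site_payload(mirna_seq: str, site_type: str) -> str:
    """Target-strand sequence written into the UTR for a seed site."""
    m = as_dna(mirna_seq)
    if site_type == "8mer":
        return revcomp(m[1:8]) + "A"
    if site_type == "7mer-m8":
        return revcomp(m[1:8])
    if site_type == "7mer-A1":
        return revcomp(m[1:7]) + "A"
    raise ValueError(f"unknown site type {site_type!r}")


def _seed_cores(mirna_seq: str) -> tuple[str, str]:
    """(m8 core 7mer, A1 core 7mer) in target space."""
    m = as_dna(mirna_seq)
    return revcomp(m[1:8]), revcomp(m[1:7]) + "A"


@dataclass
class PlantedUTRs:
    utrs: dict[str, str]
    truth: list[tuple[str, str, str, int, int]]  # (mirna, utr, type, start, end)

    def fasta(self) -> str:
        return "".join(f">{uid}\n{seq}\n" for uid, seq in self.utrs.items())


def plant_mre_sites(utr_lengths: Mapping[str, int],
                    plan: Sequence[tuple[str, str, str, int]],
                    mirna_seqs: Mapping[str, str],
                    seed: int,
                    max_tries: int = 200) -> PlantedUTRs:
    """Generate UTR sequences containing exactly the planned seed sites.

    ``plan`` holds (mirna name, utr id, site type, 1-based start).  The
    background is rejection-sampled against every planned miRNA's seed
    cores so the only matches are the planted ones.
    """
    per_utr: dict[str, list[tuple[str, str, int]]] = {u: [] for u in utr_lengths}
    for mirna, utr, site_type, start in plan:
        if site_type not in SEED_TYPES:
            raise ValueError(f"unknown site type {site_type!r}")
        if utr not in utr_lengths:
            raise ValueError(f"unknown UTR {utr!r}")
        if mirna not in mirna_seqs:
            raise ValueError(f"unknown miRNA {mirna!r}")
        end = start + (8 if site_type == "8mer" else 7) - 1
        if start < 1 or end > utr_lengths[utr]:
            raise ValueError(
                f"site {mirna}/{site_type} at {start}-{end} exceeds UTR {utr!r} "
                f"(length {utr_lengths[utr]})")
        per_utr[utr].append((mirna, site_type, start))

    for utr, sites in per_utr.items():
        spans: dict[str, list[tuple[int, int]]] = {}
        for mirna, site_type, start in sites:
            end = start + (8 if site_type == "8mer" else 7) - 1
            for a, b in spans.get(mirna, []):
                if start <= b and a <= end:
                    raise ValueError(
                        f"overlapping planned sites for {mirna} in UTR {utr!r}")
            spans.setdefault(mirna, []).append((start, end))

    # screen the background against every supplied miRNA (callers pass the
    # miRNAs of interest), so an empty plan yields a site-free sequence
    cores = {m: _seed_cores(s) for m, s in mirna_seqs.items()}
    rng = np.random.default_rng(seed)
    utrs: dict[str, str] = {}
    truth: list[tuple[str, str, str, int, int]] = []
    for utr, length in utr_lengths.items():
        planned = per_utr[utr]
        expected: list[tuple[str, str, int, int]] = []
        for mirna, site_type, start in planned:
            end = start + (8 if site_type == "8mer" else 7) - 1
            expected.append((mirna, site_type, start, end))
        for _ in range(max_tries):
            seq = list(_random_seq(rng, length))
            for mirna, site_type, start in planned:
                payload = _site_payload(mirna_seqs[mirna], site_type)
                seq[start - 1:start - 1 + len(payload)] = payload
            candidate = "".join(seq)
            if _only_planned_sites(candidate, cores, expected):
                utrs[utr] = candidate
                truth.extend((m, utr, t, s, e) for m, t, s, e in expected)
                break
        else:
            raise ConfigurationError(
                f"could not generate UTR {utr!r} without accidental seed matches")
    return PlantedUTRs(utrs, truth)


def _only_planned_sites(seq: str, cores: Mapping[str, tuple[str, str]],
                        expected: Sequence[tuple[str, str, int, int]]) -> bool:
    """Check by direct substring scan (independent of the site scanner)
    that each planned miRNA matches the sequence only where planted."""
    want: dict[str, set[tuple[str, int]]] = {}
    for mirna, site_type, start, end in expected:
        want.setdefault(mirna, set()).add((site_type, start))
    for mirna, (m8_core, a1_core) in cores.items():
        planned = want.get(mirna, set())
        m8_positions = {s for t, s in planned if t in ("8mer", "7mer-m8")}
        a1_positions = {s for t, s in planned if t == "7mer-A1"}
        a1_positions |= {s + 1 for t, s in planned if t == "8mer"}  # 8mer embeds an A1 core
        i = seq.find(m8_core)
        while i != -1:
            if i + 1 not in m8_positions:
                return False
            i = seq.find(m8_core, i + 1)
        i = seq.find(a1_core)
        while i != -1:
            if i + 1 not in a1_positions:
                return False
            i = seq.find(a1_core, i + 1)
    return True


# ---------------------------------------------------------------------------
# printed-pair-table fixtures
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairRow:
    mrna: str
    mrna_fc: float
    mrna_fdr: float
    mirna: str
    mirna_fc: float
    mirna_fdr: float
    seed_type: str
    start: int
    end: int


@dataclass
class PrintedPairTable:
    rows: list[PairRow]
    region: str


_TABLE_COLUMNS = ["mrna", "mrna_fc", "mrna_fdr", "mirna",
                  "mirna_fc", "mirna_fdr", "seed_type", "start", "end"]


def load_printed_table(path, region: str) -> PrintedPairTable:
    """Parse a printed-pair-table TSV and enforce its invariants."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise TableParseError("empty file")
    header = lines[0].split("\t")
    if header != _TABLE_COLUMNS:
        raise TableParseError(f"bad header {header!r}", line=1)
    rows: list[PairRow] = []
    for lineno, raw in enumerate(lines[1:], start=2):
        parts = raw.split("\t")
        if len(parts) != len(_TABLE_COLUMNS):
            raise TableParseError(f"expected {len(_TABLE_COLUMNS)} columns, got {len(parts)}",
                                  line=lineno)
        try:
            row = PairRow(parts[0], float(parts[1]), float(parts[2]), parts[3],
                          float(parts[4]), float(parts[5]), parts[6],
                          int(parts[7]), int(parts[8]))
        except ValueError as exc:
            raise TableParseError(str(exc), line=lineno) from exc
        if row.seed_type not in SEED_TYPES:
            raise TableParseError(f"unknown seed type {row.seed_type!r}", line=lineno)
        span = row.end - row.start + 1
        expected_span = 8 if row.seed_type == "8mer" else 7
        if span != expected_span:
            raise TableParseError(
                f"{row.seed_type} must span {expected_span} nt, got {span}", line=lineno)
        if not (row.mrna_fdr < 0.01 and row.mirna_fdr < 0.01):
            raise TableParseError("FDR must be < 0.01", line=lineno)
        if row.mrna_fc <= 0 or row.mirna_fc <= 0:
            raise TableParseError("fold changes must be > 0", line=lineno)
        rows.append(row)
    if not rows:
        raise TableParseError("no data rows")
    return PrintedPairTable(rows, region)


def packaged_table(region: str) -> PrintedPairTable:
    """Load the in-repo fixture for region 'IPN' or 'MHb'."""
    key = region.lower()
    if key not in ("ipn", "mhb"):
        raise ValueError(f"region must be 'IPN' or 'MHb', got {region!r}")
    ref = resources.files("mirflux.data") / f"table_{key}.tsv"
    with resources.as_file(ref) as path:
        return load_printed_table(path, region.upper())
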