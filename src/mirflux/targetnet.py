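"""Seed-site scanning and reciprocal miRNA-mRNA integration.

Site vocabulary (positions 1-based inclusive on the UTR 5'->3' strand):

- 8mer     -- perfect Watson-Crick match to the reverse complement of
              miRNA nt 2-8, followed by an A opposite miRNA position 1
              (8 nt span)
- 7mer-m8  -- match to nt 2-8 without the A1 (7 nt)
- 7mer-A1  -- match to nt 2-7 plus the A1 (7 nt)

At one locus only the highest-precedence classification is reported
(8mer > 7mer-m8 > 7mer-A1); G:U wobble pairs are not allowed, and 6mer
sites are never emitted.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .diffexpr import DERecord, Thresholds
from .seq import as_dna, revcomp
from .synthetic import PairRow, PrintedPairTable

SEED_TYPES = ("8mer", "7mer-m8", "7mer-A1")


@dataclass(frozen=True)
class MiRNASeq:
    name: str
    sequence: str                  # mature, 5'->3', RNA or DNA alphabet
    conserved: bool = True

    def __post_init__(self):
        if len(self.sequence) < 8:
            raise ValueError(f"miRNA {self.name!r} must be >= 8 nt")


@dataclass(frozen=True)
class SeedSite:
    mirna: str
    utr: str
    site_type: str
    start: int                     # 1-based inclusive
    end: int
    conserved: bool = True

    def __post_init__(self):
        if self.site_type not in SEED_TYPES:
            raise ValueError(f"unknown site type {self.site_type!r}")
        span = self.end - self.start + 1
        expected = 8 if self.site_type == "8mer" else 7
        if span != expected:
            raise ValueError(
                f"{self.site_type} must span {expected} nt, got {span}")
        if self.start < 1:
            raise ValueError("start must be >= 1")


@dataclass(frozen=True)
class ReciprocalPair:
    mrna: DERecord
    mirna: DERecord
    site: SeedSite


@dataclass(frozen=True)
class PairSummary:
    n_mrnas: int
    n_mirnas: int
    n_rows: int


# ---------------------------------------------------------------------------
# scanning
# ---------------------------------------------------------------------------

def seed_match_scan(mirna: MiRNASeq, utr_id: str, utr_seq: str) -> list[SeedSite]:
    """All canonical seed sites of ``mirna`` in one UTR.

    Scans the m8 core (reverse complement of nt 2-8) at every position:
    with a downstream A the site is an 8mer, otherwise a 7mer-m8.  A1-core
    matches (nt 2-7 complement plus A) not already covered by an 8mer are
    reported as 7mer-A1.
    """
    utr = as_dna(utr_seq)
    m = as_dna(mirna.sequence)
    if len(utr) < 7:
        return []
    m8_core = revcomp(m[1:8])       # 7 nt, pairs miRNA nt 2-8
    a1_core = revcomp(m[1:7]) + "A"  # 7 nt, pairs nt 2-7 plus target A1
    sites: list[SeedSite] = []
    n = len(utr)

    m8_starts: set[int] = set()
    i = utr.find(m8_core)
    while i != -1:
        m8_starts.add(i)
        i = utr.find(m8_core, i + 1)
    for i in sorted(m8_starts):
        if i + 7 < n and utr[i + 7] == "A":
            sites.append(SeedSite(mirna.name, utr_id, "8mer", i + 1, i + 8,
                                  mirna.conserved))
        else:
            sites.append(SeedSite(mirna.name, utr_id, "7mer-m8", i + 1, i + 7,
                                  mirna.conserved))

    i = utr.find(a1_core)
    while i != -1:
        # an 8mer starting one base upstream embeds this A1 core; the 8mer
        # takes precedence at that locus
        if (i - 1) not in m8_starts:
            sites.append(SeedSite(mirna.name, utr_id, "7mer-A1", i + 1, i + 7,
                                  mirna.conserved))
        i = utr.find(a1_core, i + 1)
    sites.sort(key=lambda s: (s.start, s.site_type))
    return sites


def scan_utrs(mirnas: Iterable[MiRNASeq],
              utrs: Mapping[str, str]) -> list[SeedSite]:
    sites: list[SeedSite] = []
    for mirna in mirnas:
        for utr_id, seq in utrs.items():
            sites.extend(seed_match_scan(mirna, utr_id, seq))
    return sites


# ---------------------------------------------------------------------------
# integration
# ---------------------------------------------------------------------------

def _passes_mrna(r: DERecord, t: Thresholds) -> bool:
    return r.fdr < t.fdr_max and (r.fc > t.mrna_fc_min or r.fc < 1.0 / t.mrna_fc_min)


def _passes_mirna(r: DERecord, t: Thresholds) -> bool:
    if r.fdr >= t.fdr_max:
        return False
    if t.mirna_fc_min is not None:
        return r.fc > t.mirna_fc_min or r.fc < 1.0 / t.mirna_fc_min
    return True


def integrate_reciprocal(de_mrna: Iterable[DERecord],
                         de_mirna: Iterable[DERecord],
                         sites: Iterable[SeedSite],
                         conserved_only: bool = False,
                         mirna_conserved: Mapping[str, bool] | None = None,
                         thresholds: Thresholds = Thresholds()) -> list[ReciprocalPair]:
    """One row per (mRNA, miRNA, site) passing every integration filter:
    mRNA called DE (FDR and FC rules), miRNA called DE (FDR rule),
    opposite directions, and -- when ``conserved_only`` -- both the site
    and the miRNA flagged conserved.

    Sites must reference mRNAs/miRNAs present in the DE inputs.
    """
    mrna_by_id = {r.feature: r for r in de_mrna}
    mirna_by_id = {r.feature: r for r in de_mirna}
    pairs: list[ReciprocalPair] = []
    for site in sites:
        if site.utr not in mrna_by_id:
            raise KeyError(f"site references unknown mRNA {site.utr!r}")
        if site.mirna not in mirna_by_id:
            raise KeyError(f"site references unknown miRNA {site.mirna!r}")
        rm = mrna_by_id[site.utr]
        ri = mirna_by_id[site.mirna]
        if not _passes_mrna(rm, thresholds) or not _passes_mirna(ri, thresholds):
            continue
        if rm.direction == ri.direction:
            continue
        if conserved_only:
            if not site.conserved:
                continue
            if mirna_conserved is not None and not mirna_conserved.get(site.mirna, False):
                continue
        pairs.append(ReciprocalPair(rm, ri, site))
    # table layout: up-regulated mRNAs by FC descending, then down-regulated
    # ascending; within an mRNA by miRNA FC then position
    pairs.sort(key=lambda p: (p.mrna.direction == "down",
                              -p.mrna.fc if p.mrna.direction == "up" else p.mrna.fc,
                              p.mirna.fc, p.site.start))
    return pairs


def summarize_pairs(pairs: Sequence[ReciprocalPair]) -> PairSummary:
    """Distinct mRNA / miRNA / row counts over a pair table."""
    return PairSummary(
        n_mrnas=len({p.mrna.feature for p in pairs}),
        n_mirnas=len({p.mirna.feature for p in pairs}),
        n_rows=len(pairs),
    )


# ---------------------------------------------------------------------------
# fixture adapters
# ---------------------------------------------------------------------------

def printed_table_components(table: PrintedPairTable,
                             comparison: str = "NAWD-vs-TA",
                             ) -> tuple[list[DERecord], list[DERecord], list[SeedSite]]:
    """Rebuild (mRNA DE records, miRNA DE records, sites) from a printed
    pair table, deduplicating features by id."""
    mrna: dict[str, DERecord] = {}
    mirna: dict[str, DERecord] = {}
    sites: list[SeedSite] = []
    for row in table.rows:
        mrna.setdefault(row.mrna, _record(row.mrna, row.mrna_fc, row.mrna_fdr, comparison))
        mirna.setdefault(row.mirna, _record(row.mirna, row.mirna_fc, row.mirna_fdr, comparison))
        sites.append(SeedSite(row.mirna, row.mrna, row.seed_type,
                              row.start, row.end, conserved=True))
    return list(mrna.values()), list(mirna.values()), sites


def _record(feature: str, fc: float, fdr: float, comparison: str) -> DERecord:
    return DERecord(feature, fc, p=fdr, fdr=fdr,
                    direction="up" if fc > 1 else "down", comparison=comparison)


def pairs_to_rows(pairs: Sequence[ReciprocalPair]) -> list[PairRow]:
    return [PairRow(p.mrna.feature, p.mrna.fc, p.mrna.fdr,
                    p.mirna.feature, p.mirna.fc, p.mirna.fdr,
                    p.site.site_type, p.site.start, p.site.end)
            for p in pairs]
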