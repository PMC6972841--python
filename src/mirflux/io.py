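"""Readers/writers for the plain-text formats exchanged between stages.

FASTA/FASTQ go through Biopython; GFF3 point annotations, TSV count
matrices, design files, DE tables and site tables are simple
pandas/line-based formats.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .diffexpr import DERecord
from .errors import TableParseError
from .quant import CountTable, Locus, MatureMiRNAAnnotation, Read
from .targetnet import ReciprocalPair, SeedSite


# --- sequences -------------------------------------------------------------

def read_fastq(path) -> list[Read]:
    return [Read(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fastq")]


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_text(path, payload: str) -> None:
    Path(path).write_text(payload)


def read_sam_hits(path) -> dict[str, list]:
    """Pre-aligned mode: SAM alignments -> per-read AlignmentHit lists.

    The 5' end is the leftmost reference base for forward alignments and
    the rightmost for reverse ones.  Unmapped reads get empty hit lists.
    """
    import pysam

    from .quant import AlignmentHit

    hits: dict[str, list] = {}
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam.fetch(until_eof=True):
            hits.setdefault(aln.query_name, [])
            if aln.is_unmapped:
                continue
            if aln.is_reverse:
                hit = AlignmentHit(aln.reference_name, "-", aln.reference_end)
            else:
                hit = AlignmentHit(aln.reference_name, "+", aln.reference_start + 1)
            hits[aln.query_name].append(hit)
    return hits


# --- GFF3 mature-miRNA annotations ----------------------------------------

def write_annotation_gff3(annotations: Sequence[MatureMiRNAAnnotation], path) -> None:
    lines = ["##gff-version 3"]
    for a in annotations:
        for loc in a.loci:
            lines.append("\t".join([
                loc.seqid, "mirflux", "miRNA",
                str(loc.five_prime_start), str(loc.five_prime_start), ".",
                loc.strand, ".", f"Name={a.name};sequence={a.sequence}"]))
    Path(path).write_text("\n".join(lines) + "\n")


def read_annotation_gff3(path) -> list[MatureMiRNAAnnotation]:
    loci: dict[str, list[Locus]] = {}
    seqs: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise TableParseError("GFF3 rows need 9 columns", line=lineno)
        seqid, _, _, start, _, _, strand, _, attrs = parts
        fields = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
        if "Name" not in fields or "sequence" not in fields:
            raise TableParseError("need Name= and sequence= attributes", line=lineno)
        name = fields["Name"]
        seqs[name] = fields["sequence"]
        loci.setdefault(name, []).append(Locus(seqid, strand, int(start)))
    return [MatureMiRNAAnnotation(n, seqs[n], tuple(loci[n])) for n in loci]


# --- tables ----------------------------------------------------------------

def write_count_table(table: CountTable, path) -> None:
    df = table.counts.copy()
    df.index.name = "feature"
    df.to_csv(path, sep="\t", float_format="%.6f")
    sizes = table.library_sizes.rename("mappable_reads")
    sizes.index.name = "sample"
    sizes.to_csv(str(path) + ".libsizes", sep="\t", float_format="%.6f")


def read_count_table(path, kind: str = "miRNA") -> CountTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    lib_path = Path(str(path) + ".libsizes")
    if lib_path.exists():
        lib = pd.read_csv(lib_path, sep="\t", index_col=0).iloc[:, 0]
    else:
        lib = df.sum(axis=0)
    return CountTable(df, lib, kind=kind)


def read_design(path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "sample" not in df.columns or "group" not in df.columns:
        raise TableParseError("design file needs 'sample' and 'group' columns", line=1)
    return dict(zip(df["sample"], df["group"]))


def write_de_records(records: Iterable[DERecord], path) -> None:
    rows = [{"feature": r.feature, "fc": r.fc, "p": r.p, "fdr": r.fdr,
             "direction": r.direction, "comparison": r.comparison,
             "converged": r.converged} for r in records]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_de_records(path) -> list[DERecord]:
    df = pd.read_csv(path, sep="\t")
    return [DERecord(str(r.feature), float(r.fc), float(r.p), float(r.fdr),
                     str(r.direction), str(r.comparison),
                     bool(getattr(r, "converged", True)))
            for r in df.itertuples(index=False)]


def write_sites(sites: Iterable[SeedSite], path) -> None:
    rows = [{"mirna": s.mirna, "utr": s.utr, "type": s.site_type,
             "start": s.start, "end": s.end, "conserved": s.conserved}
            for s in sites]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_sites(path) -> list[SeedSite]:
    df = pd.read_csv(path, sep="\t")
    return [SeedSite(str(r.mirna), str(r.utr), str(r.type), int(r.start),
                     int(r.end), bool(r.conserved))
            for r in df.itertuples(index=False)]


def write_pairs(pairs: Sequence[ReciprocalPair], path) -> None:
    rows = [{"mrna": p.mrna.feature, "mrna_fc": p.mrna.fc, "mrna_fdr": p.mrna.fdr,
             "mirna": p.mirna.feature, "mirna_fc": p.mirna.fc,
             "mirna_fdr": p.mirna.fdr, "seed_type": p.site.site_type,
             "start": p.site.start, "end": p.site.end} for p in pairs]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
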