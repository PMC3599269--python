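"""Readers/writers for the formats the pipeline touches, plus CDS translation.

FASTA goes through Biopython.  GFF3 covers the gene/mRNA/CDS/tRNA subset this
pipeline reads and writes (1-based inclusive on disk, 0-based half-open in
memory).  Hit tables, variant tables and growth curves are plain TSV.
"""
from __future__ import annotations

import logging
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import (GeneModel, GenomeSequence, HitRecord, TRNAModel,
                    VariantCall, revcomp)

log = logging.getLogger(__name__)


# ---------------------------------------------------------------- FASTA

def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read FASTA into GenomeSequence records (uppercased, ACGTN only)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: empty record {rec.id!r}")
        if "U" in seq:
            raise ValueError(f"{path}:{rec.id}: RNA alphabet (U) not accepted")
        records.append(GenomeSequence(rec.id, seq))  # validates alphabet
    if not records:
        raise ValueError(f"{path}: no FASTA records")
    ids = [r.chrom_id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError(f"{path}: duplicate sequence ids")
    return records


def write_fasta(records: list[GenomeSequence], path: str | Path, width: int = 70) -> None:
    SeqIO.write(
        [SeqRecord(Seq(r.seq), id=r.chrom_id, description="") for r in records],
        str(path), "fasta")
    del width  # Biopython wraps at its default; kept for signature stability


# ---------------------------------------------------------------- GFF3

def read_gff3(path: str | Path) -> tuple[list[GeneModel], list[TRNAModel]]:
    """Parse gene/mRNA/CDS (+tRNA) features into models.

    Multi-CDS mRNAs become multi-exon GeneModels with ``has_intron=True``.
    """
    cds_by_parent: dict[str, list[tuple[str, str, int, int]]] = {}
    parents: dict[str, dict] = {}
    trnas: list[TRNAModel] = []
    gene_order: list[str] = []

    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 columns")
            chrom, _src, ftype, start, end, _score, strand, _frame, attrs = cols
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                raise ValueError(f"{path}:{lineno}: end < start")
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            s0, e0 = start_i - 1, end_i  # GFF 1-based inclusive -> half-open
            if ftype in ("gene", "mRNA"):
                fid = attr.get("ID")
                if fid and fid not in parents:
                    parents[fid] = {"chrom": chrom, "strand": strand,
                                    "flags": set(attr.get("flags", "").split(",")) - {""}}
                    gene_order.append(fid)
            elif ftype == "CDS":
                parent = attr.get("Parent")
                if not parent:
                    raise ValueError(f"{path}:{lineno}: CDS without Parent")
                cds_by_parent.setdefault(parent, []).append((chrom, strand, s0, e0))
            elif ftype == "tRNA":
                trnas.append(TRNAModel(attr.get("ID", f"trna{lineno}"), chrom,
                                       strand, s0, e0,
                                       isotype=attr.get("isotype", "X")))

    genes: list[GeneModel] = []
    for fid in gene_order:
        cds = cds_by_parent.get(fid)
        if not cds:
            continue
        chroms = {c for c, _, _, _ in cds}
        if len(chroms) > 1:
            raise ValueError(f"{path}: gene {fid} spans multiple chromosomes")
        info = parents[fid]
        exons = sorted((s, e) for _, _, s, e in cds)
        genes.append(GeneModel(fid, cds[0][0], info["strand"], exons,
                               has_intron=len(exons) > 1, flags=set(info["flags"])))
    orphans = set(cds_by_parent) - set(parents)
    if orphans:
        raise ValueError(f"{path}: CDS with unknown Parent: {sorted(orphans)[:3]}")
    return genes, trnas


def write_gff3(genes: list[GeneModel], path: str | Path,
               trnas: list[TRNAModel] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            attrs = f"ID={g.gene_id}"
            if g.flags:
                attrs += ";flags=" + ",".join(sorted(g.flags))
            fh.write(f"{g.chrom_id}\tarborator\tgene\t{g.start + 1}\t{g.end}\t.\t"
                     f"{g.strand}\t.\t{attrs}\n")
            for s, e in g.exons:
                fh.write(f"{g.chrom_id}\tarborator\tCDS\t{s + 1}\t{e}\t.\t"
                         f"{g.strand}\t0\tParent={g.gene_id}\n")
        for t in trnas or []:
            fh.write(f"{t.chrom_id}\tarborator\ttRNA\t{t.start + 1}\t{t.end}\t.\t"
                     f"{t.strand}\t.\tID={t.trna_id};isotype={t.isotype}\n")


# ---------------------------------------------------------------- hit tables

HIT_COLUMNS = ["query_id", "chrom", "start", "end", "strand", "score"]


def rank_hits(hits: list[HitRecord]) -> list[HitRecord]:
    """Assign 1..k ranks per query: descending score, ties by (chrom, start)."""
    byq: dict[str, list[HitRecord]] = {}
    for h in hits:
        byq.setdefault(h.query_id, []).append(h)
    out: list[HitRecord] = []
    for q in sorted(byq):
        ordered = sorted(byq[q], key=lambda h: (-h.score, h.chrom_id, h.start))
        for i, h in enumerate(ordered, 1):
            h.rank = i
            out.append(h)
    return out


def read_hits_tsv(path: str | Path) -> list[HitRecord]:
    df = pd.read_csv(path, sep="\t")
    missing = set(HIT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    if df.duplicated(subset=HIT_COLUMNS).any():
        raise ValueError(f"{path}: duplicate hit rows")
    hits = [HitRecord(r.query_id, r.chrom, int(r.start), int(r.end),
                      r.strand, float(r.score))
            for r in df.itertuples(index=False)]
    return rank_hits(hits)


def write_hits_tsv(hits: list[HitRecord], path: str | Path) -> None:
    pd.DataFrame(
        [(h.query_id, h.chrom_id, h.start, h.end, h.strand, h.score) for h in hits],
        columns=HIT_COLUMNS).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- variants

def read_variants_tsv(path: str | Path) -> list[VariantCall]:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return [VariantCall(r.chrom, int(r.pos), str(r.ref), str(r.alt), float(r.support))
            for r in df.itertuples(index=False)]


def write_variants_tsv(calls: list[VariantCall], path: str | Path) -> None:
    pd.DataFrame([(c.chrom_id, c.pos, c.ref, c.alt, c.support) for c in calls],
                 columns=["chrom", "pos", "ref", "alt", "support"]
                 ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- growth curves

def read_growth_tsv(path: str | Path) -> pd.DataFrame:
    """Long-format curves: strain, condition, replicate, time_min, od."""
    df = pd.read_csv(path, sep="\t")
    need = {"strain", "condition", "replicate", "time_min", "od"}
    if not need <= set(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(need - set(df.columns))}")
    return df


def write_growth_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------- CDS handling

def extract_cds(gene: GeneModel, genome: dict[str, str]) -> str:
    """Spliced, strand-oriented coding sequence (starts with the start codon)."""
    chrom = genome[gene.chrom_id]
    spliced = "".join(chrom[s:e] for s, e in gene.exons)
    return revcomp(spliced) if gene.strand == "-" else spliced


def translate_cds(gene: GeneModel, genome: dict[str, str]) -> str:
    """Translate a gene; trailing stop dropped, internal stops kept as '*'.

    A CDS whose length is not a multiple of 3 is translated over its longest
    in-frame prefix (a warning is logged) — such genes are frameshift
    candidates, not translation errors.
    """
    cds = extract_cds(gene, genome)
    if len(cds) % 3:
        log.warning("gene %s: CDS length %d not divisible by 3; translating "
                    "longest in-frame prefix", gene.gene_id, len(cds))
        cds = cds[: len(cds) - len(cds) % 3]
    prot = str(Seq(cds).translate())
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot
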