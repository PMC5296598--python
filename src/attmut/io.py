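"""Readers and writers for the standard formats the pipeline touches.

All coordinate conversions live here: VCF and GFF3 are 1-based inclusive on
disk and become 0-based half-open (GFF) or keep their printed 1-based
position (VCF, mirrored in :class:`~attmut.variants.VariantRecord`);
bedGraph is 0-based half-open. Multi-allelic VCF records are split into
biallelic records on read.
"""

from __future__ import annotations

import csv
from typing import Iterable, Mapping, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .errors import InputError
from .variants import DeletionCall, GeneModel, VariantRecord

# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


def write_fasta(path, sequences: Mapping[str, str]) -> None:
    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def write_gff3(
    path, models: Sequence[GeneModel], contig_lengths: Mapping[str, int]
) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for contig, length in contig_lengths.items():
            fh.write(f"##sequence-region {contig} 1 {length}\n")
        for i, m in enumerate(models):
            name = m.name or f"cds_{i + 1}"
            fh.write(
                f"{m.contig}\tattmut\tCDS\t{m.start + 1}\t{m.end}\t.\t"
                f"{m.strand}\t0\tID={name}\n"
            )


def read_gff3(path) -> list[GeneModel]:
    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    models = []
    for feat in db.features_of_type("CDS", order_by=("seqid", "start")):
        models.append(
            GeneModel(
                contig=feat.seqid,
                start=feat.start - 1,
                end=feat.end,
                strand=feat.strand,
                name=feat.id,
            )
        )
    return models


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=attmut
##INFO=<ID=LINEAGE,Number=1,Type=String,Description="Lineage identifier">
##INFO=<ID=ROUND,Number=1,Type=Integer,Description="Selection round">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AF,Number=A,Type=Float,Description="Fraction of supporting reads">
"""


def write_vcf(
    path,
    records: Iterable[VariantRecord],
    contig_lengths: Mapping[str, int],
    sample: str = "isolate",
) -> None:
    recs = sorted(records, key=lambda r: (r.contig, r.position, r.alt))
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for contig, length in contig_lengths.items():
            fh.write(f"##contig=<ID={contig},length={length}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample + "\n"
        )
        for r in recs:
            info = f"LINEAGE={r.lineage_id};ROUND={r.round}"
            fh.write(
                f"{r.contig}\t{r.position}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t"
                f"{info}\tGT:AF\t1:{r.read_fraction:.4f}\n"
            )


def read_vcf(path, lineage_id: str | None = None, round_: int | None = None) -> list[VariantRecord]:
    """Read a VCF into VariantRecords, splitting multi-allelic sites.

    The supporting-read fraction comes from the sample-level AF field, or
    is derived from AD (alt depth / total depth) when AF is absent.
    Lineage/round default to the INFO LINEAGE/ROUND fields.
    """
    out: list[VariantRecord] = []
    vcf = VCF(str(path))
    try:
        for v in vcf:
            lid = v.INFO.get("LINEAGE") or lineage_id
            rnd = v.INFO.get("ROUND")
            rnd = int(rnd) if rnd is not None else round_
            if lid is None or rnd is None:
                raise InputError(
                    f"{path}: record {v.CHROM}:{v.POS} lacks LINEAGE/ROUND and "
                    "no defaults were supplied"
                )
            fractions = _allele_fractions(v, path)
            for i, alt in enumerate(v.ALT):
                out.append(
                    VariantRecord(
                        lineage_id=str(lid),
                        round=rnd,
                        contig=v.CHROM,
                        position=v.POS,
                        ref=v.REF,
                        alt=alt,
                        read_fraction=float(fractions[i]),
                    )
                )
    finally:
        vcf.close()
    return out


def _allele_fractions(v, path) -> list[float]:
    def _fmt(tag):
        try:
            return v.format(tag)
        except KeyError:
            return None

    af = _fmt("AF")
    if af is not None:
        return [float(x) for x in np.atleast_1d(af[0])]
    ad = _fmt("AD")
    if ad is not None:
        depths = np.asarray(ad[0], float)
        total = depths.sum()
        if total <= 0:
            raise InputError(f"{path}: zero total depth at {v.CHROM}:{v.POS}")
        return [float(d / total) for d in depths[1:]]
    raise InputError(
        f"{path}: no AF or AD sample field at {v.CHROM}:{v.POS}; "
        "an allele-fraction source is required"
    )


# ---------------------------------------------------------------------------
# bedGraph (0-based half-open)
# ---------------------------------------------------------------------------


def write_bedgraph(path, tracks: Mapping[str, np.ndarray]) -> None:
    with open(path, "w") as fh:
        fh.write('track type=bedGraph name="coverage"\n')
        for contig, depth in tracks.items():
            depth = np.asarray(depth)
            if depth.size == 0:
                continue
            change = np.flatnonzero(np.diff(depth)) + 1
            starts = np.concatenate(([0], change))
            ends = np.concatenate((change, [depth.size]))
            for s, e in zip(starts, ends):
                fh.write(f"{contig}\t{s}\t{e}\t{int(depth[s])}\n")


def read_bedgraph(path) -> dict[str, np.ndarray]:
    spans: dict[str, list[tuple[int, int, float]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("track", "#", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) != 4:
                raise InputError(f"{path}:{line_no}: malformed bedGraph line")
            contig, s, e, val = parts
            spans.setdefault(contig, []).append((int(s), int(e), float(val)))
    tracks = {}
    for contig, rows in spans.items():
        length = max(e for _, e, _ in rows)
        depth = np.zeros(length)
        for s, e, val in rows:
            depth[s:e] = val
        tracks[contig] = depth
    return tracks


# ---------------------------------------------------------------------------
# BED (deletions) and TSV (classified variants)
# ---------------------------------------------------------------------------


def write_bed(path, deletions: Sequence[DeletionCall]) -> None:
    with open(path, "w") as fh:
        for d in deletions:
            fh.write(f"{d.contig}\t{d.start}\t{d.end}\tdeletion\t{d.length}\n")


VARIANT_TSV_COLUMNS = [
    "lineage_id", "round", "contig", "position", "ref", "alt",
    "read_fraction", "substitution_class", "region", "effect",
]


def write_variants_tsv(path, records: Iterable[VariantRecord]) -> None:
    rows = [{c: getattr(r, c) for c in VARIANT_TSV_COLUMNS} for r in records]
    pd.DataFrame(rows, columns=VARIANT_TSV_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variants_tsv(path) -> list[VariantRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"lineage_id": str})
    out = []
    for row in df.itertuples(index=False):
        rec = VariantRecord(
            lineage_id=row.lineage_id,
            round=int(row.round),
            contig=row.contig,
            position=int(row.position),
            ref=row.ref,
            alt=row.alt,
            read_fraction=float(row.read_fraction),
        )
        rec.substitution_class = _na(row.substitution_class)
        rec.region = _na(row.region)
        rec.effect = _na(row.effect)
        out.append(rec)
    return out


def _na(x):
    return None if (isinstance(x, float) and np.isnan(x)) else x


# ---------------------------------------------------------------------------
# qPCR plates
# ---------------------------------------------------------------------------


def read_qpcr_csv(path) -> pd.DataFrame:
    """Read a plate CSV (sample,target,phase,replicate,dilution,cq).

    ``Undetermined`` Cq values become NaN (a below-detection sentinel, not
    a number); any other unparseable field is an input error naming the
    row.
    """
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        required = {"sample", "target", "phase", "replicate", "dilution", "cq"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise InputError(f"{path}: plate CSV must have columns {sorted(required)}")
        rows = []
        for line_no, row in enumerate(reader, 2):
            try:
                cq = row["cq"].strip()
                cq_val = np.nan if cq in ("", "Undetermined", "NA", "nan") else float(cq)
                dil = row["dilution"].strip()
                dil_val = np.nan if dil == "" else float(dil)
                rows.append(
                    {
                        "sample": row["sample"],
                        "target": row["target"],
                        "phase": row["phase"],
                        "replicate": int(row["replicate"]),
                        "dilution": dil_val,
                        "cq": cq_val,
                    }
                )
            except (KeyError, ValueError) as exc:
                raise InputError(f"{path}: row {line_no}: {exc}") from exc
    return pd.DataFrame(rows)


def write_qpcr_csv(path, plate: pd.DataFrame) -> None:
    plate.to_csv(path, index=False)
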