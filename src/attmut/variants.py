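"""Post-calling variant filters, SNP classification and per-round tabulation.

Implements the filtering rules of a mutation-accumulation experiment on a
draft (multi-contig) bacterial assembly:

* keep only *fixed* SNPs, supported by strictly more than 80% of reads;
* drop calls near contig ends or inside zero-coverage deletions, the two
  mapping-artifact classes the experiment controls for;
* call deletions as maximal zero-coverage runs strictly longer than 100 bp;
* verify lineage continuity: every selection round must retain all
  mutations fixed in the previous round;
* classify each SNP as transition/transversion, coding/noncoding and
  synonymous/nonsynonymous under the bacterial genetic code.

Internal coordinates are 0-based half-open; VCF/GFF positions (1-based) are
converted at the I/O boundary (see :mod:`attmut.io`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio.Seq import Seq

from .errors import InputError, ParameterError

_PURINES = frozenset("AG")
_PYRIMIDINES = frozenset("CT")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

TRANSITION = "transition"
TRANSVERSION = "transversion"


@dataclass
class VariantRecord:
    """One SNP/indel call from a lineage × selection-round isolate."""

    lineage_id: str
    round: int
    contig: str
    position: int  # 1-based, as printed in VCF
    ref: str
    alt: str
    read_fraction: float
    fixed: bool | None = None
    contig_end: bool = False
    in_deletion: bool = False
    substitution_class: str | None = None  # transition | transversion
    region: str | None = None  # coding | noncoding
    effect: str | None = None  # synonymous | nonsynonymous | n.a.

    def __post_init__(self) -> None:
        if not 0.0 <= self.read_fraction <= 1.0:
            raise ParameterError(
                f"read_fraction must be in [0, 1], got {self.read_fraction}"
            )

    @property
    def key(self) -> tuple[str, int, str, str]:
        """Identity of the mutation, independent of lineage/round."""
        return (self.contig, self.position, self.ref, self.alt)

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class GeneModel:
    """A single-exon CDS on the reference. 0-based half-open coordinates."""

    contig: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""


@dataclass(frozen=True)
class DeletionCall:
    """A zero-coverage deletion interval, 0-based half-open."""

    contig: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start


def filter_fixed(
    records: Iterable[VariantRecord], threshold: float = 0.80
) -> list[VariantRecord]:
    """Keep records supported by strictly more than ``threshold`` of reads.

    The boundary is strict: a call at exactly the threshold is removed.
    Order is preserved; the ``fixed`` flag is set on every input record.
    """
    if not 0.0 < threshold <= 1.0:
        raise ParameterError("threshold must be in (0, 1]")
    kept = []
    for rec in records:
        rec.fixed = rec.read_fraction > threshold
        if rec.fixed:
            kept.append(rec)
    return kept


def detect_deletions(
    coverage: np.ndarray | Mapping[str, np.ndarray],
    min_len: int = 100,
    contig: str = "contig_1",
) -> list[DeletionCall]:
    """Call maximal runs of exactly-zero coverage strictly longer than min_len.

    ``coverage`` is a per-base depth array (or a mapping contig → array).
    Calls are returned in coordinate order; an empty track yields no calls.
    """
    if min_len < 1:
        raise ParameterError("min_len must be >= 1")
    if isinstance(coverage, Mapping):
        calls: list[DeletionCall] = []
        for name in coverage:
            calls.extend(detect_deletions(coverage[name], min_len, contig=name))
        return calls

    depth = np.asarray(coverage)
    if depth.size == 0:
        return []
    zero = np.concatenate(([False], depth == 0, [False]))
    edges = np.flatnonzero(np.diff(zero.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return [
        DeletionCall(contig, int(s), int(e))
        for s, e in zip(starts, ends)
        if e - s > min_len
    ]


def exclude_unreliable(
    records: Iterable[VariantRecord],
    contigs: Mapping[str, int],
    end_margin: int = 50,
    deletions: Sequence[DeletionCall] = (),
) -> tuple[list[VariantRecord], list[VariantRecord]]:
    """Drop calls near contig ends or inside deletion intervals.

    Returns ``(kept, removed)``; removed records carry ``contig_end`` /
    ``in_deletion`` flags for auditing. A record on a contig absent from
    ``contigs`` is an input error.
    """
    if end_margin < 0:
        raise ParameterError("end_margin must be >= 0")
    by_contig: dict[str, list[DeletionCall]] = {}
    for d in deletions:
        by_contig.setdefault(d.contig, []).append(d)

    kept, removed = [], []
    for rec in records:
        if rec.contig not in contigs:
            raise InputError(f"record on unknown contig {rec.contig!r}")
        length = contigs[rec.contig]
        p0 = rec.position - 1  # to 0-based
        rec.contig_end = p0 < end_margin or p0 >= length - end_margin
        rec.in_deletion = any(
            d.start <= p0 < d.end for d in by_contig.get(rec.contig, ())
        )
        if rec.contig_end or rec.in_deletion:
            removed.append(rec)
        else:
            kept.append(rec)
    return kept, removed


def check_lineage_consistency(
    round_sets: Sequence[set],
) -> tuple[bool, dict[int, list]]:
    """Verify that each round retains every mutation of the previous round.

    ``round_sets`` holds per-round mutation-identity sets in round order.
    Returns (pass, missing) where ``missing`` maps a round index (0-based
    position in the input) to the mutations it lost.
    """
    missing: dict[int, list] = {}
    for i in range(1, len(round_sets)):
        lost = round_sets[i - 1] - round_sets[i]
        if lost:
            missing[i] = sorted(lost)
    return (not missing, missing)


def _codon_effect(
    genome_seq: str, model: GeneModel, p0: int, ref: str, alt: str
) -> str:
    """Synonymous/nonsynonymous by strand-aware codon lookup (table 11)."""
    if model.strand == "+":
        off = p0 - model.start
        ci, within = divmod(off, 3)
        cstart = model.start + 3 * ci
        codon = genome_seq[cstart : cstart + 3]
        if len(codon) < 3:
            return "n.a."
        alt_codon = codon[:within] + alt + codon[within + 1 :]
    else:
        off = model.end - 1 - p0
        ci, within = divmod(off, 3)
        cend = model.end - 3 * ci
        codon = genome_seq[cend - 3 : cend].translate(_COMPLEMENT)[::-1]
        if len(codon) < 3:
            return "n.a."
        alt_codon = (
            codon[:within] + alt.translate(_COMPLEMENT) + codon[within + 1 :]
        )
    aa_ref = str(Seq(codon).translate(table=11))
    aa_alt = str(Seq(alt_codon).translate(table=11))
    return "synonymous" if aa_ref == aa_alt else "nonsynonymous"


def classify_snp(
    record: VariantRecord,
    genome: Mapping[str, str],
    gene_models: Sequence[GeneModel],
) -> VariantRecord:
    """Classify a single-base substitution in place and return it.

    Transition means purine↔purine (A↔G) or pyrimidine↔pyrimidine (C↔T).
    A SNP inside an annotated CDS is *coding* and scored synonymous or
    nonsynonymous by translating its codon before and after substitution
    (standard bacterial code, strand-aware). Ambiguous bases classify as
    not applicable; a reference-allele mismatch with the genome is a
    consistency error.
    """
    if not record.is_snp:
        raise ParameterError("classify_snp requires a single-base substitution")
    if record.contig not in genome:
        raise InputError(f"record on unknown contig {record.contig!r}")
    seq = genome[record.contig]
    p0 = record.position - 1
    if not 0 <= p0 < len(seq):
        raise InputError(f"position {record.position} outside contig {record.contig}")
    ref, alt = record.ref.upper(), record.alt.upper()
    if seq[p0].upper() != ref:
        raise InputError(
            f"ref allele {ref} does not match genome base {seq[p0]} "
            f"at {record.contig}:{record.position}"
        )

    if ref not in "ACGT" or alt not in "ACGT":
        record.substitution_class = None
        record.region = None
        record.effect = "n.a."
        return record

    both = {ref, alt}
    record.substitution_class = (
        TRANSITION if both <= _PURINES or both <= _PYRIMIDINES else TRANSVERSION
    )

    hit = next(
        (
            m
            for m in gene_models
            if m.contig == record.contig and m.start <= p0 < m.end
        ),
        None,
    )
    if hit is None:
        record.region = "noncoding"
        record.effect = "n.a."
    else:
        record.region = "coding"
        record.effect = _codon_effect(seq.upper(), hit, p0, ref, alt)
    return record


ALL_LINEAGES = "__all__"


def tabulate_counts(records: Iterable[VariantRecord]) -> pd.DataFrame:
    """Per lineage × round transition (k) and total (n) SNP counts.

    Only single-base substitutions are counted; every one must already be
    classified. The returned frame has columns ``lineage_id, round, k, n``:
    one row per (lineage, round), a margin row per lineage (``round`` is
    <NA>), and a grand-total row (lineage ``__all__``). No records → empty
    frame.
    """
    rows = []
    for rec in records:
        if not rec.is_snp:
            continue
        if rec.substitution_class not in (TRANSITION, TRANSVERSION):
            raise InputError(
                f"unclassified SNP at {rec.contig}:{rec.position}; "
                "run classify_snp first"
            )
        rows.append(
            (rec.lineage_id, rec.round, rec.substitution_class == TRANSITION)
        )
    cols = ["lineage_id", "round", "k", "n"]
    if not rows:
        return pd.DataFrame(columns=cols)
    df = pd.DataFrame(rows, columns=["lineage_id", "round", "is_ti"])
    per_round = (
        df.groupby(["lineage_id", "round"], sort=True)["is_ti"]
        .agg(k="sum", n="size")
        .reset_index()
    )
    per_lineage = (
        df.groupby("lineage_id", sort=True)["is_ti"].agg(k="sum", n="size").reset_index()
    )
    per_lineage["round"] = pd.NA
    total = pd.DataFrame(
        {
            "lineage_id": [ALL_LINEAGES],
            "round": [pd.NA],
            "k": [int(df["is_ti"].sum())],
            "n": [len(df)],
        }
    )
    out = pd.concat([per_round, per_lineage, total], ignore_index=True)[cols]
    out["round"] = out["round"].astype("Int64")
    return out


def per_round_rows(table: pd.DataFrame) -> pd.DataFrame:
    """The non-margin rows of a :func:`tabulate_counts` table."""
    return table[table["round"].notna() & (table["lineage_id"] != ALL_LINEAGES)]


def lineage_totals(table: pd.DataFrame) -> pd.DataFrame:
    """Per-lineage margin rows of a :func:`tabulate_counts` table."""
    return table[table["round"].isna() & (table["lineage_id"] != ALL_LINEAGES)]


def grand_total(table: pd.DataFrame) -> tuple[int, int]:
    """(k, n) summed over all lineages and rounds."""
    row = table[table["lineage_id"] == ALL_LINEAGES]
    if row.empty:
        return (0, 0)
    return int(row["k"].iloc[0]), int(row["n"].iloc[0])
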