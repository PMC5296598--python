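"""Site-specific excision at an integrase attachment locus.

A mobile element integrated inside a host gene is modelled as five
concatenated pieces::

    host_upstream | core_left | element | core_right | host_downstream

``core_left`` and ``core_right`` are the direct-repeat att cores the
integrase recombines. ``core_left`` may carry ``scar_offset`` extra host
bases at its 3' end; on excision those bases travel to the circular
element, leaving the rejoined host locus (attB) shorter than the
pre-insertion gene by exactly ``scar_offset`` bp. A scar length not
divisible by 3 shifts the reading frame of the host gene and typically
exposes a premature stop codon.

Products of excision:

* attB — host_upstream + core + host_downstream (linear, rejoined host gene)
* attP — core + scar bases + element (the excised circle, written linearly
  with its origin at the first base of the repeat core)

Base conservation holds exactly: len(attB) + len(attP) equals the length of
the integrated locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

import numpy as np
from Bio.Seq import Seq

from .errors import ConfigurationError, ModelError, ParameterError

#: NCBI translation table 11 (bacterial); ATG/GTG/TTG starts are accepted.
BACTERIAL_TABLE = 11

_STOP_CODONS = {"TAA", "TAG", "TGA"}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (uppercased)."""
    return str(Seq(seq.upper()).reverse_complement())


def translate_cds(seq: str) -> str:
    """Translate a nucleotide string codon by codon (bacterial code).

    Trailing bases that do not fill a codon are ignored; stops appear
    as ``*`` and translation does NOT stop at them.
    """
    n = 3 * (len(seq) // 3)
    if n == 0:
        return ""
    return str(Seq(seq[:n].upper()).translate(table=BACTERIAL_TABLE))


def first_stop_codon(seq: str) -> int | None:
    """Index (codon units, 0-based) of the first in-frame stop, or None."""
    protein = translate_cds(seq)
    idx = protein.find("*")
    return None if idx < 0 else idx


@dataclass(frozen=True)
class GeneAnnotation:
    """Coding frame of the host gene, in pre-insertion host coordinates.

    ``cds_start``/``cds_end`` are 0-based half-open offsets into the
    pre-insertion host sequence (upstream + core_left + downstream).
    """

    cds_start: int
    cds_end: int
    strand: str = "+"
    name: str = "host_gene"


@dataclass(frozen=True)
class AttLocus:
    """An integrated mobile-element locus and its host-gene annotation."""

    host_upstream: str
    core_left: str
    element: str
    core_right: str
    host_downstream: str
    scar_offset: int
    gene_model: GeneAnnotation

    def __post_init__(self) -> None:
        if self.scar_offset < 0:
            raise ModelError("scar_offset must be non-negative")
        if len(self.core_left) != len(self.core_right) + self.scar_offset:
            raise ModelError(
                "core_left must equal core_right plus scar_offset extra bases"
            )
        if self.core_left[: len(self.core_right)] != self.core_right:
            raise ModelError("core_left and core_right disagree beyond the scar offset")

    @property
    def core(self) -> str:
        """The shared repeat core (without scar bases)."""
        return self.core_right

    @property
    def scar_bases(self) -> str:
        """Host bases transferred to the circle on excision."""
        return self.core_left[len(self.core_right):]

    @property
    def integrated_sequence(self) -> str:
        """The full integrated locus, 5'→3'."""
        return (
            self.host_upstream
            + self.core_left
            + self.element
            + self.core_right
            + self.host_downstream
        )

    @property
    def preinsertion_host(self) -> str:
        """The host locus as it was before the element integrated."""
        return self.host_upstream + self.core_left + self.host_downstream


@dataclass(frozen=True)
class ExcisionProducts:
    """The two recombination products of excision plus scar characterisation."""

    attB_sequence: str
    attP_sequence: str
    scar_length: int
    frameshift: bool
    premature_stop_codon_position: int | None
    core: str = ""
    attB_core_start: int = 0
    wildtype_stop_codon_position: int = 0

    def reintegrated(self) -> str:
        """Re-insert the circle into attB at the core; inverse of excision."""
        i = self.attB_core_start
        k = len(self.core)
        upstream, core, downstream = (
            self.attB_sequence[:i],
            self.attB_sequence[i : i + k],
            self.attB_sequence[i + k :],
        )
        if core != self.core or self.attP_sequence[:k] != self.core:
            raise ModelError("core coordinates do not match product sequences")
        return upstream + core + self.attP_sequence[k:] + core + downstream


def predict_excision(locus: AttLocus) -> ExcisionProducts:
    """Predict attB/attP products and characterise the host-gene scar.

    attB keeps one copy of the repeat core; the scar bases and the element
    leave on the circle. The host gene annotated on the locus is translated
    in attB coordinates to decide whether the scar causes a frameshift and a
    premature stop codon (any in-frame stop strictly before the wild-type
    stop).
    """
    scar = locus.scar_offset
    attB = locus.host_upstream + locus.core + locus.host_downstream
    attP = locus.core + locus.scar_bases + locus.element

    gm = locus.gene_model
    wt_gene = locus.preinsertion_host[gm.cds_start : gm.cds_end]
    wt_stop = first_stop_codon(wt_gene)
    if wt_stop is None:
        # no annotated stop: fall back to the last full codon
        wt_stop = len(wt_gene) // 3 - 1

    # the scar removes bases after cds_start, so the attB gene starts at the
    # same offset and simply ends `scar` bases earlier
    attB_gene = attB[gm.cds_start : gm.cds_end - scar]
    stop = first_stop_codon(attB_gene)
    # the wild-type stop codon itself shifts `scar` bases left in attB; only
    # a stop strictly before that shifted position truncates the protein
    wt_stop_in_attB = (3 * wt_stop - scar) // 3 if 3 * wt_stop >= scar else wt_stop
    premature = stop if (stop is not None and stop < wt_stop_in_attB) else None

    return ExcisionProducts(
        attB_sequence=attB,
        attP_sequence=attP,
        scar_length=scar,
        frameshift=(scar % 3 != 0),
        premature_stop_codon_position=premature,
        core=locus.core,
        attB_core_start=len(locus.host_upstream),
        wildtype_stop_codon_position=wt_stop,
    )


# ---------------------------------------------------------------------------
# direct-repeat discovery
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RepeatCandidate:
    """A shared exact substring between the two element/host junctions."""

    sequence: str
    left_start: int
    right_start: int
    length: int


def find_direct_repeats(
    left_junction: str, right_junction: str, min_core: int = 8
) -> list[RepeatCandidate]:
    """Find exact direct repeats shared by the two junction sequences.

    Returns maximal shared substrings of length >= ``min_core``, ranked
    longest first with ties broken by leftmost position in the left
    junction. An empty list means no candidate core (not an error).
    """
    if min_core < 4:
        raise ParameterError("min_core must be at least 4")
    left = left_junction.upper()
    right = right_junction.upper()
    nl, nr = len(left), len(right)
    if nl < min_core or nr < min_core:
        return []

    la = np.frombuffer(left.encode(), dtype="S1")
    ra = np.frombuffer(right.encode(), dtype="S1")
    eq = la[:, None] == ra[None, :]

    # M[i, j] = length of the common suffix of left[:i+1] and right[:j+1]
    lengths = np.zeros((nl, nr), dtype=np.int32)
    prev = np.zeros(nr, dtype=np.int32)
    for i in range(nl):
        cur = np.zeros(nr, dtype=np.int32)
        cur[0] = eq[i, 0]
        cur[1:] = np.where(eq[i, 1:], prev[:-1] + 1, 0)
        lengths[i] = cur
        prev = cur

    out: list[RepeatCandidate] = []
    for i, j in zip(*np.nonzero(lengths >= min_core)):
        # keep only maximal matches (not extendable to the right)
        if i + 1 < nl and j + 1 < nr and eq[i + 1, j + 1]:
            continue
        ln = int(lengths[i, j])
        out.append(
            RepeatCandidate(
                sequence=left[i - ln + 1 : i + 1],
                left_start=int(i) - ln + 1,
                right_start=int(j) - ln + 1,
                length=ln,
            )
        )
    out.sort(key=lambda c: (-c.length, c.left_start, c.right_start))
    return out


# ---------------------------------------------------------------------------
# in-silico PCR
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Amplicon:
    """One predicted PCR product on a template."""

    start: int
    end: int
    length: int
    crosses_origin: bool
    template_state: str = ""
    fwd_primer: str = ""
    rev_primer: str = ""


def _find_all(haystack: str, needle: str) -> list[int]:
    hits, i = [], haystack.find(needle)
    while i != -1:
        hits.append(i)
        i = haystack.find(needle, i + 1)
    return hits


def insilico_pcr(
    template: str,
    circular: bool,
    fwd_primer: str,
    rev_primer: str,
    max_len: int,
    template_state: str = "",
) -> list[Amplicon]:
    """Predict exact-match PCR products on a linear or circular template.

    The forward primer must match the forward strand; the reverse primer
    binds where its reverse complement appears downstream. Only products of
    length <= ``max_len`` (and, for circular templates, <= template length)
    are reported. Matching is exact — no mismatch tolerance.
    """
    if len(fwd_primer) < 15 or len(rev_primer) < 15:
        raise ParameterError("primers must be at least 15 bp")
    if max_len <= 0:
        raise ParameterError("max_len must be positive")

    tpl = template.upper()
    n = len(tpl)
    if n == 0:
        return []
    fwd = fwd_primer.upper()
    rev_site = revcomp(rev_primer)

    search = tpl + tpl if circular else tpl
    fwd_hits = [i for i in _find_all(search, fwd) if i < n]
    rev_hits = _find_all(search, rev_site)

    products: list[Amplicon] = []
    seen: set[tuple[int, int]] = set()
    cap = min(max_len, n) if circular else max_len
    for i in fwd_hits:
        for j in rev_hits:
            end = j + len(rev_site)
            length = end - i
            if length <= 0 or length > cap:
                continue
            key = (i % n, length)
            if key in seen:
                continue
            seen.add(key)
            products.append(
                Amplicon(
                    start=i % n,
                    end=end % n if circular else end,
                    length=length,
                    crosses_origin=circular and end > n,
                    template_state=template_state,
                    fwd_primer=fwd,
                    rev_primer=rev_primer.upper(),
                )
            )
    products.sort(key=lambda a: (a.start, a.length))
    return products


# ---------------------------------------------------------------------------
# four-amplicon assay
# ---------------------------------------------------------------------------

ASSAY_JUNCTIONS = ("attL", "attR", "attB", "attP")


@dataclass
class AssayPrimerSet:
    """Primer pairs for the attL/attR/attB/attP junction assay.

    ``pairs`` maps each junction name to (fwd, rev) primers and
    ``references`` to the positive-control template (sequence, circular)
    each pair is expected to amplify.
    """

    pairs: dict[str, tuple[str, str]]
    references: dict[str, tuple[str, bool]] = field(default_factory=dict)
    max_len: int = 2000


def design_assay_primers(
    locus: AttLocus,
    primer_len: int = 20,
    offset: int = 60,
    max_len: int = 2000,
) -> AssayPrimerSet:
    """Design the four junction primer pairs for a locus.

    Two anchor primers sit in the host flanks (upstream forward, downstream
    reverse) and two inside the element near its ends; the four pairwise
    combinations read out the four junction states. The attB pair must NOT
    amplify across the integrated element, so the element plus flanking
    offsets must exceed ``max_len``.
    """
    u, e, d = locus.host_upstream, locus.element, locus.host_downstream
    need = offset + primer_len
    if len(u) < need or len(d) < need or len(e) < 2 * need:
        raise ParameterError("locus flanks/element too short for primer design")

    fwd_host = u[len(u) - need : len(u) - offset]
    rev_host = revcomp(d[offset : offset + primer_len])
    fwd_elem = e[len(e) - need : len(e) - offset]
    rev_elem = revcomp(e[offset : offset + primer_len])

    pairs = {
        "attL": (fwd_host, rev_elem),
        "attR": (fwd_elem, rev_host),
        "attB": (fwd_host, rev_host),
        "attP": (fwd_elem, rev_elem),
    }
    products = predict_excision(locus)
    references = {
        "attL": (locus.integrated_sequence, False),
        "attR": (locus.integrated_sequence, False),
        "attB": (products.attB_sequence, False),
        "attP": (products.attP_sequence, True),
    }
    primer_set = AssayPrimerSet(pairs=pairs, references=references, max_len=max_len)

    for name in ASSAY_JUNCTIONS:
        seq, circ = references[name]
        if not insilico_pcr(seq, circ, *pairs[name], max_len, name):
            raise ConfigurationError(
                f"designed {name} pair fails on its positive-control template"
            )
    spurious = insilico_pcr(
        locus.integrated_sequence, False, *pairs["attB"], max_len, "integrated"
    )
    if spurious:
        raise ConfigurationError(
            "attB pair amplifies across the integrated element; "
            "reduce max_len or enlarge the element"
        )
    return primer_set


Genotype = Union[AttLocus, ExcisionProducts]


def assay_state(
    genotype: Genotype | Iterable[Genotype],
    primer_set: AssayPrimerSet,
) -> dict[str, bool]:
    """Presence/absence of the four junction products for a (mixed) genotype.

    An integrated locus presents templates for attL and attR only; an
    excised genotype for attB (linear) and attP (circular); a mixture
    presents all four. Each primer pair is first validated against its own
    positive-control template.
    """
    for name in ASSAY_JUNCTIONS:
        if name not in primer_set.pairs:
            raise ConfigurationError(f"primer set missing pair for {name}")
        ref = primer_set.references.get(name)
        if ref is None or not insilico_pcr(
            ref[0], ref[1], *primer_set.pairs[name], primer_set.max_len, name
        ):
            raise ConfigurationError(
                f"{name} primer pair fails its positive-control amplification"
            )

    if isinstance(genotype, (AttLocus, ExcisionProducts)):
        genotypes: list[Genotype] = [genotype]
    else:
        genotypes = list(genotype)

    templates: list[tuple[str, bool]] = []
    for g in genotypes:
        if isinstance(g, AttLocus):
            templates.append((g.integrated_sequence, False))
        elif isinstance(g, ExcisionProducts):
            templates.append((g.attB_sequence, False))
            templates.append((g.attP_sequence, True))
        else:
            raise ParameterError(f"unsupported genotype object: {type(g)!r}")

    result: dict[str, bool] = {}
    for name in ASSAY_JUNCTIONS:
        fwd, rev = primer_set.pairs[name]
        result[name] = any(
            insilico_pcr(seq, circ, fwd, rev, primer_set.max_len, name)
            for seq, circ in templates
        )
    return result
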