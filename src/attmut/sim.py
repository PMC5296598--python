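"""Synthetic-data generator with known ground truth.

Emulates the inputs of a hypersalinity mutation-accumulation experiment on
a marine *Vibrio*: eight lineages passaged through selection rounds of ~80
generations (three ~24-generation colony growths plus one ~8-generation
liquid culture), sequenced once per round. The strain carries a mobile
element integrated in the start of the mismatch-repair gene *mutS*; while
integrated the lineage mutates at a modest "mutator" rate, and when the
element excises (leaving a 2-bp frameshift scar that kills *mutS*) the
lineage becomes a hypermutator with a strongly transition-biased spectrum.

The generator draws, per round, new fixed mutations from a Poisson law with
mean rate × generations, assigns each a transition with the state's p_ti,
and maintains nested cumulative mutation sets — exactly the data model the
downstream filters and spectrum statistics assume. It also fabricates
zero-coverage deletion footprints, an integrated att locus with direct
repeats and a configurable scar, and qPCR plates with a 100%-excision
standard dilution series.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import GenerationError, ParameterError
from .excision import AttLocus, ExcisionProducts, GeneAnnotation, predict_excision
from .qpcr import ATTB, CONTROL, PLATE_COLUMNS, STANDARD_PHASE
from .variants import VariantRecord

ELEMENT_PRESENT = "element_present"
ELEMENT_EXCISED = "element_excised"

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

#: generation accounting per selection round: 3 colony growths + 1 liquid
GENERATIONS_PER_COLONY = 24
COLONIES_PER_ROUND = 3
GENERATIONS_PER_LIQUID = 8
GENERATIONS_PER_ROUND = (
    COLONIES_PER_ROUND * GENERATIONS_PER_COLONY + GENERATIONS_PER_LIQUID
)


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the two-state lineage simulator.

    Defaults follow the study conditions: 8 lineages, 5 rounds of 80
    generations (400 total); hypermutators at 3.75 mutations/generation
    (~1,500 mutations over 400 generations) with ts/tv 24.6, mutators two
    orders of magnitude above the ~0.003/generation bacterial baseline with
    ts/tv 16.5. Switching between states is Bernoulli per round; the study
    constrains only the steady-state excision frequency, so the switch
    probabilities are free parameters chosen to produce sporadic
    mutation bursts.
    """

    n_lineages: int = 8
    n_rounds: int = 5
    generations_per_round: int = GENERATIONS_PER_ROUND
    rate_mutator: float = 0.3
    rate_hypermutator: float = 3.75
    p_ti_mutator: float = 16.5 / 17.5  # ts/tv 16.5
    p_ti_hypermutator: float = 24.6 / 25.6  # ts/tv 24.6
    p_excise_per_round: float = 0.1
    p_reintegrate_per_round: float = 0.5
    genome_length: int = 5_000_000
    contaminant_fraction: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        probs = (
            self.p_ti_mutator,
            self.p_ti_hypermutator,
            self.p_excise_per_round,
            self.p_reintegrate_per_round,
            self.contaminant_fraction,
        )
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ParameterError("all probabilities must be in [0, 1]")
        if self.rate_mutator < 0 or self.rate_hypermutator < 0:
            raise ParameterError("mutation rates must be non-negative")
        if self.generations_per_round < 1:
            raise ParameterError("generations_per_round must be >= 1")
        if self.n_lineages < 1 or self.n_rounds < 1:
            raise ParameterError("need at least one lineage and one round")
        if self.genome_length < 1:
            raise ParameterError("genome_length must be positive")
        if self.contaminant_fraction >= 1.0:
            raise ParameterError("contaminant_fraction must be < 1")


@dataclass
class LineageTrajectory:
    """Ground truth for one simulated lineage.

    ``new_mutations[r]`` are the fixed mutations that arose in round r
    (0-based list index, 1-based round numbers on the records);
    ``contaminants[r]`` are unfixed low-fraction calls present only in that
    round's isolate. ``cumulative`` materialises the nested per-round
    mutation-identity sets on demand (kept lazy so long trajectories do not
    hold one snapshot per round).
    """

    lineage_id: str
    states: list[str] = field(default_factory=list)
    new_mutations: list[list[VariantRecord]] = field(default_factory=list)
    contaminants: list[list[VariantRecord]] = field(default_factory=list)

    @property
    def cumulative(self) -> list[set]:
        out: list[set] = []
        cum: set = set()
        for recs in self.new_mutations:
            cum = cum | {r.key for r in recs}
            out.append(cum)
        return out

    def records_for_round(self, round_index: int) -> list[VariantRecord]:
        """All variant calls a round-``round_index`` isolate would show.

        Cumulative fixed mutations (re-stamped with the sampled round) plus
        that round's contaminants. ``round_index`` is 1-based.
        """
        out: list[VariantRecord] = []
        for r in range(round_index):
            for rec in self.new_mutations[r]:
                out.append(replace_round(rec, round_index))
        out.extend(replace_round(c, round_index) for c in self.contaminants[round_index - 1])
        return out


def replace_round(rec: VariantRecord, round_index: int) -> VariantRecord:
    """Copy of a record stamped with the round whose isolate reports it."""
    return VariantRecord(
        lineage_id=rec.lineage_id,
        round=round_index,
        contig=rec.contig,
        position=rec.position,
        ref=rec.ref,
        alt=rec.alt,
        read_fraction=rec.read_fraction,
    )


def random_genome(length: int, seed=None) -> str:
    """A uniform-random DNA string (single contig)."""
    if length < 1:
        raise ParameterError("genome length must be positive")
    rng = np.random.default_rng(seed)
    return rng.choice(_BASES, size=length).tobytes().decode()


def _draw_positions(rng, genome_length: int, count: int, used: set[int]) -> list[int]:
    """Draw `count` unique 0-based positions not in `used` (rejection)."""
    if genome_length - len(used) < count:
        raise GenerationError(
            f"genome of {genome_length} bp cannot host {count} more mutations"
        )
    out: list[int] = []
    while len(out) < count:
        need = count - len(out)
        cand = rng.integers(0, genome_length, size=max(2 * need, 16))
        for p in cand:
            p = int(p)
            if p not in used:
                used.add(p)
                out.append(p)
                if len(out) == count:
                    break
    return out


def _mutate(rng, ref: str, p_ti: float) -> tuple[str, bool]:
    is_ti = bool(rng.random() < p_ti)
    if is_ti:
        return _TRANSITION[ref], True
    return _TRANSVERSIONS[ref][int(rng.integers(2))], False


def simulate_lineages(
    config: SimConfig,
    genome: str | None = None,
    contig: str = "contig_1",
) -> list[LineageTrajectory]:
    """Simulate lineage mutation trajectories under the two-state model.

    Every lineage starts with the element integrated (mutator state); at
    each subsequent round the state may switch with the configured excision
    / reintegration probabilities. New fixed mutations per round are
    Poisson(rate_state × generations); each is a transition with
    p_ti_state, placed uniformly without replacement, with supporting-read
    fraction in (0.8, 1.0]. A configurable fraction of extra low-fraction
    contaminant calls (read fraction in (0.2, 0.8)) exercises the fixed-SNP
    filter. Deterministic under the configured seed.
    """
    if genome is None:
        genome = random_genome(
            config.genome_length, np.random.default_rng(config.seed).integers(2**31)
        )
    if len(genome) != config.genome_length:
        raise ParameterError("genome length does not match config.genome_length")

    root = np.random.default_rng(config.seed)
    streams = root.spawn(config.n_lineages)
    cf = config.contaminant_fraction

    trajectories: list[LineageTrajectory] = []
    for i in range(config.n_lineages):
        rng = streams[i]
        lid = f"lineage_{i + 1}"
        traj = LineageTrajectory(lineage_id=lid)
        used: set[int] = set()
        state = ELEMENT_PRESENT
        for r in range(1, config.n_rounds + 1):
            if r > 1:
                if state == ELEMENT_PRESENT:
                    if rng.random() < config.p_excise_per_round:
                        state = ELEMENT_EXCISED
                else:
                    if rng.random() < config.p_reintegrate_per_round:
                        state = ELEMENT_PRESENT
            if state == ELEMENT_PRESENT:
                rate, p_ti = config.rate_mutator, config.p_ti_mutator
            else:
                rate, p_ti = config.rate_hypermutator, config.p_ti_hypermutator

            n_new = int(rng.poisson(rate * config.generations_per_round))
            positions = _draw_positions(rng, config.genome_length, n_new, used)
            new_recs: list[VariantRecord] = []
            for p0 in positions:
                ref = genome[p0]
                alt, _ = _mutate(rng, ref, p_ti)
                new_recs.append(
                    VariantRecord(
                        lineage_id=lid,
                        round=r,
                        contig=contig,
                        position=p0 + 1,
                        ref=ref,
                        alt=alt,
                        read_fraction=1.0 - 0.2 * float(rng.random()),
                    )
                )

            n_cont = int(rng.binomial(n_new, cf / (1.0 - cf))) if cf > 0 else 0
            cont_recs: list[VariantRecord] = []
            for p0 in _draw_positions(rng, config.genome_length, n_cont, used):
                ref = genome[p0]
                # contaminants emulate mapping noise: uniform alt choice
                alt = "ACGT".replace(ref, "")[int(rng.integers(3))]
                cont_recs.append(
                    VariantRecord(
                        lineage_id=lid,
                        round=r,
                        contig=contig,
                        position=p0 + 1,
                        ref=ref,
                        alt=alt,
                        read_fraction=0.2 + 0.6 * float(rng.random()),
                    )
                )

            traj.states.append(state)
            traj.new_mutations.append(new_recs)
            traj.contaminants.append(cont_recs)
        trajectories.append(traj)
    return trajectories


def simulate_coverage(
    genome_length: int,
    deletions,
    mean_depth: float,
    seed=None,
) -> np.ndarray:
    """Per-base read depth: Poisson(mean_depth) with zeroed deletion spans.

    ``deletions`` are (start, end) 0-based half-open intervals; they must
    be within the genome and non-overlapping.
    """
    if mean_depth <= 0:
        raise ParameterError("mean_depth must be positive")
    if genome_length < 1:
        raise ParameterError("genome_length must be positive")
    ivals = sorted((int(s), int(e)) for s, e in deletions)
    prev_end = 0
    for s, e in ivals:
        if s < 0 or e > genome_length or s >= e:
            raise ParameterError(f"malformed deletion interval ({s}, {e})")
        if s < prev_end:
            raise ParameterError("deletion intervals overlap")
        prev_end = e
    rng = np.random.default_rng(seed)
    depth = rng.poisson(mean_depth, size=genome_length)
    for s, e in ivals:
        depth[s:e] = 0
    return depth


# ---------------------------------------------------------------------------
# att locus construction
# ---------------------------------------------------------------------------

_NONSTOP_CODONS = [
    a + b + c
    for a in "ACGT"
    for b in "ACGT"
    for c in "ACGT"
    if a + b + c not in ("TAA", "TAG", "TGA")
]

#: 9-mer with no stop codon in frame 0 but a stop in both shifted frames;
#: planted at a codon boundary downstream of the scar it guarantees that
#: any frame-shifting scar exposes a premature stop.
_FRAMESHIFT_TRAP = "ATAAGTAAC"


@dataclass(frozen=True)
class AttLocusBundle:
    """A built locus plus its ground-truth excision products."""

    locus: AttLocus
    products: ExcisionProducts

    @property
    def truth_attB(self) -> str:
        return self.products.attB_sequence

    @property
    def truth_attP(self) -> str:
        return self.products.attP_sequence


def build_att_locus(
    upstream_len: int,
    element_len: int,
    core_len: int,
    scar_offset: int,
    seed=None,
    downstream_len: int = 600,
) -> AttLocusBundle:
    """Build a synthetic integrated locus with a known excision outcome.

    The pre-insertion host gene (upstream + core + scar bases + downstream)
    is a clean ORF of random non-stop codons; the element is random DNA
    flanked by the direct-repeat cores. ``scar_offset`` host bases ride on
    the left core and transfer to the circle on excision: offset 2 emulates
    the 12B01 *mutS* scar (frameshift + premature stop), offset 0 a clean
    excision that restores the host gene exactly.
    """
    if core_len < 1:
        raise ParameterError("core_len must be >= 1")
    if not 0 <= scar_offset < core_len:
        raise ParameterError("need 0 <= scar_offset < core_len")
    if element_len < core_len or element_len < 1:
        raise ParameterError("element_len must be >= core_len and positive")
    if upstream_len < 3 or downstream_len < 30:
        raise ParameterError("host flanks too short for an annotated ORF")

    rng = np.random.default_rng(seed)
    total = upstream_len + core_len + scar_offset + downstream_len
    total += (-total) % 3  # pad to a codon boundary
    n_codons = total // 3

    trap_at = (upstream_len + core_len + scar_offset + 15 + 2) // 3 + 1
    if trap_at + 4 >= n_codons:
        raise ParameterError("downstream_len too short for stop-codon layout")

    for _ in range(100):
        codons = ["ATG"] + [
            _NONSTOP_CODONS[int(i)]
            for i in rng.integers(len(_NONSTOP_CODONS), size=n_codons - 2)
        ] + ["TAA"]
        codons[trap_at : trap_at + 3] = [
            _FRAMESHIFT_TRAP[0:3], _FRAMESHIFT_TRAP[3:6], _FRAMESHIFT_TRAP[6:9]
        ]
        gene = "".join(codons)
        u = gene[:upstream_len]
        core = gene[upstream_len : upstream_len + core_len]
        scar = gene[upstream_len + core_len : upstream_len + core_len + scar_offset]
        d = gene[upstream_len + core_len + scar_offset :]
        element = random_genome(element_len, rng.integers(2**31))
        locus = AttLocus(
            host_upstream=u,
            core_left=core + scar,
            element=element,
            core_right=core,
            host_downstream=d,
            scar_offset=scar_offset,
            gene_model=GeneAnnotation(cds_start=0, cds_end=total),
        )
        products = predict_excision(locus)
        # an in-frame scar must excise cleanly: re-draw if junction codons
        # happen to spell a stop
        if scar_offset % 3 == 0 and products.premature_stop_codon_position is not None:
            continue
        return AttLocusBundle(locus=locus, products=products)
    raise GenerationError("could not build a stop-free in-frame scar junction")


# ---------------------------------------------------------------------------
# qPCR plate simulation
# ---------------------------------------------------------------------------


def simulate_qpcr(
    true_frequency,
    efficiency: float,
    dilution_factors,
    noise_sd: float,
    replicates: int,
    seed=None,
    intercept_attB: float = 24.0,
    intercept_control: float = 20.0,
) -> pd.DataFrame:
    """Simulate a qPCR plate under the log-linear amplification model.

        Cq = intercept − log10(quantity) / log10(1 + efficiency) + ε

    with ε ~ Normal(0, noise_sd²). Standards are the 100%-excision DNA
    diluted by ``dilution_factors`` (factor d → quantity 1/d) for both the
    attB and control targets; test samples carry attB at
    ``true_frequency`` (a float, or a mapping phase → frequency to put
    several growth phases on one plate) against a control quantity of 1.
    """
    if isinstance(true_frequency, dict):
        phase_freqs = dict(true_frequency)
    else:
        phase_freqs = {"exponential": float(true_frequency)}
    for phase, f in phase_freqs.items():
        if not 0.0 < f <= 1.0:
            raise ParameterError(f"true_frequency for {phase!r} must be in (0, 1]")
    if not 0.0 < efficiency <= 1.0:
        raise ParameterError("efficiency must be in (0, 1]")
    dils = [float(d) for d in dilution_factors]
    if not dils or any(d <= 0 for d in dils):
        raise ParameterError("dilution factors must be positive")
    if noise_sd < 0:
        raise ParameterError("noise_sd must be non-negative")
    if replicates < 1:
        raise ParameterError("replicates must be >= 1")

    rng = np.random.default_rng(seed)
    denom = math.log10(1.0 + efficiency)
    intercepts = {ATTB: intercept_attB, CONTROL: intercept_control}

    def cq_of(target: str, quantity: float) -> float:
        noise = float(rng.normal(0.0, noise_sd)) if noise_sd > 0 else 0.0
        return intercepts[target] - math.log10(quantity) / denom + noise

    rows = []
    for target in (ATTB, CONTROL):
        for d in dils:
            for rep in range(1, replicates + 1):
                rows.append(
                    (
                        f"standard_d{d:g}", target, STANDARD_PHASE, rep, d,
                        cq_of(target, 1.0 / d),
                    )
                )
    for phase, freq in phase_freqs.items():
        for rep in range(1, replicates + 1):
            sample = f"{phase}_rep{rep}"
            rows.append((sample, ATTB, phase, rep, np.nan, cq_of(ATTB, freq)))
            rows.append((sample, CONTROL, phase, rep, np.nan, cq_of(CONTROL, 1.0)))
    return pd.DataFrame(rows, columns=PLATE_COLUMNS)
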