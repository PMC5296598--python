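"""End-to-end stages: simulate a study bundle, filter/classify variants,
compute spectrum statistics, analyse an att locus, quantify qPCR plates.

Each ``run_*`` function is a library entry point (the CLI wraps them
thinly). Inputs and outputs are the plain-text formats declared in
:mod:`attmut.io`; every number in the JSON reports is traceable to a stage
output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
import re
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import io as aio
from . import qpcr as q
from . import spectrum as spec
from . import variants as var
from .errors import FitError, InputError, ParameterError
from .excision import (
    AttLocus,
    GeneAnnotation,
    assay_state,
    design_assay_primers,
    find_direct_repeats,
    insilico_pcr,
    predict_excision,
)
from .sim import (
    COLONIES_PER_ROUND,
    ELEMENT_EXCISED,
    GENERATIONS_PER_COLONY,
    GENERATIONS_PER_LIQUID,
    AttLocusBundle,
    SimConfig,
    build_att_locus,
    random_genome,
    simulate_coverage,
    simulate_lineages,
    simulate_qpcr,
)

logger = logging.getLogger("attmut")

#: study-condition defaults for the qPCR plate simulation
QPCR_TRUE_FREQUENCIES = {"exponential": 7.95e-5, "stationary": 1.27e-4}
QPCR_DILUTIONS = (1.0, 10.0, 100.0, 1e3, 1e4, 1e5)
QPCR_EFFICIENCY = 0.95
QPCR_NOISE_SD = 0.1
QPCR_REPLICATES = 8

#: coverage model: reported mean sequencing depth of the study isolates
DEFAULT_MEAN_DEPTH = 35.0
DEFAULT_ELEMENT_LENGTH = 27_000


def _config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:12]


def generations_summary(n_rounds: int) -> dict:
    """Generation accounting: 3 colony growths of ~24 plus ~8 in liquid per round."""
    per_round = COLONIES_PER_ROUND * GENERATIONS_PER_COLONY + GENERATIONS_PER_LIQUID
    return {
        "generations_per_colony": GENERATIONS_PER_COLONY,
        "colonies_per_round": COLONIES_PER_ROUND,
        "generations_per_liquid": GENERATIONS_PER_LIQUID,
        "generations_per_round": per_round,
        "n_rounds": n_rounds,
        "generations_total": per_round * n_rounds,
    }


# ---------------------------------------------------------------------------
# simulate
# ---------------------------------------------------------------------------


def run_simulate(
    config: SimConfig,
    outdir,
    mean_depth: float = DEFAULT_MEAN_DEPTH,
    element_length: int = DEFAULT_ELEMENT_LENGTH,
    locus_kwargs: Mapping | None = None,
    qpcr_kwargs: Mapping | None = None,
) -> dict:
    """Write a complete synthetic study bundle with ground truth.

    Produces genome.fasta, genes.gff3, per lineage × round VCFs, per-lineage
    coverage bedGraphs (with the element's zero-coverage footprint for
    lineages that finished excised), the att locus bundle, a qPCR plate and
    truth.json. Deterministic under config.seed.
    """
    outdir = Path(outdir)
    if not outdir.parent.exists():
        raise InputError(f"parent of output directory does not exist: {outdir}")
    (outdir / "variants").mkdir(parents=True, exist_ok=True)
    (outdir / "coverage").mkdir(exist_ok=True)
    (outdir / "locus").mkdir(exist_ok=True)

    cfg_dict = dataclasses.asdict(config)
    logger.info("simulate: seed=%s config=%s", config.seed, _config_hash(cfg_dict))

    genome_seed = int(np.random.default_rng(config.seed).integers(2**31))
    genome = random_genome(config.genome_length, genome_seed)
    contig = "contig_1"
    contig_lengths = {contig: config.genome_length}
    aio.write_fasta(outdir / "genome.fasta", {contig: genome})

    gene_models = _tile_gene_models(contig, config.genome_length)
    aio.write_gff3(outdir / "genes.gff3", gene_models, contig_lengths)

    trajectories = simulate_lineages(config, genome=genome, contig=contig)

    el_len = min(element_length, max(config.genome_length // 10, 1))
    el_start = config.genome_length // 2
    element_interval = (el_start, min(el_start + el_len, config.genome_length))

    aux = np.random.default_rng(np.random.SeedSequence(entropy=config.seed, spawn_key=(1,)))
    truth_lineages = {}
    for traj in trajectories:
        for r in range(1, config.n_rounds + 1):
            aio.write_vcf(
                outdir / "variants" / f"{traj.lineage_id}_round{r}.vcf",
                traj.records_for_round(r),
                contig_lengths,
                sample=f"{traj.lineage_id}_r{r}",
            )
        deletions = [element_interval] if traj.states[-1] == ELEMENT_EXCISED else []
        depth = simulate_coverage(config.genome_length, deletions, mean_depth, seed=aux)
        aio.write_bedgraph(outdir / "coverage" / f"{traj.lineage_id}.bedgraph", {contig: depth})
        truth_lineages[traj.lineage_id] = {
            "states": traj.states,
            "new_counts": [len(ms) for ms in traj.new_mutations],
            "new_transitions": [
                sum(
                    1
                    for m in ms
                    if {m.ref, m.alt} in ({"A", "G"}, {"C", "T"})
                )
                for ms in traj.new_mutations
            ],
            "deletion_intervals": deletions,
        }

    locus_kwargs = dict(locus_kwargs or {})
    locus_kwargs.setdefault("upstream_len", 300)
    locus_kwargs.setdefault("element_len", element_length)
    locus_kwargs.setdefault("core_len", 12)
    locus_kwargs.setdefault("scar_offset", 2)
    locus_kwargs.setdefault("seed", int(aux.integers(2**31)))
    bundle = build_att_locus(**locus_kwargs)
    save_locus(outdir / "locus", bundle)

    qpcr_kwargs = dict(qpcr_kwargs or {})
    qpcr_kwargs.setdefault("true_frequency", dict(QPCR_TRUE_FREQUENCIES))
    qpcr_kwargs.setdefault("efficiency", QPCR_EFFICIENCY)
    qpcr_kwargs.setdefault("dilution_factors", list(QPCR_DILUTIONS))
    qpcr_kwargs.setdefault("noise_sd", QPCR_NOISE_SD)
    qpcr_kwargs.setdefault("replicates", QPCR_REPLICATES)
    qpcr_kwargs.setdefault("seed", aux)
    plate = simulate_qpcr(**qpcr_kwargs)
    aio.write_qpcr_csv(outdir / "qpcr.csv", plate)

    truth = {
        "config": cfg_dict,
        "p_ti_mutator": config.p_ti_mutator,
        "p_ti_hypermutator": config.p_ti_hypermutator,
        "lineages": truth_lineages,
        "element_interval": list(element_interval),
        "locus": {
            "scar_offset": bundle.locus.scar_offset,
            "core": bundle.locus.core,
            "frameshift": bundle.products.frameshift,
        },
        "qpcr": {
            "true_frequency": qpcr_kwargs["true_frequency"],
            "efficiency": qpcr_kwargs["efficiency"],
        },
        "generations": generations_summary(config.n_rounds),
    }
    with open(outdir / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=2, default=str)
    return truth


def _tile_gene_models(
    contig: str, genome_length: int, gene_len: int = 900, gap: int = 150
) -> list[var.GeneModel]:
    """Tile the genome with alternating-strand CDS models (~85% coding)."""
    models = []
    pos, i = gap, 0
    while pos + gene_len <= genome_length - gap:
        models.append(
            var.GeneModel(
                contig=contig,
                start=pos,
                end=pos + gene_len,
                strand="+" if i % 2 == 0 else "-",
                name=f"gene_{i + 1:05d}",
            )
        )
        pos += gene_len + gap
        i += 1
    return models


def save_locus(outdir, bundle: AttLocusBundle) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    loc = bundle.locus
    aio.write_fasta(
        outdir / "locus.fasta",
        {
            "integrated": loc.integrated_sequence,
            "preinsertion_host": loc.preinsertion_host,
            "attB_truth": bundle.truth_attB,
            "attP_truth": bundle.truth_attP,
        },
    )
    meta = {
        "host_upstream": loc.host_upstream,
        "core_left": loc.core_left,
        "element": loc.element,
        "core_right": loc.core_right,
        "host_downstream": loc.host_downstream,
        "scar_offset": loc.scar_offset,
        "gene_model": dataclasses.asdict(loc.gene_model),
    }
    with open(outdir / "locus.json", "w") as fh:
        json.dump(meta, fh, indent=2)


def load_locus(path) -> AttLocus:
    path = Path(path)
    if path.is_dir():
        path = path / "locus.json"
    with open(path) as fh:
        meta = json.load(fh)
    gm = GeneAnnotation(**meta.pop("gene_model"))
    return AttLocus(gene_model=gm, **meta)


# ---------------------------------------------------------------------------
# filter
# ---------------------------------------------------------------------------


@dataclass
class FilterResult:
    classified: list  # new (per-round) classified VariantRecords
    counts: pd.DataFrame  # tabulate_counts table
    deletions: dict[str, list[var.DeletionCall]]
    consistency: dict[str, dict]
    removed: list  # audit trail of filtered-out records
    n_rounds: int


def run_filter(
    indir,
    outdir=None,
    threshold: float = 0.80,
    end_margin: int = 50,
    min_del_len: int = 100,
) -> FilterResult:
    """Apply the post-calling filters to a bundle and tabulate the spectrum.

    Reads the bundle written by :func:`run_simulate` (or any directory with
    the same layout), keeps fixed SNPs (> threshold read fraction), removes
    contig-end and in-deletion calls, verifies lineage continuity on the
    cumulative per-round sets, derives the new mutations of each round, and
    classifies them against the reference and gene models.
    """
    indir = Path(indir)
    genome = aio.read_fasta(indir / "genome.fasta")
    contig_lengths = {name: len(seq) for name, seq in genome.items()}
    gene_models = aio.read_gff3(indir / "genes.gff3")

    deletions: dict[str, list[var.DeletionCall]] = {}
    for bg in sorted((indir / "coverage").glob("*.bedgraph")):
        tracks = aio.read_bedgraph(bg)
        deletions[bg.stem] = var.detect_deletions(tracks, min_len=min_del_len)

    by_lineage: dict[str, dict[int, list[var.VariantRecord]]] = {}
    pattern = re.compile(r"(?P<lineage>.+)_round(?P<round>\d+)\.vcf$")
    for vcf_path in sorted((indir / "variants").glob("*.vcf")):
        m = pattern.match(vcf_path.name)
        if not m:
            raise InputError(f"unrecognised variant file name: {vcf_path.name}")
        lid, rnd = m.group("lineage"), int(m.group("round"))
        recs = aio.read_vcf(vcf_path, lineage_id=lid, round_=rnd)
        by_lineage.setdefault(lid, {})[rnd] = recs
    if not by_lineage:
        raise InputError(f"no variant files found under {indir / 'variants'}")

    all_new: list[var.VariantRecord] = []
    removed_all: list[var.VariantRecord] = []
    consistency: dict[str, dict] = {}
    n_rounds = 0
    for lid in sorted(by_lineage):
        rounds = sorted(by_lineage[lid])
        n_rounds = max(n_rounds, max(rounds))
        lineage_dels = deletions.get(lid, [])
        kept_by_round: dict[int, list[var.VariantRecord]] = {}
        for rnd in rounds:
            fixed = var.filter_fixed(by_lineage[lid][rnd], threshold)
            kept, removed = var.exclude_unreliable(
                fixed, contig_lengths, end_margin, lineage_dels
            )
            removed_all.extend(removed)
            kept_by_round[rnd] = kept

        sets = [{r.key for r in kept_by_round[rnd]} for rnd in rounds]
        ok, missing = var.check_lineage_consistency(sets)
        consistency[lid] = {
            "pass": ok,
            "missing": {str(rounds[i]): [list(k) for k in lost] for i, lost in missing.items()},
        }

        prev: set = set()
        for rnd in rounds:
            cur = {r.key for r in kept_by_round[rnd]}
            new = [r for r in kept_by_round[rnd] if r.key not in prev]
            prev = prev | cur
            for rec in new:
                if rec.is_snp:
                    var.classify_snp(rec, genome, gene_models)
            all_new.extend(new)

    counts = var.tabulate_counts([r for r in all_new if r.is_snp])
    result = FilterResult(
        classified=all_new,
        counts=counts,
        deletions=deletions,
        consistency=consistency,
        removed=removed_all,
        n_rounds=n_rounds,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        aio.write_variants_tsv(outdir / "classified.tsv", all_new)
        with open(outdir / "deletions.bed", "w") as fh:
            for lid, dels in sorted(deletions.items()):
                for d in dels:
                    fh.write(f"{d.contig}\t{d.start}\t{d.end}\t{lid}\t{d.length}\n")
        counts.to_csv(outdir / "counts.csv", index=False)
        with open(outdir / "consistency.json", "w") as fh:
            json.dump(consistency, fh, indent=2)
    return result


# ---------------------------------------------------------------------------
# spectrum
# ---------------------------------------------------------------------------


def run_spectrum(
    counts: pd.DataFrame,
    outdir=None,
    null_p: float = 0.70,
    n_boot: int = 10_000,
    seed=None,
    n_rounds: int | None = None,
) -> dict:
    """Spectrum statistics from a per-lineage × round count table.

    Reports the pooled ML transition frequency and ts/tv ratio with the
    normalised likelihood curve, per-lineage MLEs, per-lineage Poisson
    over-dispersion (rounds without new mutations count as zeros), the
    transition-bias χ² against ``null_p`` and the OLS of per-round ts/tv
    ratio on mutation load.
    """
    per_round = var.per_round_rows(counts)
    if per_round.empty:
        raise InputError("count table has no per-round rows")
    if n_rounds is None:
        n_rounds = int(per_round["round"].max())

    k_all, n_all = var.grand_total(counts)
    p_hat, curve = spec.mle_transition_freq(per_round)
    pooled_ratio = spec.ratio_from_freq(p_hat)

    lineages = {}
    rng = np.random.default_rng(seed)
    for lid, grp in per_round.groupby("lineage_id", sort=True):
        by_round = dict(zip(grp["round"].astype(int), grp["n"].astype(int)))
        per_round_counts = [by_round.get(r, 0) for r in range(1, n_rounds + 1)]
        disp = spec.dispersion_test(
            per_round_counts, n_boot=n_boot, seed=rng.integers(2**31)
        )
        lk, ln = int(grp["k"].sum()), int(grp["n"].sum())
        p_l = lk / ln if ln else float("nan")
        lineages[str(lid)] = {
            "k": lk,
            "n": ln,
            "p_ti_mle": p_l,
            "tstv_ratio": spec.ratio_from_freq(p_l) if ln else None,
            "new_counts_per_round": per_round_counts,
            "dispersion": dataclasses.asdict(disp),
        }

    chisq = spec.transition_bias_chisq(per_round, null_p=null_p)

    ols_points = [
        (int(row.n), row.k / (row.n - row.k))
        for row in per_round.itertuples(index=False)
        if row.n > row.k  # rounds with zero transversions have no finite ratio
    ]
    try:
        ols = dataclasses.asdict(spec.ols_ratio_vs_load(ols_points))
    except (ParameterError, FitError) as exc:
        ols = {"error": str(exc), "n_points": len(ols_points)}

    report = {
        "pooled": {
            "k": k_all,
            "n": n_all,
            "p_ti_mle": p_hat,
            "tstv_ratio": pooled_ratio,
            "transition_percent": 100.0 * p_hat,
        },
        "lineages": lineages,
        "transition_bias_chisq": dataclasses.asdict(chisq),
        "ols_ratio_vs_load": ols,
        "generations": generations_summary(n_rounds),
        "null_p": null_p,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        with open(outdir / "spectrum.json", "w") as fh:
            json.dump(report, fh, indent=2)
        pd.DataFrame(
            {"p_ti": curve.p_grid, "normalized_likelihood": curve.likelihood}
        ).to_csv(outdir / "likelihood_curve.csv", index=False)
    report["likelihood_curve"] = curve
    return report


def run_pipeline(
    indir,
    outdir,
    threshold: float = 0.80,
    end_margin: int = 50,
    min_del_len: int = 100,
    null_p: float = 0.70,
    n_boot: int = 10_000,
    seed: int | None = None,
    make_plots: bool = False,
) -> dict:
    """Filter + classify + spectrum statistics, with a merged JSON report."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline: indir=%s seed=%s", indir, seed)
    filt = run_filter(
        indir, outdir, threshold=threshold, end_margin=end_margin, min_del_len=min_del_len
    )
    report = run_spectrum(
        filt.counts, outdir, null_p=null_p, n_boot=n_boot, seed=seed,
        n_rounds=filt.n_rounds,
    )
    curve = report.pop("likelihood_curve")
    report["consistency"] = filt.consistency
    report["n_deletions"] = {lid: len(d) for lid, d in filt.deletions.items()}
    report["n_records_removed"] = len(filt.removed)
    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    if make_plots:
        plot_report(report, curve, outdir)
    report["likelihood_curve"] = curve
    return report


def plot_report(report: dict, curve, outdir) -> None:
    """Advisory figures: per-round counts, variance vs Poisson, ratio vs
    load with the OLS fit, and the normalised likelihood curve."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    outdir = Path(outdir)
    fig, axes = plt.subplots(2, 2, figsize=(11, 8))

    ax = axes[0, 0]
    for lid, info in report["lineages"].items():
        ax.plot(
            range(1, len(info["new_counts_per_round"]) + 1),
            info["new_counts_per_round"],
            marker="o", label=lid,
        )
    ax.set(xlabel="selection round", ylabel="new mutations", title="Mutation accumulation")
    ax.legend(fontsize=6)

    ax = axes[0, 1]
    lids = list(report["lineages"])
    obs = [report["lineages"][l]["dispersion"]["variance"] for l in lids]
    exp = [report["lineages"][l]["dispersion"]["mean"] for l in lids]
    x = np.arange(len(lids))
    ax.bar(x - 0.2, obs, width=0.4, label="observed variance")
    ax.bar(x + 0.2, exp, width=0.4, label="Poisson expectation (=mean)")
    ax.set_xticks(x, lids, rotation=45, fontsize=6)
    ax.set(yscale="log", title="Over-dispersion of per-round counts")
    ax.legend(fontsize=7)

    ax = axes[1, 0]
    ols = report["ols_ratio_vs_load"]
    pts = [
        (n, k / (n - k))
        for l in report["lineages"].values()
        for n, k in [(l["n"], l["k"])]
        if n > k
    ]
    if pts:
        xs, ys = zip(*pts)
        ax.scatter(xs, ys)
    if "slope" in ols:
        xs_fit = np.linspace(min(xs), max(xs), 10)
        ax.plot(xs_fit, ols["intercept"] + ols["slope"] * xs_fit, "r-")
    ax.set(xlabel="mutation load", ylabel="ts/tv ratio", title="Bias vs load")

    ax = axes[1, 1]
    ax.plot(curve.p_grid, curve.likelihood)
    ax.set(xlabel="p_ti", ylabel="normalised likelihood", xlim=(0.8, 1.0),
           title="Binomial likelihood of transition frequency")

    fig.tight_layout()
    fig.savefig(outdir / "report.png", dpi=120)
    plt.close(fig)


# ---------------------------------------------------------------------------
# excision & qPCR stages
# ---------------------------------------------------------------------------


def run_excision(locus, outdir=None, primer_len: int = 20, max_len: int = 2000) -> dict:
    """Scar report, direct repeats, primer design and four-amplicon assay.

    ``locus`` is an :class:`AttLocus`, an :class:`AttLocusBundle`, or a
    path to a locus.json/bundle directory.
    """
    if isinstance(locus, AttLocusBundle):
        locus = locus.locus
    elif not isinstance(locus, AttLocus):
        locus = load_locus(locus)

    products = predict_excision(locus)
    window = 60
    left_junction = (
        locus.host_upstream[-window:] + locus.core_left + locus.element[:window]
    )
    right_junction = (
        locus.element[-window:] + locus.core_right + locus.host_downstream[:window]
    )
    repeats = find_direct_repeats(left_junction, right_junction, min_core=max(4, len(locus.core) // 2))

    primer_set = design_assay_primers(locus, primer_len=primer_len, max_len=max_len)
    states = {
        "integrated": assay_state(locus, primer_set),
        "excised": assay_state(products, primer_set),
        "mixed": assay_state([locus, products], primer_set),
    }
    amplicons = []
    for name, (seq, circ) in primer_set.references.items():
        for amp in insilico_pcr(seq, circ, *primer_set.pairs[name], max_len, name):
            amplicons.append(dataclasses.asdict(amp))

    report = {
        "scar": {
            "scar_length": products.scar_length,
            "frameshift": products.frameshift,
            "premature_stop_codon_position": products.premature_stop_codon_position,
            "wildtype_stop_codon_position": products.wildtype_stop_codon_position,
        },
        "top_repeat": dataclasses.asdict(repeats[0]) if repeats else None,
        "assay_states": states,
        "amplicons": amplicons,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        aio.write_fasta(
            outdir / "products.fasta",
            {"attB": products.attB_sequence, "attP": products.attP_sequence},
        )
        with open(outdir / "scar.json", "w") as fh:
            json.dump(report["scar"], fh, indent=2)
        pd.DataFrame(amplicons).to_csv(outdir / "amplicons.csv", index=False)
        with open(outdir / "assay.json", "w") as fh:
            json.dump(states, fh, indent=2)
    return report


def run_qpcr(plate, outdir=None) -> dict:
    """Excision frequencies per phase plus the paired phase comparison."""
    if not isinstance(plate, pd.DataFrame):
        plate = aio.read_qpcr_csv(plate)
    result = q.excision_frequency(plate)
    report: dict = {
        "phases": {
            phase: dataclasses.asdict(summary)
            for phase, summary in result.summaries.items()
        },
        "curves": {t: dataclasses.asdict(c) for t, c in result.curves.items()},
    }
    phases = result.summaries
    if "exponential" in phases and "stationary" in phases:
        fe = phases["exponential"].frequencies
        fs = phases["stationary"].frequencies
        if len(fe) == len(fs) and len(fe) >= 2:
            comp = q.phase_comparison(fe, fs)
            report["phase_comparison"] = dataclasses.asdict(comp)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        result.per_replicate.to_csv(outdir / "frequencies.csv", index=False)
        with open(outdir / "qpcr_stats.json", "w") as fh:
            json.dump(report, fh, indent=2, default=_json_safe)
    return report


def _json_safe(x):
    if isinstance(x, float) and (math.isnan(x) or math.isinf(x)):
        return str(x)
    raise TypeError(f"not JSON serialisable: {type(x)}")
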