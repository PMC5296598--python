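"""Filter variants and compute the mutation-spectrum statistics.

Runs the full analysis on the bundle from 01_simulate_study.py: keep fixed
SNPs (>80% of reads), drop contig-end and in-deletion calls, check lineage
continuity, classify each new SNP, then fit the binomial maximum-likelihood
transition frequency and test for Poisson over-dispersion.
"""

from pathlib import Path

from attmut.pipeline import run_pipeline

BUNDLE = Path("scratch/example_bundle")
OUT = Path("scratch/example_report")

if not BUNDLE.exists():
    raise SystemExit("run examples/01_simulate_study.py first")

report = run_pipeline(BUNDLE, OUT, n_boot=2000, seed=1)

pooled = report["pooled"]
print(f"pooled transitions: {pooled['k']}/{pooled['n']} SNPs")
print(f"ML transition frequency p_ti = {pooled['p_ti_mle']:.4f} "
      f"(ts/tv ratio {pooled['tstv_ratio']:.1f})")
chi = report["transition_bias_chisq"]
print(f"transition bias vs wild-type null: chi2={chi['chi2']:.1f} "
      f"df={chi['df']} p={chi['p_value']:.3g}")
for lineage, info in report["lineages"].items():
    d = info["dispersion"]
    print(f"  {lineage}: n={info['n']:4d}  dispersion index={d['index']:6.1f} "
          f"(bootstrap p={d['p_value']:.4f})")
print(
    "\nA ts/tv ratio far above the wild-type 2-3 is the mismatch-repair-loss\n"
    "signature; dispersion indices >> 1 show mutations arriving in bursts\n"
    "rather than at the steady Poisson rate a constant mutator would give."
)
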