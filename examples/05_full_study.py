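"""Run the complete study pipeline on synthetic data.

Generates a 120-species study (tree, Red List census, threat traits,
source trees), then runs every stage — polytomy resolutions, EDGE ranking,
signal tests, trait contrasts, PD-loss scenarios, imbalance — and prints
the headline numbers from the machine-readable summary.
"""

from coraledge.pipeline import RunConfig, run_study
from coraledge.synth import SyntheticStudyConfig

config = RunConfig(
    outdir="scratch/example_study",
    seed=99,
    synthetic=SyntheticStudyConfig(n_species=120, seed=99),
    n_resolutions=100,
    n_null=500,
    n_signal_resolutions=5,
    n_signal_null=499,
    top_k=10,
)
summary = run_study(config)

print(f"species: {summary['n_species']}")
props = summary["category_proportions"]
print(
    f"threatened among assessed: {props['threatened_pct_of_assessed']}% "
    f"(n = {props['n_assessed']})"
)
print("top 5 EDGE species:", ", ".join(summary["edge"]["top_species"][:5]))
k = summary["signal"]["K_extinction_probability"]
print(f"K of extinction probability: {k['mean']:.2g} (p = {k['p_vs_random']:.2f})")
for row in summary["signal"]["D_table"][:4]:
    print(
        f"D[{row['trait']}] = {row['D_mean']:.2f} +/- {row['D_sd']:.2f} "
        f"(p D=0: {row['p_D_is_0']:.3f}, p D=1: {row['p_D_is_1']:.3f})"
    )
for row in summary["pd_loss"]:
    print(
        f"PD loss {row['scenario']}: {row['direction']} than random "
        f"(t-test p = {row['p_value']:.2g})"
    )
print(f"outputs written to {config.outdir}/ (TSV tables + summary.json)")
# Categories are assigned without phylogenetic signal, so K is near zero
# and threat-level D values sit near 1, while the clumped threat traits
# come out near D = 0 — the structure the generator was asked to build.
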