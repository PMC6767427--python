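"""Desk-scale simulation study of estimator performance.

Simulates replicate datasets whose truth (partition, event times, sizes) is
drawn from the priors, analyzes each with the MCMC sampler, and reports the
accuracy metrics of the performance figures: RMSE of divergence-time
estimates, 95% credible-interval coverage, and the confusion of true versus
estimated numbers of events -- for the all-sites analysis and the
one-SNP-per-locus analysis side by side.

Usage: python analysis/02_simulation_study.py [n_replicates] [seed]
(defaults: 20 replicates, seed 1; the full 100-replicate study runs in the
test suite).
"""

import sys
import time
from pathlib import Path

import numpy as np
import pandas as pd

from codivergence.mcmc import McmcSettings, run_chains
from codivergence.priors import default_priors
from codivergence.simulate import SimulationTemplate, replicate_seed, simulate_replicate
from codivergence.summarize import ReplicateResult, performance_report, summarize_traces

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

N_REPLICATES = int(sys.argv[1]) if len(sys.argv) > 1 else 20
SEED = int(sys.argv[2]) if len(sys.argv) > 2 else 1

PRIORS = default_priors("cyrtodactylus-default", "mean-five-events")
TEMPLATE = SimulationTemplate.uniform(4, 500, 100, (4, 4))
SETTINGS = dict(generations=800, sample_interval=1, burn_in=150, n_chains=1)


def run_arm(snp_only: bool) -> tuple:
    results = []
    for r in range(N_REPLICATES):
        seed = replicate_seed(SEED, r)
        rep = simulate_replicate(TEMPLATE, PRIORS, seed=seed, snp_only=snp_only)
        data = [d for d in rep.data if d.n_loci > 0]
        if len(data) < len(rep.data):  # a comparison lost every locus to the filter
            continue
        traces = run_chains(data, PRIORS, McmcSettings(seed=seed + 1, **SETTINGS))
        summary = summarize_traces(traces)
        t = summary.time_summaries
        results.append(
            ReplicateResult(
                true_times=rep.comparison_times,
                true_k=rep.k,
                post_mean_times=t["mean"].to_numpy(),
                ci_low=t["ci_low"].to_numpy(),
                ci_high=t["ci_high"].to_numpy(),
                posterior_num_events=summary.posterior_num_events,
            )
        )
    return performance_report(results), results


def main() -> None:
    rows = []
    for snp_only, name in ((False, "all sites"), (True, "one SNP per locus")):
        t0 = time.time()
        report, results = run_arm(snp_only)
        eligible = [r for r in results if r.true_k < 4]
        overshoot = sum(
            1 for r in eligible if int(np.argmax(r.posterior_num_events)) + 1 == 4
        )
        rows.append(
            {
                "arm": name,
                "replicates": report.n_replicates,
                "rmse": report.rmse,
                "coverage_95ci": report.coverage,
                "overshoot_to_all_independent": f"{overshoot}/{len(eligible)}",
            }
        )
        report.confusion.to_csv(
            OUT / f"confusion_{'snp' if snp_only else 'all_sites'}.tsv", sep="\t"
        )
        print(
            f"{name}: {report.n_replicates} replicates, RMSE {report.rmse:.2e}, "
            f"p(t in 95% CI) {report.coverage:.3f}, overshoot to k=4 "
            f"{overshoot}/{len(eligible)} ({time.time() - t0:.0f}s)"
        )
        print(report.confusion.to_string(), "\n")
    table = pd.DataFrame(rows)
    table.to_csv(OUT / "simulation_performance.tsv", sep="\t", index=False)
    print(
        "notes: with all linked sites analyzed, credible intervals are "
        "narrower than the information content of the ~500 independent gene "
        "trees warrants, so interval coverage falls below the nominal rate "
        "while point estimates remain accurate. The one-SNP-per-locus arm is "
        "analyzed with the same unconditioned likelihood (conditioning on "
        "variable-only sampling is deliberately not implemented), so feeding "
        "it variable-only data grossly inflates divergence-time and size "
        "estimates -- the reason the all-sites analysis is preferred. See "
        "docs/methods.md."
    )


if __name__ == "__main__":
    main()
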