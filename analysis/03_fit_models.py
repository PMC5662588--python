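#!/usr/bin/env python
"""Fit the empty and full animal models on the simulated census fixture.

Runs the whole pipeline (cleaning, filtering, both Gibbs fits) on the
fixture from 01_simulate_census.py, prints the posterior summaries next to
the generating truth, and writes the rendered report plus draws under
results/03_model_fit/.
"""

import argparse
from pathlib import Path

from pedherit.model import MCMCConfig
from pedherit.pipeline import RunConfig, run_analysis
from pedherit.simulate import read_truth

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--fixture", type=Path, default=ROOT / "scratch" / "census")
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--burn-in", type=int, default=2_000)
    ap.add_argument("--iterations", type=int, default=10_000)
    ap.add_argument("--thin", type=int, default=20)
    args = ap.parse_args()

    out_dir = ROOT / "results" / "03_model_fit"
    cfg = RunConfig(
        pedigree_path=str(args.fixture / "pedigree.tsv"),
        scores_path=str(args.fixture / "scores.csv"),
        covariates_path=str(args.fixture / "covariates.csv"),
        mcmc=MCMCConfig(burn_in=args.burn_in, iterations=args.iterations,
                        thin=args.thin, seed=args.seed),
        out_dir=str(out_dir),
        report_format="json",
    )
    report = run_analysis(cfg)
    truth = read_truth(args.fixture / "truth.json")

    print(f"N (empty model) = {report.n_empty}, N (full model) = {report.n_full}")
    for label, s in [("empty", report.empty_summary), ("full", report.full_summary)]:
        print(
            f"{label:>5} model: sigma2_A = {s.mean('sigma2_A'):6.2f} "
            f"({s.sd('sigma2_A'):.2f}), sigma2_E = {s.mean('sigma2_E'):6.2f} "
            f"({s.sd('sigma2_E'):.2f}), h2 = {s.mean('h2'):.3f} ({s.sd('h2'):.3f})"
        )
    print(f"generating truth: h2 = {truth.h2:.3f} "
          f"(sigma2_A = {truth.sigma2_A}, sigma2_E = {truth.sigma2_E})")
    if report.explained_points is not None:
        print(
            f"variance explained by covariates: {report.explained_points:.2f} "
            f"points ({report.explained_percent:.1f}%)"
        )
    print(f"full report written to {out_dir}")


if __name__ == "__main__":
    main()
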