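#!/usr/bin/env python
"""Probabilistic sensitivity analysis with acceptability curves.

Samples all uncertain parameters jointly from their distributions
(triangular/beta/gamma per parameter), evaluates every strategy on
each common draw, and summarizes uncertainty two ways: the probability
each screening strategy is cost-effective versus no screening, and the
probability each strategy (including no screening) is optimal among
all competitors, both as functions of willingness to pay from 0 to
three times China's 2019 per-capita GDP.

Outputs: results/ceac_vs_no_screening.csv,
         results/ceac_probability_optimal.csv
(plots, if matplotlib is available, go under scratch/figures/)
"""

import argparse
from pathlib import Path

import pandas as pd

from ugicea.cea import DEFAULT_GDP_PER_CAPITA
from ugicea.reporting import write_csv_with_metadata
from ugicea.runner import AGE_BANDS, make_runner
from ugicea.sensitivity import (ceac_vs_comparator, default_wtp_grid,
                                prob_optimal, run_psa)
from ugicea.synthetic import default_parameter_set

ROOT = Path(__file__).resolve().parents[1]


def maybe_plot(ceac: pd.DataFrame, optimal: pd.DataFrame) -> None:
    try:
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError:
        return
    fig_dir = ROOT / "scratch" / "figures"
    fig_dir.mkdir(parents=True, exist_ok=True)
    for frame, fname, title in (
            (ceac, "ceac_vs_no_screening.png",
             "P(cost-effective vs no screening)"),
            (optimal, "ceac_probability_optimal.png", "P(optimal)")):
        bands = sorted(frame.age_band.unique())
        fig, axes = plt.subplots(2, 3, figsize=(13, 7), sharey=True)
        for ax, band in zip(axes.ravel(), bands):
            sub = frame[frame.age_band == band]
            for name, grp in sub.groupby("strategy"):
                ax.plot(grp.wtp, grp.probability, label=name, lw=1.2)
            ax.axvline(DEFAULT_GDP_PER_CAPITA, ls="--", c="b", lw=0.8)
            ax.axvline(3 * DEFAULT_GDP_PER_CAPITA, ls="--", c="k",
                       lw=0.8)
            ax.set_title(band)
            ax.set_xlabel("WTP ($/QALY)")
        axes[0, 0].set_ylabel("probability")
        axes[0, 0].legend(fontsize=7)
        fig.suptitle(title)
        fig.tight_layout()
        fig.savefig(fig_dir / fname, dpi=120)
        plt.close(fig)
        print(f"figure: {fig_dir / fname}")


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--n-draws", type=int, default=500)
    parser.add_argument("--seed", type=int, default=20210630)
    args = parser.parse_args()

    pset = default_parameter_set()
    wtp = default_wtp_grid(DEFAULT_GDP_PER_CAPITA)
    ceac_frames, opt_frames = [], []
    for i, (band, age) in enumerate(AGE_BANDS.items()):
        runner = make_runner(pset, age)
        samples = run_psa(pset.distributions, runner, args.n_draws,
                          args.seed + i)
        ceac = ceac_vs_comparator(samples, "no_screening", wtp)
        opt = prob_optimal(samples, wtp)
        for frame, sink in ((ceac, ceac_frames), (opt, opt_frames)):
            frame.insert(0, "age_band", band)
            sink.append(frame)
        at_gdp = ceac[abs(ceac.wtp - DEFAULT_GDP_PER_CAPITA) ==
                      abs(ceac.wtp - DEFAULT_GDP_PER_CAPITA).min()]
        print(f"{band}: P(cost-effective vs none) at 1x GDP "
              f"{at_gdp.probability.min():.2f}-"
              f"{at_gdp.probability.max():.2f}")

    md = {"analysis": "probabilistic sensitivity analysis",
          "n_draws": str(args.n_draws), "seed": str(args.seed),
          "parameter_source": pset.source}
    ceac_all = pd.concat(ceac_frames, ignore_index=True)
    opt_all = pd.concat(opt_frames, ignore_index=True)
    write_csv_with_metadata(ceac_all,
                            ROOT / "results" / "ceac_vs_no_screening.csv",
                            md)
    write_csv_with_metadata(
        opt_all, ROOT / "results" / "ceac_probability_optimal.csv", md)
    print("wrote CEAC tables under results/")
    maybe_plot(ceac_all, opt_all)


if __name__ == "__main__":
    main()
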