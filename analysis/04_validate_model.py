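"""Simulation-based validation of the final covariate model.

Runs the visual predictive check and the normalized prediction
distribution errors against the synthetic trial, then refits the final
covariate structure to obtain the reference estimates and runs a (scaled)
bootstrap, reporting whether the reference estimates fall inside the
bootstrap interquartile ranges.
"""

import argparse
import json
import pathlib

import numpy as np
import pandas as pd

from txapk import data, diagnostics, saem, trial


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-bootstrap", type=int, default=50)
    ap.add_argument("--n-sim", type=int, default=500)
    ap.add_argument("--out", type=pathlib.Path, default=pathlib.Path("results"))
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    csv = args.out / "trial.csv"
    dataset = data.read_dataset(csv) if csv.exists() else trial.generate_trial(seed=args.seed)[0]
    model = trial.final_model()

    v = diagnostics.vpc(dataset, model, n_sim=args.n_sim, seed=args.seed)
    pd.DataFrame({
        "time": v.bin_times,
        "obs_p10": v.observed[0], "obs_p50": v.observed[1], "obs_p90": v.observed[2],
        "band_p50_lo": v.band_lo[1], "band_p50_hi": v.band_hi[1],
    }).to_csv(args.out / "vpc.csv", index=False)
    print(f"VPC ({v.n_simulations} simulations): {100 * v.coverage():.0f}% of "
          "observed percentile points inside their prediction bands -> vpc.csv")

    n = diagnostics.npde(dataset, model, n_sim=args.n_sim, seed=args.seed + 1)
    npde_summary = {
        "mean": float(n.npde.mean()), "variance": float(n.npde.var()),
        "shapiro_plasma": n.shapiro_plasma, "shapiro_urine": n.shapiro_urine,
        "outside90_plasma_pct": 100 * n.outside90_plasma,
        "outside90_urine_pct": 100 * n.outside90_urine,
    }
    with open(args.out / "npde_summary.json", "w") as fh:
        json.dump(npde_summary, fh, indent=1)
    print(f"NPDE: mean {npde_summary['mean']:+.3f}, variance "
          f"{npde_summary['variance']:.3f} (N(0,1) expected under the true model); "
          f"outside the 90% interval: plasma {npde_summary['outside90_plasma_pct']:.1f}%, "
          f"urine {npde_summary['outside90_urine_pct']:.1f}%")

    # reference fit of the final structure to this dataset, then bootstrap
    ref_settings = saem.SaemSettings(n_explore=300, n_smooth=150, n_chains=5,
                                     seed=args.seed + 3, compute_ll=False,
                                     compute_fim=False)
    ref_fit = saem.saem_fit(dataset, model, ref_settings)
    rm = ref_fit.model
    reference = {"theta_CL": rm.theta["CL"], "beta_CL_ECLCR_bef": rm.betas[0][1],
                 "theta_V1": rm.theta["V1"], "beta_V1_BWBEF": rm.betas[1][1],
                 "theta_Q": rm.theta["Q"], "theta_V2": rm.theta["V2"],
                 "theta_p_urine": rm.theta["p_urine"]}
    b = diagnostics.bootstrap(dataset, rm, n_rep=args.n_bootstrap,
                              seed=args.seed + 2)
    rows, inside = [], 0
    for key, ref_val in reference.items():
        med, q1, q3 = b.table[key]
        ok = q1 <= ref_val <= q3
        inside += ok
        rows.append({"parameter": key, "reference_fit": ref_val,
                     "boot_median": med, "q1": q1, "q3": q3, "inside_iqr": ok})
    pd.DataFrame(rows).to_csv(args.out / "bootstrap.csv", index=False)
    print(f"bootstrap ({b.n_converged}/{b.n_requested} converged): reference-fit "
          f"estimates inside (Q1;Q3) for {inside}/{len(reference)} population "
          "parameters -> bootstrap.csv")

    try:  # optional VPC figure
        import matplotlib
        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        fig, ax = plt.subplots(figsize=(6, 4))
        ax.fill_between(v.bin_times, v.band_lo[1], v.band_hi[1], alpha=0.3,
                        label="50th percentile band")
        for j, lab in ((0, "p10"), (1, "p50"), (2, "p90")):
            ax.plot(v.bin_times, v.observed[j], "o-", label=f"observed {lab}")
        ax.set_xlabel("time (min)")
        ax.set_ylabel("plasma TXA (mg/L)")
        ax.set_yscale("log")
        ax.legend(fontsize=8)
        fig.tight_layout()
        fig.savefig(args.out / "vpc.png", dpi=120)
        print("VPC figure -> vpc.png")
    except ImportError:
        pass


if __name__ == "__main__":
    main()
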