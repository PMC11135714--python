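#!/usr/bin/env python
"""The study-level statistics on synthetic cohorts, with figures.

Four analyses over per-recording summaries:
  1. volume-vs-mass validation — measured daily volume against daily mass
     change when video captures only part of each day's feeding (slope < 1);
  2. behavior comparison — Mann-Whitney U on median drinking rate between
     an extended-proboscis group and a slower curled-proboscis group;
  3. submergence-vs-rate regression on a null cohort (no true dependence),
     full and restricted to depths <= 10 mm;
  4. type-I error / power calibration of that regression across 20 seeds.

Writes results/stats/report.json and PNG figures.
"""

import json
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from nectartrack.stats import (
    linear_regression,
    mann_whitney_u,
    null_effect_experiment,
    simulate_daily_intake,
    simulate_study,
    volume_vs_mass,
)

OUT = Path("results/stats")


def fig_volume_vs_mass(report: dict) -> None:
    df = simulate_daily_intake(n_days=24, seed=6)
    reg, all_le = volume_vs_mass(df["volume_ml"], df["mass_change_ml"])
    report["volume_vs_mass"] = {
        "slope": reg.slope, "r": reg.r, "p": reg.p_value,
        "never_overestimates": all_le, "n_days": reg.n,
    }
    xq = np.linspace(0, df["mass_change_ml"].max(), 50)
    lo, hi = reg.band(xq, df["mass_change_ml"].to_numpy())
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(df["mass_change_ml"], df["volume_ml"], s=18)
    ax.plot(xq, reg.predict(xq), "b-")
    ax.fill_between(xq, lo, hi, alpha=0.25)
    ax.plot(xq, xq, "k--", lw=1, label="1:1")
    ax.set_xlabel("daily mass change (mL equiv.)")
    ax.set_ylabel("measured daily volume (mL)")
    ax.set_title(f"volume vs mass: R={reg.r:.2f}, p={reg.p_value:.2g}, slope={reg.slope:.2f}")
    ax.legend()
    fig.tight_layout()
    fig.savefig(OUT / "volume_vs_mass.png", dpi=120)
    plt.close(fig)


def fig_behavior_groups(report: dict) -> None:
    rng = np.random.default_rng(3)
    extended = simulate_study(12, 0.0, seed=20)["median_rate_ml_s"].to_numpy()
    # curled-proboscis bouts drink at a fraction of the extended-proboscis rate
    curled = simulate_study(5, 0.0, seed=21, base_rate_range=(5e-5, 3e-4))[
        "median_rate_ml_s"
    ].to_numpy()
    mw = mann_whitney_u(extended, curled)
    report["extended_vs_curled"] = {"U": mw.statistic, "p": mw.p_value, "n": list(mw.n)}
    fig, ax = plt.subplots(figsize=(4.5, 4))
    ax.violinplot([extended * 1e3, curled * 1e3], showmedians=True)
    ax.set_xticks([1, 2], ["extended", "curled"])
    ax.set_ylabel("median drinking rate (uL/s)")
    ax.set_title(f"Mann-Whitney p = {mw.p_value:.2g}")
    fig.tight_layout()
    fig.savefig(OUT / "behavior_groups.png", dpi=120)
    plt.close(fig)


def fig_submergence_regression(report: dict) -> None:
    res = null_effect_experiment(38, 0.0, seed=5)
    full, restricted, df = res["full"], res["restricted"], res["summaries"]
    report["submergence_vs_rate_null_cohort"] = {
        "r": full.r, "p": full.p_value, "n": full.n,
        "restricted_le_10mm": None
        if restricted is None
        else {"r": restricted.r, "p": restricted.p_value, "n": restricted.n},
    }
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(df["median_sub_mm"], df["median_rate_ml_s"] * 1e3, s=18)
    xq = np.linspace(df["median_sub_mm"].min(), df["median_sub_mm"].max(), 50)
    lo, hi = full.band(xq, df["median_sub_mm"].to_numpy())
    ax.plot(xq, full.predict(xq) * 1e3, "b-")
    ax.fill_between(xq, lo * 1e3, hi * 1e3, alpha=0.25)
    ax.set_xlabel("median proboscis submergence (mm)")
    ax.set_ylabel("median drinking rate (uL/s)")
    ax.set_title(f"null cohort: R={full.r:.2f}, p={full.p_value:.2g}")
    fig.tight_layout()
    fig.savefig(OUT / "submergence_vs_rate.png", dpi=120)
    plt.close(fig)


def calibration(report: dict) -> None:
    null_p = [null_effect_experiment(30, 0.0, seed=s)["full"].p_value for s in range(20)]
    power_p = [
        null_effect_experiment(30, 1e-4, seed=100 + s, base_rate_range=(9e-4, 1.1e-3))[
            "full"
        ].p_value
        for s in range(20)
    ]
    report["regression_calibration"] = {
        "null_rejection_fraction": float(np.mean(np.array(null_p) < 0.05)),
        "power_rejection_fraction": float(np.mean(np.array(power_p) < 0.05)),
        "n_seeds": 20,
    }


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    report: dict = {}
    fig_volume_vs_mass(report)
    fig_behavior_groups(report)
    fig_submergence_regression(report)
    calibration(report)
    (OUT / "report.json").write_text(json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))


if __name__ == "__main__":
    main()
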