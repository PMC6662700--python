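# eetolab

Explore–exploit strategy analysis for fishing-fleet movement data.

Commercial fishing vessels face a classic explore–exploit trade-off
(EETO): keep returning to known, productive grounds, or spend time and
fuel sampling new ones to keep their information about a shifting resource
up to date. `eetolab` quantifies that trade-off from vessel-monitoring
(VMS) position tracks and trip-level logbook revenue, and asks whether a
history of exploration buffers a vessel's revenue when a spatial closure
abruptly removes part of its fishing grounds.

The package is written for quantitative ecologists and fisheries
scientists. Because real VMS/logbook data are confidential, it ships with
a seeded synthetic fleet generator that emulates the structure of such
data — heterogeneous vessels, hourly pings alternating port/transit/
fishing, seasonal fleet-wide revenue variation, observer-labeled trips,
and an abrupt closure of the most-used grounds — so the entire pipeline is
reproducible and testable end to end.

## The method in brief

1. **Tracks → activity.** Pings are cleaned (extent filter; iterative
   deletion of arrival speeds > 20 m/s derived from rhumb-line distances),
   movement features derived, and each ping classified fishing / transit /
   port by a random forest validated on held-out observer-labeled trips
   (fishing vs non-fishing *balanced accuracy* = (TPR + TNR)/2).
2. **Activity → strategy.** Fishing pings are rasterized on a 30 × 30
   grid; consecutive same-cell pings collapse into visit bouts, giving
   each vessel a chronological visitation series **L**ᵢ. Two metrics
   summarize strategy: cumulative **choice entropy**
   *S*ᵢₘ = −Σⱼ *f*ᵢ(*j*) log₂ *f*ᵢ(*j*) (scored as the post-burn-in
   trajectory mean *S*) and **patch residence time** (mean bout duration).
   **Displacement** is the fraction of pre-closure fished cells inside the
   closure polygon.
3. **Revenue → deviance.** Undisturbed trip revenue is modeled as
   *Ru*ᵢₜ = *P*ᵢ + β₁*D*ᵢₜ + β₂*F*₋ᵢₜ + ε with vessel fixed effects,
   trip duration *D*, and the leave-one-out fleet index *F*₋ᵢₜ (mean
   revenue of other vessels' trips landing within 14 days after trip
   *t*). For disturbed trips, *Md*ᵢₜ = *Rd*ᵢₜ − β̂₁*D* − β̂₂*F* and the
   standardized deviance ΔP = *Md*/*Ed* − 1 is centred on zero under
   business as usual.
4. **Deviance → inference.** ΔP is regressed on standardized strategy
   covariates (S, S², prt, prt², activity, length, displacement) with a
   per-vessel random intercept; AIC/BIC backward selection respects the
   linear/quadratic hierarchy; a growing-window analysis (nested 10-day
   increments to day 50) traces how the entropy and displacement effects
   dissipate after the closure.

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import json
from pathlib import Path
from eetolab.config import RunConfig, FleetConfig
from eetolab.pipeline import run

cfg = RunConfig(
    fleet=FleetConfig(n_vessels=30, undisturbed_days=180, disturbed_days=50, seed=42),
    min_bouts=10,
    seed=42,
)
run("all", cfg, "demo")

summary = json.loads(Path("demo/model_summary.json").read_text())
report = json.loads(Path("demo/classifier_report.json").read_text())
print(f"balanced accuracy: {report['balanced_accuracy']:.3f}")
und = summary["undisturbed"]
print(f"beta_duration: {und['beta_duration']:.1f}  beta_fleet: {und['beta_fleet']:.3f}")
shift = summary["fleet_shift"]["entropy"]
print(f"fleet entropy before vs during: {shift['mean_before']:.2f} -> {shift['mean_during']:.2f} "
      f"(F={shift['F']:.2f}, p={shift['p']:.3f})")
eq6 = {row["term"]: row for row in summary["eq6"]["table"]}
print(f"deviance ~ entropy: {eq6['S_z']['estimate']:+.3f}  "
      f"displacement: {eq6['displacement_z']['estimate']:+.3f}")
```

prints

```
balanced accuracy: 1.000
beta_duration: 798.9  beta_fleet: 0.107
fleet entropy before vs during: 2.79 -> 2.50 (F=0.90, p=0.348)
deviance ~ entropy: +0.115  displacement: -0.041
```

Reading the output: the activity classifier separates the synthetic speed
regimes perfectly on held-out observer trips; the revenue model recovers
the generator's 800/day duration effect (the fleet coefficient is
attenuated because the empirical leave-one-out index is a noisy proxy for
the latent fleet factor, especially in a 30-vessel demo); and during the
closure, deviance in performance rises with choice entropy (+0.115 per SD)
and falls with displacement (−0.041 per SD) — broad explorers lost less.
At this reduced demo scale the before/during entropy shift is not
significant: the closure period is short, so during-period entropy
trajectories are far from their plateaus. The multi-seed behaviour of
every headline property at the default scale (100 vessels) is exercised in
`tests/test_acceptance.py`.

The same pipeline is scriptable from the shell:

```sh
eetolab all --seed 42 --outdir demo          # or: simulate / process / metrics / model / windows
```

Each stage writes plain-text artifacts (`pings.csv`, `classified_pings.csv`,
`profiles.csv`, `deviance.csv`, `growing_window.csv`, model summaries as
JSON) stamped with the config hash and seed; rerunning with the same
configuration reproduces byte-identical outputs.

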