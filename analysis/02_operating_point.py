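#!/usr/bin/env python
"""Pin the measurement-error scale at the reference operating point.

The unimodal scenario fixes the latent trait X ~ Normal(mu, 1) with
disease defined by X >= 7 and mu chosen so that 20% of the population is
diseased.  The single free parameter of the measurement model — the
additive Gaussian error sd — is then calibrated so the analytic
specificity is exactly 95%.  The resulting sensitivity (85% to the
nearest percent) defines the reference operating point used by the
prevalence sweeps in the next script.

Writes results/operating_point.csv.
"""

from pathlib import Path

import pandas as pd

from spectrum_effect import (
    MeasurementModel,
    analytic_test_performance,
    calibrate_error_sd,
    percent,
    scenario1_model,
)


def main() -> None:
    pop = scenario1_model(0.20)
    sigma_e = calibrate_error_sd(pop, "specificity", 0.95)
    perf = analytic_test_performance(pop, MeasurementModel(sigma_e))
    print(f"population mean for 20% prevalence: {pop.components[0].mean:.6f}")
    print(f"calibrated error sd: {sigma_e:.6f}")
    print(
        f"operating point: sensitivity {perf.sensitivity:.4f} "
        f"({percent(perf.sensitivity):.0f}%), specificity {perf.specificity:.4f} "
        f"({percent(perf.specificity):.0f}%)"
    )
    out = Path(__file__).resolve().parents[1] / "results" / "operating_point.csv"
    out.parent.mkdir(exist_ok=True)
    pd.DataFrame(
        [
            {
                "trait_mean": pop.components[0].mean,
                "error_sd": sigma_e,
                **perf.as_dict(),
            }
        ]
    ).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
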