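#!/usr/bin/env python
"""Why predictive values only partly travel between settings.

A clinician reads two evaluations of the same test for bacterial
infection: a hospital case-control study reporting 97%/97% sensitivity/
specificity, and a general-population cross-sectional study reporting
72%/92%.  Applying each report's accuracy at the 10% primary-care
prevalence gives very different post-test probabilities for a positive
result — 78% versus 50% — even though the prevalence adjustment itself
is done correctly in both cases.  The discrepancy is the spectrum
effect: the accuracy pair itself depends on the study population.

Writes results/bayes_worked_example.csv.
"""

from pathlib import Path

import pandas as pd

from spectrum_effect import percent, post_test_probability, predictive_values_at_prevalence

PREVALENCE = 0.10
REPORTS = {
    "hospital case-control": (0.97, 0.97),
    "population cross-sectional": (0.72, 0.92),
}


def main() -> None:
    rows = []
    for label, (sens, spec) in REPORTS.items():
        ppv, npv = predictive_values_at_prevalence(sens, spec, PREVALENCE)
        upd = post_test_probability(PREVALENCE, sens / (1 - spec))
        assert abs(upd.posttest_prob - ppv) < 1e-12  # odds path agrees
        rows.append(
            {
                "report": label,
                "sensitivity": sens,
                "specificity": spec,
                "prevalence": PREVALENCE,
                "lr_pos": sens / (1 - spec),
                "ppv": ppv,
                "npv": npv,
                "ppv_percent": percent(ppv),
            }
        )
        print(
            f"{label}: sens {sens:.0%}, spec {spec:.0%} at prevalence "
            f"{PREVALENCE:.0%} -> post-test probability {percent(ppv):.0f}%"
        )
    out = Path(__file__).resolve().parents[1] / "results" / "bayes_worked_example.csv"
    out.parent.mkdir(exist_ok=True)
    pd.DataFrame(rows).to_csv(out, index=False)
    print(f"wrote {out}")


if __name__ == "__main__":
    main()
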