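"""Replay the reference clinical cohort's reported summary statistics.

The original dual-planning cohort's raw DVHs are not public, but its gain
counts and univariable fits are; two pipeline operations take exactly those
as input.  This driver recomputes (a) the exact binomial confidence
intervals from the gain counts and (b) the prone-better cutoffs from the
fitted lines, and prints them next to nothing — the point is that they come
out of the same code paths the synthetic analysis uses.  Writes
results/reference_checks.json.
"""

import json
import pathlib
import sys

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from dosegain.datasets import CLINICAL_FITS, CLINICAL_GAIN_COUNTS
from dosegain.gain import exact_binomial_ci, two_proportion_test
from dosegain.predictors import RegressionResult, cutoff_from_fit, round_printed

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    out = {"intervals": {}, "cutoffs": {}}
    print("exact binomial 95% CIs from the reference gain counts:")
    for key, (k, n) in CLINICAL_GAIN_COUNTS.items():
        prop, lo, hi = exact_binomial_ci(k, n)
        out["intervals"][key] = {
            "successes": k, "n": n,
            "percent": round_printed(100 * prop, 1),
            "ci_low": round_printed(100 * lo, 1),
            "ci_high": round_printed(100 * hi, 1),
        }
        print(f"  {key:28s} {k:3d}/{n:3d} -> {100 * prop:5.1f}% "
              f"({100 * lo:.1f}-{100 * hi:.1f}%)")
    k1, n1 = CLINICAL_GAIN_COUNTS["type1_supine_below_2"]
    k2, n2 = CLINICAL_GAIN_COUNTS["type1_supine_at_least_2"]
    p = two_proportion_test((k1, n1), (k2, n2))
    out["subgroup_contrast_p"] = p
    print(f"  subgroup contrast (Fisher exact): p = {p:.2g}")

    print("prone-better cutoffs -intercept/coefficient from the reference fits:")
    for fit in CLINICAL_FITS:
        res = cutoff_from_fit(
            RegressionResult(fit.name, fit.intercept, fit.coefficient,
                             fit.coefficient_sd, 116,
                             abs(fit.coefficient / fit.coefficient_sd) > 1.96)
        )
        sign = ">" if res.direction == "greater_better" else "<"
        value = round_printed(res.cutoff, fit.cutoff_decimals)
        out["cutoffs"][fit.name] = {"cutoff": value, "direction": res.direction,
                                    "unit": fit.unit}
        print(f"  {fit.name:26s} prone better {sign}{value:g} {fit.unit}")

    ROOT.mkdir(parents=True, exist_ok=True)
    with open(ROOT / "reference_checks.json", "w") as fh:
        json.dump(out, fh, indent=2, sort_keys=True)


if __name__ == "__main__":
    main()
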