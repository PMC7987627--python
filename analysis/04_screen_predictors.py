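"""Univariable predictor screen of the penalty difference.

Merges the characteristics table with the type-1 paired scores, fits one
Huber robust regression per characteristic (with the FP1 nonlinearity
check), extracts prone-better cutoffs, and repeats the fits with the three
planted outliers removed.  Writes results/predictor_screen.csv and
results/predictor_screen_no_outliers.csv.
"""

import json
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from dosegain.gain import pair_scores
from dosegain.predictors import screen_all

ROOT = pathlib.Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    pen_csv = ROOT / "penalties.csv"
    chars_csv = ROOT / "cohort" / "characteristics.csv"
    if not (pen_csv.exists() and chars_csv.exists()):
        sys.exit("run analysis/01 and 02 first")
    penalties = pd.read_csv(pen_csv)
    chars = pd.read_csv(chars_csv)
    manifest = json.loads((ROOT / "cohort" / "manifest.json").read_text())

    pairs = pair_scores(penalties[penalties.weight_set == "type1"])
    records = chars.merge(pairs, on="patient_id")
    records["delta_penalty"] = records["delta"]

    table = screen_all(records)
    table.to_csv(ROOT / "predictor_screen.csv", index=False)
    no_out = screen_all(records, exclude=manifest["outlier_ids"])
    no_out.to_csv(ROOT / "predictor_screen_no_outliers.csv", index=False)

    sig = table[table.significant]
    print(f"{len(table)} characteristics screened; "
          f"{len(sig)} significant (|coefficient/SD| > 1.96):")
    for _, row in sig.iterrows():
        cut = ("NI" if pd.isna(row.cutoff)
               else f"{'>' if row.direction == 'greater_better' else '<'}"
                    f"{row.cutoff:.3g} {row.unit}")
        print(f"  {row.characteristic:40s} coef {row.coefficient:+.4f} "
              f"(SD {row.coefficient_sd:.4f})  prone better {cut}")
    merged = table.merge(no_out, on="characteristic", suffixes=("", "_noout"))
    pre = merged[merged.group != "post_dosimetry"]
    drift = (pre.coefficient - pre.coefficient_noout).abs() / pre.coefficient_sd
    print(f"robustness: removing the {len(manifest['outlier_ids'])} planted "
          f"outliers moves every pre-dosimetry slope by at most "
          f"{drift.max():.2f} SD (median {drift.median():.2f}) — the Huber "
          "fits already discount them (the post-dosimetry fits change more: "
          "the outliers are extreme prone scores, i.e. leverage points there)")


if __name__ == "__main__":
    main()
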