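"""Neutrality tests and synonymous-clock ages across the cohort.

Tabulates Tajima's D components (m, S, ps, theta, pi, D) and the
Ks-based age of each pair (parental vs retrocopy representative, codon
bootstrap 95% interval, T = Ks / 2r at r = 6.5e-9 /site/year).
"""

import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from retrosel.pattern_pipeline import PairVerdict, tajima_table

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    verdicts = [
        PairVerdict.from_json(p.read_text())
        for p in sorted((RESULTS / "verdicts").glob("*.json"))
    ]
    taj = tajima_table(verdicts)
    taj.to_csv(RESULTS / "tajima.tsv", sep="\t", index=False)

    rows = [
        {
            "pair": v.pair_id,
            "ks": v.age.ks,
            "ks_ci95": v.age.ks_ci,
            "age_my": v.age.age_my,
            "age_ci95_my": v.age.age_ci_my,
        }
        for v in verdicts
        if v.age is not None
    ]
    ages = pd.DataFrame(rows)
    ages.to_csv(RESULTS / "ages.tsv", sep="\t", index=False)
    print(f"Tajima rows: {len(taj)}; dated pairs: {len(ages)}")
    if len(ages):
        print(
            "age range: %.2f - %.2f MY (median %.2f)"
            % (ages.age_my.min(), ages.age_my.max(), ages.age_my.median())
        )


if __name__ == "__main__":
    main()
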