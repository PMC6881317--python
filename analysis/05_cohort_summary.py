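"""Cohort roll-up: positives, patterns, enrichment, and truth comparison.

Counts positive pairs, classifies the evolutionary patterns, tests the
positive fraction against a 10% genomic baseline (Fisher exact), and
scores the pipeline's calls against the simulator's planted truth.
"""

import json
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from retrosel.pattern_pipeline import AnalysisConfig, PairVerdict, summarize_cohort

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    verdicts = [
        PairVerdict.from_json(p.read_text())
        for p in sorted((RESULTS / "verdicts").glob("*.json"))
    ]
    summary = summarize_cohort(verdicts, AnalysisConfig())
    (RESULTS / "cohort_summary.json").write_text(
        json.dumps(summary, indent=1, default=float)
    )

    truth = pd.read_csv(
        RESULTS / "cohort_truth.tsv", sep="\t", na_filter=False
    ).set_index("pair")
    rows = []
    for v in verdicts:
        planted = truth.loc[v.pair_id, "scenario"]
        expected_pattern = (
            int(planted.removeprefix("pattern")) if planted != "null" else None
        )
        rows.append(
            {
                "pair": v.pair_id,
                "planted": planted,
                "called_positive": v.positive,
                "called_pattern": v.pattern,
                "correct_positive": v.positive == (planted != "null"),
                "correct_pattern": v.pattern == expected_pattern,
            }
        )
    score = pd.DataFrame(rows)
    score.to_csv(RESULTS / "truth_comparison.tsv", sep="\t", index=False)

    print(
        f"{summary['n_positive']}/{summary['n_pairs']} pairs positive "
        f"({summary['percent_positive']}%), Fisher p vs 10% baseline = "
        f"{summary['enrichment_p']:.4g}"
    )
    print(f"patterns called: {summary['patterns']}")
    print(
        "positive/negative call accuracy: "
        f"{score.correct_positive.mean():.2f}; "
        f"pattern accuracy on planted positives: "
        f"{score[score.planted != 'null'].correct_pattern.mean():.2f}"
    )


if __name__ == "__main__":
    main()
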