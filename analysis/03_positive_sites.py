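"""Collect branch-site test results and flagged sites for positive pairs.

Reads the verdicts from 02_analyze_pairs.py and tabulates, per omega > 1
branch: the two LRTs, the Model A parameter estimates, and every site
flagged at the 95% level by the empirical-Bayes analysis.
"""

import json
import pathlib
import sys

import pandas as pd

sys.path.insert(0, str(pathlib.Path(__file__).resolve().parents[1] / "src"))

from retrosel.pattern_pipeline import PairVerdict

ROOT = pathlib.Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"


def main() -> None:
    test_rows, site_rows = [], []
    for path in sorted((RESULTS / "verdicts").glob("*.json")):
        v = PairVerdict.from_json(path.read_text())
        for rep in v.site_reports:
            test_rows.append(
                {
                    "pair": v.pair_id,
                    "branch": rep["branch"],
                    "test1_stat": rep["test1"][0],
                    "test1_p": rep["test1"][1],
                    "test2_stat": rep["test2"][0],
                    "test2_p": rep["test2"][1],
                    "omega0": rep["omega0"],
                    "omega2": rep["omega2"],
                    "p0": rep["proportions"][0],
                    "p1": rep["proportions"][1],
                    "p2a": rep["proportions"][2],
                    "p2b": rep["proportions"][3],
                    "n_flagged": len(rep["flagged_sites"]),
                }
            )
            for site, residue, post in rep["flagged_sites"]:
                site_rows.append(
                    {
                        "pair": v.pair_id,
                        "branch": rep["branch"],
                        "site": site,
                        "residue": residue,
                        "label": f"{site}{residue}",
                        "posterior": post,
                    }
                )
    pd.DataFrame(test_rows).to_csv(RESULTS / "branch_site_tests.tsv", sep="\t", index=False)
    pd.DataFrame(site_rows).to_csv(RESULTS / "positive_sites.tsv", sep="\t", index=False)
    print(f"{len(test_rows)} branch-site tests, {len(site_rows)} flagged sites")


if __name__ == "__main__":
    main()
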