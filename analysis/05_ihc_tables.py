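"""Statistics for the bundled H3K27me3 immunostaining cohort: positive rate
per group and the Pearson chi-square of grade distribution across gender,
age and pathology strata.
"""
from pathlib import Path

import pandas as pd

from egwaskit.datasets import H3K27ME3_AGE, H3K27ME3_GENDER, H3K27ME3_PATHOLOGY
from egwaskit.ihc import chi_square, positive_rate

RESULTS = Path("results/analysis")


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    rows = []
    for name, table in [
        ("gender", H3K27ME3_GENDER),
        ("age", H3K27ME3_AGE),
        ("pathology", H3K27ME3_PATHOLOGY),
    ]:
        result = chi_square(table)
        for group in table.groups:
            row = table.row(group)
            rows.append(
                {
                    "stratum": name,
                    "group": group,
                    "n": int(row.sum()),
                    "positive_rate_pct": round(100 * positive_rate(row), 1),
                    "chi_square": round(result.statistic, 3),
                    "df": result.df,
                    "p": round(result.p, 4),
                }
            )
        print(
            f"{name}: chi2={result.statistic:.3f} df={result.df} p={result.p:.4f}"
            + (f" (dropped all-zero grades {result.dropped_cols})"
               if result.dropped_cols else "")
        )
    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "05_ihc_statistics.tsv", sep="\t", index=False)
    print()
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
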