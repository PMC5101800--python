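"""Published sign-partition summary tables shipped as reference data.

The printed contingency summaries of the source analyses (CSC and CPC
vectors against the cTE/nTE classifications in budding and fission
yeast) report, per dataset, the number of positive-coefficient codons
("Total"), the optimal codons among them ("Observed"), the null
expectation ("Expected"), and the chi-square p-value.  Together with the
per-organism classification sizes (n_opt: 24/30 for S. cerevisiae
cTE/nTE, 28/35 for S. pombe) these marginals determine the full 2x2
table, so the package can recompute every printed Expected cell and
p-value without access to the underlying kinetic datasets.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .association import ContingencySummary, contingency_from_marginals

#: optimal-codon counts of the published cTE/nTE classifications
N_OPTIMAL = {
    ("S. cerevisiae", "cTE"): 24,
    ("S. cerevisiae", "nTE"): 30,
    ("S. pombe", "cTE"): 28,
    ("S. pombe", "nTE"): 35,
}


def load_printed_contingency() -> pd.DataFrame:
    """The printed summary rows (both tables, all datasets and metrics)."""
    ref = resources.files("codonstab.data") / "printed_contingency.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t")


def recompute_printed_rows(correction: bool = True) -> pd.DataFrame:
    """Recompute Expected and the chi-square p for every printed row.

    Returns the printed table with ``expected_recomputed``,
    ``chi2_recomputed`` and ``p_recomputed`` columns appended.
    """
    rows = load_printed_contingency()
    recomputed = []
    for _, row in rows.iterrows():
        summary: ContingencySummary = contingency_from_marginals(
            total=int(row["total"]),
            observed=int(row["observed"]),
            n_opt=int(row["n_opt"]),
            correction=correction,
        )
        recomputed.append(
            {
                "expected_recomputed": summary.expected,
                "chi2_recomputed": summary.chi2,
                "p_recomputed": summary.p,
            }
        )
    return pd.concat([rows, pd.DataFrame(recomputed)], axis=1)
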