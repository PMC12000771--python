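"""Published reference counts from a large maternity cohort (N = 48,502).

The shipped CSV carries, for each maternal condition, the printed 2×2 cells
of its cross-tabulation against gestational diabetes (rows exposure no/yes,
columns outcome no/yes) together with the chi-square statistic the source
report printed. These serve as regression fixtures: recomputing the
continuity-corrected chi-square from the cells should reproduce the printed
statistic to one decimal for the internally consistent rows.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .association import ContingencyTable2x2

__all__ = [
    "load_reference_tables",
    "reference_table",
    "COHORT_N",
    "GDM_CASES",
    "MULTIMORBIDITY_CASES",
]

COHORT_N = 48_502
GDM_CASES = 10_343
MULTIMORBIDITY_CASES = 19_469


def load_reference_tables() -> pd.DataFrame:
    """The published condition×GDM 2×2 cells as a DataFrame."""
    with resources.files("pregmorb.data").joinpath("reference_gdm_tables.csv").open() as fh:
        return pd.read_csv(fh)


def reference_table(condition: str) -> ContingencyTable2x2:
    """The published 2×2 table for one condition."""
    df = load_reference_tables().set_index("condition")
    if condition not in df.index:
        raise KeyError(f"no reference table for {condition!r}")
    row = df.loc[condition]
    return ContingencyTable2x2(int(row.a), int(row.b), int(row.c), int(row.d))
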