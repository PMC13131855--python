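"""Bundled example datasets.

Small literature-style tables used in examples and tests, loaded from the
package's ``data`` directory.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_pvs_findings_example", "load_demographics_example"]


def load_pvs_findings_example() -> pd.DataFrame:
    """Example table of uncorrected-significant perivascular-space findings.

    One row per region x metric x model term that reached p < 0.05 in a
    cross-sectional case-control regression analysis of white-matter PVS
    metrics (VF = volume fraction, CF = count fraction, DM = mean
    diameter) in middle-aged and older adults.  Columns: metric, lobe,
    mask, term, beta, se, t, p_perm, hemisphere.  Used to demonstrate
    lobar effect summaries.
    """
    path = resources.files("csfmarkers").joinpath("data/pvs_findings_example.tsv")
    with resources.as_file(path) as p:
        table = pd.read_csv(p, sep="\t")
    table["hemisphere"] = table["mask"].str.split("-").str[0]
    return table


def load_demographics_example() -> dict:
    """Example demographic summary of a two-group imaging cohort.

    A 2x2 sex contingency table (rows: case, control; columns: M, F) for a
    cohort of 49 cases and 61 controls, as used to demonstrate the
    chi-square demographics test.
    """
    return {
        "sex_table": pd.DataFrame(
            {"M": [28, 29], "F": [21, 32]}, index=["case", "control"]
        ),
        "n_case": 49,
        "n_control": 61,
    }
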