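"""Packaged reference tables transcribed from the published study report.

Five small TSV fixtures ship with the package: the 48-trait diplotype screen
(least-squared means, SE, ANOVA p and Tukey ordering strings), the nine
FPKM records of the target-region DE screen, the qPCR validation table, and
the two CIT result tables (liver genes x 12 traits; the WAT Ifih1 gene x 12
traits). They drive the replay tests: derived quantities (fold changes,
ordering strings, relationship labels, significance counts) are recomputed
from the printed inputs and compared against the printed outputs.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .defilter import FpkmRecord, records_from_frame

_EXPECTED_ROWS = {"table1": 48, "table2": 9, "table3": 9, "table4": 48, "table5": 12}


def _read(name: str, expected_key: str) -> pd.DataFrame:
    path = resources.files("citscreen") / "data" / name
    with resources.as_file(path) as p:
        df = pd.read_csv(p, sep="\t", keep_default_na=False, na_values=["NA"])
    expected = _EXPECTED_ROWS[expected_key]
    if len(df) != expected:
        raise RuntimeError(f"fixture {name} has {len(df)} rows, expected {expected}")
    return df


def load_trait_screen() -> pd.DataFrame:
    """48 traits: per-diplotype lsmeans/SE, n, printed ANOVA p, ordering string.

    The added ``mean_ulp`` column is the unit in the last printed decimal
    place of the mean columns (0.01 for two-decimal rows, 0.001 for the
    three-decimal organ weights), used by rounding-sensitivity checks.
    """
    df = _read("table1_traits.tsv", "table1")
    df["differences"] = df["differences"].fillna("NA")
    path = resources.files("citscreen") / "data" / "table1_traits.tsv"
    with resources.as_file(path) as p:
        raw = pd.read_csv(p, sep="\t", dtype=str)

    def ulp(text: str) -> float:
        return 10.0 ** -len(text.split(".")[1]) if "." in text else 1.0

    df["mean_ulp"] = [
        max(ulp(r.mean_bb), ulp(r.mean_bc), ulp(r.mean_cc))
        for r in raw.itertuples()
    ]
    return df


def load_fpkm_table() -> pd.DataFrame:
    """Nine target-region FPKM rows with the printed log2 fold-change columns."""
    return _read("table2_fpkm.tsv", "table2")


def load_fpkm_records() -> list[FpkmRecord]:
    return records_from_frame(load_fpkm_table())


def load_qpcr_table() -> pd.DataFrame:
    """qPCR relative expression by diplotype (levels rescaled to B/B = 1)."""
    return _read("table3_qpcr.tsv", "table3")


def load_cit_tables() -> pd.DataFrame:
    """Printed CIT Test 2-4 p-values and labels (liver and WAT batteries).

    Blank label cells are empty strings; ``p3``/``p4`` are NaN where the
    battery stopped after a failed Test 2. A ``battery`` column distinguishes
    the liver table from the WAT table, and ``p1`` carries the trait's
    printed screening ANOVA p (every listed trait passed Test 1).
    """
    liver = _read("table4_cit_liver.tsv", "table4").assign(battery="liver")
    wat = _read("table5_cit_wat.tsv", "table5").assign(battery="WAT")
    both = pd.concat([liver, wat], ignore_index=True)
    both["label"] = both["label"].fillna("")
    screen = load_trait_screen().set_index("trait")["anova_p"]
    both["p1"] = both["trait"].map(screen)
    if both["p1"].isna().any():
        missing = both.loc[both["p1"].isna(), "trait"].unique()
        raise RuntimeError(f"CIT fixture traits missing from trait screen: {missing}")
    return both
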