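"""Small bundled reference tables.

``load_noncancer_table`` returns the published comparison table of
non-cancerous disease–disease associations among the top-100 blood-cancer
DDAs of a literature co-mention system (``system == "comention"``, support =
co-mention count) versus a gene-overlap database (``system ==
"gene_overlap"``, support = Jaccard index).  Several printed identifier
columns in the source table are misaligned, so bookkeeping over this table
(unique-partner counts) keys on the disease *names*.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["load_noncancer_table", "unique_partner_count"]


def load_noncancer_table() -> pd.DataFrame:
    """Columns: system, partner_id, partner_name, target_id, target_name,
    support."""
    ref = resources.files("cominer.data").joinpath("noncancer_dda_table.tsv")
    with ref.open("r") as fh:
        return pd.read_csv(fh, sep="\t")


def unique_partner_count(table: pd.DataFrame, system: str) -> int:
    """Distinct non-cancerous partner diseases (by name) for one system."""
    sub = table[table["system"] == system]
    return int(sub["partner_name"].nunique())
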