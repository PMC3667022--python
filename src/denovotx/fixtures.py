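"""Packaged worked-example tables from the source study.

Three printed tables ship with the package as TSV fixtures: the 23
PCR-validated EST-SSR marker loci with their polymorphism status, the
repeat-element distribution (with both the printed and the interpreted
bp figures — two rows carry typographic comma errors in the source), and
the three pairwise differential-expression totals. Structural invariants
are asserted at load time.
"""

from __future__ import annotations

import json
from importlib import resources

import pandas as pd

__all__ = ["load_table1", "load_table2", "load_table3", "headline_counts"]


def _data(name: str):
    return resources.files("denovotx.data").joinpath(name)


def load_table1() -> pd.DataFrame:
    """23 validated SSR marker loci: locus_id, gene_id, motif, n_repeats, status."""
    with resources.as_file(_data("table1_ssr_markers.tsv")) as path:
        # keep_default_na: "NULL" is a status value, not a missing cell
        df = pd.read_csv(path, sep="\t", comment="#", keep_default_na=False)
    if len(df) != 23:
        raise ValueError(f"marker table must have exactly 23 rows, found {len(df)}")
    if not set(df["status"]) <= {"YES", "NO", "NULL"}:
        raise ValueError("marker table has malformed status values")
    return df


def load_table2() -> pd.DataFrame:
    """Repeat-element distribution with printed and interpreted bp columns."""
    with resources.as_file(_data("table2_repeats.tsv")) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    simple = df.loc[df["element_class"] == "Simple repeats"]
    if len(simple) != 1:
        raise ValueError("repeat table must have one Simple repeats row")
    return df


def load_table3() -> pd.DataFrame:
    """Pairwise DGE totals; each total equals the sum of its directional counts."""
    with resources.as_file(_data("table3_dge_totals.tsv")) as path:
        df = pd.read_csv(path, sep="\t", comment="#")
    bad = df[df["total"] != df["up_in_t1"] + df["up_in_t2"]]
    if len(bad):
        raise ValueError(f"inconsistent DGE totals in rows: {bad.index.tolist()}")
    return df


def headline_counts() -> dict:
    """Transcriptome-wide headline counts used by the percentage bookkeeping."""
    with resources.as_file(_data("headline_counts.json")) as path:
        return json.loads(path.read_text())
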