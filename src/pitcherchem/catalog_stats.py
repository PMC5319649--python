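"""Descriptive compound statistics: per-sample counts, unique compounds,
pairwise unique compounds and floral-scent flagging.

A compound is *unique* to a sample when it is present in that sample and
in no other; pairwise uniqueness compares two samples only.  Floral-scent
flagging is a case-insensitive name match against a curated reference
list of volatiles recorded from intact flowers (the packaged default is a
constructed stand-in list — supply your own for serious use).

Also ships the reported per-accession unique/floral counts for the 48
Darlingtonia/Sarracenia accessions (lid and pitcher tissues), whose
column means summarise chemical individuality across the family.
"""

from __future__ import annotations

import warnings
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .peak_tables import QUALITATIVE, CompoundTable


def _require_qualitative(table: CompoundTable) -> None:
    if table.mode != QUALITATIVE:
        raise ValueError("qualitative (presence/absence) table required")


def compounds_per_sample(table: CompoundTable) -> pd.Series:
    """Number of compounds present in each sample (row sums)."""
    _require_qualitative(table)
    return table.values.sum(axis=1).astype(int)


def unique_compounds(table: CompoundTable) -> dict[str, list[str]]:
    """Compounds present in exactly one sample, keyed by that sample."""
    _require_qualitative(table)
    colsum = table.values.sum(axis=0)
    singles = table.values.loc[:, colsum == 1]
    out: dict[str, list[str]] = {s: [] for s in table.sample_ids}
    for compound in singles.columns:
        owner = singles.index[singles[compound] == 1][0]
        out[owner].append(compound)
    return out


def pairwise_unique(table: CompoundTable, i: str, j: str) -> tuple[int, int]:
    """(count present in i but not j, count present in j but not i).

    The two counts sum to the Hamming distance between the rows.
    """
    _require_qualitative(table)
    for s in (i, j):
        if s not in table.values.index:
            raise KeyError(f"unknown sample: {s!r}")
    if i == j:
        raise ValueError("samples must differ")
    ri = table.values.loc[i]
    rj = table.values.loc[j]
    return int(((ri == 1) & (rj == 0)).sum()), int(((rj == 1) & (ri == 0)).sum())


def pairwise_unique_matrix(table: CompoundTable) -> pd.DataFrame:
    """Full matrix M[i, j] = number of compounds present in i but not j."""
    _require_qualitative(table)
    X = table.values.to_numpy()
    m = ((X[:, None, :] == 1) & (X[None, :, :] == 0)).sum(axis=2)
    return pd.DataFrame(m, index=table.values.index, columns=table.values.index)


# ---------------------------------------------------------------------------
# floral flagging


def _normalize_name(name: str) -> str:
    return " ".join(name.split()).casefold()


def read_floral_reference(path: str | Path) -> list[str]:
    """One compound name per line; blank lines and '#' comments ignored."""
    lines = Path(path).read_text().splitlines()
    return [ln.strip() for ln in lines if ln.strip() and not ln.startswith("#")]


def default_floral_reference() -> list[str]:
    """Packaged stand-in floral-volatile name list (synthetic, editable)."""
    ref = resources.files("pitcherchem.data") / "floral_scent_reference_synthetic.txt"
    return [
        ln.strip()
        for ln in ref.read_text().splitlines()
        if ln.strip() and not ln.startswith("#")
    ]


def flag_floral(
    compound_ids: Iterable[str], reference: Iterable[str]
) -> dict[str, bool]:
    """Flag compounds whose (normalized) name appears in the reference list."""
    ref = {_normalize_name(r) for r in reference}
    if not ref:
        warnings.warn("empty floral reference list: nothing flagged", stacklevel=2)
    return {c: _normalize_name(c) in ref for c in compound_ids}


# ---------------------------------------------------------------------------
# summary table


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding (so 6.45 -> 6.5, unlike banker's rounding)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_unique(
    unique_sets: Mapping[str, list[str]], floral_flags: Mapping[str, bool]
) -> pd.DataFrame:
    """Per-sample unique and floral-unique counts plus a mean row.

    The final row, labelled ``Average``, holds the column means rounded
    half-up to one decimal.
    """
    rows = {
        sample: {
            "unique_compounds": len(compounds),
            "floral_scent_compounds": sum(
                bool(floral_flags.get(c, False)) for c in compounds
            ),
        }
        for sample, compounds in unique_sets.items()
    }
    df = pd.DataFrame.from_dict(rows, orient="index")
    means = {col: round_half_up(float(df[col].mean())) for col in df.columns}
    df.loc["Average"] = means
    return df


def column_means(df: pd.DataFrame, ndigits: int = 1) -> dict[str, float]:
    """Half-up-rounded means of every numeric column."""
    return {
        col: round_half_up(float(df[col].mean()), ndigits)
        for col in df.select_dtypes("number").columns
    }


def load_reported_unique_counts() -> pd.DataFrame:
    """Reported per-accession unique/floral compound counts (48 accessions).

    Columns: ``lid_unique``, ``lid_floral``, ``pitcher_unique``,
    ``pitcher_floral``; index is the accession label.
    """
    ref = resources.files("pitcherchem.data") / "sarraceniaceae_unique_counts.tsv"
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return df.set_index("accession")
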