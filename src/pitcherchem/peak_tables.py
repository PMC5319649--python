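"""Compound-table construction from GC-MS peak identifications.

Raw input is a long-format table of automatically integrated and
library-identified chromatogram peaks (one row per peak per sample).
This module applies the data-handling rules used for pitcher-plant
metabolite profiling:

* identifications below a match cut-off (default 70 %) are discarded;
* co-eluting peaks identified as *different* hydrocarbons in different
  samples are collapsed to a canonical n-alkane at that retention time;
* per-sample peak areas are converted to relative abundances (percent of
  the sample's total peak area), giving a quantitative samples x compounds
  matrix; presence/absence coding gives the qualitative counterpart.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MANDATORY_COLUMNS = ("sample_id", "rt", "compound_id", "match_pct", "area")

QUANTITATIVE = "quantitative"
QUALITATIVE = "qualitative"

#: straight-chain alkane names (C5-C40), used to recognise hydrocarbon
#: identifications when no compound_class column is supplied
_ALKANE_NAMES = frozenset(
    {
        "pentane", "hexane", "heptane", "octane", "nonane", "decane",
        "undecane", "dodecane", "tridecane", "tetradecane", "pentadecane",
        "hexadecane", "heptadecane", "octadecane", "nonadecane", "eicosane",
        "heneicosane", "docosane", "tricosane", "tetracosane", "pentacosane",
        "hexacosane", "heptacosane", "octacosane", "nonacosane",
        "triacontane", "hentriacontane", "dotriacontane", "tritriacontane",
        "tetratriacontane", "pentatriacontane", "hexatriacontane",
        "heptatriacontane", "octatriacontane", "nonatriacontane",
        "tetracontane",
    }
)

_HYDROCARBON_CLASSES = frozenset({"hydrocarbon", "n-alkane"})


@dataclasses.dataclass(frozen=True)
class PeakRecord:
    """One integrated, library-identified GC-MS peak."""

    sample_id: str
    rt: float
    compound_id: str
    match_pct: float
    area: float
    compound_class: str | None = None

    def __post_init__(self) -> None:
        if self.rt < 0:
            raise ValueError(f"negative retention time: {self.rt}")
        if not 0 <= self.match_pct <= 100:
            raise ValueError(f"match_pct outside [0, 100]: {self.match_pct}")
        if self.area < 0:
            raise ValueError(f"negative peak area: {self.area}")


@dataclasses.dataclass
class CompoundTable:
    """Samples x compounds matrix with per-sample metadata.

    ``values`` is a DataFrame whose index are sample ids and whose columns
    are compound ids.  ``mode`` is ``"quantitative"`` (rows are percentages
    of total peak area, summing to 100 unless a sample is empty) or
    ``"qualitative"`` (0/1 presence coding).  ``meta``, if given, is indexed
    by sample id with columns ``species``, ``infraspecific``, ``tissue``.
    """

    values: pd.DataFrame
    mode: str
    meta: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- invariants ----------------------------------------------------
    def validate(self) -> None:
        if self.mode not in (QUANTITATIVE, QUALITATIVE):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate compound ids")
        if self.values.index.duplicated().any():
            raise ValueError("duplicate sample ids")
        arr = self.values.to_numpy(dtype=float)
        if arr.size and (arr < 0).any():
            raise ValueError("negative cell values")
        if self.mode == QUANTITATIVE and arr.size:
            sums = arr.sum(axis=1)
            bad = ~(np.isclose(sums, 100.0, atol=1e-9) | (sums == 0.0))
            if bad.any():
                raise ValueError(
                    f"quantitative rows must sum to 100 or 0; offending "
                    f"samples: {list(self.values.index[bad])}"
                )
        if self.mode == QUALITATIVE and arr.size:
            if not np.isin(arr, (0.0, 1.0)).all():
                raise ValueError("qualitative cells must be 0 or 1")
        if self.meta is not None:
            missing = self.values.index.difference(self.meta.index)
            if len(missing):
                raise ValueError(f"samples missing from metadata: {list(missing)}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def compound_ids(self) -> list[str]:
        return list(self.values.columns)

    # -- IO ------------------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        self.values.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(
        cls, path: str | Path, mode: str, meta: pd.DataFrame | None = None
    ) -> "CompoundTable":
        values = pd.read_csv(path, sep="\t", index_col="sample_id")
        values.index = values.index.astype(str)
        return cls(values=values, mode=mode, meta=meta)

    def sidecar(self) -> dict:
        """JSON-ready summary: mode, sparsity, per-sample compound counts."""
        counts = (self.values.to_numpy() > 0).sum(axis=1)
        return {
            "mode": self.mode,
            "n_samples": len(self.sample_ids),
            "n_compounds": len(self.compound_ids),
            "sparsity": sparsity(self) if self.values.size else None,
            "compounds_per_sample": dict(
                zip(self.sample_ids, (int(c) for c in counts))
            ),
        }

    def write_sidecar(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.sidecar(), indent=2) + "\n")


# ---------------------------------------------------------------------------
# reading


def read_peak_records(path: str | Path) -> list[PeakRecord]:
    """Read a CSV/TSV peak table into :class:`PeakRecord` objects.

    The header must name ``sample_id``, ``rt``, ``compound_id``,
    ``match_pct`` and ``area`` (``compound_class`` is optional).  Rows with
    non-numeric or invalid ``rt``/``area``/``match_pct`` are skipped with a
    warning naming their line numbers; a missing mandatory column raises.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    missing = [c for c in MANDATORY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing mandatory column(s): {', '.join(missing)}")

    records: list[PeakRecord] = []
    bad_lines: list[int] = []
    has_class = "compound_class" in df.columns
    for pos, row in enumerate(df.itertuples(index=False)):
        line_no = pos + 2  # header is line 1
        row = row._asdict()
        try:
            rec = PeakRecord(
                sample_id=str(row["sample_id"]),
                rt=float(row["rt"]),
                compound_id=str(row["compound_id"]),
                match_pct=float(row["match_pct"]),
                area=float(row["area"]),
                compound_class=(
                    str(row["compound_class"])
                    if has_class and pd.notna(row["compound_class"])
                    else None
                ),
            )
        except (TypeError, ValueError):
            bad_lines.append(line_no)
            continue
        records.append(rec)
    if bad_lines:
        warnings.warn(
            f"{path.name}: skipped {len(bad_lines)} malformed row(s) at "
            f"line(s) {bad_lines}",
            stacklevel=2,
        )
    return records


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata (TSV: sample_id, species, infraspecific, tissue)."""
    meta = pd.read_csv(path, sep="\t", dtype=str).set_index("sample_id")
    return meta


# ---------------------------------------------------------------------------
# data-handling rules


def filter_identifications(
    records: Iterable[PeakRecord], cutoff: float = 70.0
) -> list[PeakRecord]:
    """Keep records whose library match is at least ``cutoff`` percent."""
    if not 0 <= cutoff <= 100:
        raise ValueError(f"cutoff outside [0, 100]: {cutoff}")
    return [r for r in records if r.match_pct >= cutoff]


def _is_hydrocarbon(record: PeakRecord) -> bool:
    if record.compound_class is not None:
        return record.compound_class.strip().lower() in _HYDROCARBON_CLASSES
    return record.compound_id.strip().lower() in _ALKANE_NAMES


def collapse_alkanes(
    records: Sequence[PeakRecord], rt_tol: float = 0.02
) -> list[PeakRecord]:
    """Collapse co-eluting, inconsistently identified hydrocarbons.

    Hydrocarbon peaks whose retention times chain together within
    ``rt_tol`` minutes form a group.  If a group spans at least two samples
    carrying at least two distinct identifications, every member is
    re-labelled ``n-alkane@<rt>`` where ``<rt>`` is the earliest member's
    retention time rounded to two decimals.  Everything else is unchanged.
    """
    if rt_tol <= 0:
        raise ValueError("rt_tol must be positive")
    hydro_idx = [i for i, r in enumerate(records) if _is_hydrocarbon(r)]
    out = list(records)
    if not hydro_idx:
        return out
    hydro_idx.sort(key=lambda i: records[i].rt)
    groups: list[list[int]] = [[hydro_idx[0]]]
    for i in hydro_idx[1:]:
        if records[i].rt - records[groups[-1][-1]].rt <= rt_tol:
            groups[-1].append(i)
        else:
            groups.append([i])
    for group in groups:
        samples = {records[i].sample_id for i in group}
        names = {records[i].compound_id for i in group}
        if len(samples) < 2 or len(names) < 2:
            continue
        canonical = f"n-alkane@{min(records[i].rt for i in group):.2f}"
        for i in group:
            out[i] = dataclasses.replace(
                out[i], compound_id=canonical, compound_class="n-alkane"
            )
    return out


def build_compound_table(
    records: Iterable[PeakRecord], meta: pd.DataFrame | None = None
) -> CompoundTable:
    """Assemble the quantitative (relative-abundance) compound matrix.

    Cell (s, c) is 100 * (total area of compound c in sample s) / (total
    area of sample s).  Samples listed in ``meta`` but carrying no peaks
    yield all-zero rows.  Duplicate (sample, compound, rt) triplets are
    summed with a warning; two peaks of the same compound at different
    retention times in one sample are summed silently (relative abundance
    is per compound, not per peak).  Compounds absent from every sample
    are dropped.
    """
    records = list(records)
    rows = pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "compound_id": [r.compound_id for r in records],
            "rt": [r.rt for r in records],
            "area": [r.area for r in records],
        }
    )
    if len(rows):
        dup = rows.duplicated(subset=["sample_id", "compound_id", "rt"])
        if dup.any():
            warnings.warn(
                f"summed {int(dup.sum())} duplicate (sample, compound, rt) "
                "peak(s)",
                stacklevel=2,
            )
        pivot = rows.pivot_table(
            index="sample_id", columns="compound_id", values="area",
            aggfunc="sum", fill_value=0.0,
        )
    else:
        pivot = pd.DataFrame()

    if meta is not None:
        pivot = pivot.reindex(index=meta.index, fill_value=0.0)
    pivot = pivot.fillna(0.0)
    pivot = pivot.loc[:, sorted(pivot.columns)] if pivot.size else pivot
    # drop compounds never observed
    if pivot.size:
        pivot = pivot.loc[:, pivot.sum(axis=0) > 0]
        totals = pivot.sum(axis=1)
        nonzero = totals > 0
        pivot.loc[nonzero] = pivot.loc[nonzero].div(totals[nonzero], axis=0) * 100.0
    return CompoundTable(values=pivot.astype(float), mode=QUANTITATIVE, meta=meta)


def binarize(table: CompoundTable) -> CompoundTable:
    """Presence/absence coding: cell > 0 -> 1, else 0. Idempotent."""
    values = (table.values > 0).astype(float)
    return CompoundTable(values=values, mode=QUALITATIVE, meta=table.meta)


def sparsity(table: CompoundTable) -> float:
    """Fraction of zero cells in the matrix."""
    arr = table.values.to_numpy()
    if arr.size == 0:
        raise ValueError("empty table has no sparsity")
    return float((arr == 0).sum() / arr.size)
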