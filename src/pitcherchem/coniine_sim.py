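"""Rule-based coniine detection from selected-ion-monitoring (SIM) traces.

Coniine (a piperidine alkaloid; base peak m/z 84, molecular ion m/z 126)
elutes at a constant retention time of 6.33 +/- 0.01 min on the method
this mirrors.  Five ions are monitored (m/z 56, 70, 80, 84, 126) but only
80, 84 and 126 are diagnostic — 56 and 70 are shared with many other
molecules and are recorded without ever contributing to confirmation.

Detection is rule-based: ion intensities summed over the retention-time
window are compared with a pure-standard reference pattern, qualifier
codes describe how well the observed ratios conform, and a verdict
(detected / trace / ion84_only / absent) is emitted per sample.  Species
summaries group infraspecific taxa under the binomial; a species counts
as positive when any accession or tissue yields a detected or trace call.
"""

from __future__ import annotations

import dataclasses
import enum
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

DIAGNOSTIC_IONS = (80, 84, 126)
BASE_PEAK = 84


class Qualifier(enum.Enum):
    """Qualifier codes for the observed diagnostic-ion pattern."""

    LOW_INTENSITY = "F"        # a present ion sits below the low-intensity level
    PROPORTIONS_OK = "G"       # 80/84 and 126/84 match the reference ratios
    M80_GT_M84 = "H"           # m/z 80 more intense than the base peak
    EQUAL_INTENSITY = "I"      # the three ions have (about) equal intensity
    M126_DOMINANT = "J"        # the molecular ion is the most intense


class Verdict(str, enum.Enum):
    DETECTED = "detected"
    TRACE = "trace"
    ION84_ONLY = "ion84_only"
    ABSENT = "absent"


@dataclasses.dataclass(frozen=True)
class ReferencePattern:
    """Pure-standard ion ratios and the retention-time window."""

    ratios: Mapping[int, float]  # m/z -> intensity relative to the base peak
    rt_center: float = 6.33
    rt_tol: float = 0.01

    def __post_init__(self) -> None:
        if self.ratios.get(BASE_PEAK) != 1.0:
            raise ValueError("m/z 84 must be the base peak (ratio 1.0)")
        for mz, r in self.ratios.items():
            if not 0 < r <= 1.0:
                raise ValueError(f"ratio for m/z {mz} outside (0, 1]: {r}")

    @property
    def ions(self) -> tuple[int, ...]:
        return tuple(sorted(self.ratios))

    @classmethod
    def from_tsv(cls, path: str | Path, **kwargs) -> "ReferencePattern":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(ratios=dict(zip(df["mz"].astype(int), df["ratio"])), **kwargs)

    @classmethod
    def default(cls) -> "ReferencePattern":
        """Packaged stand-in pattern (synthetic; override for real data)."""
        ref = (
            resources.files("pitcherchem.data")
            / "coniine_reference_pattern_synthetic.tsv"
        )
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)


@dataclasses.dataclass
class SpectrumSlice:
    """Per-ion intensity summed over the retention-time window."""

    intensities: dict[int, float]
    empty_window: bool = False

    def __post_init__(self) -> None:
        for mz, v in self.intensities.items():
            if v < 0:
                raise ValueError(f"negative intensity for m/z {mz}")


@dataclasses.dataclass(frozen=True)
class DetectionThresholds:
    """Intensity levels, in the synthetic generator's calibrated units.

    ``noise_floor``: an ion below this is treated as not present.
    ``trace_level``: a confirmed detection whose strongest diagnostic ion
    stays below this is downgraded to a trace call (the analogue of the
    1 ug/ml limit-of-detection qualifier); with the generator's defaults
    a spiked amount of 1.0 is a trace call and 5.0 is solid.
    ``low_intensity``: present ions below this get the F qualifier.
    On real data all three must be re-calibrated to the instrument.
    """

    noise_floor: float = 25.0
    trace_level: float = 1500.0
    low_intensity: float = 75.0
    rel_tol: float = 0.30


@dataclasses.dataclass
class DetectionCall:
    verdict: Verdict
    qualifiers: frozenset[Qualifier]
    ion_present: dict[int, bool]
    intensities: dict[int, float]

    def to_json_dict(self) -> dict:
        return {
            "verdict": self.verdict.value,
            "qualifiers": sorted(q.value for q in self.qualifiers),
            "ion_present": {str(k): v for k, v in self.ion_present.items()},
            "intensities": {str(k): float(v) for k, v in self.intensities.items()},
        }


# ---------------------------------------------------------------------------
# extraction and classification


def extract_window(
    trace: pd.DataFrame, ref: ReferencePattern
) -> SpectrumSlice:
    """Sum each monitored ion's intensity inside the closed rt window.

    ``trace`` needs columns ``rt``, ``mz``, ``intensity``.  Ions not in
    the reference pattern are ignored.  An empty window yields an
    all-zero slice flagged ``empty_window``.
    """
    lo, hi = ref.rt_center - ref.rt_tol, ref.rt_center + ref.rt_tol
    win = trace[(trace["rt"] >= lo) & (trace["rt"] <= hi)]
    intensities = {int(mz): 0.0 for mz in ref.ions}
    for mz, grp in win.groupby("mz"):
        mz = int(mz)
        if mz in intensities:
            intensities[mz] = float(grp["intensity"].sum())
    return SpectrumSlice(intensities=intensities, empty_window=win.empty)


def classify_pattern(
    slice_: SpectrumSlice,
    ref: ReferencePattern,
    rel_tol: float = 0.30,
    noise_floor: float = 0.0,
    low_intensity: float | None = None,
) -> frozenset[Qualifier]:
    """Qualifier codes for the diagnostic-ion pattern in a slice.

    G (correct proportions) requires all three diagnostic ions present
    with both 80/84 and 126/84 ratios within ``rel_tol`` relative error
    of the reference; G suppresses H, I and J.  H: 80 > 84.  I: the
    three present with pairwise intensities within ``rel_tol`` of each
    other.  J: 126 the most intense.  F flags any present diagnostic ion
    below the low-intensity level and can accompany any of the others.
    All ratio rules are scale-free.
    """
    if not 0 < rel_tol < 1:
        raise ValueError("rel_tol must lie in (0, 1)")
    i80 = slice_.intensities.get(80, 0.0)
    i84 = slice_.intensities.get(84, 0.0)
    i126 = slice_.intensities.get(126, 0.0)
    present = {mz: slice_.intensities.get(mz, 0.0) > noise_floor
               for mz in DIAGNOSTIC_IONS}
    quals: set[Qualifier] = set()

    if low_intensity is not None:
        if any(
            present[mz] and slice_.intensities[mz] < low_intensity
            for mz in DIAGNOSTIC_IONS
        ):
            quals.add(Qualifier.LOW_INTENSITY)

    def _rel_ok(observed: float, expected: float) -> bool:
        return abs(observed - expected) <= rel_tol * expected

    if all(present.values()) and i84 > 0:
        if _rel_ok(i80 / i84, ref.ratios[80]) and _rel_ok(i126 / i84, ref.ratios[126]):
            quals.add(Qualifier.PROPORTIONS_OK)
            return frozenset(quals)

    if present[80] and i80 > i84:
        quals.add(Qualifier.M80_GT_M84)
    if all(present.values()):
        vals = [i80, i84, i126]
        if max(vals) > 0 and (max(vals) - min(vals)) <= rel_tol * max(vals):
            quals.add(Qualifier.EQUAL_INTENSITY)
    if present[126] and i126 > max(i80, i84):
        quals.add(Qualifier.M126_DOMINANT)
    return frozenset(quals)


def detect_coniine(
    slice_: SpectrumSlice,
    ref: ReferencePattern,
    thresholds: DetectionThresholds | None = None,
) -> DetectionCall:
    """Verdict for one sample's SIM window.

    ``absent``: no diagnostic ion above the noise floor (an isolated m/z
    80 or 126 without the base peak is likewise treated as background —
    a single non-base fragment is not evidence).  ``ion84_only``: only
    the base peak.  ``detected``: base peak plus at least one further
    diagnostic ion (or correct proportions), downgraded to ``trace`` when
    the strongest diagnostic ion stays below the trace level.  Adding
    intensity to a diagnostic ion never moves a verdict toward absent.
    """
    th = thresholds or DetectionThresholds()
    quals = classify_pattern(
        slice_,
        ref,
        rel_tol=th.rel_tol,
        noise_floor=th.noise_floor,
        low_intensity=th.low_intensity,
    )
    present = {
        mz: slice_.intensities.get(mz, 0.0) > th.noise_floor
        for mz in DIAGNOSTIC_IONS
    }
    n_present = sum(present.values())
    if not present[BASE_PEAK]:
        verdict = Verdict.ABSENT
    elif n_present == 1:
        verdict = Verdict.ION84_ONLY
    elif n_present >= 2 or Qualifier.PROPORTIONS_OK in quals:
        max_diag = max(slice_.intensities.get(mz, 0.0) for mz in DIAGNOSTIC_IONS)
        verdict = Verdict.TRACE if max_diag < th.trace_level else Verdict.DETECTED
    else:  # pragma: no cover - unreachable with the presence logic above
        verdict = Verdict.ABSENT
    return DetectionCall(
        verdict=verdict,
        qualifiers=quals,
        ion_present=present,
        intensities=dict(slice_.intensities),
    )


# ---------------------------------------------------------------------------
# species summaries


def species_binomial(name: str) -> str:
    """Genus + epithet; infraspecific taxa collapse onto the binomial."""
    parts = name.replace("*", "").split()
    if len(parts) < 2:
        raise ValueError(f"not a binomial: {name!r}")
    return f"{parts[0]} {parts[1]}"


_POSITIVE = {Verdict.DETECTED, Verdict.TRACE}


def species_detection_summary(
    calls: Iterable[tuple[str, str, Verdict]],
) -> tuple[int, pd.DataFrame]:
    """Count positive species and tabulate per-species marks per tissue.

    ``calls`` yields (species name, tissue, verdict) triples.  Marks:
    ``x`` detected, ``x*`` trace, ``-`` negative, ``na`` not analysed.
    A species is positive when any of its calls is detected or trace.
    """
    per: dict[str, dict[str, list[Verdict]]] = {}
    for species, tissue, verdict in calls:
        binom = species_binomial(species)
        per.setdefault(binom, {}).setdefault(tissue, []).append(verdict)

    def mark(verdicts: list[Verdict]) -> str:
        if any(v == Verdict.DETECTED for v in verdicts):
            return "x"
        if any(v == Verdict.TRACE for v in verdicts):
            return "x*"
        return "-"

    tissues = sorted({t for d in per.values() for t in d})
    rows = {
        binom: {t: (mark(d[t]) if t in d else "na") for t in tissues}
        for binom, d in sorted(per.items())
    }
    table = pd.DataFrame.from_dict(rows, orient="index")
    n_positive = sum(
        any(v in _POSITIVE for verdicts in d.values() for v in verdicts)
        for d in per.values()
    )
    return n_positive, table


_MARK_TO_VERDICT = {
    "x": Verdict.DETECTED,
    "x*": Verdict.TRACE,
    "-": Verdict.ABSENT,
}


def summary_from_marks(df: pd.DataFrame) -> tuple[int, pd.DataFrame]:
    """Species summary from a mark table (columns: species, lid, pitcher).

    Marks ``x`` / ``x*`` / ``-`` map to detected / trace / absent;
    ``na`` cells (tissue not analysed) are skipped.
    """
    calls = []
    for _, row in df.iterrows():
        for tissue in ("lid", "pitcher"):
            mark = str(row[tissue]).strip()
            if mark in _MARK_TO_VERDICT:
                calls.append((row["species"], tissue, _MARK_TO_VERDICT[mark]))
    return species_detection_summary(calls)


def load_reported_sim_marks() -> pd.DataFrame:
    """Reported SIM lid/pitcher marks for the 17 targeted accessions."""
    ref = resources.files("pitcherchem.data") / "sarraceniaceae_coniine_sim.tsv"
    with resources.as_file(ref) as path:
        return pd.read_csv(path, sep="\t", comment="#")
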