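"""Synthetic GC-MS study generator with recoverable ground truth.

Emulates the statistical shape of the pitcher-plant profiling study so
every pipeline stage can be exercised without the (unpublished) raw
data: 48 samples falling into 9 clades of sizes (1, 11, 4, 3, 13, 4, 5,
5, 2) — one monotypic, like the single Darlingtonia accession — about
560 compounds at roughly 91.4 % zeros, a small set of clade-informative
compounds, peak tables whose relative abundances rebuild the matrix
exactly, a clade-structured tree with a many-to-many sample-tip mapping
(default candidate groups {3, 3, 2}, hence 18 bijective maps), and SIM
traces with a coniine-like ion pattern at 6.33 min.

Presence of an informative compound of clade c is Bernoulli(p_in) inside
c and Bernoulli(p_out) outside; background compounds are Bernoulli(p_bg)
with p_bg solved analytically so the expected overall sparsity hits the
target.  Informative compounds are apportioned to clades proportionally
to clade size (largest remainder), so the monotypic clade carries none —
a one-member clade cannot have clade-shared chemistry.
"""

from __future__ import annotations

import dataclasses
import json

import dendropy
import numpy as np
import pandas as pd

from .coniine_sim import ReferencePattern
from .peak_tables import (
    QUALITATIVE,
    QUANTITATIVE,
    CompoundTable,
    PeakRecord,
)
from .phylo_concordance import CladeFramework

DEFAULT_CLADE_SIZES = (1, 11, 4, 3, 13, 4, 5, 5, 2)
DEFAULT_N_FEATURES = 560
DEFAULT_N_INFORMATIVE = 20
DEFAULT_P_IN = 0.9
DEFAULT_P_OUT = 0.05
DEFAULT_SPARSITY = 0.914
DEFAULT_CANDIDATE_GROUPS = (3, 3, 2)


@dataclasses.dataclass
class GroundTruth:
    """What the generator knows and the pipeline tries to recover."""

    sample_clades: dict[str, str]
    informative: dict[str, str]  # feature id -> clade name
    p_in: float
    p_out: float
    p_bg: float
    seed: int

    def __post_init__(self) -> None:
        if not 0 <= self.p_out < self.p_in <= 1:
            raise ValueError("need 0 <= p_out < p_in <= 1")

    def informative_features(self) -> list[str]:
        return sorted(self.informative)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


# ---------------------------------------------------------------------------
# naming helpers


def _sample_names(clade_sizes) -> tuple[list[str], dict[str, str]]:
    samples, clade_of = [], {}
    k = 0
    for c, size in enumerate(clade_sizes, start=1):
        for _ in range(size):
            k += 1
            name = f"S{k:02d}"
            samples.append(name)
            clade_of[name] = f"clade{c}"
    return samples, clade_of


def apportion_informative(
    clade_sizes, n_informative: int
) -> list[int]:
    """Largest-remainder apportionment of feature counts to clades."""
    sizes = np.asarray(clade_sizes, dtype=float)
    quota = n_informative * sizes / sizes.sum()
    counts = np.floor(quota).astype(int)
    remainder = quota - counts
    for idx in np.argsort(-remainder)[: n_informative - counts.sum()]:
        counts[idx] += 1
    return [int(c) for c in counts]


# ---------------------------------------------------------------------------
# tree + mapping


def _random_binary_newick(labels: list[str], rng: np.random.Generator) -> str:
    """Random sequential-join binary subtree over the given labels."""
    nodes = [f"{lab}:{rng.uniform(0.02, 0.2):.4f}" for lab in labels]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.02, 0.2):.4f}")
    return nodes[0]


def simulate_clade_framework(
    clade_sizes=DEFAULT_CLADE_SIZES,
    candidate_group_sizes=DEFAULT_CANDIDATE_GROUPS,
    n_unmapped: int = 1,
    seed: int = 0,
) -> tuple[CladeFramework, dict[str, str]]:
    """Random clade-structured tree plus a many-to-many sample-tip map.

    Each clade is a monophyletic subtree.  The candidate groups are
    placed in the largest clades: a group of size g folds that clade's
    first g samples into a single tip whose candidate set they form;
    every other mapped sample gets a one-to-one tip.  ``n_unmapped``
    trailing ungrouped samples are left out of the mapping entirely
    (mirroring profiled samples with no tree counterpart).  Returns the
    framework and the sample -> clade assignment.
    """
    rng = np.random.default_rng(seed)
    samples, clade_of = _sample_names(clade_sizes)
    clade_names = [f"clade{c}" for c in range(1, len(clade_sizes) + 1)]
    by_clade = {name: [s for s in samples if clade_of[s] == name]
                for name in clade_names}

    # place candidate groups in the largest clades, one group per clade
    order = sorted(clade_names, key=lambda n: -len(by_clade[n]))
    group_host: dict[str, int] = {}
    hosts = iter(order)
    for g in sorted(candidate_group_sizes, reverse=True):
        for name in hosts:
            if len(by_clade[name]) >= g + 1:  # keep >= 1 one-to-one tip
                group_host[name] = g
                break
        else:
            raise ValueError("no clade large enough for a candidate group")
        hosts = iter([n for n in order if n not in group_host])

    # drop unmapped samples from the tail of the largest un-grouped clades
    droppable = [
        s
        for name in order
        if name not in group_host
        for s in by_clade[name][-1:]
        if len(by_clade[name]) > 1
    ]
    if n_unmapped > len(droppable):
        raise ValueError("too many unmapped samples requested")
    unmapped = set(droppable[:n_unmapped])

    sample_map: dict[str, list[str]] = {}
    clade_tips: dict[str, list[str]] = {name: [] for name in clade_names}
    for name in clade_names:
        members = by_clade[name]
        start = 0
        if name in group_host:
            g = group_host[name]
            tip = f"T_{members[0]}grp"
            sample_map[tip] = members[:g]
            clade_tips[name].append(tip)
            start = g
        for s in members[start:]:
            if s in unmapped:
                continue
            tip = f"T_{s}"
            sample_map[tip] = [s]
            clade_tips[name].append(tip)

    subtrees = [_random_binary_newick(clade_tips[name], rng) for name in clade_names]
    newick = _random_binary_newick_join(subtrees, rng) + ";"
    tree = dendropy.Tree.get(
        data=newick, schema="newick", preserve_underscores=True
    )
    tree.is_rooted = True  # built rooted; silences MRCA rootedness warnings
    fw = CladeFramework(tree=tree, clades=clade_tips, sample_map=sample_map)
    return fw, clade_of


def _random_binary_newick_join(subtrees: list[str], rng: np.random.Generator) -> str:
    nodes = list(subtrees)
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        b = nodes.pop(j)
        a = nodes.pop(i)
        nodes.append(f"({a},{b}):{rng.uniform(0.02, 0.2):.4f}")
    return f"({nodes[0]})" if len(subtrees) == 1 else nodes[0]


# ---------------------------------------------------------------------------
# compound matrix


def background_rate_for_sparsity(
    sample_clades: dict[str, str],
    informative: dict[str, str],
    n_features: int,
    p_in: float,
    p_out: float,
    target_sparsity: float,
) -> float:
    """p_bg making the expected zero fraction equal the target."""
    n = len(sample_clades)
    clade_counts = pd.Series(list(sample_clades.values())).value_counts()
    expected_inf = sum(
        clade_counts.get(clade, 0) * p_in
        + (n - clade_counts.get(clade, 0)) * p_out
        for clade in informative.values()
    )
    n_bg = n_features - len(informative)
    total_nonzero = (1.0 - target_sparsity) * n * n_features
    if n_bg == 0:
        return 0.0
    p_bg = (total_nonzero - expected_inf) / (n * n_bg)
    if not 0 <= p_bg <= 1:
        raise ValueError(
            f"target sparsity unreachable: implied p_bg = {p_bg:.4f}"
        )
    return float(p_bg)


def simulate_compound_matrix(
    sample_clades: dict[str, str],
    n_features: int = DEFAULT_N_FEATURES,
    n_informative: int = DEFAULT_N_INFORMATIVE,
    p_in: float = DEFAULT_P_IN,
    p_out: float = DEFAULT_P_OUT,
    target_sparsity: float = DEFAULT_SPARSITY,
    p_bg: float | None = None,
    quantitative: bool = False,
    seed: int = 0,
) -> tuple[CompoundTable, GroundTruth]:
    """Clade-structured sparse presence/absence (or abundance) matrix.

    With ``quantitative=True`` present cells draw log-normal(0, 1)
    abundances and rows are normalised to percentages.
    """
    rng = np.random.default_rng(seed)
    samples = list(sample_clades)
    clade_names = sorted(set(sample_clades.values()), key=_clade_sort_key)
    clade_sizes = [
        sum(1 for s in samples if sample_clades[s] == c) for c in clade_names
    ]
    feature_ids = [f"C{k + 1:04d}" for k in range(n_features)]
    inf_ids = sorted(
        feature_ids[k]
        for k in rng.choice(n_features, size=n_informative, replace=False)
    )
    counts = apportion_informative(clade_sizes, n_informative)
    informative: dict[str, str] = {}
    pos = 0
    for clade, cnt in zip(clade_names, counts):
        for fid in inf_ids[pos : pos + cnt]:
            informative[fid] = clade
        pos += cnt

    if p_bg is None:
        p_bg = background_rate_for_sparsity(
            sample_clades, informative, n_features, p_in, p_out, target_sparsity
        )
    probs = np.full((len(samples), n_features), p_bg)
    col_of = {fid: k for k, fid in enumerate(feature_ids)}
    for fid, clade in informative.items():
        k = col_of[fid]
        for i, s in enumerate(samples):
            probs[i, k] = p_in if sample_clades[s] == clade else p_out
    present = (rng.random(probs.shape) < probs).astype(float)

    if quantitative:
        abund = np.where(present > 0, rng.lognormal(0.0, 1.0, present.shape), 0.0)
        totals = abund.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore"):
            values = np.where(totals > 0, abund / totals * 100.0, 0.0)
        mode = QUANTITATIVE
    else:
        values = present
        mode = QUALITATIVE

    meta = pd.DataFrame(
        {
            "species": [sample_clades[s] for s in samples],
            "infraspecific": ["" for _ in samples],
            "tissue": ["lid" for _ in samples],
        },
        index=pd.Index(samples, name="sample_id"),
    )
    table = CompoundTable(
        values=pd.DataFrame(values, index=meta.index, columns=feature_ids),
        mode=mode,
        meta=meta,
    )
    truth = GroundTruth(
        sample_clades=dict(sample_clades),
        informative=informative,
        p_in=p_in,
        p_out=p_out,
        p_bg=float(p_bg),
        seed=seed,
    )
    return table, truth


def _clade_sort_key(name: str):
    tail = name.removeprefix("clade")
    return (0, int(tail)) if tail.isdigit() else (1, name)


# ---------------------------------------------------------------------------
# peak records


def simulate_peak_records(
    table: CompoundTable,
    rt_jitter_sd: float = 0.0,
    match_range: tuple[float, float] = (70.0, 99.0),
    seed: int = 0,
) -> list[PeakRecord]:
    """One identified peak per nonzero cell of a quantitative table.

    Retention times are evenly spaced per compound (5-29 min) plus
    Gaussian jitter; library match percentages are uniform in
    ``match_range``; areas are the cell percentage scaled by a random
    per-sample total, so rebuilding relative abundances recovers the
    table exactly.
    """
    if table.mode != QUANTITATIVE:
        raise ValueError("quantitative table required")
    rng = np.random.default_rng(seed)
    compounds = table.compound_ids
    p = len(compounds)
    rt_map = {
        c: 5.0 + (24.0 * k / max(p - 1, 1)) for k, c in enumerate(compounds)
    }
    records: list[PeakRecord] = []
    for sample in table.sample_ids:
        row = table.values.loc[sample]
        scale = float(rng.lognormal(10.0, 0.5))
        for compound in compounds:
            pct = float(row[compound])
            if pct <= 0:
                continue
            rt = rt_map[compound] + (
                rng.normal(0.0, rt_jitter_sd) if rt_jitter_sd > 0 else 0.0
            )
            records.append(
                PeakRecord(
                    sample_id=sample,
                    rt=max(rt, 0.0),
                    compound_id=compound,
                    match_pct=float(rng.uniform(*match_range)),
                    area=pct * scale,
                )
            )
    return records


# ---------------------------------------------------------------------------
# SIM traces


def simulate_sim_trace(
    amount: float,
    ref: ReferencePattern | None = None,
    noise_sd: float = 1.0,
    seed: int = 0,
    rt_range: tuple[float, float] = (6.23, 6.43),
    dt: float = 0.002,
    peak_sigma: float = 0.004,
    height_scale: float = 100.0,
) -> pd.DataFrame:
    """Gaussian-shaped SIM peaks at 6.33 min for every monitored ion.

    Peak height for ion m is ``amount * ratio(m) * height_scale``; an
    ``amount`` of 0 gives pure noise.  With the default geometry the
    summed base-peak intensity inside the +/-0.01 min window is about
    500 * amount, which is what the default detection thresholds are
    calibrated against (amount 1.0 ~ the limit of detection).
    """
    if amount < 0:
        raise ValueError("amount must be nonnegative")
    ref = ref or ReferencePattern.default()
    rng = np.random.default_rng(seed)
    rts = np.arange(rt_range[0], rt_range[1] + dt / 2, dt)
    rows = []
    for mz in ref.ions:
        height = amount * ref.ratios[mz] * height_scale
        shape = height * np.exp(-((rts - ref.rt_center) ** 2) / (2 * peak_sigma**2))
        noisy = np.clip(shape + rng.normal(0.0, noise_sd, rts.shape), 0.0, None)
        rows.append(
            pd.DataFrame({"rt": rts, "mz": mz, "intensity": noisy})
        )
    return pd.concat(rows, ignore_index=True)
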