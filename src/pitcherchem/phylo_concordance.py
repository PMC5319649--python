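"""Phylogeny-chemistry concordance via within-/between-clade distances.

The question: do samples belonging to the same phylogenetic clade have
more similar metabolite profiles than samples from different clades?
Profiled samples are related to the tips of an independently estimated
accession tree by a many-to-many candidate relation (several samples may
plausibly stand for one accession).  Every *bijective map* — an injective
choice of one sample per tip — is enumerated.  For each map the pairwise
species-level distances (SLD) over the selected metabolite features give
per-clade within-clade distances (WCD, mean of within pairs) and
per-clade-pair between-clade distances (BCD, mean of cross pairs).
Averaging over all maps yields aWCD, aBCD and the averaged species-level
matrix aSLD; a one-sided Wilcoxon rank-sum test asks whether the aWCDs
are stochastically smaller than the aBCDs.  The single map maximising
mean(BCD) - mean(WCD) is kept for tree-ordered matrix export.
"""

from __future__ import annotations

import dataclasses
import itertools
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from scipy.spatial.distance import pdist, squareform

from .peak_tables import QUALITATIVE, CompoundTable

#: refuse to enumerate beyond this many bijective maps
DEFAULT_MAP_CAP = 10_000


@dataclasses.dataclass
class CladeFramework:
    """Rooted tree + clade partition + many-to-many sample<->tip relation."""

    tree: dendropy.Tree
    clades: dict[str, list[str]]  # clade name -> tip labels
    sample_map: dict[str, list[str]]  # tip label -> candidate sample ids

    def __post_init__(self) -> None:
        self.validate()

    @property
    def tip_order(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def clade_of(self) -> dict[str, str]:
        return {tip: name for name, tips in self.clades.items() for tip in tips}

    def mapped_samples(self) -> set[str]:
        return {s for cands in self.sample_map.values() for s in cands}

    def validate(self) -> None:
        tips = set(self.tip_order)
        seen: dict[str, str] = {}
        for name, members in self.clades.items():
            for tip in members:
                if tip not in tips:
                    raise ValueError(f"clade {name!r} references unknown tip {tip!r}")
                if tip in seen:
                    raise ValueError(
                        f"tip {tip!r} assigned to both {seen[tip]!r} and {name!r}"
                    )
                seen[tip] = name
        uncladed = tips - set(seen)
        if uncladed:
            raise ValueError(f"tips missing from clade table: {sorted(uncladed)}")
        for tip in self.sample_map:
            if tip not in tips:
                raise ValueError(f"mapping references unknown tip {tip!r}")


def read_clade_framework(
    newick: str | Path, clades: str | Path, mapping: str | Path
) -> CladeFramework:
    """Load tree (Newick), clade table (tip_id, clade_name) and sample map
    (sample_id, tip_id; repeated rows encode the many-to-many relation)."""
    tree = dendropy.Tree.get(
        path=str(newick), schema="newick", preserve_underscores=True
    )
    clade_df = pd.read_csv(clades, sep="\t", dtype=str)
    map_df = pd.read_csv(mapping, sep="\t", dtype=str)
    clade_dict: dict[str, list[str]] = {}
    for _, row in clade_df.iterrows():
        clade_dict.setdefault(row["clade_name"], []).append(row["tip_id"])
    sample_map: dict[str, list[str]] = {}
    for _, row in map_df.iterrows():
        sample_map.setdefault(row["tip_id"], []).append(row["sample_id"])
    return CladeFramework(tree=tree, clades=clade_dict, sample_map=sample_map)


# ---------------------------------------------------------------------------
# bijective maps


def enumerate_bijective_maps(
    fw: CladeFramework, cap: int = DEFAULT_MAP_CAP
) -> list[dict[str, str]]:
    """All injective one-sample-per-tip assignments, in lexicographic order.

    Tips are visited in sorted order and candidates in sorted order, so the
    enumeration order is deterministic.  A tip with no candidates raises;
    exceeding ``cap`` maps raises (the procedure is defined by exhaustive
    enumeration — reduce the mapping instead).
    """
    tips = sorted(fw.sample_map)
    for tip in tips:
        if not fw.sample_map[tip]:
            raise ValueError(f"tip {tip!r} has no candidate samples")
    candidates = {tip: sorted(set(fw.sample_map[tip])) for tip in tips}
    maps: list[dict[str, str]] = []

    def extend(k: int, used: set[str], acc: dict[str, str]) -> None:
        if k == len(tips):
            maps.append(dict(acc))
            if len(maps) > cap:
                raise ValueError(
                    f"more than {cap} bijective maps; reduce the mapping"
                )
            return
        tip = tips[k]
        for samp in candidates[tip]:
            if samp in used:
                continue
            acc[tip] = samp
            used.add(samp)
            extend(k + 1, used, acc)
            used.discard(samp)
            del acc[tip]

    extend(0, set(), {})
    if not maps:
        raise ValueError("no injective assignment exists for this mapping")
    return maps


# ---------------------------------------------------------------------------
# distances


def species_level_distances(
    table: CompoundTable, features: list[str], metric: str
) -> pd.DataFrame:
    """Pairwise sample distances over a feature subset.

    ``metric`` is ``"hamming"`` (count of disagreeing compounds; requires
    a qualitative table) or ``"euclidean"``.
    """
    if not features:
        raise ValueError("empty feature list")
    unknown = [f for f in features if f not in table.values.columns]
    if unknown:
        raise ValueError(f"unknown feature id(s): {unknown}")
    X = table.values.loc[:, list(features)].to_numpy(dtype=float)
    if metric == "hamming":
        if table.mode != QUALITATIVE:
            raise ValueError("hamming distance requires a qualitative table")
        d = pdist(X, metric="cityblock")  # |0/1 differences| = disagreement count
    elif metric == "euclidean":
        d = pdist(X, metric="euclidean")
    else:
        raise ValueError(f"unknown metric: {metric!r}")
    return pd.DataFrame(
        squareform(d), index=table.values.index, columns=table.values.index
    )


def within_clade_distance(sld: pd.DataFrame, members: list[str]) -> float:
    """Mean pairwise distance within a clade; NaN for singleton clades."""
    if not members:
        raise ValueError("empty clade")
    if len(members) == 1:
        return float("nan")
    sub = sld.loc[members, members].to_numpy()
    iu = np.triu_indices(len(members), k=1)
    return float(sub[iu].mean())


def between_clade_distance(
    sld: pd.DataFrame, clade_a: list[str], clade_b: list[str]
) -> float:
    """Mean distance over all cross pairs of two disjoint clades."""
    if not clade_a or not clade_b:
        raise ValueError("empty clade")
    if set(clade_a) & set(clade_b):
        raise ValueError("clades overlap")
    return float(sld.loc[clade_a, clade_b].to_numpy().mean())


def wilcoxon_less(x, y) -> float:
    """One-sided rank-sum p-value for "x stochastically smaller than y".

    Undefined (NaN) entries are removed first.  The exact null
    distribution is used when the combined sample size is at most 20 and
    there are no ties; otherwise the normal approximation with tie
    correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        raise ValueError("empty sample after removing undefined entries")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size + y.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="less", method=method)
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# averaging over maps


@dataclasses.dataclass
class DistanceSummary:
    """Per-map and map-averaged distance statistics."""

    maps: list[dict[str, str]]
    clade_names: list[str]
    sld_per_map: list[pd.DataFrame]  # tip x tip, one per map
    wcd_per_map: pd.DataFrame  # maps x clades (NaN for singletons)
    bcd_per_map: pd.DataFrame  # maps x clade pairs ("A|B")
    awcd: pd.Series  # per clade
    abcd: pd.Series  # per clade pair
    asld: pd.DataFrame  # tip x tip
    wilcoxon_p: float
    best_map_index: int

    @property
    def best_map(self) -> dict[str, str]:
        return self.maps[self.best_map_index]


def average_over_maps(
    fw: CladeFramework,
    table: CompoundTable,
    features: list[str],
    metric: str,
    cap: int = DEFAULT_MAP_CAP,
) -> DistanceSummary:
    """Enumerate bijective maps and average SLD/WCD/BCD over them."""
    maps = enumerate_bijective_maps(fw, cap=cap)
    tips = sorted(fw.sample_map)
    # clades restricted to mapped tips, in stable (input) order
    clades = {
        name: [t for t in members if t in fw.sample_map]
        for name, members in fw.clades.items()
    }
    clades = {name: mem for name, mem in clades.items() if mem}
    clade_names = list(clades)
    pair_names = [
        f"{a}|{b}" for a, b in itertools.combinations(clade_names, 2)
    ]

    # sample-level distances are map-independent; compute once
    sample_d = species_level_distances(table, features, metric)

    sld_per_map: list[pd.DataFrame] = []
    wcd_rows, bcd_rows = [], []
    for m in maps:
        order = [m[t] for t in tips]
        sld = pd.DataFrame(
            sample_d.loc[order, order].to_numpy(), index=tips, columns=tips
        )
        sld_per_map.append(sld)
        wcd_rows.append(
            {name: within_clade_distance(sld, clades[name]) for name in clade_names}
        )
        bcd_rows.append(
            {
                f"{a}|{b}": between_clade_distance(sld, clades[a], clades[b])
                for a, b in itertools.combinations(clade_names, 2)
            }
        )
    wcd_per_map = pd.DataFrame(wcd_rows, columns=clade_names)
    bcd_per_map = pd.DataFrame(bcd_rows, columns=pair_names)
    awcd = wcd_per_map.mean(axis=0, skipna=False)
    abcd = bcd_per_map.mean(axis=0)
    asld = sum(s.to_numpy() for s in sld_per_map) / len(maps)
    asld = pd.DataFrame(asld, index=tips, columns=tips)
    p = wilcoxon_less(awcd.to_numpy(), abcd.to_numpy())
    score = bcd_per_map.mean(axis=1) - wcd_per_map.mean(axis=1, skipna=True)
    best = int(score.to_numpy().argmax())  # first index on ties
    return DistanceSummary(
        maps=maps,
        clade_names=clade_names,
        sld_per_map=sld_per_map,
        wcd_per_map=wcd_per_map,
        bcd_per_map=bcd_per_map,
        awcd=awcd,
        abcd=abcd,
        asld=asld,
        wilcoxon_p=p,
        best_map_index=best,
    )


def best_bijective_map(summary: DistanceSummary) -> dict[str, str]:
    """The enumerated map maximising mean(BCD) - mean(WCD)."""
    return summary.best_map


def concordance_report(summary: DistanceSummary) -> dict:
    """Counts of aWCDs below the aSLD/aBCD background, plus the test result.

    The aSLD background distribution is formed by all off-diagonal entries
    of the map-averaged species-level distance matrix (within-clade pairs
    included).
    """
    asld = summary.asld.to_numpy()
    iu = np.triu_indices(asld.shape[0], k=1)
    background = asld[iu]
    awcd = summary.awcd.to_numpy()
    defined = awcd[~np.isnan(awcd)]
    abcd = summary.abcd.to_numpy()
    return {
        "n_maps": len(summary.maps),
        "n_clades": len(summary.clade_names),
        "n_awcd_defined": int(defined.size),
        "awcd": {k: None if np.isnan(v) else float(v) for k, v in summary.awcd.items()},
        "abcd_mean": float(abcd.mean()),
        "abcd_median": float(np.median(abcd)),
        "asld_mean": float(background.mean()),
        "asld_median": float(np.median(background)),
        "awcd_below_asld_mean": int((defined < background.mean()).sum()),
        "awcd_below_asld_median": int((defined < np.median(background)).sum()),
        "awcd_below_abcd_mean": int((defined < abcd.mean()).sum()),
        "awcd_below_abcd_median": int((defined < np.median(abcd)).sum()),
        "wilcoxon_p": float(summary.wilcoxon_p),
        "best_map_index": summary.best_map_index,
        "best_map": summary.best_map,
    }


def export_tree_ordered_matrix(
    fw: CladeFramework,
    mapping: dict[str, str],
    table: CompoundTable,
    features: list[str],
) -> tuple[pd.DataFrame, list[str]]:
    """Selected-feature submatrix with rows in tree tip order.

    Rows are tips (carrying the assigned sample's profile); samples not
    used by the mapping are returned separately rather than in the matrix
    (heat maps drawn against the tree omit them).
    """
    unknown = [f for f in features if f not in table.values.columns]
    if unknown:
        raise ValueError(f"unknown feature id(s): {unknown}")
    tips = [t for t in fw.tip_order if t in mapping]
    rows = table.values.loc[[mapping[t] for t in tips], list(features)].to_numpy()
    out = pd.DataFrame(rows, index=tips, columns=list(features))
    out.insert(0, "sample_id", [mapping[t] for t in tips])
    unmapped = [s for s in table.values.index if s not in set(mapping.values())]
    return out, unmapped
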