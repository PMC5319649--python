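"""Seeded end-to-end study loops over the synthetic generator.

These drive the generator's default ("study-shaped") conditions through
the sparse-clustering and concordance stages and report recovery, power
and size — the quantities the package's validation rests on.  The L1
bound is fixed at sqrt(20) for these studies: an equal-weight budget for
the 20 informative compounds the structured preset plants.
"""

from __future__ import annotations

import numpy as np

from . import phylo_concordance as pc
from . import sparse_cluster as sc
from . import synthetic_data as sd

#: L1 bound used throughout the preset studies
PRESET_S = float(np.sqrt(sd.DEFAULT_N_INFORMATIVE))


def _derive(seed: int, replicate: int) -> int:
    """Distinct per-replicate child seed, kept below 2**31."""
    return (seed * 1_000_003 + replicate) % (2**31 - 1)


def simulate_study(seed: int, structured: bool = True):
    """One synthetic study: framework, qualitative matrix, ground truth.

    ``structured=False`` is the null condition: same shape and sparsity
    but no clade-informative compounds (p_in = p_out irrelevant since
    zero features are informative).
    """
    fw, clade_of = sd.simulate_clade_framework(seed=seed)
    table, truth = sd.simulate_compound_matrix(
        clade_of,
        n_informative=sd.DEFAULT_N_INFORMATIVE if structured else 0,
        seed=seed + 1,
    )
    return fw, table, truth


def feature_recovery(seed: int) -> tuple[int, int]:
    """(# true informative features among the top-k weighted, k)."""
    _, table, truth = simulate_study(seed, structured=True)
    decomp = sc.per_feature_dissimilarities(table, sc.HAMMING)
    weights = sc.optimize_feature_weights(decomp, s=PRESET_S)
    k = len(truth.informative)
    order = np.argsort(-weights.w)[:k]
    top = {weights.feature_ids[i] for i in order}
    return len(top & set(truth.informative)), k


def feature_recovery_hits(n_runs: int = 50, seed: int = 0) -> list[int]:
    """Recovered-true-feature counts over seeded replicate runs."""
    return [feature_recovery(_derive(seed, r))[0] for r in range(n_runs)]


def feature_recovery_rate(
    n_runs: int = 50, min_hits: int = 16, seed: int = 0
) -> float:
    """Fraction of runs recovering at least ``min_hits`` true features."""
    hits = feature_recovery_hits(n_runs, seed)
    return sum(h >= min_hits for h in hits) / n_runs


def concordance_pvalue(seed: int, structured: bool = True) -> float:
    """Wilcoxon p (aWCD < aBCD) for one synthetic study.

    Features are selected by the sparse-clustering weights on the
    qualitative matrix; distances are Hamming over the selected set.
    """
    fw, table, _ = simulate_study(seed, structured=structured)
    decomp = sc.per_feature_dissimilarities(table, sc.HAMMING)
    weights = sc.optimize_feature_weights(decomp, s=PRESET_S)
    features = sc.selected_features(weights)
    summary = pc.average_over_maps(fw, table, features, metric="hamming")
    return summary.wilcoxon_p


def concordance_power(
    n_runs: int = 100, alpha: float = 0.01, seed: int = 0
) -> float:
    """Fraction of structured runs with p below ``alpha``."""
    hits = sum(
        concordance_pvalue(_derive(seed, r), structured=True) < alpha
        for r in range(n_runs)
    )
    return hits / n_runs


def null_rejection_rate(
    n_runs: int = 400, alpha: float = 0.05, seed: int = 0
) -> float:
    """Fraction of null runs rejected at ``alpha`` (nominal: alpha)."""
    hits = sum(
        concordance_pvalue(_derive(seed, r), structured=False) < alpha
        for r in range(n_runs)
    )
    return hits / n_runs
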