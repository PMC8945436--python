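"""miRNA-target expression correlation and transfection shift tests.

If a miRNA represses a target, the target's expression should correlate
negatively with the miRNA's across samples (Spearman, robust to monotone
transforms), and the target should drop after miRNA over-expression (or rise
after knock-down).  The background for correlations is an empirical null:
equally sized random gene sets resampled from the expression matrix
(1000 draws by default).
"""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def spearman_profile(
    mirna_vector: pd.Series, gene_matrix: pd.DataFrame
) -> pd.Series:
    """Per-gene Spearman rho against the miRNA across matched samples.

    Samples are matched by column name; missing values are dropped pairwise
    per gene; a gene with fewer than 3 overlapping samples gets NaN.  Ties are
    handled by average ranks (rank-transform then Pearson).
    """
    common = [c for c in gene_matrix.columns if c in mirna_vector.index]
    if len(common) < 3:
        raise ValueError("fewer than 3 overlapping samples")
    m = mirna_vector[common].to_numpy(dtype=float)
    x = gene_matrix[common].to_numpy(dtype=float)
    rhos = np.full(x.shape[0], np.nan)
    complete = ~np.isnan(x).any(axis=1)
    if not np.isnan(m).any() and complete.any():
        # fast path: rank once, Pearson on ranks
        xr = stats.rankdata(x[complete], axis=1)
        mr = stats.rankdata(m)
        xc = xr - xr.mean(axis=1, keepdims=True)
        mc = mr - mr.mean()
        denom = np.sqrt((xc**2).sum(axis=1) * (mc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            rhos[complete] = np.where(denom > 0, (xc @ mc) / denom, np.nan)
    for i in np.flatnonzero(~complete | np.isnan(m).any()):
        ok = ~np.isnan(x[i]) & ~np.isnan(m)
        if ok.sum() < 3:
            continue
        rhos[i] = stats.spearmanr(x[i, ok], m[ok]).statistic
    return pd.Series(rhos, index=gene_matrix.index, name="rho")


def random_gene_null(
    n_genes_per_draw: int,
    gene_matrix: pd.DataFrame,
    mirna_vector: pd.Series,
    n_draws: int = 1000,
    rng: np.random.Generator | int = 0,
    exclude: Sequence[str] = (),
) -> np.ndarray:
    """Null rho samples: ``n_draws`` random gene sets of the target-set size.

    Genes in ``exclude`` (e.g. predicted targets of the same miRNA) are
    removed from the pool before sampling, to keep the null uncontaminated.
    Returns an (n_draws, n_genes_per_draw) array of rhos.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(rng) if isinstance(rng, int) else rng
    pool = gene_matrix.drop(index=[g for g in exclude if g in gene_matrix.index])
    if n_genes_per_draw > len(pool):
        raise ValueError(
            f"draw size {n_genes_per_draw} exceeds pool of {len(pool)} genes"
        )
    rhos = spearman_profile(mirna_vector, pool).to_numpy()
    idx = np.stack(
        [
            rng.choice(len(pool), size=n_genes_per_draw, replace=False)
            for _ in range(n_draws)
        ]
    )
    return rhos[idx]


def compare_rho_groups(
    groups: Mapping[str, np.ndarray | Sequence[float]],
) -> dict:
    """Pairwise two-sided rank-sum comparison of correlation groups.

    Typical call: {'seed_target': ..., 'bulge_target': ..., 'random': ...}.
    The report carries group medians, the median ordering (most negative
    first), pairwise p-values, and a low-power flag for single-element groups.
    NaN rhos are dropped.
    """
    clean = {
        k: np.asarray(v, dtype=float)[~np.isnan(np.asarray(v, dtype=float))]
        for k, v in groups.items()
    }
    if any(a.size == 0 for a in clean.values()):
        raise ValueError("empty group")
    medians = {k: float(np.median(v)) for k, v in clean.items()}
    report: dict = {
        "medians": medians,
        "n": {k: int(v.size) for k, v in clean.items()},
        "ordering": sorted(medians, key=medians.get),
        "pairwise": {},
        "low_power": any(v.size < 2 for v in clean.values()),
    }
    names = list(clean)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = stats.mannwhitneyu(clean[a], clean[b], alternative="two-sided")
            report["pairwise"][f"{a}|{b}"] = {
                "p": float(res.pvalue),
                "more_negative_median": a if medians[a] < medians[b] else b,
            }
    return report


def transfection_shift_test(
    fold_changes: pd.Series,
    target_set: Sequence[str],
    control_set: Sequence[str],
    direction: str,
) -> dict:
    """One-sided Mann-Whitney test for a directional fold-change shift.

    ``direction='down'`` tests the over-expression hypothesis (targets shifted
    below controls); ``'up'`` the knock-down one.  Genes present in both sets
    are removed from the control with a warning.  The effect size is the
    difference of group medians (target − control).
    """
    if direction not in ("down", "up"):
        raise ValueError("direction must be 'down' or 'up'")
    targets = [g for g in target_set if g in fold_changes.index]
    overlap = set(targets) & set(control_set)
    if overlap:
        warnings.warn(
            f"{len(overlap)} genes in both target and control sets; removed "
            "from control"
        )
    controls = [
        g for g in control_set if g in fold_changes.index and g not in overlap
    ]
    if not targets or not controls:
        raise ValueError("empty target or control group after filtering")
    t = fold_changes[targets].dropna().to_numpy()
    c = fold_changes[controls].dropna().to_numpy()
    alt = "less" if direction == "down" else "greater"
    res = stats.mannwhitneyu(t, c, alternative=alt)
    return {
        "p": float(res.pvalue),
        "direction": direction,
        "median_difference": float(np.median(t) - np.median(c)),
        "n_targets": int(t.size),
        "n_controls": int(c.size),
    }
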