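"""Per-group allele frequencies, diversity indices and Nei genetic distances.

For a biallelic locus with ALT frequency p (q = 1 - p) estimated from the
called members of a group:

* Na — number of alleles observed (1 or 2; 0 if the locus has no calls),
* Ne — effective number of alleles, 1 / (p^2 + q^2),
* I  — Shannon information index, -(p ln p + q ln q), with 0 ln 0 := 0,
* h  — gene diversity (expected heterozygosity), 1 - (p^2 + q^2),
* uh — unbiased diversity, n/(n-1) * h with n the number of called
  individuals at the locus,
* %P — percentage of loci with two observed alleles among loci with calls.

Nei's genetic distance between groups X, Y uses per-locus gene identities
Jx = p^2 + q^2, Jy likewise, Jxy = p_x p_y + q_x q_y and

    D = -ln( mean(Jxy) / sqrt(mean(Jx) * mean(Jy)) )

(means over loci).  The unbiased variant replaces each within-group identity
by (2n J - 1)/(2n - 1) before averaging, correcting for sample size.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from .datatypes import GenotypeMatrix, validate_sample_groups

__all__ = [
    "group_allele_frequencies",
    "group_frequency_arrays",
    "diversity_indices",
    "per_locus_indices",
    "unbiased_diversity",
    "nei_distance",
    "nei_distance_matrix",
]


def _group_members(gm: GenotypeMatrix, groups: pd.DataFrame) -> dict[str, np.ndarray]:
    groups = validate_sample_groups(groups, gm)
    members = {}
    for g, sub in groups.groupby("group", sort=False):
        members[g] = gm.sample_index(sub["sample_id"].to_numpy())
        if members[g].size == 0:
            raise ValueError(f"group {g!r} is empty")
    return members


def group_frequency_arrays(
    gm: GenotypeMatrix, groups: pd.DataFrame
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Per group: (ALT frequency per marker, n_called per marker).

    Frequency is NaN at markers with no calls in the group.
    """
    out = {}
    for g, idx in _group_members(gm, groups).items():
        sub_d = gm.dosages[idx]
        sub_c = ~gm.missing_mask[idx]
        n_called = sub_c.sum(axis=0)
        alt = np.where(sub_c, sub_d, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(n_called > 0, alt / (2.0 * n_called), np.nan)
        out[g] = (p, n_called)
    return out


def group_allele_frequencies(gm: GenotypeMatrix, groups: pd.DataFrame) -> pd.DataFrame:
    """Long-form FreqTable: group, marker_id, p, n_called."""
    freqs = group_frequency_arrays(gm, groups)
    frames = [
        pd.DataFrame(
            {"group": g, "marker_id": gm.marker_ids, "p": p, "n_called": n}
        )
        for g, (p, n) in freqs.items()
    ]
    return pd.concat(frames, ignore_index=True)


def unbiased_diversity(h, n):
    """Small-sample correction uh = n/(n-1) * h (n = called individuals)."""
    h = np.asarray(h, dtype=float)
    n = np.asarray(n, dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.where(n >= 2, n / (n - 1.0) * h, np.nan)


def per_locus_indices(p: np.ndarray, n_called: np.ndarray) -> pd.DataFrame:
    """Na, Ne, I, h, uh per locus from ALT frequency and call counts."""
    p = np.asarray(p, dtype=float)
    q = 1.0 - p
    called = n_called > 0
    na = np.where(called, np.where((p > 0) & (p < 1), 2, 1), 0)
    j = p * p + q * q
    with np.errstate(invalid="ignore", divide="ignore"):
        ne = np.where(called, 1.0 / j, np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        plogp = np.where(p > 0, p * np.log(p), 0.0)
        qlogq = np.where(q > 0, q * np.log(q), 0.0)
    shannon = np.where(called, -(plogp + qlogq), np.nan)
    h = np.where(called, 1.0 - j, np.nan)
    uh = unbiased_diversity(h, n_called)
    return pd.DataFrame(
        {"Na": na, "Ne": ne, "I": shannon, "h": h, "uh": uh, "n_called": n_called}
    )


def _mean_se(x: np.ndarray) -> tuple[float, float]:
    x = x[~np.isnan(x)]
    if x.size == 0:
        return np.nan, np.nan
    se = np.std(x, ddof=1) / np.sqrt(x.size) if x.size > 1 else np.nan
    return float(np.mean(x)), float(se)


def diversity_indices(
    gm: GenotypeMatrix, groups: pd.DataFrame, per_locus: bool = False
):
    """GenAlEx-style diversity summary per group.

    Returns a DataFrame with one row per group: n, mean and SE of
    Na/Ne/I/h/uh over loci with calls, and pct_polymorphic.  With
    ``per_locus=True`` also returns {group: per-locus DataFrame}.
    """
    freqs = group_frequency_arrays(gm, groups)
    sizes = groups.groupby("group", sort=False).size()
    rows, locus_tables = [], {}
    for g, (p, n_called) in freqs.items():
        tab = per_locus_indices(p, n_called)
        locus_tables[g] = tab.assign(marker_id=gm.marker_ids)
        called = n_called > 0
        n_loci_called = int(called.sum())
        n_poly = int((tab["Na"].to_numpy() >= 2).sum())
        pct_p = 100.0 * n_poly / n_loci_called if n_loci_called else np.nan
        row = {"group": g, "n": int(sizes[g]), "n_loci": n_loci_called,
               "pct_polymorphic": pct_p}
        for col in ("Na", "Ne", "I", "h", "uh"):
            mean, se = _mean_se(tab[col].to_numpy(dtype=float))
            row[f"{col}_mean"], row[f"{col}_se"] = mean, se
        rows.append(row)
    summary = pd.DataFrame(rows)
    if per_locus:
        return summary, locus_tables
    return summary


def _identities(p: np.ndarray, n: np.ndarray, unbiased: bool) -> np.ndarray:
    j = p * p + (1.0 - p) ** 2
    if not unbiased:
        return j
    two_n = 2.0 * n
    with np.errstate(invalid="ignore", divide="ignore"):
        return (two_n * j - 1.0) / (two_n - 1.0)


def nei_distance(
    p_x: np.ndarray,
    p_y: np.ndarray,
    n_x: np.ndarray | None = None,
    n_y: np.ndarray | None = None,
    variant: str = "standard",
    pair_label: str = "",
) -> float:
    """Nei genetic distance from two ALT-frequency profiles.

    Loci where either profile is NaN (no calls) are excluded.  The
    ``unbiased`` variant requires per-locus call counts ``n_x``, ``n_y``.
    """
    if variant not in ("standard", "unbiased"):
        raise ValueError(f"unknown variant {variant!r}")
    p_x = np.asarray(p_x, dtype=float)
    p_y = np.asarray(p_y, dtype=float)
    ok = ~np.isnan(p_x) & ~np.isnan(p_y)
    if not ok.any():
        raise ValueError(f"no shared called loci for pair {pair_label or '(x, y)'}")
    unbiased = variant == "unbiased"
    if unbiased and (n_x is None or n_y is None):
        raise ValueError("unbiased variant needs per-locus call counts")
    px, py = p_x[ok], p_y[ok]
    jx = _identities(px, np.asarray(n_x, float)[ok] if unbiased else None, unbiased)
    jy = _identities(py, np.asarray(n_y, float)[ok] if unbiased else None, unbiased)
    jxy = px * py + (1.0 - px) * (1.0 - py)
    ratio = jxy.mean() / np.sqrt(jx.mean() * jy.mean())
    if ratio <= 0:
        raise ValueError(f"degenerate gene identity for pair {pair_label or '(x, y)'}")
    return max(0.0, -np.log(ratio))


def nei_distance_matrix(
    gm: GenotypeMatrix, groups: pd.DataFrame, variant: str = "unbiased"
) -> DistanceMatrix:
    """Pairwise Nei distance over the groups, as a skbio DistanceMatrix."""
    freqs = group_frequency_arrays(gm, groups)
    labels = list(freqs)
    m = len(labels)
    d = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            p_i, n_i = freqs[labels[i]]
            p_j, n_j = freqs[labels[j]]
            d[i, j] = d[j, i] = nei_distance(
                p_i, p_j, n_i, n_j, variant=variant,
                pair_label=f"({labels[i]}, {labels[j]})",
            )
    return DistanceMatrix(d, labels)
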