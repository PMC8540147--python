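"""Synthetic SNP panels with known truth for every pipeline stage.

Population structure follows the Balding-Nichols model: each marker has an
ancestral ALT frequency p ~ Uniform(0.05, 0.95), and group k draws its
frequency from Beta(p(1-F)/F, (1-p)(1-F)/F), so a single parameter F (the
group's F_ST against the ancestral pool) controls differentiation.
Genotypes are Binomial(2, theta) with theta mixing group frequencies
through each sample's ancestry row Q (one-hot without admixture, Dirichlet
rows when an admixture concentration alpha > 0).  Markers get uniform
genetic-map positions over a configurable chromosome set (default 7
chromosomes of 150 cM, the karyotype of barley).

Adaptation loci can be planted: selected markers are moved next to catalog
genes (within 0.8 x window) and given fixed opposite frequencies in a focal
and a contrast group; an equal number of decoy loci get the same opposite
frequencies but sit farther than 1.2 x window from every gene, so the scan
must select them and the gene-window annotation must reject them.  While
planting, background loci are constrained to |f_focal - f_contrast| <= 0.2
so the opposite-dominance rule at thresholds >= 0.6 separates planted from
background exactly at the frequency level.

A separate generator produces panels with distance-dependent LD: haplotypes
follow a Markov copy process along each chromosome, so dosage correlation
decays as exp(-d / scale) and r^2 as exp(-2d / scale).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import GenotypeMatrix

__all__ = [
    "SimConfig",
    "SimTruth",
    "simulate_panel",
    "ld_profile_panel",
    "decay_scale_for_crossing",
]

DEFAULT_CHROMOSOMES = {f"{i}H": 150.0 for i in range(1, 8)}


@dataclass
class SimConfig:
    """Parameters of a simulated multi-group SNP panel."""

    seed: int
    n_groups: int = 2
    samples_per_group: int = 30
    n_markers: int = 600
    chromosomes: dict = field(default_factory=lambda: dict(DEFAULT_CHROMOSOMES))
    fst: float | list = 0.2
    admixture_alpha: float = 0.0
    missing_rate: float = 0.0
    n_planted: int = 0
    n_decoys: int | None = None  # None = same as n_planted
    planted_f: tuple = (0.9, 0.1)
    focal_group: int = 0
    contrast_group: int = 1
    window_cM: float = 2.5
    n_genes: int = 0
    group_names: list | None = None

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        fst = np.broadcast_to(np.asarray(self.fst, dtype=float), (self.n_groups,))
        if not ((fst > 0) & (fst < 1)).all():
            raise ValueError("fst values must lie in (0, 1)")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_planted > 0 and self.n_genes == 0:
            raise ValueError("planted loci requested but gene catalog is empty")
        if self.group_names is not None and len(self.group_names) != self.n_groups:
            raise ValueError("group_names length must equal n_groups")


@dataclass
class SimTruth:
    """Generating quantities of a simulated panel."""

    ancestral_freqs: np.ndarray  # (n_markers,)
    group_freqs: pd.DataFrame  # groups x markers
    true_q: pd.DataFrame  # samples x groups
    planted: pd.DataFrame  # marker_id, kind, gene_id, f_focal, f_contrast
    planted_links: pd.DataFrame  # every (marker_id, gene_id) within the window
    group_names: list

    def freq_table(self) -> pd.DataFrame:
        """True per-group frequencies in FreqTable layout (n_called = inf proxy)."""
        frames = [
            pd.DataFrame(
                {
                    "group": g,
                    "marker_id": self.group_freqs.columns,
                    "p": self.group_freqs.loc[g].to_numpy(),
                    "n_called": np.iinfo(np.int32).max,
                }
            )
            for g in self.group_freqs.index
        ]
        return pd.concat(frames, ignore_index=True)


def _uniform_positions(rng, n: int, chromosomes: dict) -> pd.DataFrame:
    labels = list(chromosomes)
    lengths = np.array([chromosomes[c] for c in labels], dtype=float)
    chrom_idx = rng.integers(0, len(labels), size=n)
    pos = rng.uniform(0.0, lengths[chrom_idx])
    return pd.DataFrame(
        {"chromosome": [labels[i] for i in chrom_idx], "position_cM": pos}
    )


def simulate_panel(config: SimConfig):
    """Generate (GenotypeMatrix, MarkerMap, SampleGroups, GeneCatalog, SimTruth)."""
    rng = np.random.default_rng(config.seed)
    k, L = config.n_groups, config.n_markers
    groups = config.group_names or [f"G{i + 1}" for i in range(k)]
    fst = np.broadcast_to(np.asarray(config.fst, dtype=float), (k,))

    ancestral = rng.uniform(0.05, 0.95, size=L)
    freqs = np.empty((k, L))
    for g in range(k):
        a = ancestral * (1.0 - fst[g]) / fst[g]
        b = (1.0 - ancestral) * (1.0 - fst[g]) / fst[g]
        freqs[g] = rng.beta(a, b)

    # marker map: uniform positions, markers ordered along the genome
    marker_map = _uniform_positions(rng, L, config.chromosomes)
    marker_map = marker_map.sort_values(
        ["chromosome", "position_cM"], kind="stable"
    ).reset_index(drop=True)
    marker_ids = np.array([f"M{i + 1:05d}" for i in range(L)], dtype=object)
    marker_map.insert(0, "marker_id", marker_ids)

    gene_catalog = pd.DataFrame(columns=["gene_id", "chromosome", "position_cM"])
    if config.n_genes > 0:
        gene_catalog = _uniform_positions(rng, config.n_genes, config.chromosomes)
        gene_catalog.insert(
            0, "gene_id", [f"gene{i + 1:03d}" for i in range(config.n_genes)]
        )

    planted_rows: list[dict] = []
    planted_cols: list[int] = []
    if config.n_planted > 0:
        f_hi, f_lo = config.planted_f
        n_decoys = config.n_planted if config.n_decoys is None else config.n_decoys
        foc, con = config.focal_group, config.contrast_group
        # background loci in the focal/contrast pair stay within 0.2 of each
        # other so the scan separates planted from background exactly
        for _ in range(200):
            bad = np.abs(freqs[foc] - freqs[con]) > 0.2
            if not bad.any():
                break
            for g in (foc, con):
                a = ancestral[bad] * (1.0 - fst[g]) / fst[g]
                b = (1.0 - ancestral[bad]) * (1.0 - fst[g]) / fst[g]
                freqs[g][bad] = rng.beta(a, b)
        else:
            mid = 0.5 * (freqs[foc] + freqs[con])
            bad = np.abs(freqs[foc] - freqs[con]) > 0.2
            freqs[foc][bad] = np.clip(mid[bad] + 0.09, 0.0, 1.0)
            freqs[con][bad] = np.clip(mid[bad] - 0.09, 0.0, 1.0)

        chosen = rng.choice(
            len(gene_catalog),
            size=min(config.n_planted, len(gene_catalog)),
            replace=False,
        )
        pick = rng.choice(L, size=config.n_planted + n_decoys, replace=False)
        linked_idx, decoy_idx = pick[: config.n_planted], pick[config.n_planted :]
        planted_cols = [int(j) for j in pick]
        for j, gi in zip(linked_idx, np.resize(chosen, config.n_planted)):
            gene = gene_catalog.iloc[gi]
            offset = rng.uniform(-0.8, 0.8) * config.window_cM
            pos = max(0.0, gene["position_cM"] + offset)
            marker_map.loc[j, ["chromosome", "position_cM"]] = [
                gene["chromosome"], pos,
            ]
            freqs[foc, j], freqs[con, j] = f_hi, f_lo
            planted_rows.append(
                {
                    "marker_id": marker_ids[j],
                    "kind": "linked",
                    "gene_id": gene["gene_id"],
                    "f_focal": f_hi,
                    "f_contrast": f_lo,
                }
            )
        for j in decoy_idx:
            # place decoys beyond 1.2 x window of every catalog gene
            for _ in range(1000):
                row = _uniform_positions(rng, 1, config.chromosomes).iloc[0]
                same = gene_catalog[gene_catalog["chromosome"] == row["chromosome"]]
                if (
                    same.empty
                    or (same["position_cM"] - row["position_cM"]).abs().min()
                    > 1.2 * config.window_cM
                ):
                    break
            else:
                raise RuntimeError("could not place a decoy away from all genes")
            marker_map.loc[j, ["chromosome", "position_cM"]] = [
                row["chromosome"], row["position_cM"],
            ]
            freqs[foc, j], freqs[con, j] = f_hi, f_lo
            planted_rows.append(
                {
                    "marker_id": marker_ids[j],
                    "kind": "decoy",
                    "gene_id": None,
                    "f_focal": f_hi,
                    "f_contrast": f_lo,
                }
            )

    n = k * config.samples_per_group
    sample_ids = np.array([f"S{i + 1:04d}" for i in range(n)], dtype=object)
    group_of = np.repeat(np.arange(k), config.samples_per_group)
    if config.admixture_alpha > 0:
        q = rng.dirichlet(np.full(k, config.admixture_alpha), size=n)
        # keep the nominal group dominant: swap the largest component home
        for i in range(n):
            j = int(np.argmax(q[i]))
            g = group_of[i]
            q[i, j], q[i, g] = q[i, g], q[i, j]
    else:
        q = np.zeros((n, k))
        q[np.arange(n), group_of] = 1.0

    theta = q @ freqs
    dosages = rng.binomial(2, theta).astype(np.int8)
    missing = (
        rng.random(dosages.shape) < config.missing_rate
        if config.missing_rate > 0
        else np.zeros(dosages.shape, dtype=bool)
    )
    if planted_cols:
        # planted loci must survive the QC gate: fully called, MAF held up
        # by the opposite focal/contrast frequencies
        missing[:, planted_cols] = False

    gm = GenotypeMatrix(sample_ids, marker_ids, dosages, missing)
    sample_groups = pd.DataFrame(
        {"sample_id": sample_ids, "group": [groups[g] for g in group_of]}
    )
    planted = pd.DataFrame(
        planted_rows, columns=["marker_id", "kind", "gene_id", "f_focal", "f_contrast"]
    )
    # full truth of in-window links: a planted marker may sit inside the
    # window of catalog genes besides its designated one
    link_rows = []
    if len(planted):
        mm_idx = marker_map.set_index("marker_id")
        for mid in planted["marker_id"]:
            row = mm_idx.loc[mid]
            near = gene_catalog[
                (gene_catalog["chromosome"] == row["chromosome"])
                & (
                    (gene_catalog["position_cM"] - row["position_cM"]).abs()
                    <= config.window_cM
                )
            ]
            link_rows.extend(
                {"marker_id": mid, "gene_id": g} for g in near["gene_id"]
            )
    truth = SimTruth(
        ancestral_freqs=ancestral,
        group_freqs=pd.DataFrame(freqs, index=groups, columns=marker_ids),
        true_q=pd.DataFrame(q, index=sample_ids, columns=groups),
        planted=planted,
        planted_links=pd.DataFrame(link_rows, columns=["marker_id", "gene_id"]),
        group_names=groups,
    )
    return gm, marker_map, sample_groups, gene_catalog, truth


def decay_scale_for_crossing(crossing_cM: float, r2_threshold: float = 0.1) -> float:
    """Markov copy scale giving an expected r^2 crossing at ``crossing_cM``.

    With haplotype correlation exp(-d/scale), r^2 ~ exp(-2d/scale), so the
    threshold crossing sits at d = (scale/2) ln(1/threshold).
    """
    if not 0 < r2_threshold < 1:
        raise ValueError("r2_threshold must be in (0, 1)")
    return 2.0 * crossing_cM / np.log(1.0 / r2_threshold)


def ld_profile_panel(
    n_samples: int,
    markers_per_chromosome: int,
    decay_scale: float,
    chromosomes: dict | None = None,
    seed: int = 0,
):
    """Panel whose dosage correlation decays as exp(-d / decay_scale).

    Each chromosome is a Markov chain over two haplotypes per sample:
    marker j copies marker j-1 with probability exp(-delta_d / scale), else
    draws fresh from the chromosome's allele frequency.  Chromosomes are
    independent.  Returns (GenotypeMatrix, MarkerMap).
    """
    if decay_scale <= 0:
        raise ValueError("decay_scale must be positive")
    chromosomes = chromosomes or {"1H": 150.0, "2H": 150.0}
    rng = np.random.default_rng(seed)
    marker_ids, map_rows, cols = [], [], []
    idx = 0
    for chrom, length in chromosomes.items():
        pos = np.sort(rng.uniform(0.0, length, size=markers_per_chromosome))
        p = rng.uniform(0.3, 0.7)
        haps = np.empty((n_samples, 2, markers_per_chromosome), dtype=np.int8)
        haps[:, :, 0] = rng.random((n_samples, 2)) < p
        for j in range(1, markers_per_chromosome):
            c = np.exp(-(pos[j] - pos[j - 1]) / decay_scale)
            copy = rng.random((n_samples, 2)) < c
            fresh = rng.random((n_samples, 2)) < p
            haps[:, :, j] = np.where(copy, haps[:, :, j - 1], fresh)
        cols.append(haps.sum(axis=1))
        for j in range(markers_per_chromosome):
            idx += 1
            marker_ids.append(f"L{idx:05d}")
            map_rows.append({"marker_id": marker_ids[-1], "chromosome": chrom,
                             "position_cM": pos[j]})
    dosages = np.concatenate(cols, axis=1)
    sample_ids = np.array([f"S{i + 1:04d}" for i in range(n_samples)], dtype=object)
    gm = GenotypeMatrix(sample_ids, np.array(marker_ids, dtype=object), dosages)
    return gm, pd.DataFrame(map_rows)
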