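"""Opposite-allele-dominance scan and gene-window annotation.

A marker is selected for a focal/contrast group pair when some allele is
dominant in the focal group (frequency above a threshold T >= 0.5) while the
same allele is correspondingly rare in the contrast group (frequency below
1 - T).  Both the ALT and REF alleles are tested, so selection is invariant
to how the marker is coded.  The ``strict`` flag controls whether the
comparisons are strict inequalities (T = 0.5 with strict comparisons reads
"more than 50% opposite"; T = 0.65 non-strict reads "at least 65%").

Selected markers are then linked to catalog genes on the same chromosome
within a genetic-distance window (default 2.5 cM, a typical LD-decay range
for an inbreeding crop panel); a SNP may link to several genes and a gene to
several SNPs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import validate_gene_catalog, validate_marker_map

__all__ = [
    "MiningConfig",
    "opposite_dominance_scan",
    "link_to_genes",
    "intersect_scans",
]


@dataclass
class MiningConfig:
    """Scan parameters for one focal-vs-contrast comparison."""

    focal_group: str
    contrast_group: str
    threshold: float = 0.5
    strict: bool = True
    window_cM: float = 2.5

    def __post_init__(self) -> None:
        if self.threshold < 0.5:
            raise ValueError("threshold must be >= 0.5")
        if self.window_cM < 0:
            raise ValueError("window_cM must be >= 0")


def _group_freqs(freq_table: pd.DataFrame, group: str) -> pd.DataFrame:
    sub = freq_table[freq_table["group"] == group]
    if sub.empty:
        raise ValueError(f"group {group!r} absent from frequency table")
    return sub.set_index("marker_id")


def opposite_dominance_scan(
    freq_table: pd.DataFrame, config: MiningConfig
) -> pd.DataFrame:
    """Select markers with opposite allele dominance between two groups.

    ``freq_table`` is the long FreqTable (columns group, marker_id, p,
    n_called) with p the ALT frequency.  Returns the unannotated
    MinedSNPTable: marker_id, dominant_allele, f_focal, f_contrast.
    """
    t = config.threshold
    focal = _group_freqs(freq_table, config.focal_group)
    contrast = _group_freqs(freq_table, config.contrast_group)
    common = focal.index.intersection(contrast.index)
    pf = focal.loc[common, "p"].to_numpy(dtype=float)
    pc = contrast.loc[common, "p"].to_numpy(dtype=float)
    ok = ~np.isnan(pf) & ~np.isnan(pc)

    def dominated(f_focal, f_contrast):
        if config.strict:
            return (f_focal > t) & (f_contrast < 1.0 - t)
        return (f_focal >= t) & (f_contrast <= 1.0 - t)

    alt_hit = ok & dominated(pf, pc)
    ref_hit = ok & dominated(1.0 - pf, 1.0 - pc) & ~alt_hit
    rows = []
    for i in np.flatnonzero(alt_hit | ref_hit):
        allele = "ALT" if alt_hit[i] else "REF"
        f_f = pf[i] if allele == "ALT" else 1.0 - pf[i]
        f_c = pc[i] if allele == "ALT" else 1.0 - pc[i]
        rows.append(
            {
                "marker_id": common[i],
                "dominant_allele": allele,
                "f_focal": f_f,
                "f_contrast": f_c,
            }
        )
    out = pd.DataFrame(rows, columns=["marker_id", "dominant_allele", "f_focal", "f_contrast"])
    out.attrs["config"] = config
    return out


def link_to_genes(
    mined: pd.DataFrame,
    marker_map: pd.DataFrame,
    gene_catalog: pd.DataFrame,
    window_cM: float = 2.5,
) -> tuple[pd.DataFrame, dict]:
    """Annotate mined SNPs with catalog genes within ``window_cM``.

    A (snp, gene) link requires the same chromosome and |position
    difference| <= window.  Returns (links table, summary) where the
    summary counts selected SNPs, SNPs with >= 1 link, distinct linked
    genes, and total SNP-gene pairs.
    """
    marker_map = validate_marker_map(marker_map).set_index("marker_id")
    gene_catalog = validate_gene_catalog(gene_catalog)
    unmapped = [m for m in mined["marker_id"] if m not in marker_map.index]
    if unmapped:
        raise ValueError(f"mined markers without map positions: {unmapped[:5]}")
    rows = []
    for _, snp in mined.iterrows():
        chrom = marker_map.loc[snp["marker_id"], "chromosome"]
        pos = marker_map.loc[snp["marker_id"], "position_cM"]
        near = gene_catalog[
            (gene_catalog["chromosome"] == chrom)
            & ((gene_catalog["position_cM"] - pos).abs() <= window_cM)
        ]
        for _, gene in near.iterrows():
            rows.append(
                {
                    "marker_id": snp["marker_id"],
                    "chromosome": chrom,
                    "position_cM": pos,
                    "dominant_allele": snp["dominant_allele"],
                    "f_focal": snp["f_focal"],
                    "f_contrast": snp["f_contrast"],
                    "gene_id": gene["gene_id"],
                    "gene_position_cM": gene["position_cM"],
                    "distance_cM": abs(gene["position_cM"] - pos),
                }
            )
    links = pd.DataFrame(
        rows,
        columns=[
            "marker_id", "chromosome", "position_cM", "dominant_allele",
            "f_focal", "f_contrast", "gene_id", "gene_position_cM", "distance_cM",
        ],
    )
    summary = {
        "n_selected": int(len(mined)),
        "n_linked_snps": int(links["marker_id"].nunique()),
        "n_distinct_genes": int(links["gene_id"].nunique()),
        "n_snp_gene_pairs": int(len(links)),
    }
    return links, summary


def intersect_scans(*annotated: pd.DataFrame) -> dict:
    """Genes and markers common to several annotated scans.

    Order-stable: results follow first appearance in the first table.
    """
    if len(annotated) < 2:
        raise ValueError("need at least 2 annotated tables")

    def common(col: str) -> list:
        sets = [set(tab[col]) for tab in annotated]
        inter = set.intersection(*sets)
        seen, ordered = set(), []
        for v in annotated[0][col]:
            if v in inter and v not in seen:
                seen.add(v)
                ordered.append(v)
        return ordered

    return {"genes": common("gene_id"), "markers": common("marker_id")}
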