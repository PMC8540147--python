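"""One-config orchestration of the full panel analysis.

Stage order: qc -> diversity -> distances -> pcoa -> nj -> admixture+evanno
-> ld -> mining -> intersections.  Every run writes a manifest (inputs,
seed, per-stage counts and outputs); deterministic stages are bit-identical
across reruns, and stochastic stages are seeded from the global seed by a
fixed derivation (stage_seed = (seed * 1000003 + stage_index) mod 2^31), so
any stage can be rerun in isolation.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import io as apio
from .admixture import evanno_delta_k, fit_admixture, replicate_loglik_table
from .ld import decay_curve, distance_at_threshold, pairwise_r2
from .mining import MiningConfig, intersect_scans, link_to_genes, opposite_dominance_scan
from .ordination import PCoA, ibs_distance, nj_tree
from .popgen import diversity_indices, group_allele_frequencies, nei_distance_matrix
from .qc import apply_marker_filters

__all__ = ["RunConfig", "run_pipeline"]

STAGES = (
    "qc", "diversity", "distance", "pcoa", "nj",
    "admixture", "ld", "mining", "intersections",
)


@dataclass
class RunConfig:
    """Pipeline configuration; see README for the YAML schema."""

    genotypes: str
    groups: str
    output_dir: str
    seed: int = 0
    marker_map: str | None = None
    genes: str | None = None
    missing_token: str = "NA"
    delimiter: str = "\t"
    min_call_rate: float = 0.95
    min_maf: float = 0.05
    diversity: bool = True
    distance_variant: str = "unbiased"
    pcoa_axes: int = 3
    nj: bool = True
    admixture: dict | None = None  # {k_min, k_max, replicates}
    ld: dict | None = None  # {bin_width, threshold, max_dist_cM}
    mining: list = field(default_factory=list)  # [{focal, contrast, threshold, ...}]

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        cfg = cls(**raw)
        for key in ("genotypes", "groups", "marker_map", "genes"):
            p = getattr(cfg, key)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{key}: {p}")
        return cfg


def _stage_seed(seed: int, stage: str) -> int:
    return (seed * 1000003 + STAGES.index(stage)) % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "inputs": {
            "genotypes": str(config.genotypes),
            "groups": str(config.groups),
            "marker_map": str(config.marker_map) if config.marker_map else None,
            "genes": str(config.genes) if config.genes else None,
        },
        "stages": {},
    }

    def record(stage: str, **info) -> None:
        manifest["stages"][stage] = info

    def fail(stage: str, exc: Exception):
        record(stage, status="error", error=str(exc))
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    gm = apio.read_genotype_table(
        config.genotypes, missing_token=config.missing_token, delimiter=config.delimiter
    )
    groups = apio.read_sample_groups(config.groups, gm, delimiter=config.delimiter)
    marker_map = (
        apio.read_marker_map(config.marker_map, delimiter=config.delimiter)
        if config.marker_map
        else None
    )
    genes = (
        apio.read_gene_catalog(config.genes, delimiter=config.delimiter)
        if config.genes
        else None
    )

    t0 = time.time()
    try:
        gm, report = apply_marker_filters(gm, config.min_call_rate, config.min_maf)
    except Exception as exc:  # noqa: BLE001
        fail("qc", exc)
    report.table.to_csv(out / "filter_report.tsv", sep="\t", index=False)
    record(
        "qc", status="ok", n_kept=report.n_kept, n_total=report.n_total,
        n_dropped_call_rate=report.n_dropped_call_rate,
        n_dropped_maf=report.n_dropped_maf, seconds=round(time.time() - t0, 3),
    )

    if config.diversity:
        try:
            div = diversity_indices(gm, groups)
        except Exception as exc:  # noqa: BLE001
            fail("diversity", exc)
        div.round(3).to_csv(out / "diversity.tsv", sep="\t", index=False)
        record("diversity", status="ok", n_groups=len(div))
    else:
        record("diversity", status="skipped")

    try:
        dm = nei_distance_matrix(gm, groups, variant=config.distance_variant)
    except Exception as exc:  # noqa: BLE001
        fail("distance", exc)
    pd.DataFrame(dm.data, index=list(dm.ids), columns=list(dm.ids)).to_csv(
        out / "nei_distance.tsv", sep="\t"
    )
    record("distance", status="ok", variant=config.distance_variant, n_groups=len(dm.ids))

    if config.pcoa_axes and len(dm.ids) >= 3:
        try:
            ord_fit = PCoA(n_axes=config.pcoa_axes).fit(dm)
        except Exception as exc:  # noqa: BLE001
            fail("pcoa", exc)
        ord_fit.coordinates_.to_csv(out / "pcoa_coordinates.tsv", sep="\t")
        pd.DataFrame(
            {
                "eigenvalue": ord_fit.eigenvalues_,
                "percent_variance": ord_fit.percent_variance_,
            }
        ).to_csv(out / "pcoa_eigen.tsv", sep="\t", index=False)
        record(
            "pcoa", status="ok", axes=len(ord_fit.eigenvalues_),
            percent_variance=[round(v, 3) for v in ord_fit.percent_variance_],
        )
    else:
        record("pcoa", status="skipped")

    if config.nj:
        try:
            tree = nj_tree(ibs_distance(gm))
        except Exception as exc:  # noqa: BLE001
            fail("nj", exc)
        apio.write_newick(tree, out / "nj.nwk")
        record("nj", status="ok", n_leaves=gm.n_samples)
    else:
        record("nj", status="skipped")

    if config.admixture:
        adm = dict(config.admixture)
        k_values = range(int(adm.get("k_min", 2)) - 1 or 1, int(adm.get("k_max", 5)) + 2)
        k_values = [k for k in k_values if 1 <= k <= gm.n_samples]
        try:
            lk = replicate_loglik_table(
                gm, k_values, n_replicates=int(adm.get("replicates", 4)),
                seed=_stage_seed(config.seed, "admixture"),
            )
            ev = evanno_delta_k(lk)
        except Exception as exc:  # noqa: BLE001
            fail("admixture", exc)
        lk.to_csv(out / "lk_table.tsv", sep="\t", index=False)
        ev.table.to_csv(out / "evanno.tsv", sep="\t", index=False)
        best_k = ev.selected_k or ev.elbow_k
        if best_k:
            fit = fit_admixture(gm, best_k, seed=_stage_seed(config.seed, "admixture"))
            pd.DataFrame(
                fit.Q, index=list(gm.sample_ids),
                columns=[f"Q{i + 1}" for i in range(best_k)],
            ).to_csv(out / f"q_K{best_k}.tsv", sep="\t")
        record(
            "admixture", status="ok", k_tested=list(k_values),
            selected_k=ev.selected_k, elbow_k=ev.elbow_k, ambiguous=ev.ambiguous,
        )
    else:
        record("admixture", status="skipped")

    if config.ld and marker_map is not None:
        ldc = dict(config.ld)
        try:
            table = pairwise_r2(gm, marker_map, max_dist_cM=float(ldc.get("max_dist_cM", 50.0)))
            curve = decay_curve(table, bin_width=float(ldc.get("bin_width", 0.25)))
            crossing = distance_at_threshold(curve, float(ldc.get("threshold", 0.1)))
        except Exception as exc:  # noqa: BLE001
            fail("ld", exc)
        pd.DataFrame(
            {
                "bin_center_cM": curve.bin_center,
                "mean_r2": curve.mean_r2,
                "n_pairs": curve.n_pairs,
            }
        ).to_csv(out / "ld_curve.tsv", sep="\t", index=False)
        record(
            "ld", status="ok", n_pairs=len(table),
            crossing_cM=None if crossing != crossing or crossing == float("inf") else round(crossing, 4),
        )
    else:
        record("ld", status="skipped")

    annotated = []
    if config.mining:
        if marker_map is None or genes is None:
            fail("mining", ValueError("mining requires marker_map and genes inputs"))
        freq_table = group_allele_frequencies(gm, groups)
        summaries = []
        for spec in config.mining:
            mc = MiningConfig(
                focal_group=spec["focal"],
                contrast_group=spec["contrast"],
                threshold=float(spec.get("threshold", 0.5)),
                strict=bool(spec.get("strict", True)),
                window_cM=float(spec.get("window_cM", 2.5)),
            )
            try:
                mined = opposite_dominance_scan(freq_table, mc)
                links, summary = link_to_genes(mined, marker_map, genes, mc.window_cM)
            except Exception as exc:  # noqa: BLE001
                fail("mining", exc)
            tag = f"{mc.focal_group}_vs_{mc.contrast_group}"
            links.to_csv(out / f"mined_{tag}.tsv", sep="\t", index=False)
            annotated.append(links)
            summaries.append({"comparison": tag, **summary})
        record("mining", status="ok", comparisons=summaries)
    else:
        record("mining", status="skipped")

    if len(annotated) >= 2:
        common = intersect_scans(*annotated)
        (out / "intersections.json").write_text(json.dumps(common, indent=2))
        record(
            "intersections", status="ok",
            n_common_genes=len(common["genes"]), n_common_markers=len(common["markers"]),
        )
    else:
        record("intersections", status="skipped")

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest
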