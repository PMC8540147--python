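import numpy as np
import pandas as pd
import pytest

from agripop.mining import (
    MiningConfig,
    intersect_scans,
    link_to_genes,
    opposite_dominance_scan,
)
from agripop.simulate import SimConfig, simulate_panel


def _freq_table(rows):
    """rows: (marker, p_focal, p_contrast) -> FreqTable for groups F/C."""
    recs = []
    for marker, pf, pc in rows:
        recs.append({"group": "F", "marker_id": marker, "p": pf, "n_called": 20})
        recs.append({"group": "C", "marker_id": marker, "p": pc, "n_called": 20})
    return pd.DataFrame(recs)


class TestScan:
    def test_selected_at_065(self):
        ft = _freq_table([("m1", 0.70, 0.30)])
        out = opposite_dominance_scan(ft, MiningConfig("F", "C", 0.65, strict=True))
        assert list(out["marker_id"]) == ["m1"]
        assert out["dominant_allele"].iloc[0] == "ALT"

    def test_threshold_ordering(self):
        ft = _freq_table([("m1", 0.55, 0.45)])
        at_050 = opposite_dominance_scan(ft, MiningConfig("F", "C", 0.5, strict=True))
        at_065 = opposite_dominance_scan(ft, MiningConfig("F", "C", 0.65, strict=True))
        assert len(at_050) == 1 and len(at_065) == 0

    def test_ref_allele_dominance_detected(self):
        # ALT rare in focal (0.40) and common in contrast (0.90): REF side
        # has 0.60 > 0.5 in focal and 0.10 < 0.5 in contrast
        ft = _freq_table([("m1", 0.40, 0.90)])
        out = opposite_dominance_scan(ft, MiningConfig("F", "C", 0.5, strict=True))
        assert out["dominant_allele"].iloc[0] == "REF"
        assert out["f_focal"].iloc[0] == pytest.approx(0.60)
        assert out["f_contrast"].iloc[0] == pytest.approx(0.10)

    def test_boundary_strictness(self):
        ft = _freq_table([("m1", 0.65, 0.35)])
        strict = opposite_dominance_scan(ft, MiningConfig("F", "C", 0.65, strict=True))
        loose = opposite_dominance_scan(ft, MiningConfig("F", "C", 0.65, strict=False))
        assert len(strict) == 0 and len(loose) == 1

    def test_raising_threshold_never_grows_selection(self):
        rng = np.random.default_rng(19)
        ft = _freq_table(
            [(f"m{i}", rng.uniform(0, 1), rng.uniform(0, 1)) for i in range(200)]
        )
        sets = []
        for t in (0.5, 0.6, 0.7, 0.8, 0.9):
            out = opposite_dominance_scan(ft, MiningConfig("F", "C", t, strict=False))
            sets.append(set(out["marker_id"]))
        for small, big in zip(sets[1:], sets[:-1]):
            assert small <= big

    def test_global_allele_swap_invariance(self):
        rng = np.random.default_rng(8)
        rows = [(f"m{i}", rng.uniform(0, 1), rng.uniform(0, 1)) for i in range(100)]
        ft = _freq_table(rows)
        flipped = ft.assign(p=1.0 - ft["p"])
        cfg = MiningConfig("F", "C", 0.65, strict=False)
        a = set(opposite_dominance_scan(ft, cfg)["marker_id"])
        b = set(opposite_dominance_scan(flipped, cfg)["marker_id"])
        assert a == b

    def test_uncalled_markers_excluded(self):
        ft = _freq_table([("m1", np.nan, 0.1), ("m2", 0.9, 0.1)])
        out = opposite_dominance_scan(ft, MiningConfig("F", "C", 0.65))
        assert list(out["marker_id"]) == ["m2"]

    def test_missing_group_and_bad_threshold(self):
        ft = _freq_table([("m1", 0.9, 0.1)])
        with pytest.raises(ValueError, match="absent"):
            opposite_dominance_scan(ft, MiningConfig("F", "X", 0.65))
        with pytest.raises(ValueError, match=">= 0.5"):
            MiningConfig("F", "C", 0.4)


class TestGeneLinks:
    MAP = pd.DataFrame(
        {
            "marker_id": ["s1", "s2", "s3"],
            "chromosome": ["2H", "2H", "2H"],
            "position_cM": [10.0, 10.0, 10.0],
        }
    )
    GENES = pd.DataFrame(
        {
            "gene_id": ["gA", "gB", "gC"],
            "chromosome": ["2H", "2H", "3H"],
            "position_cM": [12.4, 12.6, 10.0],
        }
    )

    def _mined(self, markers):
        return pd.DataFrame(
            {
                "marker_id": markers,
                "dominant_allele": "ALT",
                "f_focal": 0.9,
                "f_contrast": 0.1,
            }
        )

    def test_window_boundary_and_chromosome_rule(self):
        links, summary = link_to_genes(self._mined(["s1"]), self.MAP, self.GENES, 2.5)
        # gA at 2.4 cM linked; gB at 2.6 cM and gC on 3H not linked
        assert list(links["gene_id"]) == ["gA"]
        assert links["distance_cM"].iloc[0] == pytest.approx(2.4)
        assert summary == {
            "n_selected": 1, "n_linked_snps": 1,
            "n_distinct_genes": 1, "n_snp_gene_pairs": 1,
        }

    def test_unmapped_marker_listed(self):
        with pytest.raises(ValueError, match="sX"):
            link_to_genes(self._mined(["sX"]), self.MAP, self.GENES, 2.5)

    def test_planted_truth_recovery(self):
        cfg = SimConfig(seed=77, n_groups=2, samples_per_group=30, n_markers=400,
                        fst=0.08, n_planted=12, n_decoys=4, n_genes=25,
                        planted_f=(0.9, 0.1))
        gm, mm, groups, genes, truth = simulate_panel(cfg)
        mined = opposite_dominance_scan(
            truth.freq_table(), MiningConfig("G1", "G2", 0.65, strict=False)
        )
        assert set(mined["marker_id"]) == set(truth.planted["marker_id"])
        links, summary = link_to_genes(mined, mm, genes, 2.5)
        got = set(zip(links["marker_id"], links["gene_id"]))
        expected = set(zip(truth.planted_links["marker_id"], truth.planted_links["gene_id"]))
        assert got == expected
        decoys = set(truth.planted.loc[truth.planted["kind"] == "decoy", "marker_id"])
        assert not decoys & set(links["marker_id"])
        assert summary["n_selected"] == 16
        assert summary["n_linked_snps"] == truth.planted_links["marker_id"].nunique()
        assert summary["n_distinct_genes"] == truth.planted_links["gene_id"].nunique()


class TestIntersect:
    def _tab(self, genes, markers):
        return pd.DataFrame({"gene_id": genes, "marker_id": markers})

    def test_common_genes(self):
        a = self._tab(["A", "B", "C"], ["m1", "m2", "m3"])
        b = self._tab(["B", "C", "D"], ["m2", "m9", "m3"])
        out = intersect_scans(a, b)
        assert out["genes"] == ["B", "C"]
        assert out["markers"] == ["m2", "m3"]

    def test_disjoint_sets_empty(self):
        out = intersect_scans(
            self._tab(["A"], ["m1"]), self._tab(["B"], ["m2"])
        )
        assert out == {"genes": [], "markers": []}

    def test_three_tables_match_pairwise_oracle(self):
        rng = np.random.default_rng(6)
        tabs = [
            self._tab(
                rng.choice(list("ABCDEFGH"), 6, replace=False),
                rng.choice([f"m{i}" for i in range(12)], 6, replace=False),
            )
            for _ in range(3)
        ]
        out = intersect_scans(*tabs)
        oracle = set(tabs[0]["gene_id"]) & set(tabs[1]["gene_id"]) & set(tabs[2]["gene_id"])
        assert set(out["genes"]) == oracle
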