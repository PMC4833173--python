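"""LD computation, greedy clumping vs brute force, pruning, proxy search."""

import numpy as np
import pandas as pd
import pytest

from crosstrait import ld
from crosstrait.gwas_io import HarmonizedStudy
from crosstrait.ld import ClumpSpec

from conftest import make_panel


def harmonized_from_panel(panel, pvals, weights=None):
    t = pd.DataFrame(
        {
            "snp_id": panel.variants["snp_id"],
            "chrom": panel.variants["chrom"].astype(str),
            "pos": panel.variants["pos"].astype(int),
            "panel_index": np.arange(panel.n_variants),
            "weight": weights if weights is not None else np.zeros(panel.n_variants),
            "p_value": pvals,
        }
    )
    return HarmonizedStudy(table=t)


def brute_force_clump(panel, pvals, window_kb, r2_threshold):
    """Literal restatement of the greedy definition, recomputed from
    scratch at every step (independent of the fast implementation)."""
    var = panel.variants
    unclaimed = set(range(panel.n_variants))
    retained = []
    while unclaimed:
        # smallest p, ties by (chrom, pos)
        idx = min(
            unclaimed,
            key=lambda j: (pvals[j], str(var.at[j, "chrom"]), int(var.at[j, "pos"])),
        )
        retained.append(var.at[idx, "snp_id"])
        unclaimed.discard(idx)
        for j in list(unclaimed):
            if str(var.at[j, "chrom"]) != str(var.at[idx, "chrom"]):
                continue
            if abs(int(var.at[j, "pos"]) - int(var.at[idx, "pos"])) > window_kb * 1000:
                continue
            try:
                r2 = ld.pairwise_r2(panel.dosages[:, idx], panel.dosages[:, j])
            except ValueError:
                continue  # undefined LD never claims
            if r2 >= r2_threshold:
                unclaimed.discard(j)
    return retained


class TestPairwiseR2:
    def test_self_correlation(self):
        v = np.array([0.0, 1, 2, 1, 0])
        assert ld.pairwise_r2(v, v) == pytest.approx(1.0)

    def test_reflection_invariance(self):
        v = np.array([0.0, 1, 2, 1, 0, 2])
        assert ld.pairwise_r2(v, 2 - v) == pytest.approx(1.0)

    def test_hand_computed_value(self):
        a = np.array([0.0, 0, 1, 1, 2, 2])
        b = np.array([0.0, 1, 0, 1, 2, 2])
        r = np.corrcoef(a, b)[0, 1] ** 2
        assert ld.pairwise_r2(a, b) == pytest.approx(r, abs=1e-12)
        # frozen value of the direct Pearson formula on this instance
        assert ld.pairwise_r2(a, b) == pytest.approx(0.5625, abs=1e-12)

    def test_missing_pairs_excluded(self):
        a = np.array([0.0, np.nan, 1, 1, 2, 2])
        b = np.array([0.0, 1, np.nan, 1, 2, 2])
        expected = np.corrcoef([0, 1, 2, 2], [0, 1, 2, 2])[0, 1] ** 2
        assert ld.pairwise_r2(a, b) == pytest.approx(expected)

    def test_zero_variance_is_error(self):
        with pytest.raises(ValueError, match="variance"):
            ld.pairwise_r2(np.ones(5), np.array([0.0, 1, 2, 0, 1]))

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            ld.pairwise_r2(np.ones(3), np.ones(4))


class TestClump:
    def test_dominant_snp_absorbs_neighbour(self, rng):
        col = rng.integers(0, 3, 30).astype(float)
        panel = make_panel(np.column_stack([col, col]), positions=[1000, 2000])
        h = harmonized_from_panel(panel, pvals=[1e-4, 1e-8])
        kept = ld.clump(h, panel, ClumpSpec(window_kb=250, r2_threshold=0.25))
        assert kept == ["rs2"]  # smaller p wins

    def test_window_never_spans_chromosomes(self, rng):
        col = rng.integers(0, 3, 30).astype(float)
        panel = make_panel(np.column_stack([col, col]), positions=[1000, 1000])
        panel.variants.loc[1, "chrom"] = "2"
        h = harmonized_from_panel(panel, pvals=[1e-4, 1e-8])
        kept = ld.clump(h, panel, ClumpSpec())
        assert sorted(kept) == ["rs1", "rs2"]

    def test_outside_window_retained(self, rng):
        col = rng.integers(0, 3, 30).astype(float)
        panel = make_panel(np.column_stack([col, col]), positions=[1000, 300_000])
        h = harmonized_from_panel(panel, pvals=[1e-4, 1e-8])
        kept = ld.clump(h, panel, ClumpSpec(window_kb=250))
        assert sorted(kept) == ["rs1", "rs2"]

    def test_matches_brute_force_on_random_instances(self, rng):
        for _ in range(40):
            m = int(rng.integers(4, 25))
            n = int(rng.integers(12, 40))
            base = rng.integers(0, 3, size=(n, m)).astype(float)
            # induce LD by copying some columns with noise
            for j in range(1, m):
                if rng.random() < 0.4:
                    base[:, j] = base[:, j - 1]
                    flip = rng.random(n) < 0.15
                    base[flip, j] = rng.integers(0, 3, flip.sum())
            positions = np.sort(rng.choice(500_000, size=m, replace=False))
            panel = make_panel(base, positions=positions)
            pvals = rng.random(m)
            spec = ClumpSpec(window_kb=float(rng.choice([50, 250])),
                             r2_threshold=float(rng.choice([0.2, 0.5, 0.8])))
            h = harmonized_from_panel(panel, pvals)
            expected = brute_force_clump(panel, pvals, spec.window_kb, spec.r2_threshold)
            assert sorted(ld.clump(h, panel, spec)) == sorted(expected)

    def test_retained_set_invariant_to_input_order(self, rng):
        m, n = 12, 30
        d = rng.integers(0, 3, size=(n, m)).astype(float)
        d[:, 3] = d[:, 2]
        panel = make_panel(d)
        pvals = rng.random(m)
        h = harmonized_from_panel(panel, pvals)
        shuffled = HarmonizedStudy(table=h.table.sample(frac=1, random_state=0).reset_index(drop=True))
        assert sorted(ld.clump(h, panel, ClumpSpec())) == sorted(
            ld.clump(shuffled, panel, ClumpSpec())
        )

    def test_raising_threshold_never_shrinks_retention(self, rng):
        m, n = 15, 40
        d = rng.integers(0, 3, size=(n, m)).astype(float)
        for j in range(1, m, 3):
            d[:, j] = d[:, j - 1]
        panel = make_panel(d)
        h = harmonized_from_panel(panel, pvals=rng.random(m))
        sizes = [
            len(ld.clump(h, panel, ClumpSpec(r2_threshold=t)))
            for t in (0.1, 0.5, 0.9, 1.0)
        ]
        assert sizes == sorted(sizes)

    def test_retained_pairs_below_threshold(self, rng):
        """Post-condition: no two retained SNPs within the window share
        r2 >= threshold."""
        m, n = 20, 50
        d = rng.integers(0, 3, size=(n, m)).astype(float)
        for j in range(1, m, 2):
            d[:, j] = d[:, j - 1]
        panel = make_panel(d)
        spec = ClumpSpec(window_kb=250, r2_threshold=0.3)
        h = harmonized_from_panel(panel, pvals=rng.random(m))
        kept = ld.clump(h, panel, spec)
        idx = [list(panel.variants["snp_id"]).index(s) for s in kept]
        pos = panel.variants["pos"].to_numpy()
        for i in idx:
            for j in idx:
                if i < j and abs(pos[i] - pos[j]) <= spec.window_kb * 1000:
                    assert ld.pairwise_r2(panel.dosages[:, i], panel.dosages[:, j]) < 0.3

    def test_missing_snp_in_panel_is_error(self, rng):
        panel = make_panel(rng.integers(0, 3, size=(10, 2)).astype(float))
        h = harmonized_from_panel(panel, pvals=[0.1, 0.2])
        h.table.loc[1, "snp_id"] = "rs_absent"
        with pytest.raises(ValueError, match="absent"):
            ld.clump(h, panel, ClumpSpec())


class TestPrune:
    def test_independent_snps_all_retained(self, rng):
        d = rng.integers(0, 3, size=(200, 10)).astype(float)
        panel = make_panel(d)
        assert len(ld.prune(panel, 250, 0.25)) == 10

    def test_duplicated_column_keeps_exactly_one(self, rng):
        col = rng.integers(0, 3, 50).astype(float)
        other = rng.integers(0, 3, 50).astype(float)
        panel = make_panel(np.column_stack([col, col, other]))
        kept = ld.prune(panel, 250, 0.25)
        assert "rs1" in kept and "rs2" not in kept  # later member dropped

    def test_tight_block_shrinks(self):
        from crosstrait.synth import SimConfig, simulate_panel

        cfg = SimConfig(n_snps=10, block_size=10, rho=0.95,
                        n_test_cases=250, n_test_controls=250, seed=9)
        panel = simulate_panel(cfg, "test")
        assert len(ld.prune(panel, 250, 0.25)) < 10


class TestFindProxy:
    def _panel(self, rng):
        target = rng.integers(0, 3, 120).astype(float)
        near_perfect = target.copy()
        weak = target.copy()
        mask = rng.random(120) < 0.5
        weak[mask] = rng.integers(0, 3, mask.sum())
        indep = rng.integers(0, 3, 120).astype(float)
        return make_panel(
            np.column_stack([target, near_perfect, weak, indep]),
            positions=[100_000, 110_000, 120_000, 130_000],
        )

    def test_identical_candidate_chosen(self, rng):
        panel = self._panel(rng)
        assert ld.find_proxy("rs1", ["rs2", "rs3", "rs4"], panel) == "rs2"

    def test_strict_threshold_excludes_exact_r2(self, rng):
        panel = self._panel(rng)
        r2 = ld.pairwise_r2(panel.dosages[:, 0], panel.dosages[:, 2])
        assert ld.find_proxy("rs1", ["rs3"], panel, r2_min=r2) is None
        assert ld.find_proxy("rs1", ["rs3"], panel, r2_min=r2 - 1e-9) == "rs3"

    def test_no_qualifying_candidate(self, rng):
        panel = self._panel(rng)
        assert ld.find_proxy("rs1", ["rs4"], panel, r2_min=0.6) is None

    def test_distance_breaks_r2_ties(self, rng):
        col = rng.integers(0, 3, 80).astype(float)
        panel = make_panel(
            np.column_stack([col, col, col]),
            positions=[100_000, 110_000, 200_000],
        )
        assert ld.find_proxy("rs1", ["rs2", "rs3"], panel) == "rs2"

    def test_window_limits_candidates(self, rng):
        col = rng.integers(0, 3, 80).astype(float)
        panel = make_panel(
            np.column_stack([col, col]), positions=[100_000, 900_000]
        )
        assert ld.find_proxy("rs1", ["rs2"], panel, window_kb=500) is None

    def test_unknown_target_position(self, rng):
        panel = self._panel(rng)
        with pytest.raises(ValueError, match="position"):
            ld.find_proxy("rs_nowhere", ["rs2"], panel)
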