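"""Multi-allelic LD, distance binning and the Evanno delta-K helper."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

import coldmap as cm
from coldmap.popgen_ld import LD_BIN_LABELS


def haplotype_vectors(counts):
    """Expand {('A','B'): 40, ...} into two aligned label arrays."""
    g1, g2 = [], []
    for (a, b), n in counts.items():
        g1 += [a] * n
        g2 += [b] * n
    return np.array(g1, dtype=object), np.array(g2, dtype=object)


class TestPairR2:
    def test_perfect_association(self):
        g1, g2 = haplotype_vectors({("A", "B"): 30, ("a", "b"): 30})
        r2, n = cm.pair_r2(g1, g2)
        assert r2 == pytest.approx(1.0)
        assert n == 60

    def test_hand_computed_biallelic(self):
        # D = 0.40 - 0.25 = 0.15; r2 = 0.15^2 / 0.5^4 = 0.36
        g1, g2 = haplotype_vectors(
            {("A", "B"): 40, ("A", "b"): 10, ("a", "B"): 10, ("a", "b"): 40}
        )
        r2, _ = cm.pair_r2(g1, g2)
        assert r2 == pytest.approx(0.36, abs=1e-12)

    def test_monomorphic_returns_none(self):
        g1, g2 = haplotype_vectors({("A", "B"): 10, ("A", "b"): 10})
        assert cm.pair_r2(g1, g2) is None

    def test_missing_dropped_pairwise(self):
        g1, g2 = haplotype_vectors({("A", "B"): 20, ("a", "b"): 20})
        g1[0] = np.nan
        g2[1] = None
        r2, n = cm.pair_r2(g1, g2)
        assert n == 38
        assert r2 == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_biallelic_reduces_to_classical_r2(self, seed):
        """On 2-allele markers the frequency-weighted statistic equals the
        squared Pearson correlation of allele indicator vectors."""
        rng = np.random.default_rng(seed)
        g1 = rng.choice(["A", "a"], size=80, p=[0.6, 0.4]).astype(object)
        g2 = rng.choice(["B", "b"], size=80, p=[0.3, 0.7]).astype(object)
        res = cm.pair_r2(g1, g2)
        if res is None:
            pytest.skip("monomorphic draw")
        classical = np.corrcoef((g1 == "A").astype(float), (g2 == "B").astype(float))[0, 1] ** 2
        assert res[0] == pytest.approx(classical, abs=1e-12)

    @given(st.randoms(use_true_random=False))
    def test_invariant_to_allele_relabeling(self, pyrandom):
        rng = np.random.default_rng(pyrandom.randrange(2**31))
        g1 = rng.choice(["A", "B", "C"], size=60).astype(object)
        g2 = rng.choice(["X", "Y", "Z"], size=60).astype(object)
        res = cm.pair_r2(g1, g2)
        if res is None:
            return
        relabel = {"A": "q3", "B": "q1", "C": "q2"}
        g1p = np.array([relabel[v] for v in g1], dtype=object)
        assert cm.pair_r2(g1p, g2)[0] == pytest.approx(res[0], abs=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_multiallelic_r2_in_unit_interval(self, seed):
        rng = np.random.default_rng(100 + seed)
        g1 = rng.choice([f"M_{s}" for s in (100, 104, 108, 112)], size=50).astype(object)
        g2 = rng.choice([f"N_{s}" for s in (100, 104, 108)], size=50).astype(object)
        res = cm.pair_r2(g1, g2)
        if res is not None:
            assert -1e-12 <= res[0] <= 1 + 1e-12


class TestPairwiseAndBinning:
    def test_pairwise_skips_monomorphic_in_scope(self):
        panel = pd.DataFrame(
            {
                "M1": ["M1_100", "M1_104", "M1_100", "M1_104"],
                "M2": ["M2_100"] * 4,  # monomorphic
                "M3": ["M3_100", "M3_104", "M3_100", "M3_104"],
            },
            index=pd.Index(list("abcd"), name="accession"),
        )
        mm = pd.DataFrame(
            {"marker": ["M1", "M2", "M3"], "chrom": ["1", "1", "2"],
             "pos_bp": [100, 200, 300]}
        )
        rec = cm.pairwise_r2(panel, mm)
        assert set(zip(rec["marker1"], rec["marker2"])) == {("M1", "M3")}
        assert not rec["same_chrom"].iloc[0]
        assert np.isnan(rec["dist_bp"].iloc[0])

    def test_half_open_bin_boundaries(self):
        rec = pd.DataFrame(
            {
                "marker1": ["a", "a"],
                "marker2": ["b", "c"],
                "same_chrom": [True, True],
                "dist_bp": [49_999, 50_000],
                "r2": [0.5, 0.2],
                "n": [10, 10],
            }
        )
        bins = cm.bin_ld_by_distance(rec).set_index("bin")
        assert bins.loc[LD_BIN_LABELS[0], "n"] == 1
        assert bins.loc[LD_BIN_LABELS[0], "mean_r2"] == pytest.approx(0.5)
        assert bins.loc[LD_BIN_LABELS[1], "n"] == 1
        assert bins.loc[LD_BIN_LABELS[1], "mean_r2"] == pytest.approx(0.2)

    def test_constant_bin_and_empty_bins(self):
        rec = pd.DataFrame(
            {
                "marker1": ["a"] * 3,
                "marker2": list("bcd"),
                "same_chrom": [True] * 3,
                "dist_bp": [10_000] * 3,
                "r2": [0.5] * 3,
                "n": [20] * 3,
            }
        )
        bins = cm.bin_ld_by_distance(rec).set_index("bin")
        assert bins.loc[LD_BIN_LABELS[0], "mean_r2"] == pytest.approx(0.5)
        assert bins.loc[LD_BIN_LABELS[0], "sd_r2"] == pytest.approx(0.0)
        empty = bins.loc[LD_BIN_LABELS[2]]
        assert empty["n"] == 0 and np.isnan(empty["mean_r2"])

    def test_genome_wide_row_includes_interchromosomal(self):
        rec = pd.DataFrame(
            {
                "marker1": ["a", "a"],
                "marker2": ["b", "c"],
                "same_chrom": [True, False],
                "dist_bp": [10_000, np.nan],
                "r2": [0.4, 0.2],
                "n": [10, 10],
            }
        )
        gw = cm.bin_ld_by_distance(rec).set_index("bin").loc["genome-wide"]
        assert gw["n"] == 2 and gw["mean_r2"] == pytest.approx(0.3)

    def test_null_mean_r2_near_one_over_n_minus_1(self):
        """Independent biallelic markers: E[r2] = 1/(n-1)."""
        rng = np.random.default_rng(42)
        n = 174
        vals = []
        for _ in range(600):
            p1, p2 = rng.uniform(0.3, 0.7, size=2)
            g1 = rng.choice(["A", "a"], size=n, p=[p1, 1 - p1]).astype(object)
            g2 = rng.choice(["B", "b"], size=n, p=[p2, 1 - p2]).astype(object)
            res = cm.pair_r2(g1, g2)
            if res is not None:
                vals.append(res[0])
        se = np.std(vals, ddof=1) / np.sqrt(len(vals))
        assert abs(np.mean(vals) - 1 / (n - 1)) < 4 * se

    def test_block_simulation_ld_decays_with_distance(self):
        """Copy-with-mutation blocks produce non-increasing bin means."""
        cfg = cm.SimulationConfig(
            n_accessions=200, subpop_proportions=(1.0,), subpop_names=("indica",),
            n_markers=80, alleles_per_marker=4, divergence=5.0,
            ld_block_span=400_000, chrom_lengths=(3_000_000,) * 4, seed=31,
        )
        panel, mm, _ = cm.simulate_genotypes(cfg)
        bins = cm.bin_ld_by_distance(cm.pairwise_r2(panel, mm)).set_index("bin")
        means = bins.loc[list(LD_BIN_LABELS), "mean_r2"].to_numpy()
        means = means[~np.isnan(means)]
        assert np.all(np.diff(means) <= 1e-9)

    @pytest.mark.parametrize("seed", [101, 202, 303])
    def test_within_subgroup_ld_below_whole_population(self, seed):
        """Structure inflates LD between distant markers; conditioning on the
        subpopulation removes it (distant/unlinked pairs, structured sims)."""
        cfg = cm.SimulationConfig(
            n_accessions=160, subpop_proportions=(0.625, 0.375), n_markers=40,
            alleles_per_marker=3, divergence=0.3, ld_block_span=0,
            chrom_lengths=(30_000_000,) * 4, seed=seed,
        )
        panel, mm, truth = cm.simulate_genotypes(cfg)
        rec_all = cm.pairwise_r2(panel, mm)
        distant_all = rec_all[~rec_all["same_chrom"] | (rec_all["dist_bp"] >= 500_000)]
        within = []
        for subsp in cm.SUBSPECIES:
            scope = truth.subpop[truth.subpop == subsp].index
            rec = cm.pairwise_r2(panel, mm, scope)
            rec = rec[~rec["same_chrom"] | (rec["dist_bp"] >= 500_000)]
            within.append(rec["r2"].mean())
        assert max(within) <= distant_all["r2"].mean()


class TestEvannoDeltaK:
    def make_table(self, means, reps=2, jitter=None):
        rows = []
        for k, m in means.items():
            offsets = jitter.get(k, [0.0] * reps) if jitter else [0.0] * reps
            for r, off in enumerate(offsets):
                rows.append({"K": k, "rep": r, "lnpd": m + off})
        return pd.DataFrame(rows)

    def test_linear_lnpd_gives_zero_delta_k(self):
        table = self.make_table({1: -100.0, 2: -80.0, 3: -60.0, 4: -40.0},
                                jitter={k: [-1.0, 1.0] for k in range(1, 5)})
        dk = cm.evanno_delta_k(table).set_index("K")["delta_k"]
        assert np.allclose(dk.to_numpy(), 0.0, atol=1e-9)

    def test_hand_computed_delta_k(self):
        table = self.make_table(
            {1: -100.0, 2: -50.0, 3: -45.0}, jitter={2: [1.0, -1.0]}
        )
        dk = cm.evanno_delta_k(table).set_index("K")
        # |(-45) - 2(-50) + (-100)| / sqrt(2) = 45 / 1.4142 = 31.82
        assert dk.loc[2, "delta_k"] == pytest.approx(31.82, abs=0.01)

    def test_knee_at_k2_is_argmax(self):
        """A sharp knee in LnP(D) at K=2 dominates the delta-K profile."""
        rng = np.random.default_rng(3)
        means = {1: -5000.0, 2: -3000.0, 3: -2950.0, 4: -2900.0, 5: -2850.0}
        jitter = {k: rng.normal(0, 5, size=10).tolist() for k in means}
        dk = cm.evanno_delta_k(self.make_table(means, reps=10, jitter=jitter))
        best = dk.loc[dk["delta_k"].idxmax(), "K"]
        assert best == 2

    def test_zero_replicate_sd_flagged_missing(self):
        table = self.make_table({1: -10.0, 2: -8.0, 3: -7.0})
        dk = cm.evanno_delta_k(table).set_index("K")
        assert np.isnan(dk.loc[2, "delta_k"])

    def test_requires_columns(self):
        with pytest.raises(ValueError):
            cm.evanno_delta_k(pd.DataFrame({"K": [1], "lnpd": [-1.0]}))
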