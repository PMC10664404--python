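"""Gene/region statistics: enrichment, trend, dN/dS, masking, uniformity."""

import math

import numpy as np
import pandas as pd
import pytest

from pithorep import CircularGenome
from pithorep import io as pio
from pithorep.simulate import simulate_cds_pair, simulate_ipd_track
from pithorep.stats import (
    ancestry_trend,
    assign_ancestry,
    cochran_armitage,
    compare_dnds,
    enrichment_chi2,
    genes_in_regions,
    masked_metrics,
    modified_base_density,
    ng86_dnds,
    repeat_uniformity,
)


def _genes(rows):
    return pd.DataFrame(rows, columns=["genome", "gene_id", "start", "end", "strand"])


class TestGenesInRegions:
    def test_no_regions_all_false(self):
        genes = _genes([("g", "a", 100, 200, "+")])
        out = genes_in_regions(genes, pd.DataFrame(columns=["chrom", "start", "end"]))
        assert not out["in_repeat"].any()

    def test_midpoint_containment(self):
        genes = _genes([("g", "a", 100, 200, "+"), ("g", "b", 950, 1100, "+")])
        regions = pd.DataFrame({"chrom": ["g"], "start": [0], "end": [1000]})
        out = genes_in_regions(genes, regions)
        assert list(out["in_repeat"]) == [True, False]  # midpoint 1025 outside

    def test_overlap_rule_differs_from_midpoint(self):
        genes = _genes([("g", "b", 950, 1100, "+")])
        regions = pd.DataFrame({"chrom": ["g"], "start": [0], "end": [1000]})
        assert genes_in_regions(genes, regions, rule="overlap")["in_repeat"].all()

    def test_mismatched_genome_ids_rejected(self):
        genes = _genes([("g1", "a", 0, 10, "+")])
        regions = pd.DataFrame({"chrom": ["g2"], "start": [0], "end": [5]})
        with pytest.raises(ValueError):
            genes_in_regions(genes, regions)

    def test_random_flags_match_brute_force(self):
        rng = np.random.default_rng(7)
        starts = rng.integers(0, 90_000, size=100)
        genes = _genes([("g", f"g{i}", int(s), int(s) + int(rng.integers(100, 2000)), "+")
                        for i, s in enumerate(starts)])
        rs = np.sort(rng.integers(0, 95_000, size=15))
        regions = pd.DataFrame({"chrom": "g", "start": rs,
                                "end": rs + rng.integers(500, 4000, size=15)})
        out = genes_in_regions(genes, regions)
        for _, g in out.iterrows():
            mid = (g.start + g.end) // 2
            expected = any(s <= mid < e for s, e in zip(regions.start, regions.end))
            assert g.in_repeat == expected


class TestEnrichmentChi2:
    def test_equal_proportions_null(self):
        res = enrichment_chi2((10, 100), (10, 100))
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_worked_table_closed_form(self):
        res = enrichment_chi2((10, 100), (2, 100))
        closed = 200 * (10 * 98 - 90 * 2) ** 2 / (100 * 100 * 12 * 188)
        assert res.statistic == pytest.approx(closed)
        assert closed == pytest.approx(5.674, abs=1e-3)

    def test_agrees_with_permutation_null(self):
        k_in, n_in, k_out, n_out = 30, 200, 18, 200
        res = enrichment_chi2((k_in, n_in), (k_out, n_out))
        rng = np.random.default_rng(1)
        labels = np.array([1] * (k_in + k_out) + [0] * (n_in + n_out - k_in - k_out))
        stats = []
        for _ in range(10_000):
            rng.shuffle(labels)
            ki = labels[:n_in].sum()
            ko = labels[n_in:].sum()
            t = np.array([[ki, n_in - ki], [ko, n_out - ko]])
            if (t.sum(axis=0) == 0).any():
                continue
            exp = np.outer(t.sum(1), t.sum(0)) / t.sum()
            stats.append(((t - exp) ** 2 / exp).sum())
        perm_p = np.mean(np.array(stats) >= res.statistic - 1e-9)
        assert res.p_value == pytest.approx(perm_p, abs=0.03)

    def test_degenerate_margin_rejected(self):
        with pytest.raises(ValueError):
            enrichment_chi2((0, 10), (0, 10))


class TestCochranArmitage:
    def test_flat_proportions_null(self):
        res = cochran_armitage(np.array([10, 10, 10]), np.array([100, 100, 100]))
        assert abs(res.statistic) < 1e-9
        assert res.p_value == pytest.approx(1.0)

    def test_rising_trend_significant(self):
        res = cochran_armitage(np.array([10, 20, 40]), np.array([100, 100, 100]))
        assert res.statistic > 0
        assert res.p_value < 0.01

    def test_agrees_with_permutation_oracle(self):
        x = np.array([3, 6, 10])
        n = np.array([30, 30, 30])
        res = cochran_armitage(x, n)
        rng = np.random.default_rng(2)
        labels = np.repeat([0, 1, 2], n)
        flags = np.array([1] * x.sum() + [0] * (n.sum() - x.sum()))
        scores = np.arange(3)
        phat = x.sum() / n.sum()

        def stat(fl):
            xs = np.array([fl[labels == i].sum() for i in range(3)])
            return np.sum(scores * (xs - n * phat))

        obs = stat_obs = np.sum(scores * (x - n * phat))
        perm = []
        for _ in range(20_000):
            rng.shuffle(flags)
            perm.append(stat(flags))
        perm_p = np.mean(np.abs(perm) >= abs(obs) - 1e-9)
        assert res.p_value == pytest.approx(perm_p, abs=0.02)

    def test_ancestry_trend_wiring(self):
        genes = pd.DataFrame(
            {
                "ancestry_node": ["root"] * 50 + ["mid"] * 50 + ["leaf"] * 50,
                "in_repeat": [True] * 5 + [False] * 45
                + [True] * 10 + [False] * 40
                + [True] * 20 + [False] * 30,
            }
        )
        res = ancestry_trend(genes, ["root", "mid", "leaf"])
        assert res.statistic > 0
        assert res.p_value < 0.01

    def test_unordered_nodes_rejected(self):
        genes = pd.DataFrame({"ancestry_node": ["x"], "in_repeat": [True]})
        with pytest.raises(ValueError):
            ancestry_trend(genes, ["root"])


class TestAncestryAssignment:
    def test_lca_definitions(self):
        tree = pio.read_tree("(((a:1,b:1):1,c:1):1,d:1);")
        root = tree.root
        # HOG spanning all leaves maps to the root
        assert assign_ancestry(tree, ["a", "b", "c", "d"], "a") is root
        # singleton HOG maps to the focal leaf
        leaf = assign_ancestry(tree, ["a"], "a")
        assert leaf.name == "a"
        # partial HOG maps to the LCA including the focal genome
        lca = assign_ancestry(tree, ["a", "b"], "a")
        assert {t.name for t in lca.get_terminals()} == {"a", "b"}


class TestNg86:
    def test_identical_pair_rejected_by_filters(self):
        est = ng86_dnds("TTTATGGCT", "TTTATGGCT")
        assert est.dn == 0.0 and est.ds == 0.0
        assert not est.accepted

    def test_single_synonymous_change(self):
        est = ng86_dnds("TTT", "TTC")
        assert est.dn == 0.0
        assert est.ds > 0.0

    def test_matches_reference_implementation(self):
        """Cross-check against Biopython's NG86 on simulated pairs."""
        from Bio.codonalign.codonseq import CodonSeq, cal_dn_ds

        for seed in (1, 2, 3):
            a, b = simulate_cds_pair(60, omega=0.5, n_events=150, seed=seed)
            dn_ref, ds_ref = cal_dn_ds(CodonSeq(a), CodonSeq(b), method="NG86")
            est = ng86_dnds(a, b)
            assert est.dn == pytest.approx(dn_ref, abs=1e-9)
            assert est.ds == pytest.approx(ds_ref, abs=1e-9)

    def test_internal_stop_rejected(self):
        with pytest.raises(ValueError):
            ng86_dnds("TAAATG", "TAAATG")

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ng86_dnds("ATGATG", "ATG")

    def test_omega_recovery(self):
        """Realized dN/dS of selection-filtered evolution ~ the set omega."""
        omegas = []
        for seed in range(50):
            a, b = simulate_cds_pair(300, omega=0.3, n_events=500, seed=seed)
            est = ng86_dnds(a, b)
            if est.ds > 0:
                omegas.append(est.omega)
        assert abs(np.mean(omegas) - 0.3) <= 0.1

    def test_neutral_evolution_dn_equals_ds(self):
        dn, ds = [], []
        for seed in range(60):
            a, b = simulate_cds_pair(300, omega=1.0, n_events=400, seed=seed)
            est = ng86_dnds(a, b)
            dn.append(est.dn)
            ds.append(est.ds)
        assert np.mean(dn) == pytest.approx(np.mean(ds), rel=0.1)


class TestCompareDnds:
    def test_identical_distributions_null(self):
        rng = np.random.default_rng(3)
        vals = pd.DataFrame({"dn": rng.random(50), "ds": rng.random(50) + 0.2,
                             "omega": rng.random(50)})
        res = compare_dnds(vals, vals)
        for metric in ("dn", "ds", "omega"):
            assert res[metric].p_value == pytest.approx(1.0, abs=1e-9)

    def test_shifted_omega_detected(self):
        rng = np.random.default_rng(4)
        v_in = pd.DataFrame({"dn": rng.random(100), "ds": rng.random(100) + 0.2,
                             "omega": 0.9 + 0.1 * rng.random(100)})
        v_out = pd.DataFrame({"dn": rng.random(100), "ds": rng.random(100) + 0.2,
                              "omega": 0.3 + 0.1 * rng.random(100)})
        res = compare_dnds(v_in, v_out)
        assert res["omega"].p_value < 0.01
        assert res["omega"].extra["median_in"] > res["omega"].extra["median_out"]

    def test_insufficient_side_rejected(self):
        v = pd.DataFrame({"dn": [0.1], "ds": [0.5], "omega": [0.2]})
        with pytest.raises(ValueError):
            compare_dnds(v, v)


class TestMaskedMetrics:
    def test_no_regions_identical_rows(self):
        g = CircularGenome("g", "ACGT" * 2500)
        genes = pd.DataFrame({"start": [0, 5000], "end": [1000, 6000]})
        out = masked_metrics(g, pd.DataFrame(columns=["start", "end"]), genes)
        assert out.loc["real"].equals(out.loc["masked"])

    def test_masked_length(self):
        g = CircularGenome("g", "ACGT" * 25_000)  # 100 kb
        regions = pd.DataFrame({"start": [10_000], "end": [30_000]})
        out = masked_metrics(g, regions)
        assert out.loc["real", "length_kb"] == pytest.approx(100.0)
        assert out.loc["masked", "length_kb"] == pytest.approx(80.0)

    def test_at_rich_repeats_raise_masked_gc(self):
        from pithorep import SimConfig, simulate_genome
        from pithorep.simulate import FamilySpec

        cfg = SimConfig(
            genome_length=60_000, n_regions=10, gc_fraction=0.45,
            family_specs=[FamilySpec("M1", 54, 37, 0.02),
                          FamilySpec("M2", 47, 37, 0.02)],
            seed=9,
        )
        # make the repeat consensus AT-rich by regenerating with low-GC draws
        import numpy as np
        from pithorep.simulate import simulate_genome as simgen

        sim = simgen(cfg)
        # replace region sequence GC by masking truth regions directly:
        out = masked_metrics(sim.genome, sim.regions, sim.genes)
        # planted elements share the background GC here, so instead plant
        # an explicitly AT-rich block and mask it
        rng = np.random.default_rng(1)
        bg = "".join(np.array(list("ACGT"))[rng.choice(4, 50_000,
                     p=[0.275, 0.225, 0.225, 0.275])])
        at = "".join(np.array(list("ACGT"))[rng.choice(4, 10_000,
                     p=[0.4, 0.1, 0.1, 0.4])])
        g2 = CircularGenome("g2", bg[:25_000] + at + bg[25_000:])
        regions = pd.DataFrame({"start": [25_000], "end": [35_000]})
        m = masked_metrics(g2, regions)
        assert m.loc["masked", "gc_pct"] > m.loc["real", "gc_pct"]

    def test_region_outside_genome_rejected(self):
        g = CircularGenome("g", "ACGT" * 100)
        with pytest.raises(IndexError):
            masked_metrics(g, pd.DataFrame({"start": [0], "end": [5000]}))


class TestModifiedBases:
    def test_density_per_kb(self):
        track = pd.DataFrame({"genome_id": "g",
                              "position": np.arange(10_000),
                              "ipd_ratio": 1.0})
        track.loc[[5, 100, 2000, 7000, 9999], "ipd_ratio"] = 6.0
        res = modified_base_density(track, [(0, 10_000), (0, 10_000)])
        assert res.extra["density_per_kb_0"] == pytest.approx(0.5)

    def test_equal_density_halves_not_significant(self):
        a = simulate_ipd_track("g", 150_000, 0.55, seed=1)
        b = simulate_ipd_track("g", 150_000, 0.55, seed=2, start=150_000)
        track = pd.concat([a, b], ignore_index=True)
        res = modified_base_density(track, [(0, 150_000), (150_000, 300_000)])
        assert res.p_value > 0.05

    def test_paper_regime_rates_usually_not_significant(self):
        """Rates of ~0.53 vs ~0.61 per kb over 300 kb halves rarely
        reach significance (the regime of a negative result)."""
        ps = []
        for s in range(10):
            a = simulate_ipd_track("g", 300_000, 0.53, seed=2 * s)
            b = simulate_ipd_track("g", 300_000, 0.61, seed=2 * s + 1, start=300_000)
            track = pd.concat([a, b], ignore_index=True)
            res = modified_base_density(track, [(0, 300_000), (300_000, 600_000)])
            ps.append(res.p_value)
        assert np.median(ps) > 0.05

    def test_empty_interval_rejected(self):
        track = simulate_ipd_track("g", 1000, 1.0, seed=1)
        with pytest.raises(ValueError):
            modified_base_density(track, [(0, 0), (0, 1000)])


class TestRepeatUniformity:
    def test_uniform_quantile_midpoints_high_p(self):
        L = 100_000
        mids = (np.arange(1, 21) - 0.5) / 20 * L
        regions = pd.DataFrame({"start": mids - 50, "end": mids + 50})
        res = repeat_uniformity(regions, L)
        assert res.p_value > 0.95

    def test_clustered_regions_rejected_as_uniform(self):
        rng = np.random.default_rng(5)
        starts = rng.uniform(0, 10_000, size=50)  # first 10% of a 100 kb genome
        regions = pd.DataFrame({"start": starts, "end": starts + 100})
        res = repeat_uniformity(regions, 100_000)
        assert res.p_value < 0.01

    def test_statistic_matches_brute_force_ecdf(self):
        rng = np.random.default_rng(6)
        starts = np.sort(rng.uniform(0, 90_000, size=30))
        regions = pd.DataFrame({"start": starts, "end": starts + 200})
        res = repeat_uniformity(regions, 100_000)
        mids = np.sort((regions.start + regions.end) / 2 / 100_000)
        n = len(mids)
        d_plus = np.max(np.arange(1, n + 1) / n - mids)
        d_minus = np.max(mids - np.arange(0, n) / n)
        assert res.statistic == pytest.approx(max(d_plus, d_minus))

    def test_too_few_regions_rejected(self):
        regions = pd.DataFrame({"start": [0], "end": [10]})
        with pytest.raises(ValueError):
            repeat_uniformity(regions, 1000)
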