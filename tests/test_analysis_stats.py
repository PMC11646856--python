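"""Entity normalization, comparison groups, tests, profiles, backgrounds."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from tcrmotion import analysis_stats as st
from tcrmotion import synthetic_data as sd
from tcrmotion.anchors import AnchorAnnotation, AnchorMode, assign_mode
from tcrmotion.structure_io import ApoHoloPair
from tcrmotion.superposition import MovementRecord


def _rec(entity, loop, comparison, value, metric="backbone_rmsd"):
    return MovementRecord(entity, loop, comparison, metric, value, 4)


class TestNormalization:
    def test_mean_per_entity_group(self):
        out = st.normalize_by_entity([
            _rec("e1", "CDR3a", "apo_holo", 1.0),
            _rec("e1", "CDR3a", "apo_holo", 3.0),
            _rec("e2", "CDR3a", "apo_holo", 5.0),
        ])
        values = dict(zip(out["entity_id"], out["value"]))
        assert values == {"e1": 2.0, "e2": 5.0}

    def test_idempotent(self):
        records = [
            _rec("e1", "CDR1a", "apo_apo", 0.5),
            _rec("e1", "CDR1a", "apo_apo", 1.5),
            _rec("e1", "CDR1a", "apo_holo", 2.5),
        ]
        once = st.normalize_by_entity(records)
        twice = st.normalize_by_entity(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_group_sizes_equal_distinct_entities(self, rng):
        entities = [f"e{i}" for i in range(7)]
        records = []
        for e in entities:
            for _ in range(int(rng.integers(1, 5))):
                records.append(_rec(e, "CDR3b", "apo_holo", float(rng.uniform(0, 3))))
        out = st.normalize_by_entity(records)
        assert len(out) == len(entities)


class TestComparisonGroups:
    @pytest.mark.parametrize("n_apo, n_holo", [(2, 2), (1, 1), (3, 2), (1, 4)])
    def test_counts_follow_closed_form_combinatorics(self, n_apo, n_holo):
        apo = [sd.make_toy_tcr(1, structure_id=f"a{i}") for i in range(n_apo)]
        holo = [sd.make_toy_tcr(1, structure_id=f"h{i}") for i in range(n_holo)]
        comps = st.enumerate_comparisons(apo, holo)
        counts = {}
        for group, _, _ in comps:
            counts[group] = counts.get(group, 0) + 1
        assert counts.get("apo_apo", 0) == math.comb(n_apo, 2)
        assert counts.get("apo_holo", 0) == n_apo * n_holo
        assert counts.get("holo_holo", 0) == math.comb(n_holo, 2)

    def test_movement_table_from_matched_pairs(self):
        cx = sd.make_toy_complex(21, structure_id="cx")
        base = sd.extract_tcr(cx, "base")
        spec = sd.PerturbationSpec("CDR3a", rigid_displacement=1.5, seed=3)
        apo, _, gt = sd.make_apo_holo_pair(base, spec)
        apo.structure_id = "apo0"
        pairs = [ApoHoloPair("ent", apo, cx, "tcr")]
        table = st.build_comparison_groups(pairs, st.tcr_pair_metrics)
        row = table.query(
            "loop_or_region == 'CDR3a' and metric == 'backbone_rmsd'")
        assert row["value"].iloc[0] == pytest.approx(gt.expected_unsuperposed_rmsd, abs=1e-9)
        assert set(table["comparison"]) == {"apo_holo"}


class TestKruskalWallis:
    def test_identical_groups_give_p_one(self):
        h, p = st.kruskal_wallis([[1.0, 1.0, 1.0], [1.0, 1.0]])
        assert (h, p) == (0.0, 1.0)

    def test_fully_separated_groups_match_rank_formula(self):
        """No rank overlap: H reaches its maximum for two groups of 3."""
        h, p = st.kruskal_wallis([[1, 2, 3], [101, 102, 103]])
        n = 6
        r1, r2 = 2.0, 5.0  # mean ranks
        expected = 12 / (n * (n + 1)) * (3 * (r1 - 3.5) ** 2 + 3 * (r2 - 3.5) ** 2)
        assert h == pytest.approx(expected, abs=1e-12)

    def test_matches_rank_formula_with_ties(self, rng):
        for _ in range(10):
            groups = [list(rng.integers(0, 4, size=int(rng.integers(3, 7))))
                      for _ in range(3)]
            flat = np.concatenate(groups).astype(float)
            if np.all(flat == flat[0]):
                continue
            h, _ = st.kruskal_wallis(groups)
            ranks = ss.rankdata(flat)
            n = len(flat)
            idx = 0
            num = 0.0
            for g in groups:
                r = ranks[idx: idx + len(g)]
                idx += len(g)
                num += len(g) * (r.mean() - (n + 1) / 2) ** 2
            h_raw = 12 / (n * (n + 1)) * num
            _, counts = np.unique(flat, return_counts=True)
            correction = 1 - np.sum(counts ** 3 - counts) / (n ** 3 - n)
            assert h == pytest.approx(h_raw / correction, abs=1e-10)

    def test_null_p_values_are_uniform(self):
        """Permutation null at n=20: asymptotic p-values pass a KS test."""
        rng = np.random.default_rng(2024)
        sizes = (7, 7, 6)
        ps = []
        for _ in range(1000):
            vals = rng.normal(size=sum(sizes))
            groups, i = [], 0
            for s in sizes:
                groups.append(vals[i:i + s])
                i += s
            ps.append(st.kruskal_wallis(groups)[1])
        assert ss.kstest(ps, "uniform").pvalue > 0.01


class TestPosthoc:
    def test_identical_groups_not_significant(self):
        out = st.posthoc_wilcoxon_bonferroni(
            {"a": [1.0, 1.0], "b": [1.0, 1.0]}, [("a", "b")])
        assert out[0]["p_raw"] == 1.0 and not out[0]["significant"]

    def test_bonferroni_corrected_level(self):
        groups = {"a": [1, 2], "b": [3, 4], "c": [5, 6]}
        comps = [("a", "b"), ("a", "c"), ("b", "c")]
        out = st.posthoc_wilcoxon_bonferroni(groups, comps)
        assert all(r["corrected_level"] == pytest.approx(0.05 / 3) for r in out)

    def test_p_values_match_exact_enumeration(self, rng):
        """Rank-sum p equals exhaustive combination enumeration, n <= 6."""
        for _ in range(20):
            n1, n2 = int(rng.integers(3, 7)), int(rng.integers(3, 7))
            x = list(rng.normal(size=n1))
            y = list(rng.normal(size=n2))
            out = st.posthoc_wilcoxon_bonferroni({"x": x, "y": y}, [("x", "y")])
            ranks = ss.rankdata(np.concatenate([x, y]))
            n = n1 + n2
            us = []
            for comb in itertools.combinations(range(n), n1):
                us.append(ranks[list(comb)].sum() - n1 * (n1 + 1) / 2)
            us = np.asarray(us)
            u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
            p_exact = min(1.0, 2 * min((us <= u_obs).mean(), (us >= u_obs).mean()))
            assert out[0]["p_raw"] == pytest.approx(p_exact, abs=1e-12)

    def test_empty_group_skipped_with_note(self):
        out = st.posthoc_wilcoxon_bonferroni({"a": [], "b": [1.0]}, [("a", "b")])
        assert out[0]["significant"] is None and "skipped" in out[0]["note"]


class TestBindingMode:
    @pytest.mark.parametrize("values, mode, dual", [
        ([1.4, 1.2], "flexible", False),
        ([0.3], "rigid", False),
        ([0.7, 0.9], "intermediate", False),
        ([1.4, 0.3], "intermediate", True),
        ([0.3, 0.7, 1.4], "intermediate", True),
    ])
    def test_threshold_rules(self, values, mode, dual):
        bm = st.classify_binding_mode("e", values)
        assert (bm.mode, bm.dual_mode) == (mode, dual)

    def test_order_invariant(self, rng):
        values = list(rng.uniform(0, 2, size=6))
        base = st.classify_binding_mode("e", values)
        for _ in range(5):
            rng.shuffle(values)
            again = st.classify_binding_mode("e", values)
            assert (again.mode, again.dual_mode) == (base.mode, base.dual_mode)

    def test_empty_values_raise(self):
        with pytest.raises(ValueError):
            st.classify_binding_mode("e", [])


class TestProfiles:
    def test_entity_mean_and_single_entity_sd(self):
        prof = st.per_position_profile([
            ("e1", 111, 1.0), ("e2", 111, 3.0), ("e1", 112, 2.0),
        ])
        row111 = prof[prof["position"] == 111].iloc[0]
        assert row111["mean"] == pytest.approx(2.0)
        row112 = prof[prof["position"] == 112].iloc[0]
        assert np.isnan(row112["sd"])  # observed in a single entity

    def test_within_entity_values_averaged_first(self):
        prof = st.per_position_profile([
            ("e1", 5, 0.0), ("e1", 5, 2.0), ("e2", 5, 3.0),
        ])
        assert prof["mean"].iloc[0] == pytest.approx(2.0)  # mean(1.0, 3.0)

    def test_peptide_region_movement_planted(self):
        cx = sd.make_toy_complex(31, structure_id="cx")
        base = sd.extract_pmhc(cx, "base")
        spec = sd.PerturbationSpec("peptide", rigid_displacement=2.0, seed=7)
        apo, _, gt = sd.make_apo_holo_pair(base, spec)
        pairs = [ApoHoloPair("pep|X", apo, cx, "pmhc")]
        table = st.peptide_region_movement(pairs, {58, 65}, set(range(100, 140)))
        values = dict(zip(table["loop_or_region"], table["value"]))
        assert values["peptide"] == pytest.approx(gt.expected_unsuperposed_rmsd, abs=1e-9)
        assert values["mhc_tcr_contact"] == pytest.approx(0.0, abs=1e-9)
        assert values["mhc_non_contact"] == pytest.approx(0.0, abs=1e-9)

    def test_anchor_conditioned_profiles_recover_planted_shapes(self):
        pairs, annotations = [], {}
        for i, mode in enumerate(["P2_P9", "P2_P9", "P2_P5_P9", "P2_P5_P9"]):
            cx = sd.make_toy_complex(40 + i, anchor_mode=mode,
                                     structure_id=f"cx{i}", allele=f"AL{i}")
            base = sd.extract_pmhc(cx, f"b{i}")
            anchors = frozenset({2, 9} | ({5} if mode == "P2_P5_P9" else set()))
            spec = sd.PerturbationSpec("peptide", internal_amplitude=1.5,
                                       profile="anchored", anchor_positions=anchors,
                                       project_rigid_modes=False, seed=50 + i)
            apo, _, _ = sd.make_apo_holo_pair(base, spec)
            entity = f"pep{i}|AL{i}"
            pairs.append(ApoHoloPair(entity, apo, cx, "pmhc"))
            annotations[entity] = assign_mode(
                AnchorAnnotation(entity, f"AL{i}", 9, set(anchors)))
        profiles = st.anchor_conditioned_peptide_profile(pairs, annotations)
        uni = profiles[AnchorMode.P2_P9].set_index("position")["mean"]
        bi = profiles[AnchorMode.P2_P5_P9].set_index("position")["mean"]
        # unimodal: maximum in the middle, zero at anchors
        assert uni.idxmax() in (5, 6)
        assert uni[2] == pytest.approx(0.0, abs=1e-9)
        assert uni[9] == pytest.approx(0.0, abs=1e-9)
        # bimodal: local minimum at the p5 anchor
        assert bi[5] == pytest.approx(0.0, abs=1e-9)
        assert bi[4] > bi[5] and bi[6] > bi[5]


class TestBackground:
    def test_sampling_shape_and_determinism(self):
        table = sd.make_background_repertoire(2000, seed=5)
        first = st.sample_background(table, n=500, reps=3, seed=9)
        second = st.sample_background(table, n=500, reps=3, seed=9)
        assert len(first) == 3
        for a, b in zip(first, second):
            pd.testing.assert_frame_equal(a, b)
            assert len(a) == 500 and not a.duplicated().any()

    def test_sample_larger_than_table_raises(self):
        table = sd.make_background_repertoire(50, seed=5)
        with pytest.raises(ValueError):
            st.sample_background(table, n=100)

    def test_sampled_frequencies_converge_to_table_frequencies(self):
        table = sd.make_background_repertoire(12000, seed=6)
        samples = st.sample_background(table, n=10_000, reps=2, seed=6)
        base = st.frequency_table(table["TRBV"])
        for s in samples:
            freqs = st.frequency_table(s["TRBV"])
            for gene, f in base.items():
                assert freqs.get(gene, 0.0) == pytest.approx(f, abs=0.02)

    def test_enrichment_formula(self):
        samples = [pd.DataFrame({"V": ["g1"] * 10 + ["g2"] * 90})]
        out = {r.label: r for r in st.gene_usage_enrichment(
            ["g1"] * 15 + ["g2"] * 85, samples, "V")}
        assert out["g1"].percent_enrichment == pytest.approx(50.0)
        assert out["g2"].percent_enrichment == pytest.approx(100 * (0.85 - 0.9) / 0.9)

    def test_absent_background_gene_is_flagged(self):
        samples = [pd.DataFrame({"V": ["g1"] * 10})]
        out = {r.label: r for r in st.gene_usage_enrichment(["g9"], samples, "V")}
        assert out["g9"].percent_enrichment is None

    def test_allele_suffixes_are_harmonized(self):
        samples = [pd.DataFrame({"V": ["TRBV19*01"] * 5 + ["TRBV19*02"] * 5})]
        out = {r.label: r for r in st.gene_usage_enrichment(["TRBV19*03"], samples, "V")}
        assert out["TRBV19"].background_frequency == pytest.approx(1.0)

    def test_planted_overuse_recovered(self):
        """A gene planted at twice its background rate shows ~+100%."""
        freqs = {f"TRBV{i}": 0.08 for i in range(1, 11)}
        freqs["TRBV19"] = 0.2
        background = sd.make_background_repertoire(
            8000, gene_freqs={**sd.DEFAULT_V_GENES, "TRBV": freqs}, seed=8)
        rng = np.random.default_rng(9)
        names = sorted(freqs)
        # dataset uses TRBV19 at 0.4 = 2x its 0.2 background rate
        p = np.array([0.4 if g == "TRBV19" else 0.6 / 9 for g in names])
        dataset = list(rng.choice(names, size=4000, p=p / p.sum()))
        samples = st.sample_background(background, n=1000, reps=10, seed=10)
        out = {r.label: r for r in st.gene_usage_enrichment(dataset, samples, "TRBV")}
        assert out["TRBV19"].percent_enrichment == pytest.approx(100.0, abs=15.0)
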