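"""Sample composition, intermixture, seeding, dominant lineage, fluids."""

import numpy as np
import pandas as pd
import pytest

from clonetracer.dissemination import (
    classify_seeding,
    compose_sample,
    detect_intermixture,
    detect_subclones_in_fluid,
    find_dominant_lineage,
    match_fluid_to_tissue,
)
from clonetracer.phylogeny import CloneTree

# toy tree: 0 -> 1 -> {2, 3}; 2 -> 4
TREE = CloneTree(root=0, parent={0: None, 1: 0, 2: 1, 3: 1, 4: 2})


class TestComposeSample:
    def test_terminal_and_proportion_classes(self):
        comp = compose_sample("s", "prostate", {0: 1.0, 1: 0.6, 2: 0.3}, TREE, 0.02)
        assert comp.terminal_clusters == [2]
        assert comp.proportion_class == {0: "high", 1: "high", 2: "low"}

    def test_empty_composition_for_tumor_free_sample(self):
        comp = compose_sample("s", "fluid", {0: 0.001, 1: 0.0}, TREE, 0.02)
        assert comp.clusters_present == {} and comp.terminal_clusters == []

    def test_half_ccf_is_low_proportion(self):
        comp = compose_sample("s", "prostate", {0: 0.5}, TREE, 0.02)
        assert comp.proportion_class[0] == "low"


class TestIntermixture:
    def test_sibling_branches_intermixed(self):
        comp = compose_sample("s", "prostate", {0: 1.0, 2: 0.4, 3: 0.3}, TREE, 0.02)
        out = detect_intermixture([comp], TREE)
        assert bool(out.intermixed.iloc[0]) and out.lineage_count.iloc[0] == 2

    def test_chain_only_not_intermixed(self):
        comp = compose_sample("s", "prostate", {0: 1.0, 1: 0.8, 2: 0.5}, TREE, 0.02)
        out = detect_intermixture([comp], TREE)
        assert not bool(out.intermixed.iloc[0])

    def test_generator_truth_comparison(self):
        """Samples carrying two sibling branches in truth are exactly the ones
        flagged intermixed."""
        rng = np.random.default_rng(5)
        comps, expect = [], []
        for i in range(6):
            mixed = i % 2 == 0
            if mixed:
                cc = {0: 1.0, 2: float(rng.uniform(0.1, 0.5)), 3: float(rng.uniform(0.1, 0.4))}
            else:
                cc = {0: 1.0, 1: 0.7, 2: float(rng.uniform(0.1, 0.6))}
            comps.append(compose_sample(f"s{i}", "prostate", cc, TREE, 0.02))
            expect.append(mixed)
        out = detect_intermixture(comps, TREE)
        assert list(out.intermixed) == expect

    def test_no_local_sample_is_error(self):
        comp = compose_sample("s", "bone", {0: 1.0}, TREE, 0.02)
        with pytest.raises(ValueError):
            detect_intermixture([comp], TREE)


class TestSeeding:
    def test_single_path_monoclonal(self):
        comp = compose_sample("m", "bone", {0: 1.0, 1: 0.9, 2: 0.6}, TREE, 0.02)
        calls, summary = classify_seeding([comp], TREE)
        assert calls[0].mode == "monoclonal"
        assert summary["patient_polyclonal_seeding"] == "indeterminate"

    def test_two_branches_polyclonal(self):
        comp = compose_sample("m", "bone", {0: 1.0, 2: 0.5, 3: 0.3}, TREE, 0.02)
        calls, _ = classify_seeding([comp], TREE)
        assert calls[0].mode == "polyclonal"
        assert set(calls[0].contributing_branches) == {2, 3}

    def test_two_met_patient_gets_definite_summary(self):
        c1 = compose_sample("m1", "bone", {0: 1.0, 2: 0.5, 3: 0.3}, TREE, 0.02)
        c2 = compose_sample("m2", "lymph_node", {0: 1.0, 1: 0.9}, TREE, 0.02)
        _, summary = classify_seeding([c1, c2], TREE)
        assert summary["patient_polyclonal_seeding"] == "yes"
        assert summary["n_polyclonal"] == 1


class TestDominantLineage:
    def test_shared_deep_cluster(self):
        mets = [
            compose_sample("m1", "bone", {0: 1.0, 1: 0.9, 2: 0.8, 4: 0.5}, TREE, 0.02),
            compose_sample("m2", "visceral", {0: 1.0, 1: 0.9, 2: 0.7}, TREE, 0.02),
        ]
        assert find_dominant_lineage(mets, TREE) == 2

    def test_disjoint_branches_no_dominant(self):
        # two branches diverging at the trunk itself: independent seedings
        tree = CloneTree(root=0, parent={0: None, 1: 0, 2: 0})
        mets = [
            compose_sample("m1", "bone", {0: 1.0, 1: 0.8}, tree, 0.02),
            compose_sample("m2", "visceral", {0: 1.0, 2: 0.7}, tree, 0.02),
        ]
        assert find_dominant_lineage(mets, tree) is None

    def test_shared_midpoint_of_diverging_subbranches(self):
        # branches diverge below node 1, so lineage through 1 is shared
        mets = [
            compose_sample("m1", "bone", {0: 1.0, 1: 0.9, 2: 0.8}, TREE, 0.02),
            compose_sample("m2", "visceral", {0: 1.0, 1: 0.9, 3: 0.7}, TREE, 0.02),
        ]
        assert find_dominant_lineage(mets, TREE) == 1

    def test_single_met_returns_deepest_cluster(self):
        mets = [compose_sample("m", "bone", {0: 1.0, 1: 0.9, 2: 0.8, 4: 0.4}, TREE, 0.02)]
        assert find_dominant_lineage(mets, TREE) == 4

    def test_generator_dominant_branch_recovered(self):
        from clonetracer.simulate import SimConfig, simulate_patient

        hits, n = 0, 15
        for seed in range(n):
            cfg = SimConfig(seed=400 + seed, n_clusters=6, n_samples_tissue=9,
                            polyclonal_rate=0.3, mean_depth=800)
            truth, var, seg, meta = simulate_patient(cfg)
            tree = CloneTree(root=truth.root, parent=truth.parent)
            comps = []
            for sid, tc in zip(meta.sample_id, meta.tissue_class):
                if tc in ("lymph_node", "bone", "visceral"):
                    cc = truth.ccf_true.loc[sid].to_dict()
                    comps.append(compose_sample(sid, tc, cc, tree, 0.02))
            dom = find_dominant_lineage(comps, tree)
            designated = truth.dominant_branch
            on_branch = {designated} | truth.descendants(designated) | set(
                truth.ancestors(designated)
            ) - {truth.root}
            if dom in on_branch:
                hits += 1
        assert hits >= 0.95 * n


class TestFluidDetection:
    def _fluid(self, alts, indels=None):
        n = len(alts)
        return pd.DataFrame(
            {
                "variant_id": [f"v{i}" for i in range(n)],
                "alt_count": alts,
                "ccf": [a / 100 for a in alts],
                "is_indel": indels if indels is not None else [False] * n,
            }
        )

    def test_six_of_ten_detected(self):
        fluid = self._fluid([5] * 6 + [0] * 4)
        out = detect_subclones_in_fluid(fluid, {0: [f"v{i}" for i in range(10)]})
        assert bool(out.detected.iloc[0]) and out.detected_fraction.iloc[0] == pytest.approx(0.6)

    def test_four_of_ten_not_detected(self):
        fluid = self._fluid([5] * 4 + [0] * 6)
        out = detect_subclones_in_fluid(fluid, {0: [f"v{i}" for i in range(10)]})
        assert not bool(out.detected.iloc[0])

    def test_indels_excluded_from_rule(self):
        fluid = self._fluid([5, 5, 0, 0], indels=[False, False, True, True])
        out = detect_subclones_in_fluid(fluid, {0: ["v0", "v1", "v2", "v3"]})
        assert out.n_snvs.iloc[0] == 2 and bool(out.detected.iloc[0])

    def test_zero_member_cluster_flagged_undefined(self):
        fluid = self._fluid([5])
        out = detect_subclones_in_fluid(fluid, {0: []})
        assert bool(out.undefined.iloc[0])

    def test_pure_noise_fluid_detects_nothing(self):
        from clonetracer.simulate import make_noise_fluid_sample

        t = make_noise_fluid_sample(300, 800, 0.0, seed=3)
        t["ccf"] = 0.0
        member = {0: list(t.variant_id[:150]), 1: list(t.variant_id[150:])}
        out = detect_subclones_in_fluid(t, member)
        assert not out.detected.any()

    def test_prostate_only_subclones_never_detected_in_fluid(self):
        """Fluids are mixtures of metastatic compositions, so clusters private
        to the prostate have no signal there -- exact at error rate zero."""
        from clonetracer.simulate import SimConfig, simulate_patient
        from clonetracer.variants import ccf_table

        for seed in (0, 1, 2):
            cfg = SimConfig(seed=600 + seed, n_clusters=6, n_samples_tissue=8,
                            n_samples_fluid=2)
            truth, var, seg, meta = simulate_patient(cfg)
            purity = dict(zip(meta.sample_id, meta.purity_true))
            mets = meta.sample_id[meta.tissue_class.isin(["lymph_node", "bone", "visceral"])]
            prost = meta.sample_id[meta.tissue_class == "prostate"]
            prostate_only = [
                k for k in truth.ccf_true.columns
                if (truth.ccf_true.loc[prost, k] > 0).any()
                and not (truth.ccf_true.loc[mets, k] > 0).any()
            ]
            member = {
                k: list(truth.assignment.index[truth.assignment == k])
                for k in truth.ccf_true.columns
            }
            cc = ccf_table(var, purity, seg)
            for fid in meta.sample_id[meta.tissue_class == "fluid"]:
                fl = cc[cc.sample_id == fid]
                out = detect_subclones_in_fluid(fl, member).set_index("cluster_id")
                for k in prostate_only:
                    assert not bool(out.loc[k, "detected"])


class TestFluidMatching:
    def test_identical_composition_ranks_first_with_similarity_one(self):
        det = pd.DataFrame(
            {"cluster_id": [0, 1], "detected": [True, True], "fluid_ccf": [1.0, 0.5]}
        )
        tissues = {"a": {0: 1.0, 1: 0.5}, "b": {0: 1.0, 1: 0.0}}
        out = match_fluid_to_tissue(det, tissues)
        assert out.sample_id.iloc[0] == "a"
        assert out.similarity.iloc[0] == pytest.approx(1.0)

    def test_mixture_ranks_sources_above_unrelated(self):
        rng = np.random.default_rng(8)
        hits, n = 0, 20
        for _ in range(n):
            a = {0: 1.0, 1: float(rng.uniform(0.5, 1.0)), 2: 0.0}
            b = {0: 1.0, 1: 0.0, 2: float(rng.uniform(0.5, 1.0))}
            unrelated = {0: float(rng.uniform(0, 0.2)), 1: 0.0, 2: 0.0}
            mix = {k: 0.5 * a[k] + 0.5 * b[k] for k in a}
            det = pd.DataFrame(
                {"cluster_id": list(mix), "detected": True, "fluid_ccf": list(mix.values())}
            )
            out = match_fluid_to_tissue(det, {"a": a, "b": b, "u": unrelated})
            ranked = list(out.sample_id)
            if ranked.index("u") == 2:
                hits += 1
        assert hits == n

    def test_empty_fluid_is_error(self):
        det = pd.DataFrame({"cluster_id": [0], "detected": [False], "fluid_ccf": [np.nan]})
        with pytest.raises(ValueError):
            match_fluid_to_tissue(det, {"a": {0: 1.0}})
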