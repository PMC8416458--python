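"""Nearest-shrunken-centroid classification and the composite call rule."""

import numpy as np
import pandas as pd
import pytest

from cometddi import classify as cls
from cometddi import qc
from cometddi import synthetic as syn
from conftest import toy_training


class TestCollapseProbes:
    def test_single_probe_identity_and_mean(self):
        vals = pd.DataFrame({"s1": [1.0, 3.0, 7.0]},
                            index=["gA_P1", "gA_P2", "gB_P1"])
        gmap = pd.Series({"gA_P1": "gA", "gA_P2": "gA", "gB_P1": "gB"})
        out = cls.collapse_probes(vals, gmap)
        assert out.loc["gA", "s1"] == pytest.approx(2.0)
        assert out.loc["gB", "s1"] == pytest.approx(7.0)

    def test_probe_order_irrelevant(self):
        vals = pd.DataFrame({"s1": [1.0, 3.0, 7.0]},
                            index=["gA_P1", "gA_P2", "gB_P1"])
        gmap = pd.Series({"gA_P1": "gA", "gA_P2": "gA", "gB_P1": "gB"})
        out1 = cls.collapse_probes(vals, gmap)
        out2 = cls.collapse_probes(vals.iloc[::-1], gmap)
        pd.testing.assert_frame_equal(out1, out2)

    def test_missing_biomarker_gene_is_hard_error(self):
        vals = pd.DataFrame({"s1": [1.0]}, index=["gA_P1"])
        gmap = pd.Series({"gA_P1": "gA"})
        with pytest.raises(ValueError, match="no probe"):
            cls.collapse_probes(vals, gmap, required_genes=pd.Index(["gA", "gZ"]))


class TestConditionLog2fc:
    @staticmethod
    def _meta():
        return pd.DataFrame([
            dict(sample_id=s, chemical="X", concentration_uM=c, replicate=r,
                 is_vehicle=c == 0)
            for s, c, r in [("v1", 0, 1), ("v2", 0, 2), ("t1", 5, 1), ("t2", 5, 2)]])

    def test_treated_equals_control_gives_zero(self):
        vals = pd.DataFrame(np.ones((3, 4)), index=list("abc"),
                            columns=["v1", "v2", "t1", "t2"])
        prof, nrep = cls.condition_log2fc(vals, self._meta())
        assert np.allclose(prof["X@5"], 0.0)
        assert nrep["X@5"] == 2

    def test_doubling_gives_plus_one(self):
        vals = pd.DataFrame([[1, 1, 2, 2], [3, 3, 4, 4]], dtype=float,
                            index=list("ab"), columns=["v1", "v2", "t1", "t2"])
        prof, _ = cls.condition_log2fc(vals, self._meta())
        assert np.allclose(prof["X@5"], 1.0)  # log2-scale difference of +1

    def test_missing_control_errors(self):
        meta = self._meta()
        meta = meta[~meta["is_vehicle"]]
        vals = pd.DataFrame(np.ones((2, 2)), index=list("ab"),
                            columns=["t1", "t2"])
        with pytest.raises(ValueError, match="vehicle control"):
            cls.condition_log2fc(vals, meta)


class TestTrainNSC:
    def test_delta_zero_gives_class_means(self):
        tr = toy_training(seed=1)
        model = cls.train_nsc(tr, 0.0)
        for j, k in enumerate(model.classes):
            idx = (tr.labels == k).to_numpy()
            np.testing.assert_allclose(
                model.shrunken_centroids[:, j],
                tr.matrix.loc[:, idx].mean(axis=1), atol=1e-12)

    def test_full_shrinkage_collapses_to_overall(self):
        tr = toy_training(seed=2)
        model0 = cls.train_nsc(tr, 0.0)
        big = np.abs((model0.class_centroids - model0.overall_centroid[:, None])
                     / ((model0.within_class_sd + model0.s0)[:, None])).max() * 10
        model = cls.train_nsc(tr, big)
        np.testing.assert_allclose(model.shrunken_centroids,
                                   model0.overall_centroid[:, None]
                                   * np.ones((1, 2)), atol=1e-12)
        post, call = cls.classify_nsc(model, tr.matrix.iloc[:, 0],
                                      posterior_threshold=0.9)
        assert post == pytest.approx(0.5)
        assert call == cls.UNCLASSIFIED

    def test_toy_centroids_match_hand_formulas(self):
        """2-gene, 2+2-compound set: every model quantity versus the formulas."""
        mat = pd.DataFrame([[2.0, 1.0, -1.0, 0.0],
                            [0.5, 1.5, 0.5, -0.5]],
                           index=["g1", "g2"], columns=["d1", "d2", "n1", "n2"])
        labels = pd.Series(["DDI", "DDI", "non-DDI", "non-DDI"], index=mat.columns)
        delta = 0.5
        model = cls.train_nsc(cls.TrainingSet(mat, labels), delta)
        x = mat.to_numpy()
        overall = x.mean(axis=1)
        cent = np.column_stack([x[:, :2].mean(axis=1), x[:, 2:].mean(axis=1)])
        si = np.sqrt((((x[:, :2] - cent[:, [0]]) ** 2).sum(axis=1)
                      + ((x[:, 2:] - cent[:, [1]]) ** 2).sum(axis=1)) / (4 - 2))
        s0 = np.median(si)
        mk = np.sqrt(1 / 2 - 1 / 4)
        d = (cent - overall[:, None]) / (mk * (si + s0)[:, None])
        dsh = np.sign(d) * np.maximum(np.abs(d) - delta, 0)
        shrunk = overall[:, None] + mk * (si + s0)[:, None] * dsh
        np.testing.assert_allclose(model.overall_centroid, overall, atol=1e-10)
        np.testing.assert_allclose(model.within_class_sd, si, atol=1e-10)
        assert model.s0 == pytest.approx(s0, abs=1e-10)
        np.testing.assert_allclose(model.d_shrunk, dsh, atol=1e-10)
        np.testing.assert_allclose(model.shrunken_centroids, shrunk, atol=1e-10)

    def test_small_class_rejected(self):
        mat = pd.DataFrame(np.random.default_rng(0).normal(size=(3, 3)),
                           index=list("abc"), columns=["d1", "n1", "n2"])
        labels = pd.Series(["DDI", "non-DDI", "non-DDI"], index=mat.columns)
        with pytest.raises(ValueError, match="fewer than 2"):
            cls.train_nsc(cls.TrainingSet(mat, labels), 0.0)

    def test_active_gene_set_shrinks_with_delta(self):
        tr = toy_training(seed=3, n_genes=20, sd=1.0)
        sizes = [cls.train_nsc(tr, d).n_active_genes()
                 for d in (0.0, 0.5, 1.0, 2.0, 4.0)]
        assert sizes == sorted(sizes, reverse=True)


class TestClassifyNSC:
    def test_profile_at_ddi_centroid_confident(self):
        tr = toy_training(seed=4)
        model = cls.train_nsc(tr, 0.0)
        prof = pd.Series(model.shrunken_centroids[:, 0], index=tr.genes)
        post, call = cls.classify_nsc(model, prof)
        assert post > 0.90 and call == cls.DDI

    def test_threshold_boundaries(self):
        tr = toy_training(seed=5)
        model = cls.train_nsc(tr, 0.0)
        mid = pd.Series(model.overall_centroid, index=tr.genes)
        post, call = cls.classify_nsc(model, mid)
        assert call == cls.UNCLASSIFIED and post == pytest.approx(0.5, abs=1e-6)

    def test_nonfinite_profile_rejected(self):
        tr = toy_training(seed=6)
        model = cls.train_nsc(tr, 0.0)
        prof = pd.Series(np.nan, index=tr.genes)
        with pytest.raises(ValueError, match="non-finite"):
            cls.classify_nsc(model, prof)

    def test_delta_zero_matches_diagonal_nearest_centroid_oracle(self):
        """Unshrunk NSC with equal priors = diagonal-covariance nearest centroid."""
        rng = np.random.default_rng(7)
        agree = 0
        for trial in range(20):
            tr = toy_training(seed=100 + trial, n_genes=8, sd=1.0, effect=1.0)
            model = cls.train_nsc(tr, 0.0)
            prof = pd.Series(rng.normal(0, 1.5, 8), index=tr.genes)
            post, _ = cls.classify_nsc(model, prof, posterior_threshold=0.5)
            nsc_class = cls.DDI if post > 0.5 else cls.NON_DDI
            var = (model.within_class_sd + model.s0) ** 2
            d = (((prof.to_numpy()[:, None] - model.class_centroids) ** 2)
                 / var[:, None]).sum(axis=0)
            oracle = model.classes[int(np.argmin(d))]
            agree += nsc_class == oracle
        assert agree == 20

    def test_gene_permutation_changes_nothing(self, training_set):
        model_delta = 0.8
        rng = np.random.default_rng(8)
        prof = pd.Series(rng.normal(0, 1, len(training_set.genes)),
                         index=training_set.genes)
        perm = rng.permutation(len(training_set.genes))
        tr_perm = cls.TrainingSet(training_set.matrix.iloc[perm],
                                  training_set.labels)
        m1 = cls.train_nsc(training_set, model_delta)
        m2 = cls.train_nsc(tr_perm, model_delta)
        p1, c1 = cls.classify_nsc(m1, prof)
        p2, c2 = cls.classify_nsc(m2, prof)
        assert p1 == pytest.approx(p2, abs=1e-12) and c1 == c2
        assert cls.hc_call(training_set, prof) == cls.hc_call(tr_perm, prof)
        assert cls.pca_call(training_set, prof) == cls.pca_call(tr_perm, prof)


class TestPCAAndHC:
    def test_pca_class_mean_profile_called_ddi(self):
        tr = toy_training(seed=9)
        ddi_mean = tr.matrix.loc[:, (tr.labels == "DDI").to_numpy()].mean(axis=1)
        assert cls.pca_call(tr, ddi_mean) == cls.DDI

    def test_pca_boundary_profile_unclassified(self):
        # symmetric toy: classes at +/-e, zero profile sits on the midpoint
        mat = pd.DataFrame([[1, 1.2, -1, -1.2], [1.1, 0.9, -1.1, -0.9]],
                           dtype=float, index=["g1", "g2"],
                           columns=["d1", "d2", "n1", "n2"])
        labels = pd.Series(["DDI", "DDI", "non-DDI", "non-DDI"],
                           index=mat.columns)
        tr = cls.TrainingSet(mat, labels)
        prof = pd.Series(0.0, index=tr.genes)
        assert cls.pca_call(tr, prof) == cls.UNCLASSIFIED

    def test_hc_duplicate_and_far_profiles(self):
        tr = toy_training(seed=10)
        dup = tr.matrix.iloc[:, 0]
        assert cls.hc_call(tr, dup) == cls.DDI
        far = pd.Series(1e6, index=tr.genes)
        assert cls.hc_call(tr, far) == cls.UNCLASSIFIED

    def test_hc_class_means_recovered_both_ways(self):
        tr = toy_training(seed=11)
        for label, want in (("DDI", cls.DDI), ("non-DDI", cls.NON_DDI)):
            mean = tr.matrix.loc[:, (tr.labels == label).to_numpy()].mean(axis=1)
            assert cls.hc_call(tr, mean) == want


class TestCompositeAndChemicalCall:
    @pytest.mark.parametrize("pa,pca,hc,want", [
        ("DDI", "non-DDI", "non-DDI", "DDI"),
        ("non-DDI", "DDI", "non-DDI", "DDI"),
        ("non-DDI", "non-DDI", "DDI", "DDI"),
        ("non-DDI", "non-DDI", "non-DDI", "non-DDI"),
        ("unclassified", "non-DDI", "non-DDI", "unclassified"),
        ("unclassified", "DDI", "non-DDI", "DDI"),
    ])
    def test_composite_rule(self, pa, pca, hc, want):
        assert cls.composite_call(pa, pca, hc) == want

    def test_chemical_call_ignores_cytotoxic_concentration(self):
        per_conc = {1.0: "non-DDI", 2.0: "non-DDI", 4.0: "DDI"}
        assert cls.chemical_call(per_conc, cytotoxic={4.0}) == cls.NON_DDI
        assert cls.chemical_call(per_conc) == cls.DDI

    def test_chemical_call_propagates_unclassified(self):
        per_conc = {1.0: "non-DDI", 2.0: "unclassified"}
        assert cls.chemical_call(per_conc) == cls.UNCLASSIFIED


def test_simulated_ddi_top_dose_recovers_injected_effect(
        ddi_experiment, ddi_gene_level, sim_config, ddi_truth):
    """At the top dose the measured biomarker log2 FC tracks the Hill truth."""
    prof, _ = cls.condition_log2fc(ddi_gene_level, ddi_experiment.metadata)
    top = max(float(c.rsplit("@", 1)[1]) for c in prof.columns)
    expected = syn.expected_log2fc(ddi_truth, sim_config, [top])[0]
    signs = sim_config.gene_signs()
    measured = prof[f"{ddi_truth.chemical_id}@{top:g}"].to_numpy() * signs
    assert abs(measured.mean() - expected) < 0.15


def test_end_to_end_classification_accuracy(training_set, sim_config):
    """Strong-effect chemicals get ground-truth chemical-level calls."""
    delta = cls.choose_delta(training_set)
    correct = 0
    chems = []
    for i in range(6):
        if i % 2 == 0:
            chems.append(syn.GroundTruth(f"D{i}", True, true_bmc_tgx=10.0 * (i + 1)))
        else:
            chems.append(syn.GroundTruth(f"N{i}", False))
    for truth in chems:
        cfg = syn.SimulationConfig(seed=sim_config.seed + 100, n_background_probes=100)
        exp = syn.generate_test_experiment(truth, cfg)
        norm = qc.normalize_counts(exp.counts)
        gl = cls.collapse_probes(norm.log2_shifted, exp.probe_gene_map,
                                 required_genes=pd.Index(training_set.genes))
        prof, _ = cls.condition_log2fc(gl, exp.metadata)
        calls = cls.classify_conditions(training_set, prof, delta)
        overall = cls.chemical_call({c.concentration: c.overall for c in calls})
        want = cls.DDI if truth.is_ddi else cls.NON_DDI
        correct += overall == want
    assert correct == len(chems)
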