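import numpy as np
import pandas as pd
import pytest

from riboclean import (Thresholds, acute_specific_set, classify_enrichment,
                       two_arm_filter)
from riboclean.de import InteractionResult
from riboclean.errors import ContractError
from riboclean.filtration import EnrichmentProfile, FiltrationReport
from riboclean.glm import DEResult


def _de(genes, log2fc, q, contrast="IP:dpi2-vs-naive"):
    return DEResult(contrast=contrast, table=pd.DataFrame(
        {"log2fc": log2fc, "se": 0.1, "stat": 0.0, "p": q, "q": q,
         "mean_norm_count": 100.0, "flag": ""}, index=pd.Index(genes)))


def _delta(genes, delta, q, condition="dpi2"):
    return InteractionResult(condition=condition, reference="naive",
                             table=pd.DataFrame(
                                 {"delta": delta, "se": 0.1, "stat": 0.0,
                                  "p": q, "q": q, "mean_norm_count": 100.0,
                                  "flag": ""}, index=pd.Index(genes)))


def _profile(genes, enrich_by_cond, q_by_cond):
    conds = list(enrich_by_cond)
    results = {
        c: _de(genes, enrich_by_cond[c], q_by_cond[c], contrast=f"enrichment:{c}")
        for c in conds
    }
    return classify_enrichment(results)


class TestClassifyEnrichment:
    @pytest.mark.parametrize(
        "log2_enrich,q,expected",
        [
            (2.4, 1e-6, "highly_selective"),   # strong selective expression
            (0.49, 0.01, "neutral"),           # just under the 0.5 boundary
            (3.0, 0.2, "neutral"),             # significance gate
            (0.5, 0.05, "enriched"),           # inclusive at the boundary
            (-0.8, 0.001, "depleted"),
            (1.2, 0.04, "enriched"),
        ],
    )
    def test_threshold_table(self, log2_enrich, q, expected):
        prof = _profile(["g"], {"naive": [log2_enrich]}, {"naive": [q]})
        assert prof.classification.loc["g", "naive"] == expected

    def test_highly_selective_implies_enriched_side(self):
        rng = np.random.default_rng(0)
        genes = [f"g{i}" for i in range(50)]
        prof = _profile(genes, {"naive": rng.normal(0, 2, 50)},
                        {"naive": rng.uniform(0, 0.1, 50)})
        hs = prof.classification["naive"] == "highly_selective"
        assert (prof.log2_enrich.loc[hs, "naive"] >= 2).all()

    def test_mismatched_universe_rejected(self):
        a = _de(["g1"], [1.0], [0.01])
        b = _de(["g2"], [1.0], [0.01])
        with pytest.raises(ContractError, match="universe"):
            classify_enrichment({"naive": a, "dpi2": b})


class TestTwoArmFilter:
    def _run(self, genes, lfc, q_de, delta, q_delta, enr_naive, q_naive,
             enr_cond, q_cond, thresholds=None):
        de = _de(genes, lfc, q_de)
        dl = _delta(genes, delta, q_delta)
        prof = _profile(genes, {"naive": enr_naive, "dpi2": enr_cond},
                        {"naive": q_naive, "dpi2": q_cond})
        return two_arm_filter(de, dl, prof, thresholds=thresholds)

    def test_pass_via_arm1_differential_enrichment(self):
        rep = self._run(["g"], [2.0], [1e-4], [1.5], [0.01],
                        [0.0], [0.9], [0.0], [0.9])
        row = rep.table.loc["g"]
        assert row["arm1"] and not row["arm2"] and row["final"]
        assert row["direction"] == "up"

    def test_microglia_like_contaminant_fails_both_arms(self):
        """Sharply IP-upregulated but IP-depleted with unchanged
        de-enrichment: the defining contaminant pattern is rejected."""
        rep = self._run(["g"], [4.0], [1e-8], [0.05], [0.9],
                        [-2.0], [1e-5], [-2.0], [1e-5])
        row = rep.table.loc["g"]
        assert row["de_pass"] and not row["arm1"] and not row["arm2"]
        assert not row["final"]

    def test_pass_via_arm2_constant_high_enrichment(self):
        rep = self._run(["g"], [1.2], [0.01], [0.2], [0.4],
                        [1.5], [0.01], [1.5], [0.01])
        row = rep.table.loc["g"]
        assert not row["arm1"] and row["arm2"] and row["final"]

    def test_arm1_requires_sign_agreement(self):
        rep = self._run(["g"], [2.0], [1e-4], [-1.5], [0.01],
                        [0.0], [0.9], [0.0], [0.9])
        assert not rep.table.loc["g", "arm1"]

    def test_down_regulated_genes_filtered_with_mirrored_signs(self):
        rep = self._run(["g"], [-2.0], [1e-4], [-1.5], [0.01],
                        [0.0], [0.9], [0.0], [0.9])
        row = rep.table.loc["g"]
        assert row["final"] and row["direction"] == "down"

    def test_final_implies_de_pass(self):
        rng = np.random.default_rng(1)
        n = 200
        genes = [f"g{i}" for i in range(n)]
        rep = self._run(
            genes, rng.normal(0, 2, n), rng.uniform(0, 0.2, n),
            rng.normal(0, 2, n), rng.uniform(0, 0.2, n),
            rng.normal(0, 2, n), rng.uniform(0, 0.2, n),
            rng.normal(0, 2, n), rng.uniform(0, 0.2, n),
        )
        t = rep.table
        assert not (t["final"] & ~t["de_pass"]).any()

    def test_removing_arm2_never_grows_the_pass_set(self):
        """final = de & (arm1 | arm2) is monotone: dropping arm 2 can only
        shrink it."""
        rng = np.random.default_rng(2)
        n = 500
        genes = [f"g{i}" for i in range(n)]
        rep = self._run(
            genes, rng.normal(0, 2, n), rng.uniform(0, 0.2, n),
            rng.normal(0, 2, n), rng.uniform(0, 0.2, n),
            rng.normal(0, 2, n), rng.uniform(0, 0.2, n),
            rng.normal(0, 2, n), rng.uniform(0, 0.2, n),
        )
        t = rep.table
        arm1_only = t["de_pass"] & t["arm1"]
        assert set(t.index[arm1_only]) <= set(t.index[t["final"]])

    def test_universe_mismatch_lists_offenders(self):
        de = _de(["g1", "g2"], [1.0, 1.0], [0.01, 0.01])
        dl = _delta(["g1", "g3"], [1.0, 1.0], [0.01, 0.01])
        prof = _profile(["g1", "g2"], {"naive": [1, 1], "dpi2": [1, 1]},
                        {"naive": [0.01, 0.01], "dpi2": [0.01, 0.01]})
        with pytest.raises(ContractError, match="g3"):
            two_arm_filter(de, dl, prof)

    def test_passing_accessor_does_not_mutate_report(self):
        rep = self._run(["up1", "dn1"], [2.0, -2.0], [1e-4, 1e-4],
                        [1.5, -1.5], [0.01, 0.01],
                        [0.0, 0.0], [0.9, 0.9], [0.0, 0.0], [0.9, 0.9])
        before = rep.table["final"].copy()
        assert list(rep.passing("up")) == ["up1"]
        assert list(rep.passing("down")) == ["dn1"]
        pd.testing.assert_series_equal(rep.table["final"], before)
        assert list(rep.passing()) == ["up1", "dn1"]

    def test_thresholds_are_configurable(self):
        strict = Thresholds(delta_lfc=2.0)
        rep = self._run(["g"], [2.0], [1e-4], [1.5], [0.01],
                        [0.0], [0.9], [0.0], [0.9], thresholds=strict)
        assert not rep.table.loc["g", "arm1"]


class TestAcuteSpecificSet:
    def _reports(self, genes, lfc2, q2, lfc42, q42):
        de2 = _de(genes, lfc2, q2)
        de42 = _de(genes, lfc42, q42, contrast="IP:dpi42-vs-naive")
        dl2 = _delta(genes, [2.0] * len(genes), [0.001] * len(genes))
        dl42 = _delta(genes, [2.0] * len(genes), [0.001] * len(genes),
                      condition="dpi42")
        prof = _profile(genes, {"naive": [0.0] * len(genes),
                                "dpi2": [0.0] * len(genes),
                                "dpi42": [0.0] * len(genes)},
                        {"naive": [0.9] * len(genes), "dpi2": [0.9] * len(genes),
                         "dpi42": [0.9] * len(genes)})
        f2 = two_arm_filter(de2, dl2, prof)
        f42 = two_arm_filter(de42, dl42, prof)
        return f2, f42, de2, de42

    def test_two_fold_lower_at_late_timepoint_included(self):
        f2, f42, de2, de42 = self._reports(["g"], [3.0], [1e-4], [1.5], [1e-4])
        assert acute_specific_set(f2, f42, de2, de42) == ["g"]

    def test_sustained_gene_excluded(self):
        f2, f42, de2, de42 = self._reports(["g"], [3.0], [1e-4], [2.9], [1e-4])
        assert acute_specific_set(f2, f42, de2, de42) == []

    def test_not_significant_late_included(self):
        f2, f42, de2, de42 = self._reports(["g"], [2.0], [1e-4], [2.0], [0.3])
        assert acute_specific_set(f2, f42, de2, de42) == ["g"]


class TestFiltrationImprovesSpecificity:
    def test_contaminant_fraction_strictly_drops_across_seeds(self):
        """Over many simulated experiments, filtration always lowers the
        contaminant-driven share relative to unfiltered DE calls."""
        import riboclean as rc
        from riboclean.pipeline import evaluate_against_truth
        worse = 0
        for seed in range(20):
            cfg, _ = rc.paper_like_config(seed=seed, n_genes=400)
            cm, truth = rc.generate_experiment(cfg)
            filt = rc.filter_low_counts(cm, 10)
            sf = rc.rle_size_factors(filt)
            de = rc.de_between_conditions(filt, "dpi2", size_factors=sf)
            delta = rc.differential_enrichment(filt, "dpi2", size_factors=sf)
            enr = {c: rc.enrichment_for_condition(filt, c, size_factors=sf)
                   for c in ("naive", "dpi2")}
            rep = two_arm_filter(de, delta, classify_enrichment(enr))
            ev = evaluate_against_truth(rep, de, truth, "dpi2")
            if not ev["contaminant_frac_final"] < ev["contaminant_frac_unfiltered"]:
                worse += 1
        assert worse == 0
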