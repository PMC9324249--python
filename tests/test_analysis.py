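import numpy as np
import pandas as pd
import pytest

import gliograph as gg
from gliograph.exceptions import InvalidArgumentError

TR = 2.5

STRONG_LGG = gg.EffectSpec(group="LGG", delta_left_global=0.3, delta_local=-0.2)
STRONG_HGG = gg.EffectSpec(group="HGG", delta_right=-0.15)


def build_cohort(parc, effects=None, n=(12, 16, 16), T=120, seed=1):
    spec = gg.CohortSpec(n_hc=n[0], n_lgg=n[1], n_hgg=n[2], T=T, master_seed=seed)
    subjects = gg.generate_cohort(parc, spec, effects)
    return gg.compute_cohort(subjects, parc, TR=TR)


@pytest.fixture(scope="module")
def planted_cohort(parc_small):
    return build_cohort(
        parc_small,
        {"LGG": STRONG_LGG, "HGG": STRONG_HGG},
    )


class TestHemisphericAnalysis:
    def test_output_structure(self, planted_cohort):
        df = gg.hemispheric_analysis(planted_cohort)
        # 3 scopes x 3 pairings x 7 metrics + 3 groups x 7 paired contrasts
        assert len(df) == 3 * 3 * 7 + 3 * 7
        assert (df["p_fdr"] >= df["p_raw"] - 1e-12).all()
        assert set(df["scope"]) == {"whole_brain", "L", "R", "left_vs_right"}
        assert df["direction"].isin([-1, 0, 1]).all()
        assert df["test_used"].isin(["t", "mann_whitney", "wilcoxon"]).all()

    def test_planted_effects_recovered_with_direction(self, planted_cohort):
        df = gg.hemispheric_analysis(planted_cohort)

        def row(scope, metric, ga, gb):
            sel = df[(df.scope == scope) & (df.metric == metric)
                     & (df.group_a == ga) & (df.group_b == gb)]
            assert len(sel) == 1
            return sel.iloc[0]

        lgg = row("L", "global_efficiency", "LGG", "HC")
        assert lgg["p_fdr"] < 0.05 and lgg["direction"] == 1
        for metric in ("cost", "degree"):
            hgg = row("R", metric, "HGG", "HC")
            assert hgg["p_fdr"] < 0.05 and hgg["direction"] == -1
        paired = row("left_vs_right", "global_efficiency", "LGG", "LGG")
        assert paired["p_fdr"] < 0.05 and paired["direction"] == 1

    def test_fdr_families_are_scope_by_pairing(self, planted_cohort):
        df = gg.hemispheric_analysis(planted_cohort)
        family = df[(df.scope == "L") & (df.group_a == "LGG") & (df.group_b == "HC")]
        assert len(family) == 7
        assert np.allclose(
            np.sort(family["p_fdr"]),
            np.sort(gg.fdr_correct(family["p_raw"].to_numpy())),
        )

    def test_missing_group_skipped(self, parc_small):
        spec = gg.CohortSpec(n_hc=6, n_lgg=6, n_hgg=2, T=40, master_seed=2)
        subjects = [s for s in gg.generate_cohort(parc_small, spec)
                    if s.group != "HGG"]
        cohort = gg.compute_cohort(subjects, parc_small, TR=TR)
        df = gg.hemispheric_analysis(cohort)
        assert not ((df.group_a == "HGG") | (df.group_b == "HGG")).any()
        assert ((df.group_a == "LGG") & (df.group_b == "HC")).any()

    def test_unpaired_lr_variant_runs(self, planted_cohort):
        df = gg.hemispheric_analysis(planted_cohort, paired_lr=False)
        lr = df[df.scope == "left_vs_right"]
        assert lr["test_used"].isin(["t", "mann_whitney"]).all()


class TestLobarAnalysis:
    def test_frontal_effect_confined_to_frontal_rows(self, parc_small):
        cohort = build_cohort(
            parc_small,
            {
                "LGG": gg.with_location(STRONG_LGG, "frontal"),
                "HGG": gg.EffectSpec(group="HGG", tumor_location="temporal"),
            },
            T=160,
            seed=3,
        )
        df = gg.lobar_analysis(cohort)
        sig = df[df.p_fdr < 0.05]
        assert len(sig) > 0
        assert (sig["scope"] == "lobe:frontal").all()
        # Significant nodes are left-hemisphere frontal nodes.
        left_frontal = set(cohort.parcellation.lobe_ids("frontal", "L"))
        assert set(sig["node"]) <= left_frontal

    def test_small_subgroups_are_skipped(self, parc_small):
        cohort = build_cohort(
            parc_small,
            {
                "LGG": [
                    gg.EffectSpec(group="LGG", tumor_location="frontal"),
                    gg.EffectSpec(group="LGG", tumor_location="temporal"),
                ],
                "HGG": gg.EffectSpec(group="HGG", tumor_location="temporal"),
            },
            n=(8, 4, 8),  # 2 LGG per location -> below the min_n of 3
            seed=4,
        )
        df = gg.lobar_analysis(cohort)
        assert not ((df.group_a == "LGG") | (df.group_b == "LGG")).any()
        assert ((df.group_a == "HGG") & (df.group_b == "HC")).any()

    def test_no_occipital_patients_emit_no_occipital_rows(self):
        parc = gg.make_parcellation(40)
        cohort = build_cohort(parc, None, n=(6, 8, 8), T=60, seed=5)
        df = gg.lobar_analysis(cohort)
        assert not (df["scope"] == "lobe:occipital").any()
        assert len(df) > 0  # other lobes do get compared

    def test_fdr_family_is_nodes_within_lobe_metric_pairing(self, parc_small):
        cohort = build_cohort(
            parc_small, {"LGG": gg.with_location(STRONG_LGG, "frontal")},
            n=(8, 8, 8), seed=6,
        )
        df = gg.lobar_analysis(cohort)
        fam = df[(df.scope == "lobe:frontal") & (df.metric == "degree")
                 & (df.group_a == "LGG") & (df.group_b == "HC")]
        assert len(fam) == len(cohort.parcellation.lobe_ids("frontal"))
        assert np.allclose(
            np.sort(fam["p_fdr"]), np.sort(gg.fdr_correct(fam["p_raw"].to_numpy()))
        )

    def test_null_family_false_positive_rate_is_near_alpha(self, parc_small):
        """Under the null, each BH family rejects something with prob ~alpha."""
        hits = 0
        reps = 40
        for rep in range(reps):
            cohort = build_cohort(
                parc_small,
                {"LGG": gg.EffectSpec(group="LGG", tumor_location="frontal"),
                 "HGG": gg.EffectSpec(group="HGG", tumor_location="frontal")},
                n=(6, 8, 8), T=40, seed=100 + rep,
            )
            df = gg.lobar_analysis(cohort)
            fam = df[(df.metric == "degree") & (df.group_a == "LGG")
                     & (df.group_b == "HC")]
            hits += (fam["p_fdr"] < 0.05).any()
        assert hits / reps <= 0.2

    def test_direction_matrix_shape(self, parc_small):
        cohort = build_cohort(
            parc_small, {"LGG": gg.with_location(STRONG_LGG, "frontal")},
            n=(8, 8, 8), seed=7,
        )
        dm = gg.direction_matrix(gg.lobar_analysis(cohort))
        assert set(dm.columns) == {"node", "metric", "comparison", "direction", "p_fdr"}
        if len(dm):
            assert dm["direction"].isin(["increase", "decrease"]).all()


class TestConnectogram:
    def _zero_cohort(self, parc_small):
        n = parc_small.n_roi
        manifest = pd.DataFrame(
            {"subject_id": [f"HC_{i}" for i in range(5)], "group": "HC",
             "tumor_location": None, "age": 50.0, "tumor_size": np.nan, "seed": 0}
        )
        conns = {
            sid: gg.ConnectivityMatrix(z=np.zeros((n, n)), t_effective=60,
                                       subject_id=sid)
            for sid in manifest["subject_id"]
        }
        return gg.CohortData(parcellation=parc_small, manifest=manifest,
                             connectivity=conns, metrics={},
                             network_means=pd.DataFrame())

    def test_zero_connectivity_yields_empty_diagram(self, parc_small):
        result = gg.connectogram(self._zero_cohort(parc_small), seed_roi=0, group="HC")
        assert result.count == 0
        assert result.significant_targets == ()

    def test_homotopic_partner_always_significant(self, parc_small):
        cohort = build_cohort(parc_small, None, n=(20, 2, 2), T=60, seed=8)
        left, right = parc_small.homotopic_pairs()[0]
        result = gg.connectogram(cohort, seed_roi=left, group="HC")
        assert right in result.significant_targets  # planted r = 0.5

    def test_targets_exclude_seed(self, parc_small):
        cohort = build_cohort(parc_small, None, n=(6, 2, 2), T=40, seed=9)
        result = gg.connectogram(cohort, seed_roi=3, group="HC")
        assert 3 not in result.target_ids
        assert len(result.target_ids) == parc_small.n_roi - 1

    def test_count_comparison_on_identical_groups(self):
        res = gg.compare_connection_counts([3, 4, 5], [3, 4, 5])
        assert res.p == pytest.approx(1.0)
        assert res.direction == 0

    def test_too_small_group_rejected(self, parc_small):
        with pytest.raises(InvalidArgumentError):
            gg.connectogram(self._zero_cohort(parc_small).__class__(
                parcellation=parc_small,
                manifest=pd.DataFrame({"subject_id": ["a"], "group": ["HC"],
                                       "tumor_location": [None], "age": [1.0],
                                       "tumor_size": [np.nan], "seed": [0]}),
                connectivity={}, metrics={}, network_means=pd.DataFrame(),
            ), seed_roi=0, group="HC")


class TestConfoundScreen:
    def test_metric_as_its_own_covariate_gives_unit_correlation(self, planted_cohort):
        cohort = planted_cohort
        nm = cohort.network_means
        degree = nm[(nm.scope == "whole_brain") & (nm.metric == "degree")]
        degree = degree.set_index("subject_id")["value"]
        manifest = cohort.manifest.copy()
        patients = manifest["group"].isin(["LGG", "HGG"])
        manifest.loc[patients, "age"] = degree.reindex(
            manifest.loc[patients, "subject_id"]).to_numpy()
        rigged = gg.CohortData(
            parcellation=cohort.parcellation, manifest=manifest,
            connectivity=cohort.connectivity, metrics=cohort.metrics,
            network_means=nm,
        )
        screen = gg.confound_screen(rigged)
        row = screen[(screen.scope == "whole_brain") & (screen.metric == "degree")
                     & (screen.covariate == "age")].iloc[0]
        assert row["correlation"] == pytest.approx(1.0)
        assert row["flag"] == "exceeds-bound"

    def test_negated_metric_gives_minus_one(self, planted_cohort):
        cohort = planted_cohort
        nm = cohort.network_means
        degree = nm[(nm.scope == "whole_brain") & (nm.metric == "degree")]
        degree = degree.set_index("subject_id")["value"]
        manifest = cohort.manifest.copy()
        patients = manifest["group"].isin(["LGG", "HGG"])
        manifest.loc[patients, "age"] = -degree.reindex(
            manifest.loc[patients, "subject_id"]).to_numpy()
        rigged = gg.CohortData(
            parcellation=cohort.parcellation, manifest=manifest,
            connectivity=cohort.connectivity, metrics=cohort.metrics,
            network_means=nm,
        )
        row = gg.confound_screen(rigged)
        row = row[(row.scope == "whole_brain") & (row.metric == "degree")
                  & (row.covariate == "age")].iloc[0]
        assert row["correlation"] == pytest.approx(-1.0)

    def test_constant_covariate_flagged_undefined(self, planted_cohort):
        manifest = planted_cohort.manifest.copy()
        manifest["age"] = 50.0
        rigged = gg.CohortData(
            parcellation=planted_cohort.parcellation, manifest=manifest,
            connectivity=planted_cohort.connectivity,
            metrics=planted_cohort.metrics,
            network_means=planted_cohort.network_means,
        )
        screen = gg.confound_screen(rigged)
        age_rows = screen[screen.covariate == "age"]
        assert (age_rows["flag"] == "constant-covariate").all()
        assert age_rows["correlation"].isna().all()

    def test_independent_covariate_rarely_flagged(self, parc_small):
        """Randomized covariates at n=60 patients: |corr| stays small."""
        cohort = build_cohort(parc_small, None, n=(4, 30, 30), T=40, seed=10)
        rng = np.random.default_rng(11)
        inside = 0
        draws = 100
        for _ in range(draws):
            manifest = cohort.manifest.copy()
            manifest["age"] = rng.normal(50, 10, size=len(manifest))
            rigged = gg.CohortData(
                parcellation=cohort.parcellation, manifest=manifest,
                connectivity=cohort.connectivity, metrics=cohort.metrics,
                network_means=cohort.network_means,
            )
            screen = gg.confound_screen(rigged)
            row = screen[(screen.scope == "L") & (screen.metric == "degree")
                         & (screen.covariate == "age")].iloc[0]
            inside += abs(row["correlation"]) < 0.2
        # P(|r| < 0.2) ~ 0.88 for independent data at n = 60.
        assert inside / draws >= 0.8
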