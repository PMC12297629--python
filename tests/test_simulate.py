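"""Synthetic tissue masks, TIL lattices, and cohorts with known truth."""

import numpy as np
import pandas as pd
import pytest

from stilmap.hotspot import compute_hotspot_map
from stilmap.lattice import PatchLabel, compute_til_score, read_patch_table
from stilmap.simulate import (
    COLD,
    HOT,
    ArchetypeSpec,
    CohortSpec,
    generate_cohort,
    generate_til_lattice,
    generate_tissue_mask,
    write_cohort,
)

from oracles import join_count_like_pairs


class TestTissueMask:
    def test_full_fill_gives_full_rectangle(self):
        mask = generate_tissue_mask((12, 12), mask_fill=1.0, seed=0)
        assert mask.all()

    def test_same_seed_identical_mask(self):
        a = generate_tissue_mask((30, 30), 0.6, seed=4)
        b = generate_tissue_mask((30, 30), 0.6, seed=4)
        assert np.array_equal(a, b)

    def test_realized_fill_near_target_across_seeds(self):
        fills = [generate_tissue_mask((48, 48), 0.6, seed=s).mean()
                 for s in range(20)]
        assert all(abs(f - 0.6) <= 0.15 for f in fills)

    def test_mask_is_one_connected_component(self):
        from scipy import ndimage
        mask = generate_tissue_mask((40, 40), 0.5, seed=7)
        _, n = ndimage.label(mask)
        assert n == 1

    def test_invalid_fill_rejected(self):
        with pytest.raises(ValueError):
            generate_tissue_mask((20, 20), 0.0)
        with pytest.raises(ValueError):
            generate_tissue_mask((20, 20), 1.5)

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError):
            generate_tissue_mask((4, 4), 0.5)


class TestTilLattice:
    def test_hot_archetype_score_near_target(self):
        scores = []
        for seed in range(20):
            mask = generate_tissue_mask((48, 48), 0.6, seed=seed)
            g = generate_til_lattice(mask, HOT, seed=seed)
            scores.append(compute_til_score(g).value)
        assert abs(np.mean(scores) - 0.45) <= 0.05
        assert all(abs(s - 0.45) <= 0.1 for s in scores)

    def test_cold_hotspots_sparser_than_hot_paired(self):
        for seed in range(20):
            mask = generate_tissue_mask((48, 48), 0.6, seed=seed)
            cold_hf = compute_hotspot_map(
                generate_til_lattice(mask, COLD, seed=seed)).hot_fraction
            hot_hf = compute_hotspot_map(
                generate_til_lattice(mask, HOT, seed=seed)).hot_fraction
            assert cold_hf < hot_hf

    def test_unit_correlation_length_is_iid_by_join_counts(self):
        arch = ArchetypeSpec("iid", target_pos_fraction=0.5,
                             correlation_length=1, necrotic_rate=0.0)
        fracs = []
        for seed in range(10):
            mask = np.ones((40, 40), dtype=bool)
            g = generate_til_lattice(mask, arch, seed=seed)
            pos = [lab is PatchLabel.TIL_POS for lab in g.labels]
            fracs.append(join_count_like_pairs(
                list(zip(g.rows.tolist(), g.cols.tolist())), pos))
        # iid at p=0.5: like-neighbor fraction = p^2+(1-p)^2 = 0.5
        assert np.mean(fracs) == pytest.approx(0.5, abs=0.03)

    def test_clustered_field_exceeds_iid_join_counts(self):
        mask = np.ones((40, 40), dtype=bool)
        arch = ArchetypeSpec("clumpy", target_pos_fraction=0.5,
                             correlation_length=8, necrotic_rate=0.0)
        g = generate_til_lattice(mask, arch, seed=0)
        pos = [lab is PatchLabel.TIL_POS for lab in g.labels]
        frac = join_count_like_pairs(
            list(zip(g.rows.tolist(), g.cols.tolist())), pos)
        assert frac > 0.7

    def test_necrotic_rate_respected(self):
        mask = generate_tissue_mask((48, 48), 0.6, seed=1)
        g = generate_til_lattice(mask, HOT, seed=1)
        n_nec = sum(lab is PatchLabel.NECROTIC_OTHER for lab in g.labels)
        assert n_nec == round(0.05 * mask.sum())

    def test_unreachable_fraction_rejected(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[0, :3] = True
        arch = ArchetypeSpec("x", target_pos_fraction=0.05, correlation_length=1)
        with pytest.raises(ValueError, match="unreachable"):
            generate_til_lattice(mask, arch, seed=0)


class TestCohort:
    def test_default_spec_prevalence_in_plausible_band(self):
        c = generate_cohort(CohortSpec(n_patients=500, seed=21))
        assert 0.2 <= c.clinical.lnm.mean() <= 0.5

    def test_outputs_aligned_and_schema_complete(self):
        c = generate_cohort(CohortSpec(n_patients=25, seed=3))
        assert len(c.grids) == len(c.clinical) == len(c.truth) == 25
        assert list(c.clinical.columns) == ["patient_id", "age_cat", "t_stage",
                                            "til_score", "stilc", "lnm"]
        assert list(c.truth.columns) == ["patient_id", "archetype",
                                         "linear_predictor", "true_til_score"]
        assert set(c.truth.archetype) <= {"cold", "hot"}
        # stilc ground-truth coding mirrors the archetype
        merged = c.clinical.merge(c.truth, on="patient_id")
        assert ((merged.stilc == 1) == (merged.archetype == "cold")).all()

    def test_same_seed_byte_identical_csv(self, tmp_path):
        spec = CohortSpec(n_patients=20, seed=9)
        p1 = write_cohort(generate_cohort(spec), tmp_path / "a")
        p2 = write_cohort(generate_cohort(spec), tmp_path / "b")
        for key in p1:
            assert p1[key].read_bytes() == p2[key].read_bytes()

    def test_round_trips_through_patch_table_reader(self, tmp_path):
        import warnings
        c = generate_cohort(CohortSpec(n_patients=20, seed=5))
        paths = write_cohort(c, tmp_path)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            grids = read_patch_table(paths["patch_table"])
        assert len(grids) == 20
        scores = {g.patient_id: compute_til_score(g).value for g in grids}
        for _, row in c.clinical.iterrows():
            assert scores[row.patient_id] == pytest.approx(row.til_score)

    def test_too_small_cohort_rejected(self):
        with pytest.raises(ValueError, match="20"):
            generate_cohort(CohortSpec(n_patients=10, seed=0))

    def test_invalid_marginals_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            CohortSpec(age_marginals=(0.5, 0.4, 0.4))

    def test_no_til_effect_null_equalizes_models(self):
        # with beta_til = beta_cold = 0 the TIL features carry no signal;
        # M1's validation advantage over M2 should vanish (within noise)
        from stilmap.models import FEATURES_M1, FEATURES_M2, roc_auc, \
            split_cohort, train_model
        spec = CohortSpec(n_patients=400, b_til=0.0, b_cold=0.0, seed=17)
        c = generate_cohort(spec)
        train, val = split_cohort(c.clinical, seed=0)
        grid = {"n_estimators": (100,), "max_depth": (3,),
                "min_samples_leaf": (5,)}
        m1 = train_model(train, FEATURES_M1, seed=0, param_grid=grid)
        m2 = train_model(train, FEATURES_M2, seed=0, param_grid=grid)
        y = val.lnm.to_numpy()
        diff = roc_auc(m1.predict_proba(val), y) - roc_auc(m2.predict_proba(val), y)
        assert abs(diff) <= 0.1
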