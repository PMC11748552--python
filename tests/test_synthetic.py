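"""Generator contracts: planted structure, trajectories, noise, TRN."""

import numpy as np
import pandas as pd
import pytest

from imodkit import (
    GroundTruth,
    SampleDesign,
    generate_activities,
    generate_structure,
    generate_trn,
    signal_noise_sd,
    synthesize_expression,
)
from imodkit.exceptions import ConfigurationError, ShapeError, SizingError


def small_design(**kw):
    defaults = dict(
        conditions=["C-lim", "N-lim"],
        timepoints=[3.0, 4.0, 6.0, 8.0, 12.0, 24.0],
        replicates=2,
        reference=("C-lim", 3.0),
    )
    defaults.update(kw)
    return SampleDesign(**defaults)


class TestGenerateStructure:
    def test_full_support_single_module(self):
        gt = generate_structure(5, 1, 5, seed=0)
        assert gt.M_true.shape == (5, 1)
        assert (gt.M_true.to_numpy() != 0).all()
        assert gt.memberships == [set(gt.gene_ids)]

    def test_disjoint_modules_have_exact_sizes(self):
        gt = generate_structure(300, 10, 15, overlap_allowed=False, seed=1)
        assert [len(m) for m in gt.memberships] == [15] * 10
        union = set().union(*gt.memberships)
        assert len(union) == 150  # pairwise disjoint
        gt.validate()  # unit norms + support/membership agreement

    def test_infeasible_sizing_raises(self):
        with pytest.raises(SizingError):
            generate_structure(10, 3, 5, overlap_allowed=False)

    def test_deterministic_given_seed(self):
        a = generate_structure(100, 4, 10, seed=7)
        b = generate_structure(100, 4, 10, seed=7)
        pd.testing.assert_frame_equal(a.M_true, b.M_true)

    def test_weights_are_heavy_tailed_nonzero(self):
        gt = generate_structure(200, 5, 20, seed=3)
        M = gt.M_true.to_numpy()
        nonzero = M[M != 0]
        assert np.abs(nonzero).min() > 0  # magnitude floor keeps support exact


class TestGenerateActivities:
    def test_anticorrelated_pair_is_exact_negation(self):
        A = generate_activities(small_design(), 3,
                                anticorrelated_pairs=[(0, 1)], seed=0)
        r = np.corrcoef(A.iloc[0], A.iloc[1])[0, 1]
        assert r == pytest.approx(-1.0)

    def test_flat_trajectory_is_constant_amplitude(self):
        A = generate_activities(small_design(), 1,
                                trajectory_kinds=("flat",), amplitude=3.5,
                                seed=0)
        assert (A.to_numpy() == 3.5).all()

    def test_sigmoid_up_is_monotone_within_condition(self):
        design = small_design()
        A = generate_activities(design, 2, trajectory_kinds=("sigmoid-up",),
                                seed=4)
        meta = design.metadata().set_index("sample_id")
        for k in range(2):
            for cond in design.conditions:
                cols = meta[meta["condition"] == cond].sort_values(
                    ["time_h", "replicate"]
                ).index
                traj = A.iloc[k][cols].to_numpy()
                by_time = traj.reshape(-1, design.replicates).mean(axis=1)
                assert (np.diff(by_time) >= -1e-12).all()

    def test_unknown_trajectory_label_raises(self):
        with pytest.raises(ConfigurationError):
            generate_activities(small_design(), 2,
                                trajectory_kinds=("zigzag",), seed=0)

    def test_pair_index_out_of_range_raises(self):
        with pytest.raises(ConfigurationError):
            generate_activities(small_design(), 2,
                                anticorrelated_pairs=[(0, 5)], seed=0)


class TestSynthesizeExpression:
    def _gt(self, noise_sd, design, k=4):
        gt = generate_structure(200, k, 20, seed=2)
        gt.A_true = generate_activities(design, k, seed=2)
        gt.noise_sd = noise_sd
        return gt

    def test_noiseless_matrix_equals_product(self):
        design = small_design()
        gt = self._gt(0.0, design)
        centered, _ = synthesize_expression(gt, design)
        expected = gt.M_true.to_numpy() @ gt.A_true.to_numpy()
        np.testing.assert_allclose(centered.values, expected)

    def test_noiseless_rank_equals_module_count(self):
        design = small_design()
        gt = self._gt(0.0, design)
        centered, _ = synthesize_expression(gt, design)
        sv = np.linalg.svd(centered.values, compute_uv=False)
        assert int((sv > sv[0] * 1e-9).sum()) == gt.k_modules

    def test_noise_variance_matches_requested(self):
        # 200 genes x 60 samples >= 1e4 entries for the sampling check
        design = small_design(
            conditions=["C-lim", "N-lim", "S-lim"], replicates=5,
            reference=("C-lim", 3.0),
        )
        sigma = 0.3
        gt = self._gt(sigma, design)
        centered, _ = synthesize_expression(gt, design)
        resid = centered.values - gt.M_true.to_numpy() @ gt.A_true.to_numpy()
        assert np.mean(resid**2) == pytest.approx(sigma**2, rel=0.05)

    def test_tpm_columns_sum_to_library_size(self):
        design = small_design()
        gt = self._gt(0.1, design)
        _, tpm = synthesize_expression(gt, design)
        np.testing.assert_allclose(tpm.values.sum(axis=0), 1e6, rtol=1e-9)

    def test_dimension_mismatch_raises(self):
        design = small_design()
        gt = self._gt(0.0, design)
        gt.A_true = gt.A_true.iloc[:2]
        with pytest.raises(ShapeError):
            synthesize_expression(gt, design)


class TestGenerateTrn:
    def test_full_fidelity_regulons_equal_memberships(self):
        gt = generate_structure(100, 4, 10, seed=5)
        trn = generate_trn(gt, fidelity=1.0, n_decoy_regulators=0, seed=5)
        assert len(trn) == 4
        for k in range(4):
            assert trn[f"Reg{k:02d}"] == gt.memberships[k]

    def test_decoy_count_and_size(self):
        gt = generate_structure(100, 2, 10, seed=5)
        trn = generate_trn(gt, n_decoy_regulators=5, decoy_size=10, seed=5)
        decoys = [r for r in trn if r.startswith("Decoy")]
        assert len(decoys) == 5
        assert all(len(trn[d]) == 10 for d in decoys)

    def test_partial_fidelity_overlap_within_binomial_bounds(self):
        # module of 50 genes, fidelity 0.8 -> kept ~ Binomial(50, 0.8);
        # aggregate over 100 seeds and check the 99% bound on the total
        gt = generate_structure(200, 1, 50, seed=0)
        total_kept = 0
        for seed in range(100):
            trn = generate_trn(gt, fidelity=0.8, seed=seed)
            total_kept += len(trn["Reg00"] & gt.memberships[0])
        n, p = 100 * 50, 0.8
        bound = 2.576 * np.sqrt(n * p * (1 - p))
        assert abs(total_kept - n * p) < bound
        # size is preserved in every draw
        assert len(trn["Reg00"]) == 50

    def test_oversized_decoys_raise(self):
        gt = generate_structure(30, 1, 10, seed=0)
        with pytest.raises(SizingError):
            generate_trn(gt, n_decoy_regulators=1, decoy_size=40, seed=0)


class TestDesignMetadata:
    def test_label_hygiene(self):
        design = small_design()
        meta = design.metadata()
        assert list(meta.columns) == [
            "sample_id", "condition", "time_h", "replicate", "is_reference"
        ]
        assert len(meta) == design.n_samples == 24
        assert meta["sample_id"].is_unique
        # exactly one (condition, time) group flagged as reference
        ref = meta[meta["is_reference"]]
        assert len(ref.groupby(["condition", "time_h"])) == 1

    def test_reference_must_name_a_group(self):
        with pytest.raises(ConfigurationError):
            small_design(reference=("X-lim", 3.0))

    def test_background_block_counts(self):
        d = small_design(background_samples=10, reference=("base", 0.0))
        assert d.n_samples == 34
        meta = d.metadata()
        assert (meta["condition"] == "base").sum() == 10
        assert meta.loc[meta["condition"] == "base", "is_reference"].all()


def test_signal_noise_sd_scales_with_ratio():
    design = small_design()
    gt = generate_structure(120, 3, 15, seed=1)
    gt.A_true = generate_activities(design, 3, seed=1)
    assert signal_noise_sd(gt, 0.5) == pytest.approx(
        2 * signal_noise_sd(gt, 0.25)
    )


def test_ground_truth_validate_catches_support_mismatch():
    gt = generate_structure(50, 2, 10, seed=0)
    gt.memberships[0].pop()
    with pytest.raises(ValueError):
        gt.validate()
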