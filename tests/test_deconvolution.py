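"""Marker selection, reference variants, constrained solver, robustness."""

import numpy as np
import pandas as pd
import pytest

from triaxis import (
    CellConfig,
    bootstrap_stability,
    build_reference,
    compare_fractions,
    deconvolve,
    generate_cell_population,
    generate_pseudobulk,
    noise_perturbation,
    permutation_enrichment,
    select_markers,
)
from triaxis.deconvolution import ReferenceMatrix
from triaxis.synthetic import FOCAL_GENE


class TestSelectMarkers:
    def test_planted_markers_recovered(self, cells, marker_set):
        for subtype, planted in cells.planted_markers.items():
            found = set(marker_set.per_subtype[subtype].index)
            recovery = len(found & set(planted)) / len(planted)
            assert recovery >= 0.8, subtype

    def test_filters_enforced_on_retained_markers(self, marker_set):
        for tab in marker_set.per_subtype.values():
            assert (tab["log2fc"] > 1).all()
            assert (tab["auroc"] > 0.7).all()
            assert (tab["q"] < 0.01).all()

    def test_union_deduplicated(self, marker_set):
        assert len(set(marker_set.union)) == len(marker_set.union)

    def test_uniform_gene_excluded(self, cells):
        mutated = cells.expression.copy()
        mutated["BG0001"] = 5.0
        clone = type(cells)(
            cell_id=cells.cell_id, patient_id=cells.patient_id,
            response_label=cells.response_label, subtype=cells.subtype,
            expression=mutated, focal_positive=cells.focal_positive,
        )
        mk = select_markers(clone)
        assert "BG0001" not in mk.union

    def test_loose_filters_keep_all_planted(self, cells):
        mk = select_markers(cells, min_lfc=0.0, min_auroc=0.5, max_q=1.0)
        planted = {g for gs in cells.planted_markers.values() for g in gs}
        assert planted <= set(mk.union)


class TestBuildReference:
    def test_nob_removes_only_focal_row(self, cells, marker_set, full_reference):
        nob = build_reference(cells, marker_set, "noB")
        assert FOCAL_GENE in full_reference.data.index
        assert FOCAL_GENE not in nob.data.index
        shared = nob.data.index
        pd.testing.assert_frame_equal(nob.data, full_reference.data.loc[shared])

    def test_dropnb_removes_correlated_program(self, cells, marker_set):
        dnb = build_reference(cells, marker_set, "dropNB")
        removed = set(marker_set.union) - set(dnb.data.index)
        program = set(cells.planted_markers["Trm"]) | set(
            cells.planted_markers["Proliferating"])
        # the dropped genes are overwhelmingly the focal program
        assert len(removed) >= 10
        assert len(removed - program) <= 3

    def test_pos_neg_concordant_when_focal_status_uninformative(self):
        cfg = CellConfig(seed=3, n_cells=1500, focal_positive_rate=(0.4, 0.4),
                         focal_program_corr=0.0)
        cells = generate_cell_population(cfg)
        mk = select_markers(cells)
        pos = build_reference(cells, mk, "POS")
        neg = build_reference(cells, mk, "NEG")
        shared = [g for g in pos.data.index if g in neg.data.index
                  and g != FOCAL_GENE]
        for s in pos.subtypes:
            r = np.corrcoef(pos.data.loc[shared, s], neg.data.loc[shared, s])[0, 1]
            assert r > 0.95

    def test_variant_round_trips_through_tsv(self, full_reference, tmp_path):
        path = tmp_path / "ref.tsv"
        full_reference.to_tsv(path)
        back = ReferenceMatrix.from_tsv(path)
        assert back.variant == "FULL"
        np.testing.assert_allclose(back.data.to_numpy(),
                                   full_reference.data.to_numpy(), rtol=1e-9)

    def test_unknown_variant_rejected(self, cells, marker_set):
        with pytest.raises(ValueError):
            build_reference(cells, marker_set, "BOGUS")


class TestDeconvolve:
    def test_reference_column_recovered_exactly(self, full_reference):
        k = len(full_reference.subtypes)
        bulk = full_reference.data.iloc[:, 3].rename("s")
        res = deconvolve(bulk, full_reference)
        expected = np.zeros(k)
        expected[3] = 1.0
        np.testing.assert_allclose(res.fractions.iloc[0], expected, atol=1e-9)
        assert res.rmse.iloc[0] == pytest.approx(0.0, abs=1e-9)

    def test_two_component_mixture_exact(self, full_reference):
        f = np.zeros(len(full_reference.subtypes))
        f[0], f[1] = 0.6, 0.4
        bulk = generate_pseudobulk(full_reference, f, noise_sd=0.0)
        res = deconvolve(bulk, full_reference)
        np.testing.assert_allclose(res.fractions.iloc[0], f, atol=1e-6)

    def test_partial_mass_leaves_other(self, full_reference):
        k = len(full_reference.subtypes)
        f = np.full(k, 0.8 / k)
        bulk = generate_pseudobulk(full_reference, f, noise_sd=0.0)
        res = deconvolve(bulk, full_reference)
        assert res.other.iloc[0] == pytest.approx(0.2, abs=1e-6)

    def test_zero_bulk_gives_all_other(self, full_reference):
        bulk = pd.Series(0.0, index=full_reference.data.index, name="z")
        res = deconvolve(bulk, full_reference)
        np.testing.assert_allclose(res.fractions.iloc[0], 0.0, atol=1e-9)
        assert res.other.iloc[0] == pytest.approx(1.0)

    def test_simplex_invariant_under_noise(self, full_reference, rng):
        k = len(full_reference.subtypes)
        cols = {}
        for i in range(50):
            f = rng.dirichlet(np.ones(k)) * rng.uniform(0.5, 1.0)
            cols[f"m{i}"] = generate_pseudobulk(
                full_reference, f, noise_sd=5.0, seed=rng)
        bulk = pd.DataFrame(cols).clip(lower=0.0)
        res = deconvolve(bulk, full_reference)
        total = res.fractions.sum(axis=1) + res.other
        np.testing.assert_allclose(total, 1.0, atol=1e-6)
        assert (res.fractions.to_numpy() >= -1e-9).all()

    def test_insufficient_gene_overlap_rejected(self, full_reference):
        bulk = pd.Series(1.0, index=full_reference.data.index[:5], name="s")
        with pytest.raises(ValueError, match="reference genes"):
            deconvolve(bulk, full_reference)


class TestCompareFractions:
    def test_identical_groups_all_null(self, rng):
        fr = pd.DataFrame(rng.dirichlet(np.ones(4), size=30),
                          columns=list("ABCD"))
        labels = np.r_[np.zeros(15), np.ones(15)]
        fr.iloc[15:] = fr.iloc[:15].to_numpy()  # identical distribution
        tab = compare_fractions(fr, labels)
        assert (tab["q"] > 0.9).all()

    def test_planted_enrichment_detected_with_sign(self, rng):
        base = rng.dirichlet(np.ones(4), size=40)
        labels = np.r_[np.zeros(20), np.ones(20)].astype(int)
        base[labels == 1, 0] += 0.3
        fr = pd.DataFrame(base / base.sum(axis=1, keepdims=True),
                          columns=list("ABCD"))
        tab = compare_fractions(fr, labels)
        assert tab["q"].idxmin() == "A"
        assert tab.loc["A", "delta"] > 0

    def test_scale_factor_applied(self, rng):
        fr = pd.DataFrame(rng.dirichlet(np.ones(3), size=20))
        labels = np.r_[np.zeros(10), np.ones(10)]
        t1 = compare_fractions(fr, labels, scale=1.0)
        t100 = compare_fractions(fr, labels, scale=100.0)
        np.testing.assert_allclose(t100["delta"], 100 * t1["delta"])


class TestPermutationEnrichment:
    def test_empirical_p_respects_add_one_bound(self, cells):
        tab = permutation_enrichment(cells.patient_composition(),
                                     cells.patient_labels(),
                                     n_perm=200, seed=0)
        assert (tab["p"] >= 1 / 201).all()

    def test_planted_enrichment_outside_null_interval(self):
        cfg = CellConfig(seed=41, n_cells=2500, n_patients=12, enrichment=3.0)
        cells = generate_cell_population(cfg)
        tab = permutation_enrichment(cells.patient_composition(),
                                     cells.patient_labels(),
                                     n_perm=500, seed=1)
        assert tab.loc["Trm", "outside_null_ci"]

    def test_null_generator_inside_interval_mostly(self):
        inside = 0
        for seed in range(15):
            cfg = CellConfig(seed=200 + seed, n_cells=600, n_patients=12,
                             enrichment=1.0)
            cells = generate_cell_population(cfg)
            tab = permutation_enrichment(cells.patient_composition(),
                                         cells.patient_labels(),
                                         n_perm=200, seed=seed)
            inside += not tab.loc["Tcm", "outside_null_ci"]
        assert inside >= 11

    def test_seeded_runs_reproducible(self, cells):
        a = permutation_enrichment(cells.patient_composition(),
                                   cells.patient_labels(), n_perm=100, seed=5)
        b = permutation_enrichment(cells.patient_composition(),
                                   cells.patient_labels(), n_perm=100, seed=5)
        pd.testing.assert_frame_equal(a, b)


class TestRobustness:
    def _mixture_cohort(self, ref, n, rng, noise_sd=2.0):
        cols = {}
        for i in range(n):
            f = rng.dirichlet(np.ones(len(ref.subtypes))) * 0.85
            cols[f"s{i}"] = generate_pseudobulk(ref, f, noise_sd=noise_sd,
                                                seed=rng)
        return pd.DataFrame(cols).clip(lower=0.0)

    def test_identical_samples_zero_bootstrap_sd(self, full_reference, rng):
        one = self._mixture_cohort(full_reference, 1, rng)
        bulk = pd.concat([one.iloc[:, 0].rename(f"s{i}") for i in range(8)],
                         axis=1)
        tab = bootstrap_stability(bulk, full_reference, n_boot=100, seed=0)
        np.testing.assert_allclose(tab["sd"], 0.0, atol=1e-12)

    def test_bootstrap_sd_shrinks_with_cohort_size(self, full_reference, rng):
        sds = []
        for n in (10, 40, 160):
            bulk = self._mixture_cohort(full_reference, n, rng)
            tab = bootstrap_stability(bulk, full_reference, n_boot=150, seed=1)
            sds.append(tab["sd"].mean())
        assert sds[0] > sds[1] > sds[2]

    def test_noise_perturbation_zero_noise_identity(self, full_reference, rng):
        bulk = self._mixture_cohort(full_reference, 8, rng)
        out = noise_perturbation(bulk, full_reference, rel_sd=0.0, n_iter=3,
                                 seed=0)
        assert out["mean_abs_shift"] == 0.0
        assert out["pearson"] == pytest.approx(1.0)

    def test_noise_shift_monotone_in_rel_sd(self, full_reference, rng):
        bulk = self._mixture_cohort(full_reference, 10, rng)
        shifts = [
            noise_perturbation(bulk, full_reference, rel_sd=s, n_iter=20,
                               seed=2)["mean_abs_shift"]
            for s in (0.01, 0.05, 0.1)
        ]
        assert shifts[0] < shifts[1] < shifts[2]

    def test_ablation_ordering_nob_beats_dropnb(self, cells, marker_set,
                                                full_reference, rng):
        nob = build_reference(cells, marker_set, "noB")
        dnb = build_reference(cells, marker_set, "dropNB")
        bulk = self._mixture_cohort(full_reference, 25, rng)
        base = deconvolve(bulk, full_reference).fractions.to_numpy().ravel()
        r_nob = np.corrcoef(base,
                            deconvolve(bulk, nob).fractions.to_numpy().ravel())[0, 1]
        r_dnb = np.corrcoef(base,
                            deconvolve(bulk, dnb).fractions.to_numpy().ravel())[0, 1]
        assert r_nob > r_dnb
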