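"""Generator contracts: determinism, structure, noise model, ground truth."""

import numpy as np
import pytest
from scipy import stats

from cementome.elemental import fit_calibration
from cementome.io import write_quant_matrix
from cementome.properties import atomic_composition
from cementome.synthetic import (
    ParameterError,
    SyntheticConfig,
    generate_dataset,
    generate_eds_table,
    generate_elisa_plate,
)


class TestConfigValidation:
    @pytest.mark.parametrize("field,value,message", [
        ("n_proteins", -1, "n_proteins"),
        ("fraction_host", 1.5, "fraction_host"),
        ("effect_size", 0.5, "effect_size"),
        ("n_bio_reps", 0, "n_bio_reps"),
        ("sequence_length_range", (1, 0), "sequence_length_range"),
        ("tick_membership", (0.5, 0.5, 0.5), "tick_membership"),
    ])
    def test_invalid_field_named(self, field, value, message):
        cfg = SyntheticConfig()
        setattr(cfg, field, value)
        with pytest.raises(ParameterError, match=message):
            cfg.validate()

    def test_category_weights_must_sum_to_one(self):
        cfg = SyntheticConfig(category_weights={"feeding": 0.7})
        with pytest.raises(ParameterError, match="category_weights"):
            cfg.validate()


class TestGenerateDataset:
    def test_empty_case(self):
        matrix, ann, seqs, truth = generate_dataset(SyntheticConfig(n_proteins=0))
        assert matrix.values.shape[0] == 0
        assert ann.empty and seqs == {} and truth.records == {}

    def test_study_design_run_structure(self, small_dataset):
        matrix, *_ = small_dataset
        # 3 sample types x 3 times x 2 biological x 3 technical replicates
        assert matrix.n_runs == 54
        counts = matrix.runs.groupby(["tissue", "extraction", "time"]).size()
        assert (counts == 6).all()
        assert set(matrix.runs["time"]) == {"T1", "T2", "T3"}

    def test_deterministic_byte_identical(self, tmp_path):
        cfg = SyntheticConfig(n_proteins=40, seed=1)
        out = []
        for name in ("a", "b"):
            matrix, ann, seqs, truth = generate_dataset(cfg)
            path = tmp_path / f"{name}.tsv"
            write_quant_matrix(matrix, path)
            truth.to_json(tmp_path / f"{name}.json")
            out.append((path.read_bytes(), (tmp_path / f"{name}.json").read_bytes(),
                        seqs))
        assert out[0][0] == out[1][0]
        assert out[0][1] == out[1][1]
        assert out[0][2] == out[1][2]

    def test_different_seeds_differ(self):
        m1, *_ = generate_dataset(SyntheticConfig(n_proteins=20, seed=1))
        m2, *_ = generate_dataset(SyntheticConfig(n_proteins=20, seed=2))
        assert not np.allclose(m1.values, m2.values)

    def test_abundance_positive_where_present(self, small_dataset):
        matrix, _ann, _seqs, truth = small_dataset
        for protein, rec in truth.records.items():
            row = matrix.values.loc[protein]
            sial_cols = matrix.runs.index[matrix.runs["tissue"] == "salivary_gland"]
            if rec.membership in ("sialome_only", "shared"):
                assert (row[sial_cols] > 0).all()
            else:
                assert (row[sial_cols] == 0).all()

    def test_every_protein_has_truth_and_annotation(self, small_dataset):
        matrix, ann, seqs, truth = small_dataset
        assert set(matrix.proteins) == set(truth.records)
        assert set(matrix.proteins) == set(ann.index)
        assert set(matrix.proteins) == set(seqs)

    def test_gly_rich_class_band(self):
        cfg = SyntheticConfig(n_proteins=150, seed=9, gly_rich_fraction=0.5)
        _m, _a, seqs, truth = generate_dataset(cfg)
        gly = [100.0 * seqs[p].count("G") / len(seqs[p])
               for p, r in truth.records.items() if r.sequence_class == "gly_rich"]
        bg = [100.0 * seqs[p].count("G") / len(seqs[p])
              for p, r in truth.records.items() if r.sequence_class == "background"]
        assert len(gly) > 10
        assert np.mean(gly) == pytest.approx(37.5, abs=4.0)  # configured [30, 45]
        assert np.mean(bg) == pytest.approx(5.0, abs=2.0)    # uniform background

    def test_host_tilt_toward_late_categories(self):
        cfg = SyntheticConfig(n_proteins=400, seed=4, fraction_host=0.5)
        _m, _a, _s, truth = generate_dataset(cfg)
        host_cats = [r.category for r in truth.records.values() if r.origin == "host"]
        tilt = np.mean([c in ("feeding_and_oogenesis",
                              "secondary_cement_production_I",
                              "secondary_cement_production_II") for c in host_cats])
        assert tilt == pytest.approx(0.86, abs=0.08)


class TestGenerateEds:
    def test_single_protein_no_noise_matches_formula(self):
        cfg = SyntheticConfig(n_proteins=1, seed=0, fraction_host=0.0,
                              category_weights={"housekeeping": 1.0})
        matrix, _a, seqs, _t = generate_dataset(cfg)
        seqs = {p: "GGGG" for p in seqs}
        eds = generate_eds_table(matrix, seqs, noise_sd=0.0, seed=0)
        counts, _ = atomic_composition("GGGG")  # C8 H14 N4 O5
        cnos = np.array([counts[e] for e in ("C", "N", "O", "S")], dtype=float)
        expected = 100.0 * cnos / cnos.sum()
        one_scan = eds[(eds["scan"] == 1)].groupby("element")["atomic_percent"].first()
        for el, exp in zip(("C", "N", "O", "S"), expected):
            assert one_scan[el] == pytest.approx(exp, abs=1e-9)

    def test_rows_sum_to_100(self, small_dataset):
        matrix, _a, seqs, _t = small_dataset
        eds = generate_eds_table(matrix, seqs, noise_sd=1.0, seed=2)
        sums = eds.groupby(["sample_id", "scan"])["atomic_percent"].sum()
        assert np.allclose(sums, 100.0)

    def test_no_noise_rank_concordant_with_protein_composition(self, small_dataset):
        matrix, _a, seqs, _t = small_dataset
        eds = generate_eds_table(matrix, seqs, noise_sd=0.0, seed=0)
        sial = eds[eds["tissue"] == "salivary_gland"]
        mean_eds = sial.groupby("element")["atomic_percent"].mean()
        # summed protein composition over the same tissue
        cols = matrix.runs.index[matrix.runs["tissue"] == "salivary_gland"]
        weights = matrix.values[cols].mean(axis=1)
        agg = np.zeros(4)
        for p, w in weights.items():
            counts, _ = atomic_composition(seqs[p])
            agg += w * np.array([counts[e] for e in ("C", "N", "O", "S")])
        rho, _ = stats.spearmanr(
            [mean_eds[e] for e in ("C", "N", "O", "S")], agg)
        assert rho == pytest.approx(1.0)

    def test_three_scans_per_sample(self, small_dataset):
        matrix, _a, seqs, _t = small_dataset
        eds = generate_eds_table(matrix, seqs, seed=1)
        assert (eds.groupby("sample_id")["scan"].nunique() == 3).all()

    def test_negative_noise_rejected(self, small_dataset):
        matrix, _a, seqs, _t = small_dataset
        with pytest.raises(ParameterError):
            generate_eds_table(matrix, seqs, noise_sd=-1.0)


class TestGenerateElisa:
    def test_perfect_line_exact_fit(self):
        plate = generate_elisa_plate(1.0, 0.0, 0.0, [0.0, 0.5, 1.0], n_blanks=3)
        stds = plate.standards()
        assert list(stds["od"]) == pytest.approx([0.0, 0.5, 1.0])
        fit = fit_calibration(list(zip(stds["ng"], stds["od"])))
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(1.0)

    def test_empty_standards_rejected(self):
        with pytest.raises(ParameterError):
            generate_elisa_plate(1.0, 0.0, 0.0, [])

    def test_blanks_read_background(self):
        plate = generate_elisa_plate(2.0, 0.1, 0.0, [0.0, 1.0], n_blanks=4)
        assert np.allclose(plate.blanks()["od"], 0.1)
        assert len(plate.blanks()) == 4

    def test_monte_carlo_slope_within_three_se(self):
        # 100 noisy plates: fitted slope unbiased within 3 s.e. of the mean
        slopes = []
        for seed in range(100):
            plate = generate_elisa_plate(
                1.0, 0.05, 0.05, [0.0, 0.1, 0.25, 0.5, 0.75, 0.9, 1.0],
                n_blanks=3, seed=seed)
            stds = plate.standards()
            fit = fit_calibration(list(zip(stds["ng"], stds["od"])))
            slopes.append(fit.slope)
        se = np.std(slopes, ddof=1) / np.sqrt(len(slopes))
        assert np.mean(slopes) == pytest.approx(1.0, abs=3 * se + 1e-9)
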