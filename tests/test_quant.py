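"""Poisson quantification, QC cascade and replicate averaging."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ddase import (
    DropletRun,
    EmptyRunError,
    PoissonQuantifier,
    SaturationError,
    ValidationError,
    average_replicates,
    estimate_copies_per_ng,
    estimate_lambda,
    qc_filter,
)
from ddase.io import runs_to_frame
from ddase.quant import QC_MISMATCH, QC_MONOALLELIC, QC_PASS, QC_SATURATED, QC_TOO_FEW


def duplex(well_id, sample_id, k_l, k_e, n=15_000, material="RNA",
           assay="vgll3_exon2", input_ng=50.0, replicate=1):
    return DropletRun(well_id=well_id, sample_id=sample_id, accepted_droplets=n,
                      channel_positives={1: k_l, 2: k_e},
                      channel_targets={1: f"{assay}_L", 2: f"{assay}_E"},
                      input_ng=input_ng, material=material, replicate=replicate)


class TestEstimateLambda:
    def test_closed_forms(self):
        assert estimate_lambda(0, 10_000) == 0.0
        assert estimate_lambda(5_000, 10_000) == pytest.approx(math.log(2))
        assert estimate_lambda(9_800, 10_000) == pytest.approx(-math.log(0.02))

    def test_errors(self):
        with pytest.raises(SaturationError):
            estimate_lambda(10_000, 10_000)
        with pytest.raises(EmptyRunError):
            estimate_lambda(0, 0)
        with pytest.raises(ValidationError):
            estimate_lambda(11, 10)

    @given(st.floats(min_value=0.01, max_value=3.0))
    def test_inverse_consistency(self, lam):
        """Round-tripping lambda through the expected positive count."""
        n = 1_000_000
        k = round(n * (1.0 - math.exp(-lam)))
        assert abs(estimate_lambda(k, n) - lam) < 1e-4

    def test_monotone_in_k(self):
        lams = [estimate_lambda(k, 1000) for k in range(0, 1000, 50)]
        assert all(b > a for a, b in zip(lams, lams[1:]))


class TestCopiesPerNg:
    def test_zero_positives(self):
        run = duplex("w", "s", 0, 10)
        q = estimate_copies_per_ng(run, 1)
        assert q.copies_per_ng == 0.0
        assert q.ci95[0] == 0.0

    def test_linear_in_inverse_input(self):
        a = estimate_copies_per_ng(duplex("w1", "s", 400, 0, input_ng=25.0), 1)
        b = estimate_copies_per_ng(duplex("w2", "s", 400, 0, input_ng=50.0), 1)
        assert a.copies_per_ng == pytest.approx(2 * b.copies_per_ng)

    def test_volume_constant(self):
        run = duplex("w", "s", 2000, 0)
        q = estimate_copies_per_ng(run, 1, droplet_volume_nl=0.85,
                                   reaction_volume_ul=20.0)
        lam = estimate_lambda(2000, 15_000)
        assert q.copies_per_ng == pytest.approx(lam * 20_000 / 0.85 / 50.0)
        assert q.ci95[0] <= q.copies_per_ng <= q.ci95[1]


class TestQcFilter:
    genotypes = {"HET1": "EL", "HOM1": "EE", "S": "LL"}

    def test_too_few_droplets(self):
        annotated = qc_filter([duplex("w", "HET1", 10, 10, n=9_999)],
                              self.genotypes)
        assert annotated[0][1] == QC_TOO_FEW

    def test_saturation_only_for_exempted_targets(self):
        run = DropletRun("w", "S", 15_000, {1: 14_800, 2: 100},
                         {1: "amh", 2: "igf3"}, 2.0)
        assert qc_filter([run], self.genotypes)[0][1] == QC_SATURATED
        # same fraction on a vgll3 assay is NOT a QC exclusion
        run2 = duplex("w2", "HET1", 14_800, 100)
        assert qc_filter([run2], self.genotypes)[0][1] == QC_MONOALLELIC

    def test_monoallelic_heterozygote(self):
        lam_l, lam_e = 0.93, 0.07  # fractional abundance 0.93
        n = 15_000
        k_l = round(n * (1 - math.exp(-lam_l)))
        k_e = round(n * (1 - math.exp(-lam_e)))
        assert qc_filter([duplex("w", "HET1", k_l, k_e)],
                         self.genotypes)[0][1] == QC_MONOALLELIC
        # DNA controls are never monoallelic outliers
        assert qc_filter([duplex("w", "HET1", k_l, k_e, material="DNA")],
                         self.genotypes)[0][1] == QC_PASS

    def test_homozygote_opposite_channel_signal(self):
        assert qc_filter([duplex("w", "HOM1", 300, 0)],
                         self.genotypes)[0][1] == QC_MISMATCH
        assert qc_filter([duplex("w", "HOM1", 0, 300)],
                         self.genotypes)[0][1] == QC_PASS

    def test_pass_case_and_rule_order(self):
        run = duplex("w", "HET1", 200, 180, n=10_000)
        assert qc_filter([run], self.genotypes)[0][1] == QC_PASS
        # droplet-count rule precedes everything else
        bad = duplex("w2", "HOM1", 300, 0, n=500)
        assert qc_filter([bad], self.genotypes)[0][1] == QC_TOO_FEW

    def test_unknown_genotype_rejected(self):
        with pytest.raises(ValidationError):
            qc_filter([duplex("w", "X", 10, 10)], {"X": "EX"})

    def test_order_invariance(self):
        runs = [duplex(f"w{i}", "HET1", 100 * i, 50, n=12_000)
                for i in range(1, 8)]
        fwd = {r.well_id: label for r, label in qc_filter(runs, self.genotypes)}
        rev = {r.well_id: label
               for r, label in qc_filter(runs[::-1], self.genotypes)}
        assert fwd == rev


class TestAverageReplicates:
    def make(self, sample, copies, qc=QC_PASS, rep=1):
        from ddase.quant import QuantResult
        return QuantResult(sample_id=sample, target="vgll3_total",
                           lambda_hat=0.1, copies_per_ng=copies,
                           ci95=(copies - 5, copies + 5), qc=qc, replicate=rep)

    def test_mean_of_pass_replicates(self):
        out = average_replicates([self.make("s", 100.0), self.make("s", 110.0)])
        assert len(out) == 1
        assert out[0].copies_per_ng == pytest.approx(105.0)
        assert out[0].n_replicates_used == 2

    def test_failed_replicate_excluded(self):
        out = average_replicates([self.make("s", 100.0),
                                  self.make("s", 999.0, qc=QC_SATURATED)])
        assert out[0].copies_per_ng == pytest.approx(100.0)
        assert out[0].n_replicates_used == 1

    def test_all_failed_sample_dropped(self):
        out = average_replicates([self.make("s", 1.0, qc=QC_TOO_FEW)])
        assert out == []

    def test_mean_of_normalized_not_normalization_of_pooled(self):
        """Averaging must happen after per-well normalization."""
        wells = [duplex("w1", "s", 1000, 0, input_ng=25.0, replicate=1),
                 duplex("w2", "s", 1000, 0, input_ng=50.0, replicate=2)]
        per_well = [estimate_copies_per_ng(w, 1) for w in wells]
        averaged = average_replicates(per_well)[0].copies_per_ng
        brute = np.mean([q.copies_per_ng for q in per_well])
        assert averaged == pytest.approx(brute)
        pooled_lambda = estimate_lambda(2000, 30_000)
        pooled = pooled_lambda * 20_000 / 0.85 / 37.5
        assert abs(averaged - pooled) > 1e-3  # genuinely different quantity


def test_poisson_quantifier_transformer_roundtrip():
    runs = [duplex("w1", "HET1", 1500, 1400, replicate=1),
            duplex("w2", "HET1", 1520, 1380, replicate=2)]
    frame = runs_to_frame(runs)
    pq = PoissonQuantifier().fit(frame, genotypes={"HET1": "EL"})
    out = pq.transform(frame)
    assert set(out["target"]) == {"vgll3_exon2_L", "vgll3_exon2_E"}
    assert (out["n_replicates_used"] == 2).all()
    params = pq.get_params()
    assert params["min_droplets"] == 10_000
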