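"""Species partitioning, filtering, spike-in scale factors, recovery."""

import numpy as np
import pandas as pd
import pytest

import polterm as pt
from polterm.calibration import (
    CalibrationError,
    SampleCounts,
    calibrate_track,
    coverage_from_reads,
    estimate_mixing_fraction,
    partition_and_filter,
    read_sam,
    spikein_scale_factor,
)
from tests.helpers import calibrated_gene_body_ratio


def make_reads(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "strand", "n_hits"])


class TestPartitionAndFilter:
    def test_spikein_prefix_routes_to_spikein_bucket(self):
        counts, _ = partition_and_filter(
            make_reads([("spikein_chrI", 10, "+", 1), ("chrI", 10, "+", 1)])
        )
        assert counts.reads_spikein == 1 and counts.reads_pombe == 1

    def test_identical_position_reads_collapse_to_one(self):
        counts, kept = partition_and_filter(
            make_reads([("chrI", 10, "+", 1), ("chrI", 10, "+", 1)])
        )
        assert counts.reads_pombe == 1 and counts.reads_duplicate == 1
        assert len(kept) == 1

    def test_opposite_strand_same_position_not_duplicates(self):
        counts, _ = partition_and_filter(
            make_reads([("chrI", 10, "+", 1), ("chrI", 10, "-", 1)])
        )
        assert counts.reads_pombe == 2

    def test_multimappers_discarded(self):
        counts, kept = partition_and_filter(
            make_reads([("chrI", 10, "+", 2), ("chrI", 50, "+", 1)])
        )
        assert counts.reads_multimapped == 1 and counts.reads_pombe == 1

    def test_unknown_reference_counted_and_excluded(self):
        counts, kept = partition_and_filter(
            make_reads([("weird", 10, "+", 1), ("chrI", 50, "+", 1)]),
            pombe_chroms={"chrI"},
        )
        assert counts.reads_unassigned == 1
        assert counts.reads_pombe == 1
        assert set(kept["chrom"]) == {"chrI"}

    def test_planted_duplicates_and_multimappers_match_brute_tally(self):
        """1000 reads with 100 planted duplicates and 50 multi-mappers:
        filtered counts equal an independent set-based tally."""
        rng = np.random.default_rng(123)
        base = pd.DataFrame(
            {
                "chrom": np.where(rng.random(1000) < 0.2, "spikein_chrI", "chrI"),
                "start": rng.integers(0, 200_000, size=1000),
                "strand": np.where(rng.random(1000) < 0.5, "+", "-"),
                "n_hits": 1,
            }
        )
        base.loc[rng.choice(1000, 50, replace=False), "n_hits"] = 3
        dup = base.iloc[rng.choice(1000, 100, replace=True)]
        reads = pd.concat([base, dup], ignore_index=True).sample(
            frac=1.0, random_state=0
        )
        counts, _ = partition_and_filter(reads)
        unique = {
            (r.chrom, r.start, r.strand)
            for r in reads.itertuples(index=False)
            if r.n_hits == 1
        }
        assert counts.reads_pombe == sum(1 for c, *_ in unique if c == "chrI")
        assert counts.reads_spikein == sum(
            1 for c, *_ in unique if c == "spikein_chrI"
        )


class TestScaleFactor:
    def ip(self, spikein=200_000):
        return SampleCounts("ip", "IP", reads_pombe=2_000_000, reads_spikein=spikein)

    def input_(self, pombe=1_000_000, spikein=150_000):
        return SampleCounts("in", "input", reads_pombe=pombe, reads_spikein=spikein)

    def test_hand_computed_example(self):
        assert spikein_scale_factor(self.ip(), self.input_()) == pytest.approx(0.75)

    def test_identical_counts_identical_factor(self):
        assert spikein_scale_factor(self.ip(), self.input_()) == spikein_scale_factor(
            self.ip(), self.input_()
        )

    def test_input_depth_rescaling_invariance(self):
        a = spikein_scale_factor(self.ip(), self.input_())
        b = spikein_scale_factor(self.ip(), self.input_(2_000_000, 300_000))
        assert a == pytest.approx(b)

    def test_zero_count_raises_naming_sample(self):
        with pytest.raises(CalibrationError, match="in"):
            spikein_scale_factor(self.ip(), SampleCounts("in", "input",
                                                         reads_pombe=10))

    def test_role_mismatch_rejected(self):
        with pytest.raises(CalibrationError):
            spikein_scale_factor(self.input_(), self.input_())


class TestCalibrateTrack:
    def test_identity_factor(self):
        cov = {"chrI": np.array([10.0, 20.0])}
        assert np.array_equal(
            calibrate_track(cov, 1.0).coverage["chrI"], cov["chrI"]
        )

    def test_scalar_multiply(self):
        out = calibrate_track({"chrI": np.array([10.0, 20.0])}, 0.75)
        assert np.allclose(out.coverage["chrI"], [7.5, 15.0])

    def test_round_trip_inverse(self):
        raw = {"chrI": np.linspace(0, 5, 100)}
        out = calibrate_track(raw, 0.37)
        assert np.allclose(out.coverage["chrI"] / 0.37, raw["chrI"], atol=1e-12)

    def test_nonfinite_factor_rejected(self):
        with pytest.raises(CalibrationError):
            calibrate_track({"chrI": np.ones(3)}, float("nan"))


class TestMixingFraction:
    def test_equal_genome_sizes_direct_ratio(self):
        c = SampleCounts("in", "input", reads_pombe=1000, reads_spikein=150)
        assert estimate_mixing_fraction(c, 100, 100) == pytest.approx(0.15)

    def test_genome_size_normalization(self):
        c = SampleCounts("in", "input", reads_pombe=1000, reads_spikein=75)
        assert estimate_mixing_fraction(c, 100, 50) == pytest.approx(0.15)

    def test_zero_pombe_reads_rejected(self):
        c = SampleCounts("in", "input", reads_pombe=0, reads_spikein=75)
        with pytest.raises(CalibrationError):
            estimate_mixing_fraction(c, 100, 50)


class TestSamRoundTrip:
    def test_sam_written_by_generator_reloads_identically(self, tmp_path):
        cfg = pt.SimulationConfig(
            seed=2, n_genes=5,
            chrom_sizes_pombe={"chrA": 30_000},
            chrom_sizes_spikein={"spikein_chrI": 5_000},
            reads_per_sample=2_000, multimap_rate=0.05,
        )
        genes = pt.simulate_annotation(cfg)
        samples, _ = pt.simulate_chip_samples(cfg, genes)
        sample = samples["wt_pol2_ip"]
        sizes = dict(cfg.chrom_sizes_pombe) | dict(cfg.chrom_sizes_spikein)
        path = tmp_path / "s.sam"
        pt.simulate.write_sam(sample, str(path), sizes, cfg.read_length)
        reloaded = read_sam(str(path))
        orig = sample.reads.reset_index(drop=True)
        assert len(reloaded) == len(orig)
        assert (reloaded["chrom"] == orig["chrom"]).all()
        assert (reloaded["start"] == orig["start"]).all()
        assert (reloaded["strand"] == orig["strand"]).all()
        assert (reloaded["n_hits"] == orig["n_hits"]).all()


class TestCalibrationRecovery:
    def test_identical_occupancy_ratio_near_one(self):
        """2x IP-efficiency and jittered mixing with identical occupancy:
        calibrated gene-body ratio recovers 1.0 within 5%."""
        assert calibrated_gene_body_ratio({}, seed=21) == pytest.approx(1.0, abs=0.05)

    def test_planted_two_fold_occupancy_recovered(self):
        assert calibrated_gene_body_ratio({"b": 2.0}, seed=21) == pytest.approx(
            2.0, abs=0.1
        )


def test_coverage_from_reads_counts_read_span():
    reads = make_reads([("chrI", 10, "+", 1), ("chrI", 30, "-", 1)])
    cov = coverage_from_reads(reads, {"chrI": 200}, read_length=50)["chrI"]
    assert cov[9] == 0 and cov[10] == 1 and cov[35] == 2 and cov[60] == 1
    assert cov.sum() == 100
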