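"""Synthetic-data generators: determinism, calibration, format validity."""

import hashlib
import json
from pathlib import Path

import numpy as np
import pysam
import pytest

from clipdiff.ingest import IngestConfig, read_alignments
from clipdiff.mixture import MixtureParams
from clipdiff.simulate import (
    SimulationScenario,
    simulate_bin_sequences,
    simulate_mixture,
    simulate_sam_pair,
)


def file_hashes(directory):
    return {p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(Path(directory).iterdir())}


class TestBinSequences:
    def test_identity_chain_gives_constant_states(self):
        scenario = SimulationScenario(seed=1, n_clusters=20, bins_per_cluster=30,
                                      transitions=np.eye(3))
        _, paths = simulate_bin_sequences(scenario)
        for p in paths:
            assert (p == p[0]).all()

    def test_empirical_transition_frequencies(self):
        # law of large numbers over ~1e5 steps
        scenario = SimulationScenario(seed=2, n_clusters=2000, bins_per_cluster=50)
        _, paths = simulate_bin_sequences(scenario)
        counts = np.zeros((3, 3))
        for p in paths:
            for a, b in zip(p[:-1], p[1:]):
                counts[a, b] += 1
        freq = counts / counts.sum(axis=1, keepdims=True)
        assert np.abs(freq - scenario.transitions).max() < 0.01

    def test_emissions_follow_state_means(self):
        scenario = SimulationScenario(seed=3, n_clusters=500, bins_per_cluster=50,
                                      mixture=MixtureParams(0.15, 2.0, 0.3))
        seqs, paths = simulate_bin_sequences(scenario)
        m = np.concatenate(seqs)
        s = np.concatenate(paths)
        means = [m[s == k].mean() for k in range(3)]
        assert means[0] == pytest.approx(2.0, abs=0.05)
        assert means[1] == pytest.approx(0.0, abs=0.05)
        assert means[2] == pytest.approx(-2.0, abs=0.05)

    def test_variable_cluster_lengths(self):
        scenario = SimulationScenario(seed=4, n_clusters=50,
                                      bins_per_cluster=(10, 20))
        seqs, _ = simulate_bin_sequences(scenario)
        lengths = {len(s) for s in seqs}
        assert lengths <= set(range(10, 21)) and len(lengths) > 1


class TestSimulateMixture:
    def test_moments(self):
        params = MixtureParams(0.15, 1.5, 0.8)
        rng = np.random.default_rng(5)
        m = simulate_mixture(200_000, params, rng)
        assert m.mean() == pytest.approx(0.0, abs=0.02)
        expect_second = 2 * params.p * params.mu**2 + params.sigma**2
        assert np.mean(m**2) == pytest.approx(expect_second, rel=0.02)


class TestSimulateSamPair:
    def test_seed_determinism(self, tmp_path):
        s1 = simulate_sam_pair(SimulationScenario(seed=7), tmp_path / "a")
        s2 = simulate_sam_pair(SimulationScenario(seed=7), tmp_path / "b")
        assert file_hashes(tmp_path / "a") == file_hashes(tmp_path / "b")

    def test_different_seed_differs(self, tmp_path):
        simulate_sam_pair(SimulationScenario(seed=7), tmp_path / "a")
        simulate_sam_pair(SimulationScenario(seed=8), tmp_path / "b")
        assert file_hashes(tmp_path / "a") != file_hashes(tmp_path / "b")

    def test_sam_parses_cleanly(self, tmp_path):
        manifest = simulate_sam_pair(SimulationScenario(seed=9, n_regions=10),
                                     tmp_path)
        for cond in ("cond1", "cond2"):
            with pysam.AlignmentFile(manifest["files"][cond]) as fh:
                n = sum(1 for rec in fh if not rec.is_unmapped)
            assert n > 0

    def test_truth_bed_state_composition(self, tmp_path):
        scenario = SimulationScenario(seed=10, n_regions=20,
                                      common_fraction_target=0.7)
        manifest = simulate_sam_pair(scenario, tmp_path)
        states = [l.split("\t")[3] for l in open(manifest["files"]["truth_bed"])]
        assert states.count("state1") == 14
        assert len(states) == 20

    def test_all_common_scenario(self, tmp_path):
        scenario = SimulationScenario(seed=11, n_regions=10,
                                      common_fraction_target=0.999)
        manifest = simulate_sam_pair(scenario, tmp_path)
        assert all(r["state"] == 1 for r in manifest["regions"])

    def test_depth_ratio_scales_condition2(self, tmp_path):
        base = SimulationScenario(seed=12, n_regions=20, duplication_rate=0.0)
        doubled = SimulationScenario(seed=12, n_regions=20, duplication_rate=0.0,
                                     depth_ratio=2.0)
        m1 = simulate_sam_pair(base, tmp_path / "a")
        m2 = simulate_sam_pair(doubled, tmp_path / "b")

        def n_reads(path):
            with pysam.AlignmentFile(path) as fh:
                return sum(1 for _ in fh)

        # compare within-run cond2/cond1 ratios: Poisson noise on each
        # count is ~2%, so the doubled scenario's ratio is ~2x the base's
        r_base = n_reads(m1["files"]["cond2"]) / n_reads(m1["files"]["cond1"])
        r_doubled = n_reads(m2["files"]["cond2"]) / n_reads(m2["files"]["cond1"])
        assert r_doubled / r_base == pytest.approx(2.0, rel=0.1)

    def test_parclip_mutations_planted_and_rate_zero_clean(self, tmp_path):
        cfg = IngestConfig(mutation_type="T2C")
        with_mut = simulate_sam_pair(
            SimulationScenario(seed=13, protocol="PAR-CLIP", n_regions=10,
                               mutation_rate=0.5), tmp_path / "mut")
        tags = list(read_alignments(with_mut["files"]["cond1"], 1, cfg))
        assert sum(len(t.mutations) for t in tags) > 0
        without = simulate_sam_pair(
            SimulationScenario(seed=13, protocol="PAR-CLIP", n_regions=10,
                               mutation_rate=0.0), tmp_path / "clean")
        tags = list(read_alignments(without["files"]["cond1"], 1, cfg))
        assert sum(len(t.mutations) for t in tags) == 0

    def test_hitsclip_deletions_at_crosslink(self, tmp_path):
        manifest = simulate_sam_pair(
            SimulationScenario(seed=14, n_regions=6, mutation_rate=0.5), tmp_path)
        crosslinks = {(r["chrom"], r["crosslink"]) for r in manifest["regions"]}
        tags = read_alignments(manifest["files"]["cond1"], 1,
                               IngestConfig(mutation_type="deletion"))
        muts = [m for t in tags for m in t.mutations]
        assert muts and all((m.chrom, m.pos) in crosslinks for m in muts)

    def test_iclip_fastq_has_barcodes_and_duplicates(self, tmp_path):
        scenario = SimulationScenario(seed=15, protocol="iCLIP", n_regions=8,
                                      duplication_rate=0.5)
        manifest = simulate_sam_pair(scenario, tmp_path)
        fq = manifest["files"]["fastq1"]
        seqs = [l.strip() for i, l in enumerate(open(fq)) if i % 4 == 1]
        assert len(seqs) > len(set(seqs))  # planted PCR duplicates
        assert all(len(s) == scenario.read_length + scenario.iclip_barcode_length
                   for s in seqs)

    def test_manifest_written(self, tmp_path):
        simulate_sam_pair(SimulationScenario(seed=16, n_regions=5), tmp_path)
        manifest = json.load(open(tmp_path / "manifest.json"))
        assert manifest["n_regions"] == 5


def test_scenario_validation():
    with pytest.raises(ValueError):
        SimulationScenario(protocol="CLIP")
    with pytest.raises(ValueError):
        SimulationScenario(common_fraction_target=1.5)
    with pytest.raises(ValueError):
        SimulationScenario(mutation_rate=2.0)
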