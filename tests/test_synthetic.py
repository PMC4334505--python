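"""Generator properties: determinism, composition, recoverable structure."""

import numpy as np
import pytest

from rnt1kit import motif, rna_fold, synthetic
from rnt1kit.core_io import GenomicInterval


class TestGenGenome:
    def test_uniform_frequencies_give_half_gc(self):
        freqs = np.full((4, 4), 1 / 16)
        genome, _ = synthetic.gen_genome(1000, freqs, seed=1)
        seq = genome["chrS"]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(0.5, abs=0.05)

    def test_same_seed_identical(self):
        g1, _ = synthetic.gen_genome(2000, seed=4)
        g2, _ = synthetic.gen_genome(2000, seed=4)
        assert g1 == g2

    def test_yeastlike_gc_converges(self):
        """Law of large numbers: empirical GC approaches the target at 1 Mb."""
        genome, _ = synthetic.gen_genome(1_000_000, seed=8)
        seq = genome["chrS"]
        target = synthetic.yeast_dinucleotide_freqs().sum(axis=1)
        target_gc = target[1] + target[2]
        gc = (seq.count("G") + seq.count("C")) / len(seq)
        assert gc == pytest.approx(target_gc, abs=0.01)

    def test_dinucleotide_convergence(self):
        genome, _ = synthetic.gen_genome(500_000, seed=9)
        seq = genome["chrS"]
        counts = np.zeros((4, 4))
        idx = {b: i for i, b in enumerate("ACGT")}
        for a, b in zip(seq, seq[1:]):
            counts[idx[a], idx[b]] += 1
        emp = counts / counts.sum()
        assert np.abs(emp - synthetic.yeast_dinucleotide_freqs()).max() < 0.01

    def test_negative_frequency_rejected(self):
        freqs = np.full((4, 4), 1 / 16)
        freqs[0, 0] = -freqs[0, 0]
        freqs[1, 1] += 2 / 16
        with pytest.raises(ValueError):
            synthetic.gen_genome(100, freqs)


class TestPlantLoop:
    def test_planted_loop_folds_to_single_hairpin(self):
        seq, loop_start = synthetic.build_hairpin("AGTT", stem_len=16, seed=3)
        res = rna_fold.fold(seq)
        assert len(res.terminal_loops) == 1
        start, end, loop = res.terminal_loops[0]
        assert (start, end) == (loop_start, loop_start + 4)
        assert loop == "AGUU"

    def test_aagu_is_ahnn(self):
        seq, _ = synthetic.build_hairpin("AAGT", stem_len=12, seed=5)
        assert rna_fold.classify_loop(rna_fold.fold(seq)) == "AHNN"

    def test_loop_length_bounds(self):
        with pytest.raises(ValueError):
            synthetic.build_hairpin("AG")
        with pytest.raises(ValueError):
            synthetic.build_hairpin("AGUUAAA")

    def test_manifest_records_plant(self):
        genome, manifest = synthetic.gen_genome(5000, seed=6)
        genome = synthetic.plant_loop(genome, manifest, 1000, "AGTT", seed=7)
        assert len(manifest.planted_loops) == 1
        planted = manifest.planted_loops[0]
        li = planted.loop_interval
        assert genome["chrS"][li.start : li.end] == "AGTT"
        manifest.validate(genome)

    def test_plant_outside_genome_rejected(self):
        genome, manifest = synthetic.gen_genome(100, seed=6)
        with pytest.raises(ValueError, match="fit"):
            synthetic.plant_loop(genome, manifest, 90, "AGTT")


class TestSimProbes:
    def _transcripts(self, samples=("wt", "mut"), fold=1.0):
        iv = GenomicInterval("chrS", 1000, 2500, "+")
        ab = {"wt": 400.0, "mut": 400.0 * fold}
        return [synthetic.Transcript("T1", iv, {s: ab[s] for s in samples})]

    def test_zero_noise_zero_bias_exact(self):
        genome, _ = synthetic.gen_genome(4000, seed=10)
        probes = synthetic.sim_probes(
            genome, self._transcripts(), ["wt", "mut"], noise_sd=0, dG_bias_coeff=0,
        )
        for p in probes:
            expected = (
                400.0
                if p.interval.strand == "+" and p.interval.overlaps(
                    GenomicInterval("chrS", 1000, 2500, "+"))
                else 50.0
            )
            assert p.intensity["wt"] == pytest.approx(expected)

    def test_two_fold_transcript_log2_ratio(self):
        genome, _ = synthetic.gen_genome(4000, seed=11)
        probes = synthetic.sim_probes(
            genome, self._transcripts(fold=2.0), ["wt", "mut"],
            noise_sd=0.05, seed=12,
        )
        inside = [
            np.log2(p.intensity["mut"] / p.intensity["wt"])
            for p in probes
            if p.interval.strand == "+"
            and p.interval.start >= 1000 and p.interval.end <= 2500
        ]
        assert np.mean(inside) == pytest.approx(1.0, abs=0.1)

    def test_bias_slope_recoverable(self):
        """Regression of log2 intensity on hybridisation ΔG over background
        probes recovers the injected bias coefficient."""
        genome, _ = synthetic.gen_genome(30_000, seed=13)
        probes = synthetic.sim_probes(
            genome, [], ["s"], dG_bias_coeff=0.05, noise_sd=0.02, seed=14,
        )
        dg = np.array([p.hyb_dG for p in probes])
        y = np.log2([p.intensity["s"] for p in probes])
        slope = np.polyfit(dg, y, 1)[0]
        assert slope == pytest.approx(0.05, abs=0.01)


class TestSimCutchip:
    def _setup(self, efficiency):
        genome, _ = synthetic.gen_genome(6000, seed=15)
        t = synthetic.Transcript(
            "T1", GenomicInterval("chrS", 1000, 4000, "+"), {"untreated": 500.0}
        )
        probes = synthetic.sim_probes(genome, [t], ["untreated"], noise_sd=0)
        site = synthetic.CleavageSite(
            GenomicInterval("chrS", 2000, 2035, "+"), efficiency, 1965, "T1"
        )
        return synthetic.sim_cutchip(probes, [t], [site]), site

    def test_zero_efficiency_identity(self):
        probes, _ = self._setup(0.0)
        for p in probes:
            assert p.intensity["treated"] == pytest.approx(p.intensity["untreated"])

    def test_half_cleavage_minus_one_log2(self):
        probes, site = self._setup(0.5)
        for p in probes:
            if (
                p.interval.strand == "+"
                and p.interval.start >= site.interval.end
                and p.interval.end <= 4000
            ):
                ratio = np.log2(p.intensity["treated"] / p.intensity["untreated"])
                assert ratio == pytest.approx(-1.0)
            elif p.interval.strand == "+" and p.interval.end <= site.interval.start:
                assert p.intensity["treated"] == pytest.approx(p.intensity["untreated"])

    def test_site_outside_transcript_rejected(self):
        genome, _ = synthetic.gen_genome(3000, seed=16)
        t = synthetic.Transcript(
            "T1", GenomicInterval("chrS", 100, 600, "+"), {"untreated": 100.0}
        )
        probes = synthetic.sim_probes(genome, [t], ["untreated"], noise_sd=0)
        site = synthetic.CleavageSite(GenomicInterval("chrS", 2000, 2035, "+"), 0.5, 10)
        with pytest.raises(ValueError, match="transcript"):
            synthetic.sim_cutchip(probes, [t], [site])


class TestSimSali:
    def test_reads_deterministic(self):
        genome, _ = synthetic.gen_genome(5000, seed=17)
        site = synthetic.CleavageSite(GenomicInterval("chrS", 1000, 1035, "+"), 0.9, 100)
        t1, c1 = synthetic.sim_sali(genome, [(site, 20)], seed=18)
        t2, c2 = synthetic.sim_sali(genome, [(site, 20)], seed=18)
        assert t1 == t2 and c1 == c2

    def test_fragment_copies_and_shared_background(self):
        genome, _ = synthetic.gen_genome(5000, seed=17)
        site = synthetic.CleavageSite(GenomicInterval("chrS", 1000, 1035, "+"), 0.9, 100)
        treated, control = synthetic.sim_sali(
            genome, [(site, 20)], n_background=30, seed=19
        )
        frag = synthetic.DEFAULT_ADAPTER + genome["chrS"][1000:1035]
        assert treated.count(frag) == 20
        assert control.count(frag) == 0
        assert set(control) <= set(treated)  # background is shared


class TestSimQpcr:
    def test_fold_expectation(self):
        recs = synthetic.sim_qpcr(["g"], {"g": 2.0}, replicate_sd=0.0, n_reps=3)
        wt = np.mean([r.delta_ct for r in recs if r.genotype == "wild-type"])
        mut = np.mean([r.delta_ct for r in recs if r.genotype == "mutant"])
        assert 2.0 ** (wt - mut) == pytest.approx(2.0)

    def test_min_replicates(self):
        with pytest.raises(ValueError):
            synthetic.sim_qpcr(["g"], {}, n_reps=2)


class TestFixtureTable:
    def test_roundtrip_and_shape(self, tmp_path, substrates):
        path = tmp_path / "subs.tsv"
        synthetic.write_substrate_table(substrates, path)
        back = []
        for line in path.read_text().splitlines()[1:]:
            name, seq, ls = line.split("\t")
            back.append((name, seq, int(ls)))
        assert back == substrates

    def test_fixture_loops_are_g2(self, substrates):
        for _, seq, loop_start in substrates:
            assert seq[loop_start + 1] == "G"
            assert seq[loop_start] == "A"
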