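"""Stem-loop enumeration, scoring model and genome scan."""

import numpy as np
import pytest

from rnt1kit import motif, synthetic
from rnt1kit.core_io import Feature, GenomicInterval


def brute_force_loops(seq, min_stem=3):
    """Independent oracle: loop start positions with G at loop position 2
    and min_stem consecutive stable closing pairs."""
    seq = seq.upper().replace("T", "U")
    pairs = {"AU", "UA", "GC", "CG", "GU", "UG"}
    out = set()
    for i in range(min_stem, len(seq) - 3 - min_stem):
        if seq[i + 1] != "G":
            continue
        if all(seq[i - k] + seq[i + 3 + k] in pairs for k in range(1, min_stem + 1)):
            out.add(i)
    return out


class TestEnumeration:
    def test_poly_a_has_no_candidates(self):
        assert motif.enumerate_candidates("A" * 1000) == []

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=2000))
            got = {
                c.loop_interval.start
                for c in motif.enumerate_candidates(seq, strand="+")
            }
            assert got == brute_force_loops(seq)

    def test_planted_perfect_loop_found(self):
        insert, loop_start = synthetic.build_hairpin("AGTT", stem_len=16, seed=1)
        seq = "A" * 300 + insert + "A" * 300
        cands = motif.enumerate_candidates(seq, strand="+")
        starts = [c.loop_interval.start for c in cands]
        assert 300 + loop_start in starts
        planted = cands[starts.index(300 + loop_start)]
        assert planted.loop_seq == "AGUU"
        assert planted.downstream_bp >= 16  # full stem incl. clamp region

    def test_strand_symmetry(self):
        rng = np.random.default_rng(13)
        seq = "".join(rng.choice(list("ACGT"), size=1500))
        fwd = motif.enumerate_candidates(seq, strand="both")
        rev = motif.enumerate_candidates(motif.revcomp(seq), strand="both")
        n = len(seq)

        def key(c):
            return (c.loop_interval.start, c.loop_interval.end, c.interval.strand)

        mirrored = {
            (n - c.loop_interval.end, n - c.loop_interval.start,
             "+" if c.interval.strand == "-" else "-")
            for c in rev
        }
        assert {key(c) for c in fwd} == mirrored

    def test_weak_downstream_candidate_reachable_at_lower_min_stem(self):
        # only 2 consecutive closing pairs: absent at the default filter,
        # emitted with downstream_bp = 2 when the filter is relaxed
        insert, loop_start = synthetic.build_hairpin(
            "AGTT", stem_len=16, mismatches=[3], seed=2
        )
        seq = "AAAA" + insert + "AAAA"
        default = {
            c.loop_interval.start for c in motif.enumerate_candidates(seq, strand="+")
        }
        assert 4 + loop_start not in default
        relaxed = motif.enumerate_candidates(seq, strand="+", min_stem=2)
        cand = next(c for c in relaxed if c.loop_interval.start == 4 + loop_start)
        assert cand.downstream_bp == 2


class TestTraining:
    def test_requires_ten_substrates(self, substrates):
        with pytest.raises(ValueError, match="10"):
            motif.train_model(substrates[:5])

    def test_degenerate_position_maximises_weight(self, substrates):
        model = motif.train_model(substrates)
        # fixture loops all start with A: position 1 log-odds maximal at A
        assert np.argmax(model.loop_weights[0]) == 0
        assert np.argmax(model.loop_weights[1]) == motif._CODE["G"]

    def test_base_relabelling_equivariance(self, substrates):
        """Permuting base labels in the training set permutes the learned
        loop weights identically."""
        perm = {"A": "C", "C": "G", "G": "U", "U": "A", "T": "A", "N": "N"}
        releb = [
            (name, "".join(perm[b] for b in seq.replace("T", "U")), ls)
            for name, seq, ls in substrates
        ]
        bg = {"A": 0.3, "C": 0.2, "G": 0.2, "U": 0.3}
        bg_perm = {perm[b]: f for b, f in bg.items()}
        m1 = motif.train_model(substrates, background_freqs=bg)
        m2 = motif.train_model(releb, background_freqs=bg_perm)
        cols = [motif._CODE[perm[b]] for b in "ACGU"]
        assert np.allclose(m2.loop_weights[:, cols], m1.loop_weights)

    def test_conservation_disabled_without_alignments(self, substrates):
        model = motif.train_model(substrates)
        assert model.conservation_enabled is False


class TestScoring:
    def test_scores_in_unit_interval(self, default_model, small_genome):
        genome, _ = small_genome
        cands = motif.enumerate_candidates(genome["chrS"], strand="both")
        motif.score_candidates(cands, default_model)
        scored = [c.score for c in cands if c.score is not None]
        assert scored and all(0.0 <= s <= 1.0 for s in scored)

    def test_training_substrate_has_unit_similarity(self, substrates, default_model):
        name, seq, loop_start = substrates[0]
        cand = motif.candidate_from_hairpin(seq, loop_start)
        raw = motif.raw_components([cand], default_model)
        assert raw[0, 2] == pytest.approx(1.0)

    def test_fixture_substrates_clear_cutoff(self, substrates, default_model):
        """At least 80% of the packaged fixture substrates score above the
        published 0.85 cutoff under the shipped calibrated model."""
        cands = [motif.candidate_from_hairpin(s, ls) for _, s, ls in substrates]
        motif.score_candidates(cands, default_model)
        frac = np.mean([c.score is not None and c.score >= 0.85 for c in cands])
        assert frac >= 0.8

    def test_weak_downstream_gets_no_score(self, default_model):
        insert, loop_start = synthetic.build_hairpin(
            "AGTT", stem_len=16, mismatches=[3], seed=2
        )
        cand = motif.candidate_from_hairpin("AAAA" + insert + "AAAA", 4 + loop_start)
        assert cand.downstream_bp < 3
        motif.score_candidate(cand, default_model)
        assert cand.score is None

    def test_frame_mismatch_rejected(self, default_model):
        insert, loop_start = synthetic.build_hairpin("AGTT", seed=3)
        cand = motif.candidate_from_hairpin(insert, loop_start, stem_span=8)
        with pytest.raises(ValueError, match="frame"):
            motif.score_candidate(cand, default_model)


class TestScan:
    def test_planted_loops_recovered(self, default_model):
        genome, manifest = synthetic.gen_genome(40_000, seed=21)
        rng = np.random.default_rng(22)
        for pos in (8_000, 20_000, 32_000):
            genome = synthetic.plant_loop(
                genome, manifest, pos, "AGTT", seed=int(rng.integers(2**31))
            )
        hits, summary = motif.scan_genome(genome, default_model)
        hit_loops = {
            (h.loop_interval.start, h.loop_interval.strand) for h in hits
        }
        for planted in manifest.planted_loops:
            assert (planted.loop_interval.start, "+") in hit_loops
        assert summary["hits"] == len(hits)

    def test_cutoff_monotonicity(self, default_model, small_genome):
        genome, _ = small_genome
        sets = {}
        for cutoff in (0.80, 0.85, 0.90):
            hits, _ = motif.scan_genome(genome, default_model, cutoff=cutoff)
            sets[cutoff] = {(h.interval.start, h.interval.strand) for h in hits}
        assert sets[0.90] <= sets[0.85] <= sets[0.80]

    def test_impossible_cutoff_empty(self, default_model, small_genome):
        genome, _ = small_genome
        hits, summary = motif.scan_genome(genome, default_model, cutoff=1.01)
        assert hits == [] and summary["spacing_kb"] == np.inf


class TestDensity:
    def test_spacing_arithmetic(self):
        assert motif.density([object()] * 10, 40_000) == pytest.approx(4.0)

    def test_zero_hits_infinite(self):
        assert motif.density([], 1000) == np.inf

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            motif.density([], 0)


class TestAnnotation:
    def _hit(self, start, end, strand="+"):
        iv = GenomicInterval("chrI", start, end, strand)
        cand = motif.LoopCandidate(
            interval=iv, loop_interval=iv, loop_seq="AGUU", frame_seq="A" * 36,
            up_arm="A" * 16, down_arm="A" * 16,
            pairing_up=np.zeros(16, bool), pairing_down=np.zeros(16, bool),
            downstream_bp=3, wobble_proximal=False, dG=0.0,
        )
        return cand

    def test_precedence_rules(self):
        features = [
            Feature(GenomicInterval("chrI", 0, 500, "+"), "GENE1", "gene"),
            Feature(GenomicInterval("chrI", 100, 200, "+"), "SNR1", "snoRNA"),
            Feature(GenomicInterval("chrI", 900, 1000, "+"), "LTR1", "LTR"),
        ]
        hits = [
            self._hit(120, 156),          # snoRNA + gene overlap -> ncRNA
            self._hit(300, 336),          # gene only, same strand -> PCG-sense
            self._hit(300, 336, "-"),     # gene only, opposite -> antisense
            self._hit(920, 956, "-"),     # LTR (strand-blind)
            self._hit(2000, 2036),        # nothing -> intergenic
        ]
        assert motif.annotate_hits(hits, features) == [
            "ncRNA", "PCG-sense", "antisense", "LTR", "intergenic",
        ]


class TestCalibration:
    def test_fixed_point_when_already_feasible(self, default_model, substrates):
        genome, _ = synthetic.gen_genome(300_000, seed=31)
        bg = motif.enumerate_candidates(genome["chrS"], strand="both")
        fix = [motif.candidate_from_hairpin(s, ls) for _, s, ls in substrates]
        calibrated, report = motif.calibrate_model(
            default_model, fix, bg, scanned_nt=600_000
        )
        assert report.feasible
        assert calibrated.component_weights == default_model.component_weights

    def test_infeasible_constraints_fail_loudly(self, default_model, substrates):
        genome, _ = synthetic.gen_genome(100_000, seed=32)
        bg = motif.enumerate_candidates(genome["chrS"], strand="both")
        fix = [motif.candidate_from_hairpin(s, ls) for _, s, ls in substrates]
        with pytest.raises(ValueError, match="best achieved"):
            motif.calibrate_model(
                default_model, fix, bg, scanned_nt=200_000,
                spacing_band_kb=(0.001, 0.002),
            )
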