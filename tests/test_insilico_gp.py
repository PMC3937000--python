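"""In-silico random PCR and gel feature-point model."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from genoprof.insilico_gp import (
    HUNT,
    REF1,
    REF2,
    DistortionSpec,
    MobilityModel,
    Primer,
    enumerate_amplicons,
    find_binding_sites,
    melting_temperature,
    mobility,
    profile_fragments,
    select_fragments,
)
from genoprof.lineage_sim import random_genome

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s):
    return s.translate(_COMP)[::-1]


def scan_oracle(genome, primer, max_mismatch, anchor3):
    """Position-by-position reference implementation."""
    m = len(primer.sequence)
    rc = revcomp(primer.sequence)
    out = []
    for pos in range(len(genome) - m + 1):
        win = genome[pos:pos + m]
        mm = sum(a != b for a, b in zip(win, primer.sequence))
        if mm <= max_mismatch and (
            anchor3 == 0
            or win[m - anchor3:] == primer.sequence[m - anchor3:]
        ):
            out.append((pos, "+", mm))
        mm = sum(a != b for a, b in zip(win, rc))
        if mm <= max_mismatch and (anchor3 == 0 or win[:anchor3] == rc[:anchor3]):
            out.append((pos, "-", mm))
    return sorted(out)


def pairing_oracle(sites, genome, min_len, max_len):
    """All convergent (+,-) pairs, O(n^2)."""
    out = []
    for p in sites:
        if p.strand != "+":
            continue
        for q in sites:
            if q.strand != "-" or q.position < p.position:
                continue
            end = q.position + q.footprint
            if min_len <= end - p.position <= max_len and end <= len(genome):
                out.append((p.position, end, p.mismatches + q.mismatches))
    return sorted(out)


class TestFindBindingSites:
    def test_exact_primer_found(self):
        genome = "A" * 50 + HUNT.sequence + "A" * 50
        sites = find_binding_sites(genome, HUNT, max_mismatch=0, anchor3=3)
        plus = [s for s in sites if s.strand == "+"]
        assert [(s.position, s.mismatches) for s in plus] == [(50, 0)]

    def test_reverse_complement_site_on_minus_strand(self):
        genome = "A" * 50 + revcomp(HUNT.sequence) + "A" * 50
        sites = find_binding_sites(genome, HUNT, max_mismatch=0, anchor3=3)
        minus = [s for s in sites if s.strand == "-"]
        assert [(s.position, s.mismatches) for s in minus] == [(50, 0)]

    def test_tgc_repeat_genome_has_periodic_sites(self):
        genome = "TGC" * 100
        sites = find_binding_sites(genome, HUNT, max_mismatch=0, anchor3=3)
        plus = [s.position for s in sites if s.strand == "+"]
        assert plus == list(range(0, 3 * 100 - 12 + 1, 3))

    def test_matches_exhaustive_scan_oracle(self, genome_1kb):
        sites = find_binding_sites(genome_1kb, HUNT, max_mismatch=2, anchor3=3)
        got = [(s.position, s.strand, s.mismatches) for s in sites]
        assert got == scan_oracle(genome_1kb, HUNT, 2, 3)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), mm=st.integers(0, 5),
           anchor=st.integers(0, 4))
    def test_oracle_equivalence_property(self, seed, mm, anchor):
        genome = random_genome(300, seed=seed, gc=0.6)
        primer = Primer("P", "AGAACGCGCCTG")
        sites = find_binding_sites(genome, primer, mm, anchor)
        got = [(s.position, s.strand, s.mismatches) for s in sites]
        assert got == scan_oracle(genome, primer, mm, anchor)

    def test_primer_longer_than_genome_gives_empty(self):
        assert find_binding_sites("ACGT", HUNT, 5, 3) == []


class TestEnumerateAmplicons:
    def test_single_convergent_pair(self):
        genome = random_genome(1000, seed=3)
        genome = HUNT.sequence + genome[12:488] + revcomp(HUNT.sequence) + genome[500:]
        sites = find_binding_sites(genome, HUNT, max_mismatch=0, anchor3=3)
        frags = enumerate_amplicons(sites, genome, 100, 2000)
        assert len(frags) == 1
        assert (frags[0].start, frags[0].end, frags[0].length) == (0, 500, 500)

    def test_one_strand_only_gives_empty(self):
        genome = "A" * 50 + HUNT.sequence + "A" * 500 + HUNT.sequence + "A" * 50
        sites = find_binding_sites(genome, HUNT, max_mismatch=0, anchor3=3)
        assert all(s.strand == "+" for s in sites)
        assert enumerate_amplicons(sites, genome, 100, 2000) == []

    def test_matches_pairing_oracle_on_random_sites(self):
        primer = Primer("P", "AGAACGCGCCTG")
        for seed in range(5):
            genome = random_genome(2000, seed=seed, gc=0.6)
            sites = find_binding_sites(genome, primer, 4, 1)
            frags = enumerate_amplicons(sites, genome, 150, 1200)
            got = sorted((f.start, f.end, f.score) for f in frags)
            assert got == pairing_oracle(sites, genome, 150, 1200)

    def test_fragment_sequence_matches_coordinates(self):
        genome = random_genome(1500, seed=9)
        primer = Primer("P", "AGAACGCGCCTG")
        sites = find_binding_sites(genome, primer, 4, 1)
        for f in enumerate_amplicons(sites, genome, 100, 1500):
            assert f.sequence == genome[f.start:f.end]


class TestSelectFragments:
    def test_returns_all_when_fewer_than_requested(self):
        genome = random_genome(600, seed=1)
        primer = Primer("P", "AGAACGCGCCTG")
        sites = find_binding_sites(genome, primer, 4, 1)
        frags = enumerate_amplicons(sites, genome, 100, 600)
        assert len(frags) < 10
        assert select_fragments(frags, 10) == frags

    def test_deterministic_tiebreak_by_start(self):
        genome = random_genome(5000, seed=2, gc=0.6)
        primer = Primer("P", "AGAACGCGCCTG")
        sites = find_binding_sites(genome, primer, 5, 1)
        frags = enumerate_amplicons(sites, genome, 100, 2000)
        a = select_fragments(frags, 5)
        b = select_fragments(list(reversed(frags)), 5)
        assert a == b
        keys = [(f.score, f.length, f.start) for f in a]
        assert keys == sorted(keys)

    def test_rejects_nonpositive_band_count(self):
        with pytest.raises(ValueError):
            select_fragments([], 0)


class TestMeltingTemperature:
    def test_gc_rich_melts_higher_than_at_rich(self):
        assert melting_temperature("G" * 60, 50) > melting_temperature("A" * 60, 50)

    def test_window_equal_to_length_is_global_formula(self):
        seq = random_genome(80, seed=4)
        gc = sum(c in "GC" for c in seq)
        expected = 64.9 + 41 * (gc - 16.4) / 80 - 20.0
        assert melting_temperature(seq, 80) == pytest.approx(expected)

    def test_substitution_in_minimal_window_lowers_tm(self):
        """A G->A hit inside the governing window strictly lowers Tm;
        brute-force window recomputation agrees everywhere."""
        w = 30
        seq = random_genome(300, seed=5)

        def brute(s):
            vals = [
                64.9 + 41 * (sum(c in "GC" for c in s[i:i + w]) - 16.4) / w - 20.0
                for i in range(len(s) - w + 1)
            ]
            return min(vals)

        base = melting_temperature(seq, w)
        assert base == pytest.approx(brute(seq))
        # locate a G inside one of the minimal windows
        vals = [melting_temperature(seq[i:i + w], w) for i in range(len(seq) - w + 1)]
        argmin = int(np.argmin(vals))
        gpos = next(i for i in range(argmin, argmin + w) if seq[i] == "G")
        mutated = seq[:gpos] + "A" + seq[gpos + 1:]
        assert melting_temperature(mutated, w) < base
        assert melting_temperature(mutated, w) == pytest.approx(brute(mutated))

    def test_substitution_outside_all_minimal_windows_is_invisible(self):
        w = 30
        seq = random_genome(300, seed=6)
        vals = np.array(
            [melting_temperature(seq[i:i + w], w) for i in range(len(seq) - w + 1)]
        )
        mn = vals.min()
        covered = np.zeros(len(seq), dtype=bool)
        for i in np.nonzero(vals <= mn + 41.0 / w + 1e-9)[0]:
            covered[i:i + w] = True  # near-minimal windows could take over
        free = np.nonzero(~covered)[0]
        assert free.size > 0
        pos = int(free[0])
        repl = "G" if seq[pos] in "AT" else "A"
        mutated = seq[:pos] + repl + seq[pos + 1:]
        assert melting_temperature(mutated, w) == pytest.approx(
            melting_temperature(seq, w)
        )

    def test_errors(self):
        with pytest.raises(ValueError):
            melting_temperature("", 10)
        with pytest.raises(ValueError):
            melting_temperature("ACGT", 10)


class TestMobility:
    def test_reference_order(self):
        assert mobility(REF1.length) > mobility(REF2.length)

    def test_boundaries_and_monotonicity(self):
        m = MobilityModel(100, 3000)
        assert mobility(100, m) == pytest.approx(1.0)
        assert mobility(3000, m) == pytest.approx(0.0)
        lengths = [100, 200, 500, 900, 1500, 3000]
        vals = [mobility(x, m) for x in lengths]
        assert vals == sorted(vals, reverse=True)

    def test_equal_lengths_equal_mobility(self):
        assert mobility(750) == mobility(750)

    def test_nonpositive_length_rejected(self):
        with pytest.raises(ValueError):
            mobility(0)


class TestProfileFragments:
    def _fragments(self):
        genome = random_genome(8000, seed=8, gc=0.6)
        primer = Primer("P", "AGAACGCGCCTG")
        sites = find_binding_sites(genome, primer, 5, 1)
        return enumerate_amplicons(sites, genome, 500, 1500)

    def test_zero_distortion_gives_model_values(self):
        frags = self._fragments()
        pts = profile_fragments(frags, distortion=DistortionSpec.none(), seed=0)
        refs = [p for p in pts if p.is_reference]
        assert {p.source for p in refs} == {"Ref1", "Ref2"}
        by = {p.source: p for p in refs}
        assert by["Ref1"].mobility_raw == pytest.approx(mobility(200))
        assert by["Ref1"].temp_raw == pytest.approx(60.0)
        assert by["Ref2"].temp_raw == pytest.approx(61.4)
        sample = [p for p in pts if not p.is_reference]
        assert sample[0].mobility_raw == pytest.approx(mobility(frags[0].length))
        assert sample[0].temp_raw == pytest.approx(
            melting_temperature(frags[0].sequence, 500)
        )

    def test_affine_parameters_recoverable_from_references(self):
        """With pure affine distortion the two observed reference points
        determine the transform exactly, per axis."""
        frags = self._fragments()
        dist = DistortionSpec((1.07, 1.07), (0.03, 0.03), (0.96, 0.96),
                              (1.5, 1.5), 0.0, 0.0)
        pts = profile_fragments(frags, distortion=dist, seed=1)
        by = {p.source: p for p in pts if p.is_reference}
        s_m = (by["Ref2"].mobility_raw - by["Ref1"].mobility_raw) / (
            mobility(900) - mobility(200)
        )
        o_m = by["Ref1"].mobility_raw - s_m * mobility(200)
        assert s_m == pytest.approx(1.07)
        assert o_m == pytest.approx(0.03)
        s_t = (by["Ref2"].temp_raw - by["Ref1"].temp_raw) / (61.4 - 60.0)
        o_t = by["Ref1"].temp_raw - s_t * 60.0
        assert s_t == pytest.approx(0.96)
        assert o_t == pytest.approx(1.5)

    def test_same_seed_identical_output(self):
        frags = self._fragments()
        assert profile_fragments(frags, seed=7) == profile_fragments(frags, seed=7)

    def test_missing_reference_rejected(self):
        with pytest.raises(ValueError):
            profile_fragments(self._fragments(), refs=(REF1,), seed=0)
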