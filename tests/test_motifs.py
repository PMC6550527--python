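import itertools
import math

import numpy as np
import pytest

from mesoimmunity import (
    DiscoveryParams,
    PhageGenome,
    StoperatorSite,
    build_pwm,
    classify_orientation,
    discover_stoperators,
    motif_distance,
    positional_distribution,
    scan_sites,
)
from mesoimmunity.core_io import GeneRecord
from mesoimmunity.motifs import MotifModel, read_meme, revcomp, write_meme
from mesoimmunity.simulate import CladeSimConfig, simulate_clade


def _random_sites(rng, n, w):
    return ["".join("ACGT"[i] for i in rng.integers(0, 4, w)) for _ in range(n)]


def _pwm_oracle(sites, k, bg):
    """Independent straight-from-the-formula PWM computation."""
    w = len(sites[0])
    P = np.zeros((4, w))
    for j in range(w):
        counts = {b: 0 for b in "ACGT"}
        for s in sites:
            counts[s[j]] += 1
        N = sum(counts.values())
        for bi, b in enumerate("ACGT"):
            P[bi, j] = (counts[b] + k * bg[bi] * math.sqrt(N)) / (
                N + k * math.sqrt(N)
            )
    return P


def _distance_oracle(P1, P2):
    w = P1.shape[1]
    total = 0.0
    for j in range(w):
        ss = sum((P1[b, j] - P2[b, j]) ** 2 for b in range(4))
        total += math.sqrt(ss / 2.0)
    return total / w


class TestBuildPwm:
    def test_single_site_no_pseudocount_is_point_mass(self):
        m = build_pwm(["AAAA"], k=0.0)
        assert np.allclose(m.P[0], 1.0)
        assert np.allclose(m.P[1:], 0.0)

    def test_matches_independent_formula(self, rng):
        sites = _random_sites(rng, 4, 13)
        m = build_pwm(sites, k=0.8)
        expected = _pwm_oracle(sites, 0.8, [0.25] * 4)
        assert np.allclose(m.P, expected, atol=1e-12)
        with np.errstate(divide="ignore"):
            assert np.allclose(m.W, np.log2(expected / 0.25), atol=1e-12)

    def test_core_width_preserved(self, rng):
        m = build_pwm(_random_sites(rng, 8, 13))
        assert m.width == 13
        assert m.P.shape == (4, 13)

    def test_mixed_widths_rejected(self):
        with pytest.raises(ValueError, match="mixed widths"):
            build_pwm(["ACGT", "ACG"])

    def test_columns_sum_to_one_and_ic_bounded(self, rng):
        for _ in range(20):
            counts = rng.integers(0, 40, size=(4, 13)).astype(float)
            counts[:, counts.sum(axis=0) == 0] += 1
            m = MotifModel(counts=counts)
            assert np.allclose(m.P.sum(axis=0), 1.0, atol=1e-9)
            ic = m.information_content()
            assert (ic >= -1e-9).all() and (ic <= 2 + 1e-9).all()


class TestMotifDistance:
    def test_identical_models_zero(self, rng):
        m = build_pwm(_random_sites(rng, 10, 13))
        assert motif_distance(m, m) == 0.0

    def test_disjoint_point_masses_hit_unit_maximum(self):
        a = build_pwm(["A"], k=0.0)
        t = build_pwm(["T"], k=0.0)
        assert motif_distance(a, t) == pytest.approx(1.0)

    def test_matches_independent_formula_and_symmetry(self, rng):
        for _ in range(10):
            m1 = build_pwm(_random_sites(rng, 6, 13))
            m2 = build_pwm(_random_sites(rng, 9, 13))
            d = motif_distance(m1, m2)
            assert d == pytest.approx(_distance_oracle(m1.P, m2.P), abs=1e-12)
            assert d == pytest.approx(motif_distance(m2, m1), abs=1e-12)
            assert 0.0 <= d <= 1.0

    def test_pseudometric_on_random_triples(self, rng):
        models = [build_pwm(_random_sites(rng, 5, 13)) for _ in range(12)]
        triples = list(itertools.combinations(range(12), 3))[:100]
        for i, j, k in triples:
            dij = motif_distance(models[i], models[j])
            djk = motif_distance(models[j], models[k])
            dik = motif_distance(models[i], models[k])
            assert dik <= dij + djk + 1e-12

    def test_unequal_widths_need_offset_mode(self, rng):
        m13 = build_pwm(_random_sites(rng, 5, 13))
        m14 = build_pwm(_random_sites(rng, 5, 14))
        with pytest.raises(ValueError, match="widths differ"):
            motif_distance(m13, m14)
        d = motif_distance(m13, m14, allow_offset=True)
        assert 0.0 <= d <= 1.0

    def test_offset_mode_finds_embedded_submotif(self, rng):
        sites = _random_sites(rng, 8, 13)
        inner = build_pwm([s[1:] for s in sites])  # width 12 slice
        outer = build_pwm(sites)
        assert motif_distance(inner, outer, allow_offset=True) == pytest.approx(
            0.0, abs=1e-12
        )


class TestScanSites:
    CONSENSUS = "TTGACAGCTAGCT"

    def _genome_with_plants(self, rng, positions, strands):
        L = 6000
        seq = list("".join("ACGT"[i] for i in rng.integers(0, 4, L)))
        for p, strand in zip(positions, strands):
            core = self.CONSENSUS if strand == "+" else revcomp(self.CONSENSUS)
            seq[p - 1 : p + 12] = list(core)
        return "".join(seq)

    def test_exact_consensus_threshold_recovers_planted_positions(self, rng):
        positions = [500, 1500, 2500, 3500, 4500]
        strands = ["+", "-", "+", "-", "+"]
        seq = self._genome_with_plants(rng, positions, strands)
        model = build_pwm([self.CONSENSUS] * 4, k=0.8)
        thr = model.score(self.CONSENSUS) - 1e-9
        sites = scan_sites(seq, model, thr, genome_id="g")
        assert [(s.start, s.strand) for s in sites] == list(zip(positions, strands))
        for s in sites:
            assert s.sequence == self.CONSENSUS

    def test_infinite_threshold_returns_nothing(self, rng):
        seq = self._genome_with_plants(rng, [500], ["+"])
        model = build_pwm([self.CONSENSUS] * 4)
        assert scan_sites(seq, model, float("inf")) == []

    def test_palindromic_site_reported_once_on_plus(self):
        pal = "ACGCGT"  # reverse complement of itself
        seq = "T" * 50 + pal + "T" * 50
        model = build_pwm([pal] * 3, k=0.8)
        thr = model.score(pal) - 1e-9
        sites = scan_sites(seq, model, thr)
        assert len(sites) == 1
        assert sites[0].strand == "+"

    def test_width_longer_than_genome_errors(self):
        model = build_pwm(["ACGTACGTACGTA"])
        with pytest.raises(ValueError, match="exceeds genome length"):
            scan_sites("ACGT", model, 0.0)


class TestOrientation:
    def _site(self, start, strand):
        return StoperatorSite("g", start, start + 12, strand, "A" * 13, 0.0)

    @pytest.mark.parametrize(
        "start,strand,expected",
        [
            (9994, "+", "syn"),   # midpoint 10000, left of center
            (39994, "-", "syn"),  # midpoint 40000, right of center
            (39994, "+", "anti"),
            (9994, "-", "anti"),
        ],
    )
    def test_syn_rule(self, start, strand, expected):
        assert classify_orientation(self._site(start, strand), 25000) == expected

    def test_midpoint_on_center_ties_by_strand(self):
        with pytest.warns(UserWarning, match="center"):
            assert classify_orientation(self._site(24994, "+"), 25000) == "syn"
        with pytest.warns(UserWarning, match="center"):
            assert classify_orientation(self._site(24994, "-"), 25000) == "anti"


class TestPositionalDistribution:
    def test_no_sites_gives_empty_histogram(self):
        assert positional_distribution({"g": []}, {"g": 1000}) == {}

    def test_known_offsets_land_in_expected_bins(self):
        sites = [
            StoperatorSite("g", 880, 892, "+", "A" * 13, 0.0),   # end 892, off -108
            StoperatorSite("g", 995, 1007, "+", "A" * 13, 0.0),  # end 1007, off +7
            StoperatorSite("g", 1190, 1202, "-", "A" * 13, 0.0), # end 1202, off +202
        ]
        hist = positional_distribution({"g": sites}, {"g": 1000}, bin_width=100)
        assert hist == {-200: 1, 0: 1, 200: 1}

    def test_rep_3prime_anchor_is_strand_aware(self):
        genome = PhageGenome(
            id="g",
            sequence="A" * 5000,
            genes=[GeneRecord("rep", 3000, 3551, "-", "p", "rep")],
        )
        # bottom-strand gene: 3' end is the interval start
        site = StoperatorSite("g", 2988, 3000, "-", "A" * 13, 0.0)
        hist = positional_distribution(
            {"g": [site]}, "rep_3prime", genomes={"g": genome}, bin_width=50
        )
        assert hist == {0: 1}

    def test_unresolvable_anchor_skips_genome(self):
        site = StoperatorSite("g", 100, 112, "+", "A" * 13, 0.0)
        with pytest.warns(UserWarning, match="unresolvable"):
            hist = positional_distribution({"g": [site]}, {"other": 5})
        assert hist == {}


@pytest.fixture(scope="module")
def planted():
    clade = simulate_clade(
        CladeSimConfig(n_phages=4, genome_length=50_000), seed=42
    )
    taxon = "T01"
    return clade.genomes[taxon], clade.planted_sites[taxon], clade.true_motif(taxon)


@pytest.fixture(scope="module")
def discovered(planted):
    genome, _, true_model = planted
    return discover_stoperators(genome, reference_motif=true_model)


class TestDiscovery:

    def test_planted_motif_recovered(self, planted, discovered):
        genome, sites, true_model = planted
        res = discovered
        assert res.found
        recovered = sum(
            1
            for p in sites
            if any(
                min(p.end, s.end) - max(p.start, s.start) + 1 >= p.width // 2
                for s in res.sites
            )
        )
        assert recovered / len(sites) >= 0.8
        assert motif_distance(res.model, true_model, allow_offset=True) < 0.1

    def test_site_count_in_biological_range(self, discovered):
        res = discovered
        assert 10 <= len(res.sites) <= 50

    def test_rescan_at_discovery_threshold_is_superset(self, planted, discovered):
        genome, _, _ = planted
        res = discovered
        rescanned = scan_sites(genome, res.model, res.threshold)
        found = {(s.start, s.end, s.strand) for s in res.sites}
        again = {(s.start, s.end, s.strand) for s in rescanned}
        assert found <= again

    def test_random_sequence_yields_not_found(self):
        rng = np.random.default_rng(7)
        seq = "".join("ACGT"[i] for i in rng.integers(0, 4, 50_000))
        res = discover_stoperators(seq, genome_id="null")
        assert not res.found
        assert res.sites == []

    def test_syn_fraction_high_in_both_arms(self, planted):
        # genomes are planted with the transcription-orientation rule:
        # re-deriving each planted site's orientation from its strand and
        # the genome center must give a high syn fraction in both arms
        genome, sites, _ = planted
        center = genome.center_marker().midpoint
        for arm in ("left", "right"):
            arm_sites = [
                s for s in sites if (s.midpoint < center) == (arm == "left")
            ]
            assert len(arm_sites) >= 5
            syn = sum(
                1 for s in arm_sites if classify_orientation(s, center) == "syn"
            )
            assert syn / len(arm_sites) >= 0.9

    def test_short_genome_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            discover_stoperators("ACGT" * 10, genome_id="tiny")


class TestMemeFormat:
    def test_round_trip(self, tmp_path, rng):
        models = [
            build_pwm(_random_sites(rng, 7, 13), name="m1"),
            build_pwm(_random_sites(rng, 5, 14), name="m2"),
        ]
        path = tmp_path / "motifs.meme"
        write_meme(models, path)
        back = read_meme(path)
        assert len(back) == 2
        for orig, rec in zip(models, back):
            assert rec.width == orig.width
            assert np.allclose(rec.P, orig.P, atol=1e-5)
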