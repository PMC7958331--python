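"""Hybridization DP vs exhaustive enumeration, site selection, and significance."""

import itertools
import math
from collections import Counter

import numpy as np
import pytest

from regscan.mre import (
    EnergyModel,
    EvdCalibration,
    HybridizationSite,
    MatureMiR,
    best_duplex_mfe,
    calibrate_evd,
    dinucleotide_shuffle,
    feature_counts,
    hybridize,
    map_to_features,
    multi_site_pvalue,
    normalized_score,
    scan_transcript,
    seed_sites,
    site_pvalue,
)
from regscan.seqcore import (
    FeatureAnnotation,
    GenomicInterval,
    NucleotideSequence,
    reverse_complement,
)

from conftest import random_rna


def enumerate_mfe(mir_seq, win_seq, model):
    """Exhaustive minimum over all legal duplex structures.

    A structure is any set of pairs with miR indices strictly increasing
    and target indices strictly decreasing (antiparallel, non-crossing,
    intermolecular only), every pair being GC/AU/GU, scored with the
    model's pair energies and loop penalties.  Feasible for m<=8, n<=12.
    """
    m, n = len(mir_seq), len(win_seq)
    best = 0.0
    for k in range(1, min(m, n) + 1):
        for mi in itertools.combinations(range(m), k):
            for ti in itertools.combinations(range(n), k):
                tj = tuple(reversed(ti))  # target indices descending
                e = 0.0
                ok = True
                for a, b in zip(mi, tj):
                    pe = model.pair_energy(mir_seq[a], win_seq[b])
                    if math.isinf(pe):
                        ok = False
                        break
                    e += pe
                if not ok:
                    continue
                for (a0, b0), (a1, b1) in zip(zip(mi, tj), zip(mi[1:], tj[1:])):
                    pen = model.loop_penalty(a1 - a0 - 1, b0 - b1 - 1)
                    if math.isinf(pen):
                        ok = False
                        break
                    e += pen
                if ok and e < best:
                    best = e
    return best


class TestHybridize:
    def test_poly_a_vs_poly_u_closed_form(self):
        model = EnergyModel()
        mfe, structure = hybridize(MatureMiR("m", "AAAAAAA"),
                                   NucleotideSequence("w", "UUUUUUU", "RNA"), model)
        assert mfe == pytest.approx(7 * model.au)
        assert len(structure) == 7

    def test_unpairable_input_gives_zero(self):
        mfe, structure = hybridize(MatureMiR("m", "AAAAAA"),
                                   NucleotideSequence("w", "AAAA", "RNA"))
        assert (mfe, structure) == (0.0, ())

    def test_structure_is_antiparallel_noncrossing(self, rng):
        mir = MatureMiR("m", random_rna(rng, 15))
        win = NucleotideSequence("w", random_rna(rng, 40), "RNA")
        _, structure = hybridize(mir, win)
        mir_idx = [a for a, _ in structure]
        tar_idx = [b for _, b in structure]
        assert mir_idx == sorted(mir_idx)
        assert tar_idx == sorted(tar_idx, reverse=True)
        assert len(set(mir_idx)) == len(mir_idx) and len(set(tar_idx)) == len(tar_idx)

    def test_dp_equals_exhaustive_enumeration(self, rng):
        model = EnergyModel()
        for _ in range(12):
            mir_seq = random_rna(rng, int(rng.integers(6, 9)))
            win_seq = random_rna(rng, int(rng.integers(8, 13)))
            mfe, _ = hybridize(MatureMiR("m", mir_seq),
                               NucleotideSequence("w", win_seq, "RNA"), model)
            assert mfe == pytest.approx(enumerate_mfe(mir_seq, win_seq, model))

    def test_mfe_monotone_in_pair_energies(self, rng):
        mir = MatureMiR("m", random_rna(rng, 12))
        win = NucleotideSequence("w", random_rna(rng, 30), "RNA")
        weak = EnergyModel(gc=-2.0, au=-1.5, gu=-0.5)
        strong = EnergyModel(gc=-4.0, au=-3.0, gu=-1.5)
        assert hybridize(mir, win, strong)[0] <= hybridize(mir, win, weak)[0]


class TestSeedSites:
    def test_perfect_7mer_by_construction(self):
        mir = MatureMiR("m", "AGAGGUAGAAAAAAAAAAAAA")  # seed (2-8) = GAGGUAG
        target = NucleotideSequence("t", "GGGG" + "CUACCUC" + "GGGG", "RNA")
        assert seed_sites(mir, target) == [5]

    def test_poly_a_pair_is_empty(self):
        assert seed_sites(MatureMiR("m", "A" * 10),
                          NucleotideSequence("t", "A" * 50, "RNA")) == []

    def test_matches_brute_force_complement_scan(self, rng):
        mir = MatureMiR("m", random_rna(rng, 21))
        target = NucleotideSequence("t", random_rna(rng, 800), "RNA")
        seed = mir.sequence[1:8]
        comp = {"A": "U", "C": "G", "G": "C", "U": "A"}
        rc_seed = "".join(comp[b] for b in reversed(seed))
        expect = [i + 1 for i in range(len(target.residues) - 6)
                  if target.residues[i : i + 7] == rc_seed]
        assert seed_sites(mir, target) == expect


class TestScanTranscript:
    def _transcript_with_plants(self, rng, mir, gap=60):
        site = reverse_complement(
            NucleotideSequence("x", mir.sequence, "RNA")
        ).residues
        a = random_rna(rng, 200)
        b = random_rna(rng, gap)
        c = random_rna(rng, 200)
        tx = a + site + b + site + c
        return NucleotideSequence("tx", tx, "RNA"), 201, 201 + len(site) + gap

    def test_two_planted_sites_found_at_truth(self, rng):
        mir = MatureMiR("m", random_rna(rng, 22))
        tx, p1, p2 = self._transcript_with_plants(rng, mir)
        sites = scan_transcript(mir, tx, max_sites=10)
        starts = [s.leftmost for s in sites[:2]]
        assert sorted(starts)[:2] == [p1, p2]

    def test_max_sites_one_keeps_lower_mfe(self, rng):
        mir = MatureMiR("m", random_rna(rng, 22))
        tx, *_ = self._transcript_with_plants(rng, mir)
        all_sites = scan_transcript(mir, tx, max_sites=10)
        (single,) = scan_transcript(mir, tx, max_sites=1)
        assert single.mfe == min(s.mfe for s in all_sites)

    def test_no_padding_beyond_real_sites(self, rng):
        mir = MatureMiR("m", "ACGUACGUACGUACGUACGUA")
        site = reverse_complement(NucleotideSequence("x", mir.sequence, "RNA")).residues
        tx = NucleotideSequence("tx", "A" * 150 + site + "A" * 150, "RNA")
        sites = scan_transcript(mir, tx, max_sites=5, energy_cutoff=-30.0)
        assert len(sites) == 1

    def test_selected_sites_disjoint_and_second_best_stable(self, rng):
        mir = MatureMiR("m", random_rna(rng, 20))
        tx = NucleotideSequence("tx", random_rna(rng, 600), "RNA")
        sites = scan_transcript(mir, tx, max_sites=8, exhaustive=True)
        for a, b in itertools.combinations(sites, 2):
            assert not a.target_interval.overlaps(b.target_interval)
        if len(sites) >= 2:
            by_mfe = sorted(sites, key=lambda s: s.mfe)
            best, second = by_mfe[0], by_mfe[1]
            masked = (
                tx.residues[: best.target_interval.start - 1]
                + "A" * len(best.target_interval)
                + tx.residues[best.target_interval.end :]
            )
            rescanned = scan_transcript(
                mir, NucleotideSequence("tx", masked, "RNA"), max_sites=1, exhaustive=True
            )
            assert rescanned and rescanned[0].mfe == pytest.approx(second.mfe, abs=1.5)

    def test_planted_site_rank_one_across_seeds(self):
        # reverse-complement plant into a random 2-kb transcript, 20 seeds
        for seed in range(20):
            rng = np.random.default_rng(1000 + seed)
            mir = MatureMiR("m", random_rna(rng, 22))
            site = reverse_complement(
                NucleotideSequence("x", mir.sequence, "RNA")
            ).residues
            pos = int(rng.integers(0, 2000 - len(site)))
            tx = random_rna(rng, 2000)
            tx = tx[:pos] + site + tx[pos + len(site) :]
            best = scan_transcript(mir, NucleotideSequence("tx", tx, "RNA"), max_sites=1)
            assert best and best[0].leftmost == pos + 1, f"seed {seed}"


class TestShuffleAndEvd:
    def test_shuffle_preserves_dinucleotide_counts(self, rng):
        s = random_rna(rng, 300)
        t = dinucleotide_shuffle(s, rng)
        assert Counter(zip(t, t[1:])) == Counter(zip(s, s[1:]))
        assert t[0] == s[0] and t[-1] == s[-1]

    def test_calibration_deterministic_and_positive_scale(self, rng):
        mir = MatureMiR("m", random_rna(rng, 22))
        bg = NucleotideSequence("bg", random_rna(rng, 300), "RNA")
        a = calibrate_evd(mir, bg, shuffle_count=100, rng_seed=5)
        b = calibrate_evd(mir, bg, shuffle_count=100, rng_seed=5)
        assert a == b and a.scale > 0

    def test_degenerate_background_rejected(self):
        mir = MatureMiR("m", "ACGUACGUACGUACGUA")
        with pytest.raises(ValueError):
            calibrate_evd(mir, NucleotideSequence("bg", "A" * 200, "RNA"),
                          shuffle_count=100, rng_seed=0)

    def test_pvalue_range_and_monotonicity(self):
        cal = EvdCalibration(location=3.0, scale=0.2)
        m, n = 22, 400
        weak = HybridizationSite("m", "t", GenomicInterval("t", 10, 30), -5.0, ((1, 30),))
        strong = HybridizationSite("m", "t", GenomicInterval("t", 50, 70), -40.0, ((1, 70),))
        p_weak = site_pvalue(weak, cal, m, n)
        p_strong = site_pvalue(strong, cal, m, n)
        assert 0.0 <= p_strong < p_weak <= 1.0
        # mfe -> 0 gives x minimal and p near 1
        assert site_pvalue(normalized_score(0.0, m, n), cal) > 0.99


class TestMultiSitePoisson:
    def test_closed_forms(self):
        lam = 0.7
        assert multi_site_pvalue(1, lam) == pytest.approx(1 - math.exp(-lam))
        assert multi_site_pvalue(0, lam) == 1.0

    def test_matches_summed_mass(self):
        lam = 2.5
        for k in range(21):
            tail = 1.0 - sum(math.exp(-lam) * lam**j / math.factorial(j) for j in range(k))
            assert multi_site_pvalue(k, lam) == pytest.approx(tail, abs=1e-12)


class TestFeatureMapping:
    ann = FeatureAnnotation(
        "tx",
        [
            ("5'UTR", GenomicInterval("tx", 1, 26)),
            ("CDS", GenomicInterval("tx", 27, 707)),
            ("3'UTR", GenomicInterval("tx", 708, 1200)),
        ],
    )

    def _site(self, leftmost):
        return HybridizationSite(
            "m", "tx", GenomicInterval("tx", leftmost, leftmost + 18), -20.0, ((1, leftmost),)
        )

    def test_leftmost_position_selects_feature(self):
        (s,) = map_to_features([self._site(908)], self.ann)
        assert s.feature_label == "3'UTR"
        (s,) = map_to_features([self._site(1)], self.ann)
        assert s.feature_label == "5'UTR"

    def test_counts_conserve_sites(self):
        sites = [self._site(p) for p in (1, 30, 100, 800, 900)]
        labeled = map_to_features(sites, self.ann)
        counts = feature_counts(labeled)
        assert sum(counts.values()) == 5
        assert counts == {"5'UTR": 1, "CDS": 2, "3'UTR": 2}

    def test_position_outside_annotation_is_unannotated(self):
        (s,) = map_to_features([self._site(1500)], self.ann)
        assert s.feature_label == "unannotated"
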