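"""B-box pentamer scanning and branch-point positional analyses."""

from __future__ import annotations

import math

import numpy as np
import pytest

from conftest import make_bp_site, make_site
from repag import branchpoint as bp


def naive_bbox_hits(tail: str) -> list[tuple[str, int]]:
    """Oracle: check every 5-mer of the intron tail (last base = -1)."""
    L = len(tail)
    out = []
    for i in range(L - 4):
        pos = i - L
        if tail[i : i + 5] in bp.BBOX_MOTIFS and pos >= -100:
            out.append((tail[i : i + 5], pos))
    return out


class TestScan:
    def test_planted_motif_position_by_construction(self):
        tail = "CTGAC" + "T" * 12 + "CAG"
        site = make_site(tail)
        [hit] = bp.scan_bboxes(site)
        assert (hit.motif, hit.start) == ("CTGAC", -20)
        assert hit.bp_a_position == -17

    def test_no_motif_empty(self):
        assert bp.scan_bboxes(make_site("T" * 18 + "AG")) == []

    def test_overlapping_ctaactaac_two_hits(self):
        # enumerating all 5-mers of CTAACTAAC gives starts at its 1st and 5th
        tail = "CTAACTAAC" + "T" * 9 + "AG"
        site = make_site(tail)
        hits = bp.scan_bboxes(site)
        assert [(h.motif, h.start) for h in hits] == [
            ("CTAAC", -20), ("CTAAC", -16)
        ]

    def test_matches_naive_oracle_on_random_windows(self):
        rng = np.random.default_rng(31)
        for _ in range(1000):
            tail = "".join(rng.choice(list("ACGT"), size=60))
            site = make_site(tail)
            assert [(h.motif, h.start) for h in bp.scan_bboxes(site)] == \
                naive_bbox_hits(tail)

    def test_bp_adenosine_is_structural(self):
        """The credited branch base is 'A' for every hit of every motif."""
        rng = np.random.default_rng(32)
        checked = 0
        for _ in range(500):
            tail = "".join(rng.choice(list("ACGT"), size=80))
            site = make_site(tail)
            for hit in bp.scan_bboxes(site):
                assert site.base(hit.bp_a_position) == "A"
                checked += 1
        assert checked > 50

    def test_unknown_motif_rejected(self):
        with pytest.raises(ValueError):
            bp.BBoxHit(("c", "+", 1), "CTAAA", -50)


class TestPositionalDistribution:
    def test_shared_position_gives_unit_spike(self):
        sites = [make_bp_site([-23], key=("c", "+", i)) for i in range(4)]
        dist = bp.positional_distribution(sites)
        frac = dist.fractions("all_sites")
        assert frac[dist.positions == -23] == pytest.approx(1.0)
        assert frac.sum() == pytest.approx(1.0)

    def test_no_hit_sites_dilute_all_sites_denominator(self):
        sites = [make_bp_site([-23], key=("c", "+", 1)),
                 make_site("T" * 98 + "AG", key=("c", "+", 2))]
        dist = bp.positional_distribution(sites)
        assert dist.fractions("all_sites").max() == pytest.approx(0.5)
        assert dist.fractions("with_hit").max() == pytest.approx(1.0)

    def test_nearest_hit_selection_takes_lariat_proximal(self):
        site = make_bp_site([-80, -20])
        dist = bp.positional_distribution([site], selection="nearest")
        assert dist.window_count((-24, -4)) == 1
        assert dist.window_count((-97, -25)) == 0
        both = bp.positional_distribution([site], selection="all")
        assert both.counts.sum() == 2

    def test_generator_seeded_peak_recovered(self, sim_genome, sim_bundle):
        """Distal-only planting in G-tract acceptors puts the argmax distal."""
        dist = bp.positional_distribution(sim_bundle.repag)
        peak = dist.positions[np.argmax(dist.counts)]
        assert -97 <= peak <= -25

    def test_empty_set_rejected(self):
        with pytest.raises(ValueError):
            bp.positional_distribution([])

    def test_permutation_invariance(self):
        sites = [make_bp_site([-23 - i], key=("c", "+", i)) for i in range(6)]
        a = bp.positional_distribution(sites).counts
        b = bp.positional_distribution(sites[::-1]).counts
        assert (a == b).all()


class TestWindowOccupancy:
    def test_exclusion_zone_reproduced_definitionally(self):
        repag = [make_bp_site([-50], key=("c", "+", i)) for i in range(5)]
        control = [make_bp_site([-6], key=("c", "+", 100 + i), motif="CTGAC")
                   for i in range(5)]
        occ = bp.window_occupancy(
            bp.positional_distribution(repag),
            bp.positional_distribution(control),
        )
        assert occ.occupancy("exclusion", "set") == 0.0
        assert occ.occupancy("exclusion", "control") > 0.0

    def test_identical_distributions_not_significant(self):
        sites = [make_bp_site([-50], key=("c", "+", i)) for i in range(5)]
        occ = bp.window_occupancy(
            bp.positional_distribution(sites),
            bp.positional_distribution(sites),
        )
        assert occ.table.loc["distal", "p_enrichment"] > 0.5

    def test_planted_distal_shift_detected(self, sim_bundle):
        occ = sim_bundle.bbox_occupancy
        assert occ.occupancy("distal", "set") > occ.occupancy("distal", "control")
        assert occ.table.loc["distal", "p_enrichment"] < 1e-6
        assert occ.table.loc["proximal", "p_depletion"] < 1e-6


class TestMotifOverrepresentation:
    def test_set_equal_to_background_gives_unit_ratios(self):
        sites = [make_bp_site([-50], motif=m, key=("c", "+", i))
                 for i, m in enumerate(bp.BBOX_MOTIFS)]
        df = bp.motif_overrepresentation(sites, sites)
        present = df[df.background_fraction > 0]
        assert (present.ratio == 1.0).all()

    def test_g_plus_one_ratio_arithmetic(self):
        def site_with_exon(base, i):
            return make_site("T" * 18 + "AG", exon=base + "TT",
                             key=("c", "+", i))

        background = [site_with_exon(b, i)
                      for i, b in enumerate("ACGT" * 5)]  # 25% G at +1
        set_sites = [site_with_exon("G", 100 + i) for i in range(5)]
        df = bp.motif_overrepresentation(set_sites, background)
        assert df.loc["G+1", "ratio"] == pytest.approx(4.0)

    def test_absent_background_feature_unavailable(self):
        background = [make_site("T" * 18 + "AG", key=("c", "+", i))
                      for i in range(5)]
        set_sites = [make_bp_site([-50], key=("c", "+", 100))]
        df = bp.motif_overrepresentation(set_sites, background)
        assert not df.loc["CTGAC", "available"]
        assert math.isnan(df.loc["CTGAC", "ratio"])


class TestBpDistanceVsAltExon:
    @staticmethod
    def _cohort(n_distal, k_distal, n_prox, k_prox):
        out = []
        for i in range(n_distal):
            out.append((make_bp_site([-50], key=("c", "+", i)),
                        i >= k_distal))  # constitutive flag
        for i in range(n_prox):
            out.append((make_bp_site([-20], key=("c", "+", 1000 + i)),
                        i >= k_prox))
        return out

    def test_all_alternative_everywhere_is_null(self):
        df = bp.bp_distance_vs_alt_exon(self._cohort(4, 4, 4, 4))
        assert df.loc["distal", "alt_pct"] == 100.0
        assert df.loc["proximal", "alt_pct"] == 100.0
        assert df.loc["distal", "p_distal_enriched"] == pytest.approx(1.0)

    def test_published_scale_counts_against_frozen_oracle(self):
        # distal 229/260 (88%) vs proximal 25/32 (78%): one-sided
        # hypergeometric enumeration gives p = 0.1011
        df = bp.bp_distance_vs_alt_exon(self._cohort(260, 229, 32, 25))
        assert df.loc["distal", "alt_pct"] == pytest.approx(88.08, abs=0.01)
        assert df.loc["proximal", "alt_pct"] == pytest.approx(78.125)
        assert df.loc["distal", "p_distal_enriched"] == pytest.approx(
            0.10106205885370671, rel=1e-9
        )

    def test_strong_planted_effect_detected(self):
        df = bp.bp_distance_vs_alt_exon(self._cohort(260, 229, 100, 40))
        assert df.loc["distal", "p_distal_enriched"] < 1e-6

    def test_single_group_unavailable(self):
        assert bp.bp_distance_vs_alt_exon(self._cohort(5, 3, 0, 0)) is None
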