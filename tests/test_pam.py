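import random

import pytest

from magecs.pam import (
    ConfigurationError,
    Verdict,
    build_sgrna,
    escaper_scan,
    find_pam_sites,
    is_disabled,
    sites_table,
)
from magecs.seqmodel import EditSpec, GenomeRecord, revcomp

from oracles import brute_pam_sites, brute_protospacer, brute_seed_pam_count


def scan_all(genome):
    return find_pam_sites(genome, (0, len(genome)))


class TestScanner:
    def test_no_gg_or_cc_means_no_sites(self):
        assert scan_all(GenomeRecord("x", "A" * 24)) == []

    def test_single_planted_forward_site(self):
        g = GenomeRecord("x", "T" * 20 + "AGG")
        (site,) = scan_all(g)
        assert (site.pam_start, site.strand) == (20, "+")
        assert site.pam_seq == "AGG"
        assert site.protospacer == "T" * 20
        assert site.seed == "T" * 8

    def test_single_planted_reverse_site(self):
        # reverse PAM CCT at the start, protospacer downstream
        g = GenomeRecord("x", "CCT" + "A" * 20)
        (site,) = scan_all(g)
        assert (site.pam_start, site.strand) == (0, "-")
        assert site.pam_seq == "AGG"
        assert site.protospacer == "T" * 20

    def test_protospacer_running_off_linear_end_is_dropped(self):
        assert scan_all(GenomeRecord("x", "T" * 19 + "AGG")) == []

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_on_random_sequences(self, seed):
        rng = random.Random(seed)
        seq = "".join(rng.choice("ACGT") for _ in range(200))
        got = {(s.pam_start, s.strand) for s in scan_all(GenomeRecord("x", seq))}
        assert got == brute_pam_sites(seq)

    @pytest.mark.parametrize("seed", range(50))
    def test_matches_bruteforce_on_short_sequences(self, seed):
        rng = random.Random(1000 + seed)
        seq = "".join(rng.choice("ACGT") for _ in range(rng.randint(23, 30)))
        got = {(s.pam_start, s.strand) for s in scan_all(GenomeRecord("x", seq))}
        assert got == brute_pam_sites(seq)

    @pytest.mark.parametrize("seed", range(10))
    def test_emitted_anatomy_reproduces_the_genome(self, seed):
        rng = random.Random(7000 + seed)
        seq = "".join(rng.choice("ACGT") for _ in range(300))
        for site in scan_all(GenomeRecord("x", seq)):
            assert site.protospacer == brute_protospacer(seq, site.pam_start, site.strand)
            assert site.protospacer.endswith(site.seed)
            if site.strand == "+":
                assert seq[site.pam_start : site.pam_start + 3] == site.pam_seq
            else:
                assert revcomp(seq[site.pam_start : site.pam_start + 3]) == site.pam_seq

    def test_circular_scan_finds_origin_spanning_site(self):
        # PAM straddles the origin: ...GG | sequence | ...A at the junction
        seq = "G" + "T" * 30 + "AG"  # PAM = A G G wrapping positions 32,0
        lin = {(s.pam_start, s.strand)
               for s in scan_all(GenomeRecord("x", seq))}
        circ = {(s.pam_start, s.strand)
                for s in scan_all(GenomeRecord("x", seq, topology="circular"))}
        assert (31, "+") in circ
        assert (31, "+") not in lin

    def test_window_restricts_pam_position(self):
        g = GenomeRecord("x", "T" * 20 + "AGG" + "T" * 20 + "AGG")
        sites = find_pam_sites(g, (0, 23))
        assert [(s.pam_start, s.strand) for s in sites] == [(20, "+")]

    def test_sorted_by_distance_then_coordinate(self):
        g = GenomeRecord("x", "T" * 20 + "AGG" + "T" * 10 + "AGG" + "T" * 20)
        sites = find_pam_sites(g, (0, len(g)), edit_span=(34, 35))
        dists = [s.distance_to_edit for s in sites]
        assert dists == sorted(dists)
        assert sites[0].pam_start == 33


def make_site(seq, pam_start=None, strand=None):
    sites = find_pam_sites(GenomeRecord("x", seq), (0, len(seq)))
    if pam_start is None:
        return sites[0]
    return next(s for s in sites
                if s.pam_start == pam_start and s.strand == strand)


class TestIsDisabled:
    # layout: 12 filler + 20-nt protospacer (T) + AGG; PAM at [32, 35)
    SEQ = "ACATACATACAT" + "T" * 20 + "AGG" + "ACAT"

    def site(self):
        return make_site(self.SEQ, 32, "+")

    def test_pam_g_edit_disables(self):
        verdict = is_disabled(self.site(), [EditSpec(34, "G", "A")])
        assert verdict == Verdict.DISABLED_BY_PAM

    def test_n_position_edit_never_counts_as_pam_break(self):
        verdict = is_disabled(self.site(), [EditSpec(32, "A", "C")])
        assert verdict == Verdict.STILL_ACTIVE

    def test_seed_edit_disables(self):
        # any of the 8 protospacer positions adjacent to the PAM
        for pos in range(24, 32):
            verdict = is_disabled(self.site(), [EditSpec(pos, "T", "G")])
            assert verdict == Verdict.DISABLED_BY_SEED

    def test_protospacer_edit_outside_seed_is_still_active(self):
        # 15 nt 5' of the PAM: inside the protospacer, outside the 8-nt seed
        verdict = is_disabled(self.site(), [EditSpec(32 - 15, "T", "A")])
        assert verdict == Verdict.STILL_ACTIVE

    def test_reverse_strand_site_seed_geometry(self):
        seq = "ACAT" + "CCT" + "A" * 20 + "ACAT"
        site = make_site(seq, 4, "-")
        # seed lies at [7, 15) in genome coordinates for a reverse site
        assert is_disabled(site, [EditSpec(7, "A", "C")]) == Verdict.DISABLED_BY_SEED
        assert is_disabled(site, [EditSpec(14, "A", "C")]) == Verdict.DISABLED_BY_SEED
        assert is_disabled(site, [EditSpec(15, "A", "C")]) == Verdict.STILL_ACTIVE
        # the G positions of the reverse PAM are the forward C's
        assert is_disabled(site, [EditSpec(4, "C", "T")]) == Verdict.DISABLED_BY_PAM

    def test_monotone_adding_edits_never_reactivates(self):
        site = self.site()
        rng = random.Random(5)
        order = [Verdict.STILL_ACTIVE, Verdict.DISABLED_BY_SEED, Verdict.DISABLED_BY_PAM]
        for _ in range(50):
            positions = rng.sample(range(12, 35), rng.randint(1, 6))
            edits, seen = [], set()
            for p in positions:
                ref = self.SEQ[p]
                alt = rng.choice([b for b in "ACGT" if b != ref])
                edits.append(EditSpec(p, ref, alt))
            prev = order.index(is_disabled(site, edits[:1]))
            for k in range(2, len(edits) + 1):
                cur = order.index(is_disabled(site, edits[:k]))
                assert cur >= prev or cur == order.index(Verdict.DISABLED_BY_PAM)
                prev = max(prev, cur)


class TestSgRNA:
    def test_concatenation_contract(self):
        site = make_site("T" * 20 + "AGG")
        rec = build_sgrna(site, scaffold="GTTTTAGAGCTAGAA")
        assert rec.spacer == "T" * 20
        assert rec.full_sequence == rec.spacer + "GTTTTAGAGCTAGAA"
        assert len(rec.spacer) == 20
        assert "AGG" not in rec.spacer  # PAM never enters the guide

    def test_empty_scaffold_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            build_sgrna(make_site("T" * 20 + "AGG"), scaffold="")


class TestEscaperScan:
    def test_genome_with_only_the_site_scores_zero(self):
        g = GenomeRecord("x", "T" * 20 + "AGG")
        (site,) = scan_all(g)
        assert escaper_scan(g, site) == 0

    def test_planted_duplicate_counts_once(self):
        core = "GATTACAG"  # the site's seed
        g = GenomeRecord("x", "T" * 12 + core + "AGG" + "AT" * 6 + core + "TGG" + "AT")
        site = next(s for s in scan_all(g) if s.strand == "+" and s.pam_start == 20)
        assert site.seed == core
        assert escaper_scan(g, site) == 1

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_bruteforce_substring_count(self, seed):
        rng = random.Random(123 + seed)
        seq = "".join(rng.choice("ACGT") for _ in range(500))
        g = GenomeRecord("x", seq)
        for site in scan_all(g)[:8]:
            assert escaper_scan(g, site) == brute_seed_pam_count(seq, site.seed) - 1


def test_sites_table_columns_and_1based_coordinates():
    g = GenomeRecord("x", "T" * 20 + "AGG")
    tbl = sites_table(scan_all(g), ["still_active"])
    assert list(tbl.columns) == ["id", "strand", "pam_1based", "protospacer",
                                 "seed", "distance_to_edit", "disabled_status"]
    assert tbl.loc[0, "pam_1based"] == 21
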