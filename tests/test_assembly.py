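import random

import pytest

from magecs.assembly import (
    AmbiguousReplichoreWarning,
    NoPamInRegionError,
    WindowClippedError,
    build_crRNA_array,
    build_mage_oligo,
    build_user_pair,
    choose_strand,
    design_selfkill_spacers,
)
from magecs.design import plan_counterselection
from magecs.seqmodel import (
    EditSpec,
    Feature,
    GenomeRecord,
    InputError,
    apply_edits,
    hamming,
    revcomp,
)


def toy_plan(genome, desired, ctx=None, **kw):
    return plan_counterselection(genome, desired, ctx, **kw)[0]


class TestMageOligo:
    def make_genome(self):
        rng = random.Random(42)
        # random flanks around a guaranteed PAM at the edit position so a
        # plan exists; edit at position 100 overlaps the PAM's GG
        seq = "".join(rng.choice("ACGT") for _ in range(99)) + "AGG" \
              + "".join(rng.choice("ACGT") for _ in range(98))
        return GenomeRecord("toy", seq)

    def test_window_centred_on_single_substitution(self):
        genome = self.make_genome()
        ref = genome.seq[100]  # the first G of the planted PAM
        plan = toy_plan(genome, [EditSpec(100, ref, "T")])
        oligo = build_mage_oligo(genome, plan, size=70, strand="+")
        expected = genome.seq[65:135]
        expected = expected[:35] + "T" + expected[36:]
        assert oligo.sequence == expected
        assert len(oligo.sequence) == 70
        assert (oligo.window_start, oligo.window_end) == (65, 135)

    def test_minus_strand_is_reverse_complement(self):
        genome = self.make_genome()
        plan = toy_plan(genome, [EditSpec(100, genome.seq[100], "T")])
        fwd = build_mage_oligo(genome, plan, size=70, strand="+")
        rev = build_mage_oligo(genome, plan, size=70, strand="-")
        assert rev.sequence == revcomp(fwd.sequence)

    def test_oligo_carries_desired_plus_silent_edit(self, fixture_genome):
        genome, truth = fixture_genome
        pos = truth.stop_edit_position
        plan = toy_plan(genome, [EditSpec(pos, "TAC", "TAG")],
                        truth.contexts["geneA"])
        assert plan.counterselection  # TAC>TAG needs the silent companion
        oligo = build_mage_oligo(genome, plan, size=70)
        assert hamming(oligo.sequence, oligo.wildtype_window(genome)) == 2
        assert oligo.n_edited_bases(genome) == 2

    def test_round_trip_edits_reproduce_oligo(self, fixture_genome):
        genome, truth = fixture_genome
        pos = truth.stop_edit_position
        plan = toy_plan(genome, [EditSpec(pos, "TAC", "TAG")],
                        truth.contexts["geneA"])
        for strand in "+-":
            oligo = build_mage_oligo(genome, plan, size=70, strand=strand)
            edited = apply_edits(genome, oligo.applied_edits)
            window = edited[oligo.window_start : oligo.window_end]
            assert oligo.sequence == (window if strand == "+" else revcomp(window))

    def test_too_small_size_rejected(self):
        genome = self.make_genome()
        plan = toy_plan(genome, [EditSpec(100, genome.seq[100], "T")])
        with pytest.raises(InputError):
            build_mage_oligo(genome, plan, size=40)

    def test_window_clipped_near_linear_end(self):
        seq = "T" * 20 + "AGG" + "T" * 10
        genome = GenomeRecord("x", seq)
        plan = toy_plan(genome, [EditSpec(21, "G", "T")], window_size=33)
        with pytest.raises(WindowClippedError):
            build_mage_oligo(genome, plan, size=70)

    def test_circular_genome_wraps_instead_of_clipping(self):
        seq = "T" * 20 + "AGG" + "T" * 40
        genome = GenomeRecord("x", seq, topology="circular")
        plan = toy_plan(genome, [EditSpec(21, "G", "T")])
        oligo = build_mage_oligo(genome, plan, size=60)
        assert len(oligo.sequence) == 60
        assert "T" * 19 + "ATG" in oligo.sequence  # edited PAM in context


class TestChooseStrand:
    def test_replichore_convention(self):
        assert choose_strand(25, ori=0, ter=50, genome_length=100) == "-"
        assert choose_strand(75, ori=0, ter=50, genome_length=100) == "+"

    def test_wrapped_replichore(self):
        assert choose_strand(10, ori=90, ter=40, genome_length=100) == "-"
        assert choose_strand(60, ori=90, ter=40, genome_length=100) == "+"

    def test_boundary_warns_and_defaults_to_replichore_1(self):
        with pytest.warns(AmbiguousReplichoreWarning):
            assert choose_strand(0, ori=0, ter=50, genome_length=100) == "-"
        with pytest.warns(AmbiguousReplichoreWarning):
            assert choose_strand(50, ori=0, ter=50, genome_length=100) == "-"

    def test_convention_is_overridable(self):
        conv = {1: "+", 2: "-"}
        assert choose_strand(25, 0, 50, 100, conv) == "+"


class TestUserPair:
    CORE = "GATTACAGATTACAGATTAC"

    def test_construction_contract(self, toy_config):
        pair = build_user_pair(self.CORE, toy_config["tail_f"], toy_config["tail_r"])
        assert pair.forward == toy_config["tail_f"] + self.CORE
        assert pair.reverse == toy_config["tail_r"] + revcomp(self.CORE)
        assert pair.forward[10:30] == revcomp(pair.reverse[10:30])

    def test_duplex_and_overhang_geometry(self, toy_config):
        pair = build_user_pair(self.CORE, toy_config["tail_f"], toy_config["tail_r"])
        assert pair.duplex_length == 20
        assert pair.overhang_lengths == (10, 10)
        assert pair.anneals()

    @pytest.mark.parametrize("core,tf,tr", [
        ("GATTACA", "A" * 10, "C" * 10),         # core too short
        ("GATTACAGATTACAGATTAC", "A" * 9, "C" * 10),
        ("GATTACAGATTACAGATTAC", "A" * 10, "C" * 11),
    ])
    def test_length_validation(self, core, tf, tr):
        with pytest.raises(InputError):
            build_user_pair(core, tf, tr)


class TestCrRNAArray:
    def spacer(self, seed, n=30):
        rng = random.Random(seed)
        return "".join(rng.choice("ACGT") for _ in range(n))

    def test_single_spacer_layout(self, toy_config):
        r = toy_config["repeat"]
        s = self.spacer(1)
        design = build_crRNA_array([s], r)
        assert design.sequence == r + s + r
        assert len(design.sequence) == 90

    def test_two_spacer_layout(self, toy_config):
        r = toy_config["repeat"]
        s1, s2 = self.spacer(1), self.spacer(2)
        design = build_crRNA_array([s1, s2], r)
        assert design.sequence == r + s1 + r + s2 + r
        assert len(design.sequence) == 150

    def test_blocks_parse_back(self, toy_config):
        r = toy_config["repeat"]
        spacers = [self.spacer(k) for k in range(3)]
        design = build_crRNA_array(spacers, r)
        blocks = design.blocks()
        assert blocks[::2] == [r] * 4
        assert blocks[1::2] == spacers
        assert all(len(b) == 30 for b in blocks)

    def test_empty_or_misshaped_blocks_rejected(self, toy_config):
        with pytest.raises(InputError):
            build_crRNA_array([], toy_config["repeat"])
        with pytest.raises(InputError):
            build_crRNA_array([self.spacer(1, n=29)], toy_config["repeat"])
        with pytest.raises(InputError):
            build_crRNA_array([self.spacer(1)], "ACGT")


class TestSelfKill:
    def make_plasmid(self):
        rng = random.Random(9)
        def block(core):
            return "AT" * 5 + core + "AT" * 5
        # ori region: planted forward NGG with 30 nt of context inside
        ori_core = "".join(rng.choice("AT") for _ in range(30)) + "AGG"
        kan_core = "".join(rng.choice("AT") for _ in range(30)) + "TGG"
        seq = "AT" * 10 + block(ori_core) + "AT" * 10 + block(kan_core) + "AT" * 10
        feats = [
            Feature("ori", 20, 20 + len(block(ori_core))),
            Feature("kanR", 20 + len(block(ori_core)) + 20,
                    20 + len(block(ori_core)) + 20 + len(block(kan_core))),
        ]
        return GenomeRecord("plasmid", seq, topology="circular", features=feats)

    def test_two_region_array(self, toy_config):
        plasmid = self.make_plasmid()
        design = design_selfkill_spacers(plasmid, ["ori", "kanR"],
                                         toy_config["repeat"])
        assert len(design.spacers) == 2
        assert len(design.sequence) == 150
        for spacer, label in zip(design.spacers, ["ori", "kanR"]):
            feat = plasmid.feature(label)
            region = plasmid.seq[feat.start : feat.end]
            # spacer+NGG occurs in the region; the spacer itself stops 1 nt
            # short of the PAM (the PAM never enters the guide)
            idx = region.find(spacer)
            assert idx >= 0
            assert region[idx + 31 : idx + 33] == "GG"

    def test_region_without_pam_raises_naming_it(self, toy_config):
        plasmid = self.make_plasmid()
        plasmid.features.append(Feature("polyA", 0, 20))
        with pytest.raises(NoPamInRegionError, match="polyA"):
            design_selfkill_spacers(plasmid, ["polyA"], toy_config["repeat"])

    def test_spacer_order_follows_region_list(self, toy_config):
        plasmid = self.make_plasmid()
        a = design_selfkill_spacers(plasmid, ["ori", "kanR"], toy_config["repeat"])
        b = design_selfkill_spacers(plasmid, ["kanR", "ori"], toy_config["repeat"])
        assert a.spacers == tuple(reversed(b.spacers))
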