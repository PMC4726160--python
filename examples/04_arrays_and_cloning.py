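"""Multiplex pre-crRNA arrays and the self-curing array.

A pre-crRNA array interleaves 30-nt targets with 30-nt repeats
(repeat-target-repeat-target-...-repeat); processed with the tracrRNA it
yields one mature guide per target, so several loci can be counter-selected
at once.  The same layout, aimed at a plasmid's own origin and antibiotic
marker, makes the guide vector destroy itself on induction so strains can
be recycled for the next engineering round.
"""

from magecs import GenomeRecord, build_crRNA_array, design_selfkill_spacers
from magecs.fixtures import fixture_config
from magecs.seqmodel import Feature

cfg = fixture_config(seed=1)

spacer1 = "ATTTATTAAATATTTAATTTAATTTATTAG"  # 30-nt targets (toy)
spacer2 = "TATTTAAATTATTTAATTAATTATTTATTG"
array = build_crRNA_array([spacer1, spacer2], cfg["repeat"])
print(f"multiplex array ({len(array.spacers)} targets, {len(array.sequence)} nt):")
print(" -".join(f"{'R' if k % 2 == 0 else 'S'}" for k in range(len(array.blocks()))),
      "(R = 30-nt repeat, S = 30-nt target)")
print(array.sequence)

plasmid = GenomeRecord(
    "toy_vector",
    "AT" * 20 + "ATATAT" * 6 + "AGG" + "AT" * 20 + "TATATA" * 6 + "TGG" + "AT" * 12,
    topology="circular",
    features=[Feature("ori", 40, 79), Feature("kanR", 119, 158)],
)
selfkill = design_selfkill_spacers(plasmid, ["ori", "kanR"], cfg["repeat"])
print(f"\nself-curing array against ori + kanR ({len(selfkill.sequence)} nt):")
for label, spacer in zip(["ori", "kanR"], selfkill.spacers):
    print(f"  {label:5s} spacer: {spacer}")
print("\nEach spacer is the 30 nt immediately 5' of an NGG inside its")
print("region; the PAM itself never enters the guide.")
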