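"""One-shot design: from an edit request to orderable reagent sequences.

Runs the whole pipeline — plan the counter-selection, assemble the 70-nt
ssDNA MAGE oligo carrying the desired plus silent edit, program the sgRNA
spacer, and build the USER cloning pair that swaps that spacer into the
guide plasmid.  Scaffold/tail sequences are construct-specific; here the
fixture supplies synthetic placeholders.
"""

from magecs import DesignConfig, DesignRequest, make_fixture, run_design
from magecs.fixtures import fixture_config
from magecs.seqmodel import hamming

genome, truth = make_fixture(seed=1)
ctx = truth.contexts["geneA"]
pos = truth.stop_edit_position

request = DesignRequest(
    genome=genome,
    edit=f"{pos + 1}:TAC>TAG",
    frame=f"{ctx.cds_start + 1}..{ctx.cds_end}:+",
    config=DesignConfig(**fixture_config(seed=1)),
    name="stop_knockout",
)
bundle = run_design(request)

oligo = bundle.oligos[0]
print("top-ranked design")
print(f"  PAM          : {bundle.top.site.pam_start + 1} ({bundle.top.site.strand})")
print(f"  silent break : {bundle.top.counterselection[0].describe()}")
print(f"  sgRNA spacer : {bundle.sgrnas[0].spacer}")
print(f"  MAGE oligo   : {oligo.sequence}")
print(f"  oligo length : {len(oligo.sequence)} nt, "
      f"{hamming(oligo.sequence, oligo.wildtype_window(genome))} edited bases")
print(f"  USER forward : {bundle.user_pairs[0].forward}")
print(f"  USER reverse : {bundle.user_pairs[0].reverse}")
print("\nThe oligo differs from wild type at exactly two bases: the stop")
print("codon itself and the synonymous PAM-destroying companion.")
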