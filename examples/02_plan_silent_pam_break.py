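"""Plan counter-selection for an edit that is not linked to any PAM.

The desired edit introduces a premature stop codon (TAC>TAG).  It touches
no PAM or seed, so on its own the edited chromosome would still be cut by
Cas9 along with the wild type.  The planner therefore enumerates synonymous
codon substitutions in the codon(s) covering a nearby PAM and keeps exactly
those that destroy the GG dinucleotide — here the threonine wobble edit
ACC>ACA, which leaves the protein untouched while abolishing the
reverse-strand PAM used for negative selection.
"""

from magecs import EditSpec, make_fixture, plan_counterselection
from magecs.design import plan_table

genome, truth = make_fixture(seed=1)
ctx = truth.contexts["geneA"]
pos = truth.stop_edit_position

print(f"desired edit: {pos + 1}:TAC>TAG (premature stop in geneA)\n")
plans = plan_counterselection(genome, [EditSpec(pos, "TAC", "TAG")], ctx)
print(plan_table(plans).to_string(index=False))

top = plans[0]
print(f"\ntop plan: PAM at {top.site.pam_start + 1} ({top.site.strand}) "
      f"broken by {top.counterselection[0].describe()}")
print("verdict:", top.verdict)
print("\nThe silent_edit column lists only substitutions verified to break")
print("the PAM; synonyms that keep the PAM intact appear under warnings.")
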