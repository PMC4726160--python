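"""Scan for candidate Cas9 target sites near a position of interest.

Builds a small deterministic genome, scans a 70-nt window (the region a
recombineering oligo can cover) around a chosen edit position, and prints
every NGG PAM found on either strand with its 20-nt protospacer and 8-nt
seed.  The distance column is what the planner ranks on: the closer the
PAM to the edit, the easier it is to carry both changes in one oligo.
"""

from magecs import make_fixture, find_pam_sites
from magecs.pam import sites_table

genome, truth = make_fixture(seed=1)
edit_pos = truth.stop_edit_position  # 0-based position of a TAC codon

window = (edit_pos - 35, edit_pos + 35)
sites = find_pam_sites(genome, window, edit_span=(edit_pos, edit_pos + 1))

print(f"genome: {genome.id} ({len(genome)} nt)")
print(f"scanning a 70-nt window around position {edit_pos + 1} (1-based)\n")
print(sites_table(sites).to_string(index=False))
print("\nEach row is one NGG PAM; the protospacer is the 20 nt the guide")
print("will match, and the seed is the 8 PAM-proximal nt where a single")
print("mismatch already abolishes cutting.")
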