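# magecs

Design toolkit for CRISPR/Cas9 counter-selected ssDNA recombineering
(MAGE) in *E. coli*-style hosts.

## The problem

λ-Red ssDNA oligo recombineering edits a genome by annealing a short
synthetic oligo at the replication fork, but only a few percent of cells
incorporate the edit, so every experiment ends in PCR screening.  Coupling
recombineering to Cas9 counter-selection fixes this: a guide RNA is aimed
at the *wild-type* locus, so cells that failed to recombine are cut and
killed, and the edited population takes over.  That only works if the
recombineering oligo also removes the guide's target from the edited
chromosome — by destroying the NGG PAM or mutating its seed region.  When
the desired edit does not touch any PAM ("PAM-independent" loci), a
*synonymous* codon substitution must be found that breaks a nearby PAM
without changing the protein.

`magecs` automates that co-design.  Given a wild-type sequence and a
substitution request it produces:

* the ranked list of candidate NGG PAM sites near the edit (both strands),
  with the 20-nt protospacer (`20N-NGG`) and the 8-nt PAM-proximal seed;
* the silent, machine-verified PAM-destroying codon edits
  (e.g. `ACC>ACA`, Thr→Thr) when the desired edit alone does not disable
  the site — synonyms that *fail* to break the PAM are reported as
  warnings, never emitted as valid designs;
* the ssDNA MAGE oligo (default 70 nt) carrying the desired edit plus the
  silent companion, optionally reverse-complemented for lagging-strand
  targeting via a configurable replichore convention;
* the sgRNA spacer, the USER plug-and-play cloning pair (20-nt variable
  core, two 10-nt 5′ overhangs), multiplex pre-crRNA arrays
  (30-nt repeat / 30-nt target alternation), and self-curing arrays that
  aim a vector's guides at its own origin and resistance marker.

The disabling rule at the core of the package: Cas9 loses the target when
the two G positions of the NGG PAM no longer read `GG` (a change at the N
position never counts), or when at least one edited base falls in the
8-nt seed adjacent to the PAM.  Every emitted plan is checked against this
rule programmatically.

## Worked example

A premature stop codon (`TAC>TAG`) is wanted at a locus with no PAM of its
own.  On the bundled deterministic toy genome:

```python
from magecs import EditSpec, make_fixture, plan_counterselection
from magecs.design import plan_table

genome, truth = make_fixture(seed=1)
pos = truth.stop_edit_position
plans = plan_counterselection(genome, [EditSpec(pos, "TAC", "TAG")],
                              truth.contexts["geneA"])
print(plan_table(plans).head(3).to_string(index=False))
```

prints

```
 rank     desired  pam_1based pam_strand          protospacer     silent_edit         verdict
    1 159:TAC>TAG         166          - TATATTTTAAATAAAAATAT codon24:ACC>ACA disabled_by_pam
    2 159:TAC>TAG         166          - TATATTTTAAATAAAAATAT codon24:ACC>ACG disabled_by_pam
    3 159:TAC>TAG         166          - TATATTTTAAATAAAAATAT codon24:ACC>ACT disabled_by_pam
```

The nearest usable PAM sits on the reverse strand 6 nt from the edit; it
is covered by a threonine codon, and all three wobble substitutions
(`ACC>ACA/ACG/ACT`) destroy its GG while encoding the same amino acid.
Running the full pipeline (`examples/03_design_oligo_bundle.py`) emits the
70-nt MAGE oligo, which differs from wild type at exactly two bases — the
stop codon and the silent PAM break:

```
MAGE oligo   : GATATTTTATTTTTATGGATAATATTAATTTAGATAACAAATATTTTTATTTAAAATATATAATTAAATA
oligo length : 70 nt, 2 edited bases
```

The `examples/` directory holds one short script per capability (PAM
scanning, silent-break planning, the one-shot bundle, arrays and cloning
oligos).  The same operations are available from the shell via the
`magecs` command (`scan`, `plan`, `oligo`, `array`, `userpair`,
`selfkill`, `fixture`).

Reagent sequences that are construct-specific — the sgRNA scaffold, the
array repeat, the USER tails — are **required configuration** with no
built-in defaults; see `magecs.config.DesignConfig` and
`docs/methods.md`.

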