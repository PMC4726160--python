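# Methods

## Model of Cas9 counter-selection

The package targets the *S. pyogenes* type II system: Cas9 cuts where a
20-nt protospacer is followed 3′ by an NGG PAM on the targeted strand, and
the guide can be delivered either as an sgRNA (20-nt spacer + scaffold) or
as a pre-crRNA array (30-nt targets interleaved with 30-nt repeats,
matured by the tracrRNA).  The PAM is never part of the guide sequence.

Counter-selection succeeds when the recombineering oligo removes the
guide's target from the edited chromosome.  The disabling rule implemented
in `magecs.pam.is_disabled` is:

* `disabled_by_pam` — after the edits, the two G positions of the PAM no
  longer read `GG`.  A change confined to the N position never counts.
* `disabled_by_seed` — the PAM survives but at least one *changed* base
  falls in the seed, defined as the 8 protospacer nucleotides immediately
  adjacent to the PAM.  This mirrors the escaper route: a single point
  mutation in PAM or seed confers resistance to cutting, which is exactly
  what the designed oligo must exploit (and what spontaneous escapers
  exploit — hence `escaper_scan`, an exact-match census of the site's
  seed+NGG elsewhere in the genome).
* `still_active` otherwise.  Mismatches PAM-distal of the seed are treated
  as tolerated; no quantitative mismatch-activity model is attempted.

Only NGG is a PAM.  NAG is neither accepted as a target nor modelled as
residual activity; a silent edit that turns NGG into NAG raises
`NagConversionWarning` so the user can judge that risk themselves.

The rule is a pure function of the site anatomy and the edits' changed
positions, which makes it monotone (edits can only be added, and refs are
validated against wild type, so no edit can restore a destroyed G).  The
planner machine-checks `is_disabled != still_active` on every plan it
returns.

## Silent PAM disruption ("degenerate codons")

When the desired edit does not itself disable any nearby site, the planner
determines which codon(s) of the supplied reading frame cover the PAM —
one codon when the PAM is in frame, two when it straddles a boundary — and
enumerates synonymous replacements of each covering codon independently.
Design choices here:

* **The PAM must lie wholly inside the CDS** for silent planning; a PAM
  sticking even one base out of frame raises `NotInFrameError` and the
  caller falls back to non-coding planning.  Silent edits outside the
  frame cannot be guaranteed silent.
* **Verified, not advisory.** Only substitutions whose induced genomic
  edits yield `disabled_by_pam` are emitted as valid; synonymous options
  that keep the PAM intact, codons with no synonym (Met/Trp:
  `NoSilentOption`), and clashes with the desired edit are reported as
  warnings.  Leaving PAM-destruction verification to the user is the
  error-prone step this tool exists to remove.
* **Single-codon edits only.** When two codons cover the PAM each is
  varied on its own; combined two-codon substitutions are not enumerated,
  keeping divergence from wild type minimal.
* A silent edit that destroys the chosen PAM but creates a new NGG in the
  immediate neighbourhood triggers `NewPamCreated` (a warning, not a
  rejection — the new site's protospacer differs from the guide's spacer).

## Candidate ranking

Sites are scanned on both strands within a window (default 70 nt, the
MAGE-oligo coverage) centred on the desired edit span; the 3-nt PAM must
lie inside the window (the disrupting edit has to ride in the oligo), the
20-nt protospacer only inside the genome.  Plans are ordered by a
deterministic tie-break: distance to the edit, then fewest silent changed
bases, then coordinate, then + strand.  This ordering is a documented
convention chosen for reproducibility, not a claim about relative guide
activity — no on-target scoring is attempted.

## Reagent geometry

* **MAGE oligo** — default 70 nt; window centred on the union span of all
  changed bases, odd flank toward the lower coordinate; at least 20 nt of
  homology required on each side (plans that cannot fit are dropped from
  the bundle).  Strand `-` emits the reverse complement.
  Phosphorothioate protection is carried as annotation only (a count of
  protected 5′ linkages, default 0).
* **Lagging-strand choice** — `choose_strand` implements a documented,
  overridable replichore convention: replichore 1 is the arc ori→ter
  ascending (wrapping), default strands `{1: "-", 2: "+"}`.  The
  convention used is echoed in every bundle; positions exactly at ori/ter
  warn and default to replichore 1.  No organism-specific replication map
  is baked in.
* **USER pair** — `forward = tail_f + core`, `reverse = tail_r +
  revcomp(core)` with a 20-nt core and 10-nt tails, so annealing leaves a
  20-bp duplex with two 10-nt 5′ single-stranded overhangs.
* **Arrays** — `repeat (+ target + repeat)×n`, 30/30 blocks; length
  `30·(2n+1)`.  A repeat-length override exists for users supplying the
  native repeat at another length.  The self-kill designer takes the first
  eligible PAM (ascending coordinate, forward strand first) in each named
  region and excludes the PAM from the 30-nt spacer.
* **Scaffold, repeat and tails have no defaults.** They are properties of
  the user's constructs; inventing sequences would be a silent wet-lab
  hazard.  `magecs.fixtures.fixture_config` supplies clearly synthetic
  placeholders for testing only.

## Coordinates, alphabets, topology

Internally 0-based half-open; all user-facing output 1-based (edit syntax
`pos:REF>ALT`, e.g. `38:TAC>TAG`).  Sequences are uppercase `{A,C,G,T}`;
IUPAC ambiguity codes are rejected by default (designs on ambiguous bases
are unverifiable) and, under the permissive flag, are excluded from
PAM/protospacer eligibility.  Circular records wrap for scanning and
windowing; linear records never pad, and sites whose protospacer would run
off an end are dropped.  Edits are same-length substitutions only; the
genetic code is the standard table, with alternates accepted via the
translation helpers.

## What the fixture generator emulates — and what it does not

`make_fixture` builds small (600 nt) deterministic genomes whose coding
sequences contain the four canonical PAM geometries (in-frame one-codon
PAM with synonyms, boundary-spanning two-codon PAM, Trp-covered PAM with
no silent option, and the ACC-covered reverse-strand PAM), plus a PAM-free
A/T-only zone and a TAC codon for stop-codon edits.  Filler is A/T-only so
no stray GG/CC can appear near planted sites, and the generator verifies
its own truth table against the scanner before returning.  These genomes
exercise every code path deterministically, but they do not resemble real
genomic base composition, codon usage or PAM density; passing tests show
the algorithms are correct on their contracts, not that any particular
guide will perform well in a real strain.  Recombineering and killing
efficiencies are wet-lab quantities outside the package's scope.

## Problem sizes and determinism

The validation suite checks the scanner and escaper census against
brute-force enumeration on 1,000 random sequences of length ≤ 500 and
re-validates plans on 200 generated genomes; these sizes give exhaustive
coverage of the site geometries at negligible cost.  All randomness is
seeded (`random.Random(seed)`); identical requests and configs produce
byte-identical output bundles, which the suite asserts at file level.
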