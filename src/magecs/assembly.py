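"""Physical reagent assembly: MAGE oligos, USER pairs, crRNA arrays.

Everything here is deterministic string construction from a validated plan:

* the ssDNA MAGE oligo — a window of the genome (default 70 nt, the
  coverage within which a counter-selection PAM must fall) centred on the
  union span of all edits, with the edits applied, optionally
  reverse-complemented to target the lagging strand;
* the USER plug-and-play oligo pair — two oligos differing from universal
  scaffolds in only a 20-nt core, annealing to leave two 10-nt 5'
  single-stranded overhangs that match the USER-treated backbone;
* pre-crRNA arrays — the natural CRISPR layout of 30-nt repeats
  interleaved with 30-nt targets (repeat-target-repeat-target-...-repeat);
* the self-killing array — one spacer against each named plasmid region
  (typically the origin and the antibiotic marker), so induction cures the
  vector.

Repeat, tail and scaffold sequences are construct-specific configuration
with no baked-in defaults: shipping invented sequences would be a silent
wet-lab hazard.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

from .design import EditPlan
from .pam import PAM_LEN
from .seqmodel import (
    EditSpec,
    GenomeRecord,
    InputError,
    apply_edits,
    hamming,
    revcomp,
)

__all__ = [
    "DEFAULT_OLIGO_SIZE",
    "ARRAY_BLOCK_LEN",
    "USER_CORE_LEN",
    "USER_TAIL_LEN",
    "OligoDesign",
    "UserOligoPair",
    "ArrayDesign",
    "WindowClippedError",
    "NoPamInRegionError",
    "AmbiguousReplichoreWarning",
    "build_mage_oligo",
    "choose_strand",
    "build_user_pair",
    "build_crRNA_array",
    "design_selfkill_spacers",
]

DEFAULT_OLIGO_SIZE = 70   # nt of MAGE-oligo coverage
ARRAY_BLOCK_LEN = 30      # nt per repeat and per target in a pre-crRNA array
USER_CORE_LEN = 20        # variable nt between the universal USER scaffolds
USER_TAIL_LEN = 10        # single-stranded overhang left after annealing
_MIN_FLANK = 20           # homology guard rail on each side of the edit span


class WindowClippedError(InputError):
    """The oligo window cannot be centred without running off a linear end."""


class NoPamInRegionError(InputError):
    """A named region contains no NGG with a full spacer of 5' context."""


class AmbiguousReplichoreWarning(UserWarning):
    """Position sits exactly on ori or ter; replichore assignment defaulted."""


@dataclass(frozen=True)
class OligoDesign:
    """A MAGE ssDNA oligo: an edited genome window, possibly revcomp'd.

    ``phosphorothioate_5prime`` is annotation only — the number of
    protected terminal linkages to request at synthesis (default 0).
    """

    name: str
    sequence: str
    strand: str
    window_start: int
    window_end: int
    applied_edits: tuple[EditSpec, ...]
    phosphorothioate_5prime: int = 0

    def wildtype_window(self, genome: GenomeRecord) -> str:
        """The unedited genome window on the oligo's strand."""
        wt = genome.fetch(self.window_start, self.window_end)
        return wt if self.strand == "+" else revcomp(wt)

    def n_edited_bases(self, genome: GenomeRecord) -> int:
        return hamming(self.sequence, self.wildtype_window(genome))


def build_mage_oligo(
    genome: GenomeRecord,
    plan: EditPlan,
    size: int = DEFAULT_OLIGO_SIZE,
    strand: str = "+",
    name: str | None = None,
    phosphorothioate_5prime: int = 0,
) -> OligoDesign:
    """Assemble the recombineering oligo carrying every edit in the plan.

    The window is centred on the union span of the changed bases, the tie
    for an odd flank going toward the lower coordinate; it must leave at
    least 20 nt of homology on each side of the span.  On a linear record
    a window that cannot be centred raises :class:`WindowClippedError`
    (circular records wrap instead).
    """
    if strand not in ("+", "-"):
        raise InputError(f"strand must be +|-, got {strand!r}")
    edits = plan.all_edits
    changed = sorted(p for e in edits for p in e.changed_positions())
    lo, hi = changed[0], changed[-1] + 1
    span = hi - lo
    if size < span + 2 * _MIN_FLANK:
        raise InputError(
            f"oligo size {size} < edit span {span} + {2 * _MIN_FLANK} nt homology"
        )
    start = lo - (size - span + 1) // 2
    end = start + size
    if not genome.circular and (start < 0 or end > len(genome)):
        raise WindowClippedError(
            f"cannot centre a {size}-nt window on [{lo}, {hi}) within a "
            f"linear record of length {len(genome)}"
        )
    edited = apply_edits(genome, edits)
    n = len(genome)
    if genome.circular:
        start %= n
        end = start + size
        window = (edited[start:] + edited[: end - n]) if end > n else edited[start:end]
    else:
        window = edited[start:end]
    seq = window if strand == "+" else revcomp(window)
    return OligoDesign(
        name=name or f"mage_{lo + 1}",
        sequence=seq,
        strand=strand,
        window_start=start,
        window_end=end,
        applied_edits=tuple(edits),
        phosphorothioate_5prime=phosphorothioate_5prime,
    )


def choose_strand(
    position: int,
    ori: int,
    ter: int,
    genome_length: int,
    convention: dict[int, str] | None = None,
) -> str:
    """Pick the oligo strand that targets the lagging strand at ``position``.

    Recombineering is most efficient when the oligo anneals to the lagging
    strand template, which flips between the two replichores of a circular
    chromosome.  Replichore 1 is the arc from ``ori`` to ``ter`` ascending
    (wrapping through the origin of coordinates if needed); replichore 2 is
    the rest.  The strand used for each replichore is a documented,
    overridable convention (default: ``-`` for replichore 1, ``+`` for
    replichore 2) — callers should confirm it against their replication
    map.  A position exactly at ori or ter is ambiguous: a warning is
    raised and replichore 1 is used.
    """
    conv = convention or {1: "-", 2: "+"}
    if ori == ter:
        raise InputError("ori and ter must differ")
    position %= genome_length
    ori %= genome_length
    ter %= genome_length
    if position in (ori, ter):
        warnings.warn(
            f"position {position} lies exactly at "
            f"{'ori' if position == ori else 'ter'}; defaulting to replichore 1",
            AmbiguousReplichoreWarning,
            stacklevel=2,
        )
        return conv[1]
    if ori < ter:
        replichore = 1 if ori < position < ter else 2
    else:
        replichore = 1 if (position > ori or position < ter) else 2
    return conv[replichore]


@dataclass(frozen=True)
class UserOligoPair:
    """Plug-and-play USER cloning pair: universal tails + a 20-nt core.

    Only the core changes between targets; the two cores are reverse
    complements, so annealing forms a 20-bp duplex flanked by two 10-nt
    single-stranded 5' tails that match the USER-opened backbone.
    """

    forward: str
    reverse: str
    variable_core: str
    tail_f: str
    tail_r: str

    @property
    def duplex_length(self) -> int:
        return len(self.variable_core)

    @property
    def overhang_lengths(self) -> tuple[int, int]:
        return len(self.tail_f), len(self.tail_r)

    def anneals(self) -> bool:
        """Base-pairing check over the core at every position."""
        f_core = self.forward[len(self.tail_f):]
        r_core = self.reverse[len(self.tail_r):]
        return f_core == revcomp(r_core)


def build_user_pair(spacer20: str, tail_f: str, tail_r: str) -> UserOligoPair:
    """Two oligos that swap the guide target into the USER backbone."""
    spacer20 = spacer20.upper()
    if len(spacer20) != USER_CORE_LEN:
        raise InputError(f"core must be {USER_CORE_LEN} nt, got {len(spacer20)}")
    if len(tail_f) != USER_TAIL_LEN or len(tail_r) != USER_TAIL_LEN:
        raise InputError(f"tails must be {USER_TAIL_LEN} nt")
    pair = UserOligoPair(
        forward=tail_f.upper() + spacer20,
        reverse=tail_r.upper() + revcomp(spacer20),
        variable_core=spacer20,
        tail_f=tail_f.upper(),
        tail_r=tail_r.upper(),
    )
    assert pair.anneals()
    return pair


@dataclass(frozen=True)
class ArrayDesign:
    """A pre-crRNA array: repeat interleaved with 30-nt targets.

    Layout is repeat + target + repeat + ... + target + repeat, so the
    sequence always starts and ends with a repeat and every target is
    embedded between two repeats.
    """

    spacers: tuple[str, ...]
    repeat: str
    sequence: str = field(init=False)

    def __post_init__(self) -> None:
        seq = self.repeat + "".join(s + self.repeat for s in self.spacers)
        object.__setattr__(self, "sequence", seq)

    def blocks(self) -> list[str]:
        """Alternating repeat/target blocks, recoverable from the sequence."""
        out, pos = [], 0
        for k in range(2 * len(self.spacers) + 1):
            width = len(self.repeat) if k % 2 == 0 else len(self.spacers[k // 2])
            out.append(self.sequence[pos : pos + width])
            pos += width
        return out


def build_crRNA_array(
    spacers: Sequence[str],
    repeat: str,
    *,
    spacer_len: int = ARRAY_BLOCK_LEN,
    repeat_len: int = ARRAY_BLOCK_LEN,
) -> ArrayDesign:
    """Assemble a multiplex pre-crRNA array from 30-nt targets.

    ``repeat_len`` exists for users supplying the native S. pyogenes repeat
    at a different length; the default keeps the 30/30 block layout.
    """
    if not spacers:
        raise InputError("at least one spacer is required")
    repeat = repeat.upper()
    if len(repeat) != repeat_len:
        raise InputError(f"repeat must be {repeat_len} nt, got {len(repeat)}")
    ups = [s.upper() for s in spacers]
    for s in ups:
        if len(s) != spacer_len:
            raise InputError(f"spacer must be {spacer_len} nt, got {len(s)}")
    return ArrayDesign(spacers=tuple(ups), repeat=repeat)


def _first_spacer_in_region(genome: GenomeRecord, start: int, end: int,
                            spacer_len: int) -> str | None:
    """First 30-nt target 5' of an NGG lying wholly inside [start, end).

    Positions scanned in ascending order; at equal coordinate the forward
    strand wins — the same deterministic tie-break order used for guides.
    """
    seq = genome.seq
    for i in range(start, end - 1):
        # forward PAM at [i, i+3): needs spacer_len of context to the left
        if (seq[i + 1 : i + 3] == "GG" and i - spacer_len >= start
                and i + PAM_LEN <= end):
            return seq[i - spacer_len : i]
        # reverse PAM at [i, i+3): spacer context to the right, revcomp'd
        if (seq[i : i + 2] == "CC" and i + PAM_LEN + spacer_len <= end
                and i >= start):
            return revcomp(seq[i + PAM_LEN : i + PAM_LEN + spacer_len])
    return None


def design_selfkill_spacers(
    plasmid: GenomeRecord,
    regions: Sequence[str],
    repeat: str,
    *,
    spacer_len: int = ARRAY_BLOCK_LEN,
    repeat_len: int = ARRAY_BLOCK_LEN,
) -> ArrayDesign:
    """Self-curing array: one spacer per named plasmid region.

    For the canonical two-region design the regions are the replication
    origin and the antibiotic-resistance marker; inducing the array makes
    Cas9 destroy its own vector.  Spacer order follows the given region
    list.  A region without an NGG carrying a full spacer of 5' context
    raises :class:`NoPamInRegionError`.
    """
    spacers = []
    for label in regions:
        feat = plasmid.feature(label)
        spacer = _first_spacer_in_region(plasmid, feat.start, feat.end, spacer_len)
        if spacer is None:
            raise NoPamInRegionError(
                f"region {label!r} has no NGG with {spacer_len} nt of 5' context"
            )
        spacers.append(spacer)
    return build_crRNA_array(spacers, repeat, spacer_len=spacer_len,
                             repeat_len=repeat_len)
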