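"""Counter-selection planning: choose a PAM and break it silently if needed.

The recombineering oligo must carry, besides the desired edit, something
that stops Cas9 from cutting the edited chromosome.  If the desired edit
already falls in the chosen PAM or its seed, nothing more is needed.
Otherwise — a "PAM-independent" locus — the planner enumerates synonymous
(degenerate) codon substitutions in whichever one or two codons cover the
PAM, keeps exactly those that destroy the GG dinucleotide, and verifies
each programmatically.  Synonymous codons that fail to break the PAM are
reported as warnings, never emitted as valid plans: leaving that check to
the user is the error-prone step this module exists to remove.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import pandas as pd

from .pam import PamSite, Verdict, find_pam_sites, is_disabled
from .seqmodel import (
    CodonContext,
    EditSpec,
    GenomeRecord,
    InputError,
    apply_edits,
    revcomp,
    synonymous_codons,
    translate,
)

__all__ = [
    "CodonEdit",
    "EditPlan",
    "NotInFrameError",
    "NoCounterselectionError",
    "codons_covering_pam",
    "enumerate_silent_pam_breaks",
    "plan_counterselection",
    "plan_table",
    "DEFAULT_WINDOW",
]

# The planning window defaults to the MAGE-oligo coverage: a PAM (and any
# silent edit breaking it) is only usable if the oligo can carry the change.
DEFAULT_WINDOW = 70


class NotInFrameError(InputError):
    """The PAM does not lie wholly inside the supplied CDS."""


class NoCounterselectionError(RuntimeError):
    """No PAM in the window can be disabled by the desired or any silent edit."""


@dataclass(frozen=True)
class CodonEdit:
    """A single synonymous codon substitution and the genomic edit it induces."""

    codon_index: int  # 1-based within the CDS, as reported to the user
    old_codon: str
    new_codon: str
    edits: tuple[EditSpec, ...]
    destroys_pam: bool

    def __post_init__(self) -> None:
        if translate(self.old_codon) != translate(self.new_codon):
            raise InputError(
                f"{self.old_codon}>{self.new_codon} is not synonymous"
            )
        if self.old_codon == self.new_codon:
            raise InputError("codon edit must change the codon")

    @property
    def n_changed(self) -> int:
        return sum(len(e.changed_positions()) for e in self.edits)

    def describe(self) -> str:
        return f"codon{self.codon_index}:{self.old_codon}>{self.new_codon}"


@dataclass
class EditPlan:
    """One ranked design: desired edits + chosen PAM + silent companions.

    ``counterselection`` is empty exactly when the desired edits alone
    disable the site; a plan is only ever constructed with a verdict other
    than ``still_active``.
    """

    desired: list[EditSpec]
    site: PamSite
    counterselection: list[CodonEdit]
    verdict: str
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.verdict == Verdict.STILL_ACTIVE:
            raise InputError("a valid plan must disable its PAM site")

    @property
    def all_edits(self) -> list[EditSpec]:
        out = list(self.desired)
        for ce in self.counterselection:
            out.extend(ce.edits)
        return out

    @property
    def n_silent_changed(self) -> int:
        return sum(ce.n_changed for ce in self.counterselection)


def codons_covering_pam(site: PamSite, ctx: CodonContext) -> list[int]:
    """0-based indices of the codon(s) whose footprint intersects the PAM.

    The 3-nt PAM must lie wholly inside the CDS; a PAM sticking out of the
    reading frame (even by one base) raises :class:`NotInFrameError` and the
    caller falls back to non-coding planning.  A 3-nt motif on a 3-nt codon
    grid intersects one codon (in frame) or two (offset by 1 or 2).
    """
    for pos in site.pam_positions:
        if not ctx.cds_start <= pos < ctx.cds_end:
            raise NotInFrameError(
                f"PAM of {site.id} not wholly inside CDS "
                f"[{ctx.cds_start}, {ctx.cds_end})"
            )
    if ctx.strand == "+":
        idx = {(pos - ctx.cds_start) // 3 for pos in site.pam_positions}
    else:
        idx = {(ctx.cds_end - 1 - pos) // 3 for pos in site.pam_positions}
    out = sorted(idx)
    assert 1 <= len(out) <= 2
    return out


def _codon_editspec(ctx: CodonContext, genome: GenomeRecord, index: int,
                    new_codon: str) -> EditSpec:
    s, e = ctx.codon_footprint(index)
    ref = genome.fetch(s, e)
    alt = new_codon if ctx.strand == "+" else revcomp(new_codon)
    return EditSpec(s, ref, alt, role="counterselection")


def _new_pams_near(genome: GenomeRecord, site: PamSite,
                   edits: Sequence[EditSpec]) -> list[str]:
    """Ids of NGG sites near the target that exist only after the edits."""
    lo = min(min(site.pam_positions), min(site.seed_positions)) - 5
    hi = max(max(site.pam_positions), max(site.seed_positions)) + 5
    if not genome.circular:
        lo, hi = max(0, lo), min(len(genome), hi)

    def pam_keys(g: GenomeRecord) -> set[tuple[int, str]]:
        return {(s.pam_start, s.strand) for s in find_pam_sites(g, (lo, hi))}

    before = pam_keys(genome)
    edited = GenomeRecord(genome.id, apply_edits(genome, edits),
                          topology=genome.topology,
                          allow_ambiguous=genome.allow_ambiguous)
    after = pam_keys(edited)
    return [f"pam{p + 1}{'f' if st == '+' else 'r'}" for p, st in sorted(after - before)]


def enumerate_silent_pam_breaks(
    site: PamSite,
    ctx: CodonContext,
    genome: GenomeRecord,
    desired: Sequence[EditSpec] = (),
) -> tuple[list[CodonEdit], list[str], dict[str, list[str]]]:
    """All single-codon synonymous substitutions that destroy the PAM.

    Each covering codon is varied independently (single-codon edits only —
    minimal divergence from wild type).  Returns ``(valid, warnings,
    per_edit_warnings)``: valid holds only PAM-destroying edits, each
    machine-verified through :func:`is_disabled`; synonymous-but-non-
    destroying options, clashes with the desired edit, and Met/Trp dead
    ends land in the shared warnings; a NewPamCreated note is keyed by the
    edit that caused it.
    """
    indices = codons_covering_pam(site, ctx)
    desired_changed = {p for e in desired for p in e.changed_positions()}
    valid: list[CodonEdit] = []
    notes: list[str] = []
    per_edit_notes: dict[str, list[str]] = {}
    for idx in indices:
        old = ctx.codon_seq(genome, idx)
        alternatives = sorted(synonymous_codons(old) - {old})
        if not alternatives:
            notes.append(
                f"NoSilentOption: codon {idx + 1} ({old}, "
                f"{translate(old)}) has no synonym"
            )
            continue
        for new in alternatives:
            spec = _codon_editspec(ctx, genome, idx, new)
            if desired_changed & set(spec.changed_positions()):
                notes.append(
                    f"skipped codon{idx + 1}:{old}>{new} — overlaps the desired edit"
                )
                continue
            verdict = is_disabled(site, [spec])
            if verdict == Verdict.DISABLED_BY_PAM:
                ce = CodonEdit(idx + 1, old, new, (spec,), destroys_pam=True)
                created = _new_pams_near(genome, site, [spec])
                if created:
                    per_edit_notes[ce.describe()] = [
                        f"NewPamCreated: {ce.describe()} creates "
                        f"{','.join(created)} near the target"
                    ]
                valid.append(ce)
            else:
                notes.append(
                    f"synonymous but does not destroy PAM: codon{idx + 1}:{old}>{new}"
                )
    return valid, notes, per_edit_notes


def plan_counterselection(
    genome: GenomeRecord,
    desired: Sequence[EditSpec],
    ctx: CodonContext | None = None,
    window_size: int = DEFAULT_WINDOW,
) -> list[EditPlan]:
    """Rank every way to pair the desired edit with a disabled PAM site.

    Scans a ``window_size`` window (default 70 nt — the MAGE-oligo
    coverage) centred on the desired edit span.  For each candidate PAM:
    if the desired edits alone disable it, the plan needs no silent
    companion; otherwise, with a reading frame supplied, one plan is made
    per PAM-destroying synonymous codon substitution.  Sites that stay
    active and have no silent option are skipped.  Plans are ranked by
    distance to the edit, then fewest silent changed bases, then
    coordinate, then + strand.  Raises :class:`NoCounterselectionError`
    when nothing in the window can be disabled.
    """
    desired = list(desired)
    if not desired:
        raise InputError("at least one desired edit is required")
    apply_edits(genome, desired)  # validates refs and overlaps
    changed = sorted(p for e in desired for p in e.changed_positions())
    if not changed:
        raise InputError("desired edits change nothing")
    lo, hi = changed[0], changed[-1] + 1
    span = hi - lo
    if window_size < span:
        raise InputError(f"window_size {window_size} smaller than edit span {span}")
    wstart = lo - (window_size - span + 1) // 2
    wend = wstart + window_size
    if not genome.circular:
        shift = max(0, -wstart) - max(0, wend - len(genome))
        wstart, wend = wstart + shift, wend + shift
        wstart, wend = max(0, wstart), min(len(genome), wend)

    plans: list[EditPlan] = []
    for site in find_pam_sites(genome, (wstart, wend), edit_span=(lo, hi)):
        verdict = is_disabled(site, desired)
        if verdict != Verdict.STILL_ACTIVE:
            plans.append(EditPlan(desired, site, [], verdict))
            continue
        if ctx is None:
            continue
        try:
            valid, notes, per_edit = enumerate_silent_pam_breaks(
                site, ctx, genome, desired)
        except NotInFrameError:
            continue
        for ce in valid:
            full_verdict = is_disabled(site, desired + list(ce.edits))
            plans.append(EditPlan(
                desired, site, [ce], full_verdict,
                list(notes) + per_edit.get(ce.describe(), [])))

    plans.sort(key=lambda p: (
        p.site.distance_to_edit or 0,
        p.n_silent_changed,
        p.site.pam_start,
        p.site.strand == "-",
    ))
    if not plans:
        raise NoCounterselectionError(
            "no PAM site in the window can be disabled by the desired edit "
            "or by a silent codon substitution"
        )
    for p in plans:  # machine-check the core invariant on every plan
        assert is_disabled(p.site, p.all_edits) != Verdict.STILL_ACTIVE
    return plans


def plan_table(plans: Sequence[EditPlan]) -> pd.DataFrame:
    """Plan report with 1-based coordinates and `pos:REF>ALT` edit syntax."""
    rows = []
    for rank, p in enumerate(plans, start=1):
        rows.append({
            "rank": rank,
            "desired": ";".join(f"{e.position + 1}:{e.ref}>{e.alt}" for e in p.desired),
            "pam_1based": p.site.pam_start + 1,
            "pam_strand": p.site.strand,
            "protospacer": p.site.protospacer,
            "silent_edit": ";".join(ce.describe() for ce in p.counterselection),
            "verdict": p.verdict,
            "warnings": " | ".join(p.warnings),
        })
    return pd.DataFrame(rows, columns=[
        "rank", "desired", "pam_1based", "pam_strand", "protospacer",
        "silent_edit", "verdict", "warnings",
    ])
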