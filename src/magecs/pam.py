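"""NGG PAM discovery, protospacer/seed extraction and Cas9-disabling logic.

S. pyogenes Cas9 cuts where a 20-nt protospacer sits immediately 5' of an
NGG PAM (the 20N-NGG rule).  Counter-selection survives only on chromosomes
that still present an intact PAM and seed: a single changed base in the two
G positions of the PAM, or anywhere in the 8 protospacer nucleotides
adjacent to the PAM (the seed), abolishes targeting.  That rule is what
:func:`is_disabled` encodes, and it is the validity criterion for every
edit plan downstream.

Only NGG is treated as a PAM.  NAG is neither accepted as a target nor
counted as residual activity; a silent edit that turns NGG into NAG raises
a :class:`NagConversionWarning` so the designer can judge the risk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .seqmodel import (
    DNA_ALPHABET,
    EditSpec,
    GenomeRecord,
    InputError,
    revcomp,
)

__all__ = [
    "PROTOSPACER_LEN",
    "SEED_LEN",
    "PAM_LEN",
    "PamSite",
    "SgRNARecord",
    "ConfigurationError",
    "NagConversionWarning",
    "Verdict",
    "find_pam_sites",
    "is_disabled",
    "build_sgrna",
    "escaper_scan",
    "sites_table",
]

PROTOSPACER_LEN = 20
SEED_LEN = 8
PAM_LEN = 3

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


class ConfigurationError(ValueError):
    """A required configuration value (scaffold, repeat, tails) is missing."""


class NagConversionWarning(UserWarning):
    """A PAM-destroying edit converted NGG to NAG; NAG tolerance is untested."""


class Verdict:
    DISABLED_BY_PAM = "disabled_by_pam"
    DISABLED_BY_SEED = "disabled_by_seed"
    STILL_ACTIVE = "still_active"


@dataclass(frozen=True)
class PamSite:
    """One NGG occurrence and its guide-relevant anatomy.

    ``pam_positions`` are the three genomic positions of the PAM in reading
    order (N, G, G) on the site's strand; ``seed_positions`` are the eight
    protospacer positions adjacent to the PAM, ordered 5'→3' on the site's
    strand (the last one abuts the PAM).  Storing explicit positions keeps
    every membership test exact on circular records, where intervals wrap.
    """

    pam_start: int
    pam_end: int
    strand: str
    protospacer: str
    pam_seq: str
    seed: str
    pam_positions: tuple[int, int, int]
    seed_positions: tuple[int, ...]
    protospacer_start: int
    distance_to_edit: int | None = None

    def __post_init__(self) -> None:
        if self.pam_seq[1:3] != "GG":
            raise InputError(f"PAM {self.pam_seq!r} does not read NGG")
        if len(self.protospacer) != PROTOSPACER_LEN:
            raise InputError(f"protospacer must be {PROTOSPACER_LEN} nt")
        if len(self.seed) != SEED_LEN or not self.protospacer.endswith(self.seed):
            raise InputError("seed must be the 8 PAM-adjacent protospacer nt")

    @property
    def id(self) -> str:
        return f"pam{self.pam_start + 1}{'f' if self.strand == '+' else 'r'}"

    def pam_base_after(self, edits_by_pos: dict[int, str]) -> str:
        """PAM sequence on the site's strand after applying per-position edits."""
        out = []
        for offset, pos in enumerate(self.pam_positions):
            if pos in edits_by_pos:
                base = edits_by_pos[pos]
                out.append(base if self.strand == "+" else _COMP[base])
            else:
                out.append(self.pam_seq[offset])
        return "".join(out)


def _changed_bases(edits: Iterable[EditSpec]) -> dict[int, str]:
    """Map genomic position -> new forward-strand base, for positions that change."""
    out: dict[int, str] = {}
    for e in edits:
        for i, (r, a) in enumerate(zip(e.ref, e.alt)):
            if r != a:
                out[e.position + i] = a
    return out


def _interval_distance(a_lo: int, a_hi: int, b_lo: int, b_hi: int,
                       length: int | None) -> int:
    """Gap in nt between half-open intervals; 0 if they overlap.

    ``length`` set ⇒ circular: the shorter way around counts.
    """
    def linear(alo: int, ahi: int, blo: int, bhi: int) -> int:
        if ahi <= blo:
            return blo - ahi
        if bhi <= alo:
            return alo - bhi
        return 0

    d = linear(a_lo, a_hi, b_lo, b_hi)
    if length is None:
        return d
    return min(d, linear(a_lo + length, a_hi + length, b_lo, b_hi),
               linear(a_lo, a_hi, b_lo + length, b_hi + length))


def _eligible(fragment: str) -> bool:
    return set(fragment) <= DNA_ALPHABET


def find_pam_sites(genome: GenomeRecord, window: tuple[int, int],
                   edit_span: tuple[int, int] | None = None) -> list[PamSite]:
    """Every NGG PAM on either strand whose PAM lies inside ``window``.

    The 3-nt PAM must fall entirely within the window (the window is the
    MAGE-oligo coverage region, and the PAM-disrupting edit must sit in the
    oligo); the 20-nt protospacer need only lie inside the genome.  Sites
    whose protospacer would run off a linear sequence end are dropped.
    Circular genomes wrap.  Output is sorted by distance to the desired
    edit (when ``edit_span`` is given), then coordinate, then strand — a
    deterministic order the planner's tie-breaks rely on.
    """
    n = len(genome)
    wstart, wend = window
    if wend < wstart:
        raise InputError(f"inverted window [{wstart}, {wend})")
    if genome.circular:
        if wend - wstart >= n:
            # full scan: extend past the origin so wrapping PAMs are seen once
            wstart, wend = 0, n + PAM_LEN - 1
    else:
        wstart, wend = max(0, wstart), min(n, wend)
        if wstart >= wend:
            raise InputError("window outside linear genome")

    length = n if genome.circular else None
    sites: list[PamSite] = []
    for i in range(wstart, wend - PAM_LEN + 1):
        # forward strand: protospacer [i-20, i), PAM [i, i+3)
        if genome.fetch(*_norm_iv(genome, i + 1, i + 3)) == "GG":
            ps_start = i - PROTOSPACER_LEN
            if genome.circular or ps_start >= 0:
                proto = genome.fetch(*_norm_iv(genome, ps_start, i))
                pam = genome.fetch(*_norm_iv(genome, i, i + PAM_LEN))
                if _eligible(proto + pam):
                    sites.append(_make_site(genome, i, "+", proto, pam, edit_span, length))
        # reverse strand: PAM occupies [i, i+3) with forward CC at [i, i+2);
        # protospacer is revcomp of [i+3, i+23)
        if genome.fetch(*_norm_iv(genome, i, i + 2)) == "CC":
            ps_end = i + PAM_LEN + PROTOSPACER_LEN
            if genome.circular or ps_end <= n:
                proto = revcomp(genome.fetch(*_norm_iv(genome, i + PAM_LEN, ps_end)))
                pam = revcomp(genome.fetch(*_norm_iv(genome, i, i + PAM_LEN)))
                if _eligible(proto + pam):
                    sites.append(_make_site(genome, i, "-", proto, pam, edit_span, length))

    sites.sort(key=lambda s: (
        s.distance_to_edit if s.distance_to_edit is not None else 0,
        s.pam_start,
        s.strand == "-",
    ))
    return sites


def _norm_iv(genome: GenomeRecord, start: int, end: int) -> tuple[int, int]:
    if genome.circular:
        n = len(genome)
        s = start % n
        return s, s + (end - start)
    return start, end


def _make_site(genome: GenomeRecord, pam_start: int, strand: str, proto: str,
               pam: str, edit_span: tuple[int, int] | None,
               length: int | None) -> PamSite:
    n = len(genome)
    norm = (lambda p: p % n) if genome.circular else (lambda p: p)
    if strand == "+":
        pam_positions = tuple(norm(pam_start + k) for k in range(PAM_LEN))
        seed_positions = tuple(norm(pam_start - SEED_LEN + k) for k in range(SEED_LEN))
        ps_start = norm(pam_start - PROTOSPACER_LEN)
    else:
        # reading order on the reverse strand runs right-to-left in genome coords
        pam_positions = tuple(norm(pam_start + PAM_LEN - 1 - k) for k in range(PAM_LEN))
        seed_positions = tuple(norm(pam_start + PAM_LEN + SEED_LEN - 1 - k)
                               for k in range(SEED_LEN))
        ps_start = norm(pam_start + PAM_LEN)
    dist = None
    if edit_span is not None:
        dist = _interval_distance(pam_start, pam_start + PAM_LEN,
                                  edit_span[0], edit_span[1], length)
    return PamSite(
        pam_start=norm(pam_start),
        pam_end=norm(pam_start) + PAM_LEN,
        strand=strand,
        protospacer=proto,
        pam_seq=pam,
        seed=proto[-SEED_LEN:],
        pam_positions=pam_positions,  # type: ignore[arg-type]
        seed_positions=seed_positions,
        protospacer_start=ps_start,
        distance_to_edit=dist,
    )


def is_disabled(site: PamSite, edits: Sequence[EditSpec]) -> str:
    """Classify whether ``edits`` abolish Cas9 targeting of ``site``.

    ``disabled_by_pam`` — after the edits the two G positions of the PAM no
    longer read GG (a change confined to the N position never counts);
    ``disabled_by_seed`` — the PAM survives but at least one changed base
    falls in the 8-nt seed; ``still_active`` otherwise.  Pure function of
    the site anatomy and the edits' changed positions, so it is monotone:
    adding edits can never resurrect a disabled site (refs are checked
    against wild type, so no edit can restore a G that another removed).
    """
    changed = _changed_bases(edits)
    new_pam = site.pam_base_after(changed)
    if new_pam[1:3] != "GG":
        if new_pam[1:3] == "AG":
            warnings.warn(
                f"site {site.id}: PAM {site.pam_seq} edited to {new_pam} (NGG→NAG); "
                "residual NAG activity is not modelled",
                NagConversionWarning,
                stacklevel=2,
            )
        return Verdict.DISABLED_BY_PAM
    if any(pos in changed for pos in site.seed_positions):
        return Verdict.DISABLED_BY_SEED
    return Verdict.STILL_ACTIVE


@dataclass(frozen=True)
class SgRNARecord:
    """A programmed single guide: 20-nt spacer fused to the invariant scaffold.

    The scaffold (crRNA-repeat/tracrRNA fusion) is construct-specific and
    must be supplied by configuration — there is no safe universal default.
    """

    spacer: str
    scaffold: str
    site: PamSite
    full_sequence: str = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "full_sequence", self.spacer + self.scaffold)


def build_sgrna(site: PamSite, scaffold: str) -> SgRNARecord:
    """Program an sgRNA for ``site``: spacer == protospacer, PAM excluded."""
    if not scaffold:
        raise ConfigurationError(
            "sgRNA scaffold sequence is required (supply it in the config; "
            "it is construct-specific and has no default)"
        )
    return SgRNARecord(spacer=site.protospacer, scaffold=scaffold.upper(), site=site)


def _pattern_matches(haystack: str, seed: str) -> list[int]:
    """Start positions where seed + N + GG occurs (N = any base)."""
    k = len(seed)
    hits = []
    idx = haystack.find(seed)
    while idx != -1:
        if haystack[idx + k + 1 : idx + k + 3] == "GG":
            hits.append(idx)
        idx = haystack.find(seed, idx + 1)
    return hits


def escaper_scan(genome: GenomeRecord, site: PamSite) -> int:
    """Count other exact seed+NGG occurrences in the genome, either strand.

    A guide whose 8-nt seed + PAM recurs elsewhere can cut unintended loci
    and select escapers there; this is an exact-match census only (no
    mismatch-tolerant off-target search).
    """
    n = len(genome)
    ext = SEED_LEN + PAM_LEN - 1
    fwd = genome.seq + (genome.seq[:ext] if genome.circular else "")
    rev = revcomp(genome.seq)
    rev_ext = rev + (rev[:ext] if genome.circular else "")

    total = 0
    own = 0
    for q in _pattern_matches(fwd, site.seed):
        if q < n:
            total += 1
            if site.strand == "+" and q % max(n, 1) == site.seed_positions[0]:
                own += 1
    for q in _pattern_matches(rev_ext, site.seed):
        if q < n:
            total += 1
            # map revcomp index back to forward genome coords: the seed's
            # 5'-most base on the reverse strand sits at forward n-1-q
            if site.strand == "-" and (n - 1 - q) % n == site.seed_positions[0]:
                own += 1
    return total - own


def sites_table(sites: Sequence[PamSite],
                verdicts: Sequence[str] | None = None) -> pd.DataFrame:
    """Candidate table with 1-based user-facing coordinates."""
    rows = []
    for k, s in enumerate(sites):
        rows.append({
            "id": s.id,
            "strand": s.strand,
            "pam_1based": s.pam_start + 1,
            "protospacer": s.protospacer,
            "seed": s.seed,
            "distance_to_edit": s.distance_to_edit,
            "disabled_status": verdicts[k] if verdicts is not None else "",
        })
    return pd.DataFrame(rows, columns=[
        "id", "strand", "pam_1based", "protospacer", "seed",
        "distance_to_edit", "disabled_status",
    ])
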