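"""Deterministic toy genomes with PAM sites planted at known offsets.

Everything in the test suite and the examples runs offline on genomes made
here.  The generator plants, inside designed coding sequences, the exact
geometries the planner must handle:

* ``one_codon``   — an AGG arginine codon that is itself an in-frame NGG
                    PAM (synonyms exist; AGA breaks it, CGG does not);
* ``two_codon``   — an NGG spanning a codon boundary (ACG|GAT), so two
                    mutation boxes cover the PAM;
* ``no_synonym``  — a TGG tryptophan codon that is itself a PAM: Trp has
                    no synonym, the silent-break dead end;
* ``acc_reverse`` — an ACC threonine codon whose CC is the forward-strand
                    image of a reverse-strand GG PAM, the classic
                    silent-break geometry (ACC>ACA);
* a PAM-free zone (A/T-only, so no GG or CC dinucleotide can occur);
* optionally a reverse-strand gene with its own in-frame PAM.

All padding and filler codons are drawn from the A/T alphabet, so no
accidental NGG can appear near a planted site; the generator verifies this
by scanning every planted window and fails loudly if the layout is
contradicted.  A TAC tyrosine codon planted upstream of the ACC site gives
examples and tests a ready-made stop-codon edit (TAC>TAG).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .pam import PAM_LEN, PROTOSPACER_LEN, find_pam_sites
from .seqmodel import CodonContext, Feature, GenomeRecord, revcomp

__all__ = ["PlantedSite", "FixtureTruth", "GenerationError", "make_fixture",
           "fixture_config"]

# filler codons over {A,T} only: cannot take part in any GG/CC dinucleotide
_AT_CODONS = ("ATT", "TTA", "AAT", "TAT", "ATA", "TTT")
_KINDS = ("one_codon", "two_codon", "no_synonym", "acc_reverse")


class GenerationError(RuntimeError):
    """The requested planting is contradictory or produced stray PAMs."""


@dataclass(frozen=True)
class PlantedSite:
    """One deliberately placed PAM and the window that should contain it alone."""

    kind: str
    pam_start: int
    strand: str
    window: tuple[int, int]
    codon_indices_1based: tuple[int, ...]


@dataclass
class FixtureTruth:
    """Ground truth for a generated fixture genome."""

    planted: list[PlantedSite]
    contexts: dict[str, CodonContext]
    pam_free: tuple[int, int]
    stop_edit_position: int | None = None  # 0-based T of the planted TAC codon
    notes: list[str] = field(default_factory=list)


def _at_filler(rng: random.Random, n_codons: int) -> list[str]:
    return [rng.choice(_AT_CODONS) for _ in range(n_codons)]


def _at_pad(rng: random.Random, n: int) -> str:
    return "".join(rng.choice("AT") for _ in range(n))


def make_fixture(
    seed: int,
    length: int = 600,
    n_genes: int = 2,
    planted_sites: tuple[str, ...] = _KINDS,
) -> tuple[GenomeRecord, FixtureTruth]:
    """Build a deterministic toy genome plus its truth table.

    Same seed ⇒ byte-identical genome.  ``planted_sites`` selects which of
    the four canonical PAM geometries go into the forward gene;
    ``n_genes=2`` adds a reverse-strand gene with one in-frame PAM.
    """
    unknown = set(planted_sites) - set(_KINDS)
    if unknown:
        raise GenerationError(f"unknown planted site kinds: {sorted(unknown)}")
    rng = random.Random(seed)
    planted: list[PlantedSite] = []
    pending: list[tuple[str, int, str, int, tuple[int, ...]]] = []
    # (kind, offset_in_cds, strand, pam_len_window, codon indices)

    pos = 0
    chunks: list[str] = []

    def emit(s: str) -> None:
        nonlocal pos
        chunks.append(s)
        pos += len(s)

    emit(_at_pad(rng, PROTOSPACER_LEN + 5))

    pam_free = (pos, pos + 60)
    emit(_at_pad(rng, 60))
    emit(_at_pad(rng, 10))

    # ---- forward gene -------------------------------------------------
    cds_codons: list[str] = ["ATG"]
    site_specs: list[tuple[str, int, str, tuple[int, ...]]] = []
    # each planted construct is preceded by >= 4 A/T codons so windows
    # around distinct sites never overlap
    stop_edit_position: int | None = None
    cds_start = pos
    for kind in planted_sites:
        cds_codons.extend(_at_filler(rng, 4))
        if kind == "one_codon":
            idx = len(cds_codons)
            cds_codons.append("AGG")  # in-frame PAM == the codon itself
            site_specs.append((kind, 3 * idx, "+", (idx + 1,)))
        elif kind == "two_codon":
            idx = len(cds_codons)
            cds_codons.extend(["ACG", "GAT"])  # PAM CGG spans the boundary
            site_specs.append((kind, 3 * idx + 1, "+", (idx + 1, idx + 2)))
        elif kind == "no_synonym":
            idx = len(cds_codons)
            cds_codons.append("TGG")  # Trp: PAM with no silent escape
            site_specs.append((kind, 3 * idx, "+", (idx + 1,)))
        elif kind == "acc_reverse":
            # TAC two codons upstream: the stop-codon edit target
            stop_idx = len(cds_codons)
            cds_codons.append("TAC")
            cds_codons.extend(_at_filler(rng, 1))
            idx = len(cds_codons)
            cds_codons.append("ACC")  # reverse-strand PAM image
            site_specs.append((kind, 3 * idx + 1, "-", (idx + 1, idx + 2)))
            stop_edit_position = cds_start + 3 * stop_idx
    cds_codons.extend(_at_filler(rng, 4))
    cds_codons.append("TAA")
    cds = "".join(cds_codons)
    emit(cds)
    cds_end = cds_start + len(cds)

    for kind, off, strand, idxs in site_specs:
        pam_start = cds_start + off
        win = (pam_start - 6, pam_start + PAM_LEN + 6)
        planted.append(PlantedSite(kind, pam_start, strand, win, idxs))

    contexts = {"geneA": CodonContext(cds_start, cds_end, "+")}
    features = [Feature("geneA", cds_start, cds_end, "+")]

    # ---- reverse gene -------------------------------------------------
    if n_genes >= 2:
        emit(_at_pad(rng, PROTOSPACER_LEN + 10))
        rc_codons = ["ATG"] + _at_filler(rng, 4) + ["AGG"] + _at_filler(rng, 4) + ["TAA"]
        rc_cds = "".join(rc_codons)
        g_start = pos
        emit(revcomp(rc_cds))
        g_end = g_start + len(rc_cds)
        contexts["geneB"] = CodonContext(g_start, g_end, "-")
        features.append(Feature("geneB", g_start, g_end, "-"))
        # reverse codon 5 (0-based) is AGG; genomic footprint of codon k on
        # '-' is [cds_end - 3(k+1), cds_end - 3k); PAM occupies that footprint
        agg_idx = 5
        pam_start = g_end - 3 * (agg_idx + 1)
        win = (pam_start - 6, pam_start + PAM_LEN + 6)
        planted.append(PlantedSite("one_codon_reverse_gene", pam_start, "-", win,
                                   (agg_idx + 1,)))

    emit(_at_pad(rng, PROTOSPACER_LEN + 5))
    if pos < length:
        emit(_at_pad(rng, length - pos))

    genome = GenomeRecord(id=f"fixture_seed{seed}", seq="".join(chunks),
                          topology="linear", features=features)

    # ---- verify the layout against the scanner ------------------------
    for site in planted:
        found = find_pam_sites(genome, site.window)
        keys = {(s.pam_start, s.strand) for s in found}
        if keys != {(site.pam_start, site.strand)}:
            raise GenerationError(
                f"planted {site.kind} at {site.pam_start}{site.strand}: "
                f"scanner saw {sorted(keys)} in window {site.window}"
            )
    if find_pam_sites(genome, pam_free):
        raise GenerationError("PAM-free zone is not PAM-free")

    truth = FixtureTruth(
        planted=planted,
        contexts=contexts,
        pam_free=pam_free,
        stop_edit_position=stop_edit_position,
    )
    return genome, truth


def fixture_config(seed: int) -> dict[str, str]:
    """Synthetic placeholder reagent sequences for testing.

    These are arbitrary deterministic stand-ins for the construct-specific
    scaffold, repeat and USER-tail sequences a real design would load from
    its config; they carry no biological meaning.
    """
    rng = random.Random(seed ^ 0x5CAFF01D)
    mk = lambda n: "".join(rng.choice("ACGT") for _ in range(n))
    return {
        "scaffold": mk(76),
        "repeat": mk(30),
        "tail_f": mk(10),
        "tail_r": mk(10),
    }
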