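"""End-to-end design workflow: request in, reagent bundle out.

Mirrors the three-step interactive flow — load a wild-type sequence, name
the base(s) to change, pick the guide and oligo — as a single deterministic
function.  One request designs one locus; multiplexing is a list of
requests, each yielding its own guide and oligo (the arrays tie them
together downstream).
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from .assembly import build_mage_oligo, build_user_pair, choose_strand
from .config import DesignConfig
from .design import (
    EditPlan,
    NoCounterselectionError,
    plan_counterselection,
    plan_table,
)
from .pam import SgRNARecord, build_sgrna, escaper_scan, sites_table
from .seqmodel import (
    CodonContext,
    EditSpec,
    GenomeRecord,
    InputError,
    read_genome,
    write_fasta,
)

__all__ = ["DesignRequest", "DesignBundle", "parse_edit", "parse_frame",
           "run_design", "run_multiplex"]

_EDIT_RE = re.compile(r"^(\d+):([ACGTacgt]+)>([ACGTacgt]+)$")


def parse_edit(text: str) -> EditSpec:
    """Parse the user edit syntax ``pos:REF>ALT`` (1-based), e.g. ``38:TAC>TAG``."""
    m = _EDIT_RE.match(text.strip())
    if not m:
        raise InputError(
            f"malformed edit {text!r}; expected 1-based 'pos:REF>ALT', "
            "e.g. '38:TAC>TAG'"
        )
    pos, ref, alt = int(m.group(1)), m.group(2).upper(), m.group(3).upper()
    if pos < 1:
        raise InputError("edit position is 1-based and must be >= 1")
    return EditSpec(pos - 1, ref, alt, role="desired")


def parse_frame(text: str) -> CodonContext | None:
    """Parse ``start..end[:strand]`` (1-based inclusive) or ``non-coding``."""
    t = text.strip().lower()
    if t in ("non-coding", "noncoding", "none"):
        return None
    m = re.match(r"^(\d+)\.\.(\d+)(?::([+-]))?$", text.strip())
    if not m:
        raise InputError(
            f"malformed frame {text!r}; expected 'start..end[:strand]' "
            "(1-based inclusive) or 'non-coding'"
        )
    start, end = int(m.group(1)) - 1, int(m.group(2))
    return CodonContext(start, end, m.group(3) or "+")


@dataclass
class DesignRequest:
    """One locus to edit: the input sequence, the edit, and the conventions."""

    genome: GenomeRecord
    edit: str                      # "pos:REF>ALT", 1-based
    frame: str = "non-coding"      # "start..end[:strand]" or "non-coding"
    oligo_size: int | None = None
    strand_policy: str = "auto"    # auto | + | -
    config: DesignConfig = field(default_factory=DesignConfig)
    name: str = "design"

    @classmethod
    def from_path(cls, path: str | Path, edit: str, **kw) -> "DesignRequest":
        return cls(genome=read_genome(path), edit=edit, **kw)


@dataclass
class DesignBundle:
    """Everything one request produced, ready to write or inspect."""

    request: DesignRequest
    plans: list[EditPlan]
    oligos: list                   # OligoDesign, parallel to plans
    sgrnas: list[SgRNARecord | None]
    user_pairs: list
    strand: str
    strand_note: str
    escapers: list[int]

    @property
    def top(self) -> EditPlan:
        return self.plans[0]

    def to_json(self) -> str:
        rows = []
        for k, (plan, oligo) in enumerate(zip(self.plans, self.oligos)):
            rows.append({
                "rank": k + 1,
                "top": k == 0,
                "desired": [f"{e.position + 1}:{e.ref}>{e.alt}" for e in plan.desired],
                "pam_1based": plan.site.pam_start + 1,
                "pam_strand": plan.site.strand,
                "spacer": plan.site.protospacer,
                "counterselection": [ce.describe() for ce in plan.counterselection],
                "verdict": plan.verdict,
                "warnings": plan.warnings,
                "oligo": {
                    "name": oligo.name,
                    "sequence": oligo.sequence,
                    "strand": oligo.strand,
                    "window_1based": [oligo.window_start + 1, oligo.window_end],
                },
                "seed_pam_duplicates_elsewhere": self.escapers[k],
            })
        return json.dumps({
            "name": self.request.name,
            "oligo_strand": self.strand,
            "strand_note": self.strand_note,
            "plans": rows,
        }, indent=2, sort_keys=True)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write the report bundle (TSV + FASTA + JSON); deterministic bytes."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}

        verdicts = [p.verdict for p in self.plans]
        tbl = sites_table([p.site for p in self.plans], verdicts)
        paths["sites"] = outdir / f"{self.request.name}.sites.tsv"
        tbl.to_csv(paths["sites"], sep="\t", index=False)

        paths["plans"] = outdir / f"{self.request.name}.plans.tsv"
        plan_table(self.plans).to_csv(paths["plans"], sep="\t", index=False)

        entries = []
        for k, (plan, oligo) in enumerate(zip(self.plans, self.oligos)):
            tag = f"{self.request.name}.rank{k + 1}"
            entries.append((f"{tag}.mage_oligo.{oligo.strand}", oligo.sequence))
            if self.sgrnas[k] is not None:
                entries.append((f"{tag}.sgrna", self.sgrnas[k].full_sequence))
            if self.user_pairs[k] is not None:
                entries.append((f"{tag}.user_fwd", self.user_pairs[k].forward))
                entries.append((f"{tag}.user_rev", self.user_pairs[k].reverse))
        paths["fasta"] = outdir / f"{self.request.name}.reagents.fasta"
        write_fasta(paths["fasta"], entries)

        paths["json"] = outdir / f"{self.request.name}.json"
        paths["json"].write_text(self.to_json() + "\n")
        return paths


def run_design(request: DesignRequest) -> DesignBundle:
    """Execute the full design for one locus.

    Plans the counter-selection, chooses the oligo strand (per the
    replichore convention when ``auto`` and configured, else ``+``),
    assembles the MAGE oligo for every ranked plan, and programs the sgRNA
    and USER pair when the config provides scaffold/tails.  Raises
    :class:`magecs.design.NoCounterselectionError` when no valid plan
    exists — callers surface that verbatim.
    """
    cfg = request.config
    genome = request.genome
    desired = [parse_edit(request.edit)]
    ctx = parse_frame(request.frame)
    if ctx is not None:
        ctx.validate(genome)

    plans = plan_counterselection(genome, desired, ctx,
                                  window_size=cfg.window_size)

    if request.strand_policy in ("+", "-"):
        strand, note = request.strand_policy, "strand fixed by request"
    elif cfg.ori is not None and cfg.ter is not None and genome.circular:
        strand = choose_strand(desired[0].position, cfg.ori, cfg.ter,
                               len(genome), cfg.strand_convention)
        note = (f"lagging-strand convention: ori={cfg.ori} ter={cfg.ter} "
                f"replichore map {cfg.strand_convention}")
    else:
        strand, note = "+", "no replichore configured; defaulted to +"

    size = request.oligo_size or cfg.oligo_size
    kept, oligos, sgrnas, pairs, escapers = [], [], [], [], []
    for plan in plans:
        # a ranked plan whose edit span cannot fit the oligo (with full
        # homology flanks) is unusable at this oligo size: drop it
        try:
            oligo = build_mage_oligo(
                genome, plan, size=size, strand=strand,
                name=f"{request.name}.rank{len(kept) + 1}",
                phosphorothioate_5prime=cfg.phosphorothioate_5prime)
        except InputError:
            continue
        kept.append(plan)
        oligos.append(oligo)
        sgrnas.append(build_sgrna(plan.site, cfg.scaffold) if cfg.scaffold else None)
        if cfg.tail_f and cfg.tail_r:
            pairs.append(build_user_pair(plan.site.protospacer, cfg.tail_f, cfg.tail_r))
        else:
            pairs.append(None)
        escapers.append(escaper_scan(genome, plan.site))
    if not kept:
        raise NoCounterselectionError(
            f"no plan fits a {size}-nt oligo with 20 nt of homology on each "
            "side of the combined edit span"
        )

    return DesignBundle(
        request=request,
        plans=kept,
        oligos=oligos,
        sgrnas=sgrnas,
        user_pairs=pairs,
        strand=strand,
        strand_note=note,
        escapers=escapers,
    )


def run_multiplex(requests: Sequence[DesignRequest]) -> list[DesignBundle]:
    """Plan several loci independently (one bundle per request)."""
    return [run_design(r) for r in requests]
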