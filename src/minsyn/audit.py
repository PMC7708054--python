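"""Junction-TFBS audit of assembled MinSyn designs.

Concatenating CREs, spacers and core elements can create binding sites that
none of the parts contain — a known failure mode of synthetic promoter
libraries, where such sites explain outliers between predicted and measured
strength.  The audit rescans the assembled sequence against a motif library
and classifies every hit:

* *intended* — wholly inside one CRE segment **and** matching a motif listed
  for that CRE (anything else inside a CRE still counts as unintended);
* *unintended* — everything else;
* *junction* — the unintended hits that straddle a segment boundary.

A design is flagged as soon as it has one unintended hit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .design import MinSynDesign
from .motifs import BackgroundModel, MotifHit, scan_sequence

__all__ = ["AuditReport", "audit_design"]


@dataclass(frozen=True)
class AuditReport:
    design_id: str
    intended_hits: tuple[MotifHit, ...]
    unintended_hits: tuple[MotifHit, ...]
    junction_hits: tuple[MotifHit, ...]

    def __post_init__(self) -> None:
        if not set(self.junction_hits) <= set(self.unintended_hits):
            raise ValueError("junction hits must be a subset of unintended hits")

    @property
    def verdict(self) -> str:
        return "flagged" if self.unintended_hits else "clean"

    @property
    def all_hits(self) -> tuple[MotifHit, ...]:
        return tuple(sorted(self.intended_hits + self.unintended_hits, key=lambda h: h.sort_key))


def audit_design(
    design: MinSynDesign,
    motifs,
    bg: BackgroundModel,
    p: float,
) -> AuditReport:
    """Rescan an assembled design and classify every motif hit."""
    coords = design.coordinates()
    sequence = design.sequence
    hits = scan_sequence(sequence, motifs, bg, p, sequence_id=design.design_id)
    # internal boundaries between consecutive segments
    boundaries = {start for _, start, _ in coords if start > 0}
    cre_spans = [
        (start, end, seg.motif_ids)
        for seg, start, end in coords
        if seg.kind == "cre"
    ]
    intended, unintended, junction = [], [], []
    for h in hits:
        is_intended = any(
            start <= h.start and h.end <= end and h.motif_id in motif_ids
            for start, end, motif_ids in cre_spans
        )
        if is_intended:
            intended.append(h)
            continue
        unintended.append(h)
        if any(h.start < b < h.end for b in boundaries):
            junction.append(h)
    return AuditReport(
        design_id=design.design_id,
        intended_hits=tuple(intended),
        unintended_hits=tuple(unintended),
        junction_hits=tuple(junction),
    )
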