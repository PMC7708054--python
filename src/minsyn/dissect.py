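"""Candidate-CRE annotation of natural promoters and in-silico variants.

``annotate_promoter`` maps motif hits back onto a promoter and collapses
overlapping hits of the same motif family into candidate CRE regions.  The
variant builders reproduce the two classic promoter-dissection perturbations:
clean deletion of a region, and relocation of a region to a distal / mid /
proximal slot relative to the TATA box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .motifs import BackgroundModel, MotifHit, scan_sequence

__all__ = [
    "PromoterAnnotation",
    "annotate_promoter",
    "presence_matrix",
    "deletion_variant",
    "relocation_variant",
    "SLOTS",
]

SLOTS = ("distal", "mid", "proximal")


@dataclass
class PromoterAnnotation:
    sequence_id: str
    sequence: str
    hits: list[MotifHit] = field(default_factory=list)
    cre_regions: list[tuple[str, int, int]] = field(default_factory=list)
    tata_start: int | None = None

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for cre_id, start, end in self.cre_regions:
            if not 0 <= start < end <= n:
                raise ValueError(f"region {cre_id} [{start}, {end}) outside sequence")
        if self.tata_start is not None and not 0 <= self.tata_start < n:
            raise ValueError(f"tata_start {self.tata_start} outside sequence")

    def region(self, cre_id: str) -> tuple[int, int]:
        for rid, start, end in self.cre_regions:
            if rid == cre_id:
                return start, end
        raise KeyError(f"no CRE region {cre_id!r} in {self.sequence_id}")


def _merge_same_motif(hits: list[MotifHit]) -> list[tuple[str, int, int]]:
    """Merge strictly overlapping hits of the same motif into regions.

    Region ids are ``{motif_id}_{ordinal}``; abutting hits stay separate.
    """
    regions: list[tuple[str, int, int]] = []
    by_motif: dict[str, list[MotifHit]] = {}
    for h in hits:
        by_motif.setdefault(h.motif_id, []).append(h)
    for motif_id in sorted(by_motif):
        merged: list[list[int]] = []
        for h in sorted(by_motif[motif_id], key=lambda h: (h.start, h.end)):
            if merged and h.start < merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], h.end)
            else:
                merged.append([h.start, h.end])
        for i, (start, end) in enumerate(merged, 1):
            regions.append((f"{motif_id}_{i}", start, end))
    regions.sort(key=lambda r: (r[1], r[2], r[0]))
    return regions


def annotate_promoter(
    sequence_id: str,
    sequence: str,
    motifs,
    bg: BackgroundModel,
    p: float,
    tata_start: int | None = None,
) -> PromoterAnnotation:
    """Scan a promoter and derive candidate CRE regions from the hits."""
    hits = scan_sequence(sequence, motifs, bg, p, sequence_id=sequence_id)
    return PromoterAnnotation(
        sequence_id=sequence_id,
        sequence=sequence,
        hits=hits,
        cre_regions=_merge_same_motif(hits),
        tata_start=tata_start,
    )


def presence_matrix(annotations, motif_ids=None) -> pd.DataFrame:
    """Boolean promoter x motif matrix: True iff >= 1 hit at the scan threshold.

    Row order follows the input annotations; column order follows
    ``motif_ids`` when given, else first appearance across annotations.
    """
    annotations = list(annotations)
    if not annotations:
        raise ValueError("need at least one annotation")
    if motif_ids is None:
        seen: list[str] = []
        for ann in annotations:
            for h in ann.hits:
                if h.motif_id not in seen:
                    seen.append(h.motif_id)
        motif_ids = seen
    data = {
        mid: [any(h.motif_id == mid for h in ann.hits) for ann in annotations]
        for mid in motif_ids
    }
    return pd.DataFrame(data, index=[ann.sequence_id for ann in annotations], columns=list(motif_ids))


def deletion_variant(ann: PromoterAnnotation, cre_id: str) -> str:
    """Promoter with the named CRE region cleanly excised (no scar)."""
    start, end = ann.region(cre_id)
    return ann.sequence[:start] + ann.sequence[end:]


def relocation_variant(
    ann: PromoterAnnotation,
    cre_id: str,
    slot: str,
    proximal_gap: int = 10,
) -> str:
    """Move a CRE region so its 3' edge sits at a slot-defined distance
    upstream of the TATA box; total length is conserved.

    Gaps (bases between the region's 3' edge and the first TATA base, in the
    rearranged sequence): ``proximal`` = ``proximal_gap``; ``mid`` = half the
    available upstream span; ``distal`` = the whole upstream span (region at
    the 5' end).
    """
    if slot not in SLOTS:
        raise ValueError(f"slot must be one of {SLOTS}, got {slot!r}")
    if ann.tata_start is None:
        raise ValueError(f"{ann.sequence_id}: relocation requires tata_start")
    start, end = ann.region(cre_id)
    if end > ann.tata_start:
        raise ValueError(f"region {cre_id} is not upstream of the TATA box")
    region = ann.sequence[start:end]
    rest = ann.sequence[:start] + ann.sequence[end:]
    upstream_span = ann.tata_start - len(region)  # bases upstream of TATA in `rest`
    if slot == "proximal":
        gap = proximal_gap
    elif slot == "mid":
        gap = upstream_span // 2
    else:
        gap = upstream_span
    if gap > upstream_span:
        raise ValueError(
            f"slot {slot!r} needs a {gap} bp gap but only {upstream_span} bp "
            f"of upstream span is available"
        )
    insert_at = upstream_span - gap
    return rest[:insert_at] + region + rest[insert_at:]
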