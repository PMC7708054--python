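"""The pool of candidate cis-regulatory elements (CREs) MinSyns are built from.

A CRE is a short promoter segment predicted to bind one or more transcription
factors.  The pool distinguishes three classes: GENERIC elements, and two
kinds of "common CRE" (C-CRE) — the element shared by the pathogen-derived
constitutive promoters — split by whether direct TGA/bZIP binding is
predicted.  The class drives the strength model's proximity weighting.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GENERIC",
    "C_CRE_TGA",
    "C_CRE_NON_TGA",
    "CRE_CLASSES",
    "CRERecord",
    "CREPool",
    "PoolError",
    "build_pool",
    "load_pool",
    "save_pool",
]

GENERIC = "GENERIC"
C_CRE_TGA = "C_CRE_TGA"
C_CRE_NON_TGA = "C_CRE_NON_TGA"
CRE_CLASSES = frozenset({GENERIC, C_CRE_TGA, C_CRE_NON_TGA})
#: the two C-CRE classes, which take TATA-proximity weights
CCRE_CLASSES = frozenset({C_CRE_TGA, C_CRE_NON_TGA})

_POOL_COLUMNS = [
    "cre_id",
    "class",
    "sequence",
    "source_promoter",
    "flank5",
    "flank3",
    "motif_ids",
]


class PoolError(ValueError):
    pass


def _check_dna(seq: str, what: str) -> None:
    if set(seq) - set("ACGT"):
        raise PoolError(f"{what}: non-DNA characters in {seq!r}")


@dataclass(frozen=True)
class CRERecord:
    """One candidate CRE: its sequence, class and provenance.

    ``flank5``/``flank3`` carry native flanking sequence from the source
    promoter (used when rebuilding native-context variants); ``motif_ids``
    lists the motifs expected to bind within this element, which the junction
    audit treats as *intended* hits.
    """

    cre_id: str
    sequence: str
    cre_class: str
    source_promoter: str = ""
    flank5: str = ""
    flank3: str = ""
    motif_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.cre_class not in CRE_CLASSES:
            raise PoolError(
                f"CRE {self.cre_id}: illegal class {self.cre_class!r} "
                f"(expected one of {sorted(CRE_CLASSES)})"
            )
        if not 4 <= len(self.sequence) <= 40:
            raise PoolError(
                f"CRE {self.cre_id}: sequence length {len(self.sequence)} outside [4, 40]"
            )
        _check_dna(self.sequence, f"CRE {self.cre_id}")
        for flank in (self.flank5, self.flank3):
            if flank:
                _check_dna(flank, f"CRE {self.cre_id} flank")
        object.__setattr__(self, "motif_ids", tuple(self.motif_ids))


@dataclass
class CREPool:
    records: list[CRERecord] = field(default_factory=list)
    provenance: str = ""
    version: str = "1"

    def __post_init__(self) -> None:
        ids = [r.cre_id for r in self.records]
        dupes = {i for i in ids if ids.count(i) > 1}
        if dupes:
            raise PoolError(f"duplicate cre_ids in pool: {sorted(dupes)}")

    def __len__(self) -> int:
        return len(self.records)

    def __eq__(self, other) -> bool:
        if not isinstance(other, CREPool):
            return NotImplemented
        return (
            self.records == other.records
            and self.provenance == other.provenance
            and self.version == other.version
        )

    def by_id(self, cre_id: str) -> CRERecord:
        for r in self.records:
            if r.cre_id == cre_id:
                return r
        raise KeyError(cre_id)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in sorted(CRE_CLASSES)}
        for r in self.records:
            counts[r.cre_class] += 1
        return counts


def build_pool(
    hits,
    class_assignments: pd.DataFrame,
    promoter_seqs: dict[str, str],
    flank_len: int = 10,
    provenance: str = "",
) -> CREPool:
    """Excise assigned CRE regions from promoters into a :class:`CREPool`.

    ``class_assignments`` needs columns ``cre_id, promoter_id, start, end,
    class`` and optionally ``motif_ids`` (comma-separated).  Each assigned
    region must lie within its promoter and, when ``hits`` are supplied,
    overlap at least one scanned hit there.  Flanks of up to ``flank_len``
    bases are captured from the promoter on each side.
    """
    records = []
    hits = list(hits) if hits is not None else []
    for _, row in class_assignments.iterrows():
        cre_id = str(row["cre_id"])
        prom_id = str(row["promoter_id"])
        if prom_id not in promoter_seqs:
            raise PoolError(f"CRE {cre_id}: unknown promoter {prom_id!r}")
        seq = promoter_seqs[prom_id]
        start, end = int(row["start"]), int(row["end"])
        if not 0 <= start < end <= len(seq):
            raise PoolError(
                f"CRE {cre_id}: region [{start}, {end}) outside promoter "
                f"{prom_id} (length {len(seq)})"
            )
        if hits:
            overlapping = [
                h
                for h in hits
                if h.sequence_id == prom_id and h.start < end and start < h.end
            ]
            if not overlapping:
                raise PoolError(
                    f"CRE {cre_id}: region [{start}, {end}) in {prom_id} "
                    "overlaps no scanned hit"
                )
        motif_ids: tuple[str, ...] = ()
        if "motif_ids" in row.index and pd.notna(row.get("motif_ids")) and str(row["motif_ids"]):
            motif_ids = tuple(str(row["motif_ids"]).split(","))
        records.append(
            CRERecord(
                cre_id=cre_id,
                sequence=seq[start:end],
                cre_class=str(row["class"]),
                source_promoter=prom_id,
                flank5=seq[max(0, start - flank_len) : start],
                flank3=seq[end : end + flank_len],
                motif_ids=motif_ids,
            )
        )
    return CREPool(records=records, provenance=provenance)


def save_pool(pool: CREPool, path) -> None:
    """Write the pool as TSV with a ``#`` provenance/version header."""
    rows = [
        {
            "cre_id": r.cre_id,
            "class": r.cre_class,
            "sequence": r.sequence,
            "source_promoter": r.source_promoter,
            "flank5": r.flank5,
            "flank3": r.flank3,
            "motif_ids": ",".join(r.motif_ids),
        }
        for r in pool.records
    ]
    frame = pd.DataFrame(rows, columns=_POOL_COLUMNS)
    with open(path, "w", newline="") as fh:
        fh.write(f"# minsyn CRE pool\tversion={pool.version}\tprovenance={pool.provenance}\n")
        frame.to_csv(fh, sep="\t", index=False)


def load_pool(path) -> CREPool:
    """Load a pool TSV written by :func:`save_pool`; validates every row."""
    with open(path, newline="") as fh:
        first = fh.readline()
        version, provenance = "1", ""
        line_offset = 2  # 1-based line of the first data row minus the frame index
        if first.startswith("#"):
            line_offset = 3
            for part in first.lstrip("#").strip().split("\t"):
                if part.startswith("version="):
                    version = part.split("=", 1)[1]
                elif part.startswith("provenance="):
                    provenance = part.split("=", 1)[1]
            body = fh.read()
        else:
            body = first + fh.read()
    frame = pd.read_csv(io.StringIO(body), sep="\t", dtype=str).fillna("")
    missing = set(_POOL_COLUMNS[:3]) - set(frame.columns)
    if missing:
        raise PoolError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for i, row in frame.iterrows():
        try:
            records.append(
                CRERecord(
                    cre_id=row["cre_id"],
                    sequence=row["sequence"],
                    cre_class=row["class"],
                    source_promoter=row.get("source_promoter", ""),
                    flank5=row.get("flank5", ""),
                    flank3=row.get("flank3", ""),
                    motif_ids=tuple(x for x in row.get("motif_ids", "").split(",") if x),
                )
            )
        except PoolError as exc:
            raise PoolError(f"{path}, line {i + line_offset}: {exc}") from exc
    try:
        return CREPool(records=records, provenance=provenance, version=version)
    except PoolError as exc:
        raise PoolError(f"{path}: {exc}") from exc
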