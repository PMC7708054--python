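"""Stochastic assembly of minimal synthetic promoters (MinSyns).

Every MinSyn follows the fixed architecture

    prefix(19 nt random) . (spacer . CRE)^N . TATATAA . core(43 nt)

For the constitutive library, N is drawn uniformly from [3, 10], each spacer
is a fresh random sequence of uniform length in [5, 30] nt, and the N CREs are
drawn uniformly *without replacement* from the pool, so no design repeats an
element.  Because each spacer precedes its CRE, the last CRE abuts the TATA
box — the position where C-CRE activity is strongest.  The orthogonal-array
builder instead tiles k copies of one synthetic-TF binding site with short
fixed-length spacers, giving promoters whose strength tracks copy number.

All randomness flows from a single numpy Generator, so a (pool, config) pair
reproduces a library byte for byte.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .pool import CREPool, CRERecord, GENERIC

__all__ = [
    "DEFAULT_TATA",
    "DEFAULT_CORE",
    "GeneratorConfig",
    "Segment",
    "MinSynDesign",
    "MinSynLibrary",
    "random_dna",
    "sample_design",
    "assemble_sequence",
    "generate_library",
    "build_orthogonal_minsyn",
]

DEFAULT_TATA = "TATATAA"
# Synthetic stand-in for the 43 nt minimal core + TSS (generated once, fixed);
# replace via GeneratorConfig.core_seq to use a core of known provenance.
DEFAULT_CORE = "GATCAGTCTAAATCTCTTTTTCTGATACCCACAGAACAGTTGG"

SEGMENT_KINDS = ("prefix", "spacer", "cre", "tata", "core")


@dataclass(frozen=True)
class GeneratorConfig:
    """Architecture and sampling parameters for the constitutive library."""

    n_cre_min: int = 3
    n_cre_max: int = 10
    spacer_min: int = 5
    spacer_max: int = 30
    prefix_len: int = 19
    tata_seq: str = DEFAULT_TATA
    core_seq: str = DEFAULT_CORE
    library_size: int = 1000
    rng_seed: int = 0
    gc_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 1 <= self.n_cre_min <= self.n_cre_max:
            raise ValueError("need 1 <= n_cre_min <= n_cre_max")
        if not 0 <= self.spacer_min <= self.spacer_max:
            raise ValueError("need 0 <= spacer_min <= spacer_max")
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        for name in ("tata_seq", "core_seq"):
            seq = getattr(self, name)
            if not seq or set(seq) - set("ACGT"):
                raise ValueError(f"{name} must be non-empty DNA")

    @property
    def core_len(self) -> int:
        return len(self.core_seq)


@dataclass(frozen=True)
class Segment:
    """One architectural block of a design; ``cre_*`` set only for kind 'cre'."""

    kind: str
    text: str
    cre_id: str | None = None
    cre_class: str | None = None
    motif_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in SEGMENT_KINDS:
            raise ValueError(f"unknown segment kind {self.kind!r}")
        if self.kind == "cre" and self.cre_id is None:
            raise ValueError("cre segment needs a cre_id")
        object.__setattr__(self, "motif_ids", tuple(self.motif_ids))

    @classmethod
    def from_record(cls, record: CRERecord) -> "Segment":
        return cls(
            kind="cre",
            text=record.sequence,
            cre_id=record.cre_id,
            cre_class=record.cre_class,
            motif_ids=record.motif_ids,
        )


@dataclass(frozen=True)
class MinSynDesign:
    design_id: str
    segments: tuple[Segment, ...]
    rng_seed: int | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "segments", tuple(self.segments))
        if sum(1 for s in self.segments if s.kind == "tata") != 1:
            raise ValueError(f"design {self.design_id}: exactly one tata segment required")
        cre_ids = [s.cre_id for s in self.segments if s.kind == "cre"]
        if len(set(cre_ids)) != len(cre_ids):
            raise ValueError(f"design {self.design_id}: repeated cre_id (without-replacement)")

    @property
    def sequence(self) -> str:
        return "".join(s.text for s in self.segments)

    @property
    def n_cre(self) -> int:
        return sum(1 for s in self.segments if s.kind == "cre")

    def coordinates(self) -> list[tuple[Segment, int, int]]:
        """Each segment with its 0-based half-open span in the assembled sequence."""
        out = []
        pos = 0
        for seg in self.segments:
            out.append((seg, pos, pos + len(seg.text)))
            pos += len(seg.text)
        return out

    @property
    def tata_start(self) -> int:
        for seg, start, _ in self.coordinates():
            if seg.kind == "tata":
                return start
        raise ValueError("no tata segment")  # unreachable: enforced in __post_init__

    def feature_table(self) -> pd.DataFrame:
        rows = [
            {
                "design_id": self.design_id,
                "kind": seg.kind,
                "start": start,
                "end": end,
                "cre_id": seg.cre_id or "",
                "cre_class": seg.cre_class or "",
            }
            for seg, start, end in self.coordinates()
        ]
        return pd.DataFrame(rows, columns=["design_id", "kind", "start", "end", "cre_id", "cre_class"])


@dataclass
class MinSynLibrary:
    designs: list[MinSynDesign]
    config: GeneratorConfig
    pool_version: str = "1"

    def __post_init__(self) -> None:
        ids = [d.design_id for d in self.designs]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate design_ids in library")

    def __len__(self) -> int:
        return len(self.designs)


_BASES = np.array(list("ACGT"))


def random_dna(rng: np.random.Generator, length: int, gc_fraction: float = 0.5) -> str:
    """i.i.d. random DNA with the given expected GC content."""
    at, gc = (1 - gc_fraction) / 2, gc_fraction / 2
    return "".join(rng.choice(_BASES, size=length, p=[at, gc, gc, at]))


def sample_design(
    pool: CREPool,
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    design_id: str = "MinSyn",
) -> MinSynDesign:
    """Draw one MinSyn: N ~ U[n_cre_min, n_cre_max]; per CRE a fresh random
    spacer (length U[spacer_min, spacer_max]) then a CRE sampled uniformly
    without replacement; framed by the random prefix and the TATA + core."""
    if len(pool) < cfg.n_cre_max:
        raise ValueError(
            f"pool of {len(pool)} CREs cannot support without-replacement draws "
            f"of up to {cfg.n_cre_max}"
        )
    n = int(rng.integers(cfg.n_cre_min, cfg.n_cre_max + 1))
    order = rng.choice(len(pool), size=n, replace=False)
    segments = [Segment("prefix", random_dna(rng, cfg.prefix_len, cfg.gc_fraction))]
    for idx in order:
        spacer_len = int(rng.integers(cfg.spacer_min, cfg.spacer_max + 1))
        segments.append(Segment("spacer", random_dna(rng, spacer_len, cfg.gc_fraction)))
        segments.append(Segment.from_record(pool.records[int(idx)]))
    segments.append(Segment("tata", cfg.tata_seq))
    segments.append(Segment("core", cfg.core_seq))
    return MinSynDesign(design_id=design_id, segments=tuple(segments), rng_seed=cfg.rng_seed)


def assemble_sequence(design: MinSynDesign) -> tuple[str, pd.DataFrame]:
    """The assembled promoter sequence and its per-segment feature table."""
    return design.sequence, design.feature_table()


def generate_library(pool: CREPool, cfg: GeneratorConfig) -> MinSynLibrary:
    """Generate ``cfg.library_size`` designs from one seeded random stream."""
    rng = np.random.default_rng(cfg.rng_seed)
    width = max(3, len(str(cfg.library_size)))
    designs = [
        sample_design(pool, cfg, rng, design_id=f"MinSyn{i + 1:0{width}d}")
        for i in range(cfg.library_size)
    ]
    return MinSynLibrary(designs=designs, config=cfg, pool_version=pool.version)


def build_orthogonal_minsyn(
    binding_site: str,
    copies: int,
    cfg: GeneratorConfig | None = None,
    rng: np.random.Generator | None = None,
    spacer_len: int = 5,
    design_id: str | None = None,
) -> MinSynDesign:
    """Array of ``copies`` identical synthetic-TF binding sites in the variable
    region, separated by fixed-length random spacers.

    With k = 0 the design collapses to prefix + TATA + core (the no-site
    control).  Expression of such promoters tracks k, so a copies series gives
    a strength ladder driven by one orthogonal TF.
    """
    if copies < 0:
        raise ValueError("copies must be >= 0")
    if not binding_site or set(binding_site.upper()) - set("ACGT"):
        raise ValueError("binding_site must be non-empty DNA")
    cfg = cfg or GeneratorConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.rng_seed)
    site = binding_site.upper()
    segments = [Segment("prefix", random_dna(rng, cfg.prefix_len, cfg.gc_fraction))]
    for i in range(copies):
        if i > 0:
            segments.append(Segment("spacer", random_dna(rng, spacer_len, cfg.gc_fraction)))
        segments.append(
            Segment("cre", site, cre_id=f"site{i + 1}", cre_class=GENERIC)
        )
    segments.append(Segment("tata", cfg.tata_seq))
    segments.append(Segment("core", cfg.core_seq))
    return MinSynDesign(
        design_id=design_id or f"OrthoMinSyn_x{copies}",
        segments=tuple(segments),
        rng_seed=cfg.rng_seed,
    )
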