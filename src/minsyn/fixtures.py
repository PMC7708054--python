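"""Seeded synthetic inputs emulating the promoter-design study's data.

The generator produces the four inputs the pipeline consumes, with the same
structure as the real ones but fully synthetic content:

* a library of sharp position probability matrices (consensus-dominated
  columns), the two TGA-binding motifs carrying the TGACG core of the as-1
  element;
* promoter sequences with motif instances planted at recorded coordinates
  (ground truth for scanner recovery);
* a CRE pool mirroring the study's composition — two TGA-binding C-CREs, one
  non-TGA C-CRE and twelve generic elements, each CRE being the consensus of
  one motif in the library;
* a measured-strength table for calibration tests, generated as
  ``k_true * raw_score + Gaussian noise`` over a small design set, emulating
  ratiometric protoplast assay measurements.

Everything flows from one seed; identical specs give byte-identical files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import GeneratorConfig, MinSynLibrary, generate_library
from .motifs import Motif, write_meme_motifs
from .pool import C_CRE_NON_TGA, C_CRE_TGA, GENERIC, CREPool, CRERecord, save_pool
from .strength import StrengthModel, raw_score
from . import io as minsyn_io

__all__ = ["FixtureSpec", "FixtureBundle", "generate_fixtures"]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class FixtureSpec:
    """Shape of the synthetic dataset.

    Defaults mirror the study conditions: a pool of 2 + 1 + 12 CREs, a
    24-design measured set (the number of library members synthesized and
    assayed), and motif widths 8–12 so a consensus match clears the 1e-4
    p-value threshold (a width-w consensus has exact p-value 4^-w under the
    uniform background).
    """

    n_motifs: int = 15
    width_min: int = 8
    width_max: int = 12
    n_promoters: int = 6
    promoter_length: int = 300
    planted_per_promoter: int = 3
    n_tga_ccre: int = 2
    n_nontga_ccre: int = 1
    n_generic: int = 12
    n_measured: int = 24
    k_true: float = 2.5
    noise_sd: float = 0.12
    consensus_prob: float = 0.97
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.width_min < 4:
            raise ValueError("motif widths must be >= 4")
        if self.width_max > self.promoter_length:
            raise ValueError("motif longer than promoter: planting infeasible")
        if self.pool_size != self.n_motifs:
            raise ValueError(
                "fixture pool is one CRE per motif: n_motifs must equal "
                f"pool size {self.pool_size}"
            )

    @property
    def pool_size(self) -> int:
        return self.n_tga_ccre + self.n_nontga_ccre + self.n_generic


@dataclass
class FixtureBundle:
    motifs: list[Motif]
    promoters: list[tuple[str, str]]
    planted: pd.DataFrame  # promoter_id, motif_id, start, end
    pool: CREPool
    measured: pd.DataFrame  # design_id, normalized_expression
    measured_library: MinSynLibrary


def _sharp_ppm(rng: np.random.Generator, consensus: str, consensus_prob: float) -> np.ndarray:
    ppm = np.full((len(consensus), 4), (1 - consensus_prob) / 3)
    for i, base in enumerate(consensus):
        ppm[i, "ACGT".index(base)] = consensus_prob
    return ppm


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def generate_fixtures(spec: FixtureSpec, outdir=None) -> FixtureBundle:
    """Build the synthetic dataset; optionally write it to ``outdir``.

    Files written: ``motifs.meme``, ``promoters.fasta``, ``pool.tsv``,
    ``measured_strength.tsv`` and ``planted.tsv`` (the ground-truth plant
    coordinates).
    """
    rng = np.random.default_rng(spec.rng_seed)

    # motifs: the first n_tga_ccre carry the TGACG bZIP core
    motifs: list[Motif] = []
    for i in range(spec.n_motifs):
        width = int(rng.integers(spec.width_min, spec.width_max + 1))
        consensus = _random_dna(rng, width)
        if i < spec.n_tga_ccre:
            consensus = "TGACG" + consensus[5:]
        motifs.append(
            Motif.from_raw_ppm(
                f"M{i + 1:02d}",
                _sharp_ppm(rng, consensus, spec.consensus_prob),
                source="synthetic",
            )
        )

    # promoters with planted, non-overlapping motif instances
    promoters: list[tuple[str, str]] = []
    planted_rows = []
    for j in range(spec.n_promoters):
        seq = list(_random_dna(rng, spec.promoter_length))
        occupied: list[tuple[int, int]] = []
        planted = 0
        attempts = 0
        while planted < spec.planted_per_promoter and attempts < 1000:
            attempts += 1
            motif = motifs[int(rng.integers(len(motifs)))]
            start = int(rng.integers(0, spec.promoter_length - motif.width + 1))
            end = start + motif.width
            if any(start < e and s < end for s, e in occupied):
                continue
            seq[start:end] = list(motif.consensus)
            occupied.append((start, end))
            planted_rows.append(
                {
                    "promoter_id": f"prom{j + 1}",
                    "motif_id": motif.id,
                    "start": start,
                    "end": end,
                }
            )
            planted += 1
        if planted < spec.planted_per_promoter:
            raise ValueError("could not place planted motifs without overlap")
        promoters.append((f"prom{j + 1}", "".join(seq)))
    planted_df = pd.DataFrame(
        planted_rows, columns=["promoter_id", "motif_id", "start", "end"]
    ).sort_values(["promoter_id", "start"], ignore_index=True)

    # pool: one CRE per motif, classes in spec proportions
    classes = (
        [C_CRE_TGA] * spec.n_tga_ccre
        + [C_CRE_NON_TGA] * spec.n_nontga_ccre
        + [GENERIC] * spec.n_generic
    )
    records = []
    for i, (motif, cls) in enumerate(zip(motifs, classes)):
        records.append(
            CRERecord(
                cre_id=f"CRE{i + 1:02d}",
                sequence=motif.consensus,
                cre_class=cls,
                source_promoter="synthetic",
                flank5=_random_dna(rng, 10),
                flank3=_random_dna(rng, 10),
                motif_ids=(motif.id,),
            )
        )
    pool = CREPool(records=records, provenance="synthetic fixture pool", version="fixture-1")

    # measured strengths: k_true * raw_score + Gaussian noise over a small set
    # seeded with the fixture seed so `calibrate` can regenerate these designs
    # from (pool, seed, size) alone
    cfg = GeneratorConfig(library_size=spec.n_measured, rng_seed=spec.rng_seed)
    measured_library = generate_library(pool, cfg)
    model = StrengthModel()
    raws = np.array([raw_score(d, model) for d in measured_library.designs])
    noise = rng.normal(0.0, spec.noise_sd, size=len(raws))
    measured = pd.DataFrame(
        {
            "design_id": [d.design_id for d in measured_library.designs],
            "normalized_expression": np.maximum(spec.k_true * raws + noise, 0.0),
        }
    )

    bundle = FixtureBundle(
        motifs=motifs,
        promoters=promoters,
        planted=planted_df,
        pool=pool,
        measured=measured,
        measured_library=measured_library,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_meme_motifs(motifs, outdir / "motifs.meme")
        minsyn_io.write_fasta(promoters, outdir / "promoters.fasta")
        save_pool(pool, outdir / "pool.tsv")
        measured.to_csv(outdir / "measured_strength.tsv", sep="\t", index=False)
        planted_df.to_csv(outdir / "planted.tsv", sep="\t", index=False)
    return bundle
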