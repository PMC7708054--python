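import numpy as np
import pytest

from minsyn import (
    BackgroundModel,
    FixtureSpec,
    GeneratorConfig,
    Motif,
    Segment,
    MinSynDesign,
    generate_fixtures,
)
from minsyn.design import DEFAULT_CORE, DEFAULT_TATA
from minsyn.pool import GENERIC


@pytest.fixture(scope="session")
def bg():
    return BackgroundModel.uniform()


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic dataset: 15 sharp motifs, 6 promoters with planted
    sites, a 2+1+12 CRE pool and a 24-design measured-strength table."""
    return generate_fixtures(FixtureSpec(rng_seed=0))


@pytest.fixture(scope="session")
def pool(bundle):
    return bundle.pool


@pytest.fixture(scope="session")
def soft_motifs():
    """Small motifs (width <= 6) with graded columns, for enumeration oracles."""
    rng = np.random.default_rng(7)
    motifs = []
    for i, width in enumerate((3, 4, 5, 6, 6)):
        raw = rng.dirichlet(np.full(4, 0.8), size=width)
        motifs.append(Motif.from_raw_ppm(f"soft{i + 1}", raw))
    return motifs


def make_design(design_id, parts, rng_seed=None):
    """Build a MinSynDesign from (kind, text[, cre_id, cre_class, motif_ids])
    tuples, appending the default TATA + core when absent."""
    segments = []
    for part in parts:
        kind, text = part[0], part[1]
        cre_id = part[2] if len(part) > 2 else None
        cre_class = part[3] if len(part) > 3 else (GENERIC if kind == "cre" else None)
        motif_ids = part[4] if len(part) > 4 else ()
        segments.append(Segment(kind, text, cre_id=cre_id, cre_class=cre_class, motif_ids=motif_ids))
    kinds = {s.kind for s in segments}
    if "tata" not in kinds:
        segments.append(Segment("tata", DEFAULT_TATA))
    if "core" not in kinds:
        segments.append(Segment("core", DEFAULT_CORE))
    return MinSynDesign(design_id=design_id, segments=tuple(segments), rng_seed=rng_seed)
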