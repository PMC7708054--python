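"""Per-base promoter strength scoring with TATA-proximity weighting.

The model encodes three experimental observations about MinSyn behaviour:

* bases inside CREs contribute to strength; bases inside C-CREs contribute
  more;
* C-CRE contribution falls off with distance from the TATA box — TGA-binding
  C-CREs act at full strength only within 60 bp of the TATA box, non-TGA
  C-CREs within 130 bp; past the plateau the weight decays linearly to zero
  over ``decay_span`` (default 70 bp);
* when more than 50 bp separate the most TATA-proximal CRE from the TATA box,
  overall expression drops — modelled as a linear penalty on the summed score;
* with two or more C-CREs, the bases between the outermost pair pick up an
  extra contribution weighted by the distance of the region's midpoint to the
  TATA box (cooperative interaction between the elements).

The raw score of a design is the per-base sum divided by total length.  A
single calibration scalar k (least squares through the origin against measured
normalized expression) converts raw scores to predicted strengths.

The three distance breakpoints (60, 130 and 50 bp) are measured quantities;
the per-base score magnitudes and the linear decay are declared model
constants, all configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .design import MinSynDesign
from .pool import C_CRE_NON_TGA, C_CRE_TGA, CCRE_CLASSES, GENERIC

__all__ = [
    "StrengthModel",
    "CalibrationDiagnostics",
    "proximity_weight",
    "raw_score",
    "calibrate",
    "predict_strength",
    "score_library",
]


@dataclass(frozen=True)
class StrengthModel:
    """Scoring constants and, once fitted, the calibration scalar.

    Distances are in bases, measured from a C-CRE's TATA-proximal (3') edge
    to the first base of the TATA box; 0 means abutting.
    """

    s_generic: float = 1.0
    s_ccre: float = 2.0
    s_between: float = 0.5
    plateau_tga: int = 60
    plateau_nontga: int = 130
    generic_gap_limit: int = 50
    decay_span: int = 70
    calibration_k: float | None = None

    def __post_init__(self) -> None:
        for name in ("s_generic", "s_ccre", "s_between"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("plateau_tga", "plateau_nontga", "generic_gap_limit"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.decay_span <= 0:
            raise ValueError("decay_span must be > 0")
        if self.calibration_k is not None and self.calibration_k <= 0:
            raise ValueError("calibration_k must be > 0 once fitted")

    def plateau(self, cre_class: str) -> int:
        if cre_class == C_CRE_TGA:
            return self.plateau_tga
        if cre_class == C_CRE_NON_TGA:
            return self.plateau_nontga
        raise ValueError(f"no proximity plateau for class {cre_class!r}")


@dataclass(frozen=True)
class CalibrationDiagnostics:
    n_points: int
    calibration_k: float
    r_squared: float
    residuals: pd.DataFrame  # columns: raw_score, measured, predicted, residual


def proximity_weight(
    distance_to_tata: float, cre_class: str, model: StrengthModel | None = None
) -> float:
    """TATA-proximity weight in [0, 1] for a C-CRE class.

    1 on the class plateau (<= 60 bp for TGA-binding, <= 130 bp otherwise),
    then linear to 0 over ``decay_span`` bases, 0 beyond.  GENERIC elements
    have no proximity weight (the design-level gap rule covers them) and
    raise ``ValueError``.
    """
    model = model or StrengthModel()
    if cre_class not in CCRE_CLASSES:
        raise ValueError(
            f"proximity_weight applies to C-CRE classes only, not {cre_class!r}"
        )
    if distance_to_tata < 0:
        raise ValueError("distance must be >= 0")
    plateau = model.plateau(cre_class)
    if distance_to_tata <= plateau:
        return 1.0
    excess = distance_to_tata - plateau
    if excess >= model.decay_span:
        return 0.0
    return 1.0 - excess / model.decay_span


def _gap_penalty(gap: float, model: StrengthModel) -> float:
    """Penalty on the summed score when the last CRE sits too far upstream."""
    if gap <= model.generic_gap_limit:
        return 1.0
    excess = gap - model.generic_gap_limit
    if excess >= model.decay_span:
        return 0.0
    return 1.0 - excess / model.decay_span


def raw_score(design: MinSynDesign, model: StrengthModel | None = None) -> float:
    """Mean per-base score of an assembled design.

    Per base: 0 by default; ``s_generic`` inside GENERIC CREs; ``s_ccre`` times
    the class proximity weight inside C-CREs; plus, when the design holds two
    or more C-CREs, ``s_between`` times the TGA-schedule weight of the
    midpoint for every base strictly between the outermost C-CRE pair.  The
    summed score is multiplied by the first-CRE gap penalty and divided by the
    total length.
    """
    model = model or StrengthModel()
    coords = design.coordinates()
    total_len = sum(end - start for _, start, end in coords)
    if total_len == 0:
        raise ValueError("empty design")
    tata_start = design.tata_start
    scores = np.zeros(total_len)
    ccre_spans: list[tuple[int, int]] = []
    last_cre_end: int | None = None
    for seg, start, end in coords:
        if seg.kind != "cre":
            continue
        if end > tata_start:
            raise ValueError(
                f"design {design.design_id}: CRE {seg.cre_id} not upstream of the TATA box"
            )
        last_cre_end = end if last_cre_end is None else max(last_cre_end, end)
        cls = seg.cre_class or GENERIC
        if cls == GENERIC:
            scores[start:end] += model.s_generic
        else:
            distance = tata_start - end
            scores[start:end] += model.s_ccre * proximity_weight(distance, cls, model)
            ccre_spans.append((start, end))
    if len(ccre_spans) >= 2:
        ccre_spans.sort()
        inner_start = ccre_spans[0][1]  # end of the most distal C-CRE
        inner_end = ccre_spans[-1][0]  # start of the most proximal C-CRE
        if inner_end > inner_start:
            midpoint = (inner_start + inner_end) / 2
            d_mid = tata_start - midpoint
            w_mid = proximity_weight(max(d_mid, 0.0), C_CRE_TGA, model)
            scores[inner_start:inner_end] += model.s_between * w_mid
    total = float(scores.sum())
    if last_cre_end is not None:
        total *= _gap_penalty(tata_start - last_cre_end, model)
    return total / total_len


def calibrate(
    model: StrengthModel, pairs
) -> tuple[StrengthModel, CalibrationDiagnostics]:
    """Fit the calibration scalar on (raw_score, measured_strength) pairs.

    Least squares through the origin: k = sum(x*y) / sum(x^2) — a single
    multiplier, no intercept.  Diagnostics report the R-squared of k*x against
    y (about the mean of y; can be negative for a poor fit).
    """
    data = np.asarray(list(pairs), dtype=float)
    if data.ndim != 2 or data.shape[1] != 2 or data.shape[0] < 2:
        raise ValueError("need >= 2 (raw_score, measured_strength) pairs")
    x, y = data[:, 0], data[:, 1]
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("cannot calibrate: all raw scores are zero")
    k = float(np.sum(x * y) / sxx)
    if k <= 0:
        raise ValueError(f"fitted calibration_k = {k:.4g} is not positive")
    predicted = k * x
    ss_res = float(np.sum((y - predicted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else -np.inf)
    residuals = pd.DataFrame(
        {"raw_score": x, "measured": y, "predicted": predicted, "residual": y - predicted}
    )
    fitted = replace(model, calibration_k=k)
    return fitted, CalibrationDiagnostics(
        n_points=len(x), calibration_k=k, r_squared=r2, residuals=residuals
    )


def predict_strength(design: MinSynDesign, model: StrengthModel) -> float:
    """Predicted strength (normalized expression units) = k * raw_score."""
    if model.calibration_k is None:
        raise ValueError("model is not calibrated; fit calibration_k first")
    return model.calibration_k * raw_score(design, model)


def score_library(library, model: StrengthModel | None = None) -> pd.DataFrame:
    """Raw scores (and predictions when calibrated) for every design.

    Returns a manifest-style frame: design_id, n_cre, length, raw_score and,
    if the model carries a calibration scalar, predicted_strength.
    """
    model = model or StrengthModel()
    rows = []
    for design in library.designs:
        raw = raw_score(design, model)
        row = {
            "design_id": design.design_id,
            "n_cre": design.n_cre,
            "length": len(design.sequence),
            "raw_score": raw,
        }
        if model.calibration_k is not None:
            row["predicted_strength"] = model.calibration_k * raw
        rows.append(row)
    return pd.DataFrame(rows)
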