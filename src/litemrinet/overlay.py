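"""Four-color confusion overlay for qualitative error inspection.

Each pixel is colored by its confusion outcome against the reference
mask: true negatives black, true positives white, false negatives red,
false positives green.
"""

from __future__ import annotations

import dataclasses

import numpy as np

__all__ = ["OverlaySpec", "render_overlay"]


@dataclasses.dataclass(frozen=True)
class OverlaySpec:
    tn_color: tuple[int, int, int] = (0, 0, 0)
    tp_color: tuple[int, int, int] = (255, 255, 255)
    fn_color: tuple[int, int, int] = (255, 0, 0)
    fp_color: tuple[int, int, int] = (0, 255, 0)

    def __post_init__(self):
        colors = {self.tn_color, self.tp_color, self.fn_color, self.fp_color}
        if len(colors) != 4:
            raise ValueError("the four outcome colors must be distinct")


def render_overlay(pred_mask: np.ndarray, true_mask: np.ndarray,
                   spec: OverlaySpec | None = None) -> np.ndarray:
    """RGB uint8 image coloring every pixel by its TP/TN/FP/FN outcome."""
    spec = spec or OverlaySpec()
    pred = np.asarray(pred_mask)
    true = np.asarray(true_mask)
    for name, m in (("pred_mask", pred), ("true_mask", true)):
        if not np.isin(np.unique(m), (0, 1)).all():
            raise ValueError(f"{name} must be binary {{0,1}}")
    if pred.shape != true.shape:
        raise ValueError(f"mask shapes differ: {pred.shape} vs {true.shape}")
    pred = pred.astype(bool)
    true = true.astype(bool)
    out = np.empty(pred.shape + (3,), dtype=np.uint8)
    out[~pred & ~true] = spec.tn_color
    out[pred & true] = spec.tp_color
    out[~pred & true] = spec.fn_color
    out[pred & ~true] = spec.fp_color
    return out
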