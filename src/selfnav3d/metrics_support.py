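"""Small shared helpers for evaluation masks."""

from __future__ import annotations

import numpy as np

__all__ = ["support_mask"]


def support_mask(magnitude: np.ndarray, rel_threshold: float = 0.1) -> np.ndarray:
    """Boolean object-support mask: voxels above a fraction of the peak."""
    return magnitude > rel_threshold * magnitude.max()
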