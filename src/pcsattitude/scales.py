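"""Survey rating scales and their mapping onto model quantities.

All survey instruments are bounded rating scales; the network model works
on dimensionless quantities in [-1, 1] (link weights) or [0, 1] (goal
priorities).  Each scale is an affine map from the raw rating range onto
the model range, with an exact inverse so that round-tripping a valid
scale point reproduces it.

Scales
------
LIKERT6
    Six-point agreement scale (1..6) used for beliefs about how well an
    option serves a goal; mapped onto [-1, 1] with midpoint 3.5 -> 0.
IMPORTANCE6
    Six-point goal-importance scale (1..6); mapped onto [0, 1] because
    priority links are non-negative.
SEMANTIC_DIFFERENTIAL
    Bipolar valence scale (-4..+4); mapped onto [-1, 1].
CHANGE7
    Seven-point self-reported attitude-change scale (1..7, 4 = "no
    change"); mapped onto [-1, 1] with 4 -> 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "Scale",
    "LIKERT6",
    "IMPORTANCE6",
    "SEMANTIC_DIFFERENTIAL",
    "CHANGE7",
    "rescale",
    "inverse_rescale",
]


@dataclass(frozen=True)
class Scale:
    """An affine mapping from a bounded rating scale onto a model range.

    ``rescale(x) = lo_out + (x - lo_in) * (hi_out - lo_out) / (hi_in - lo_in)``
    """

    name: str
    lo_in: float
    hi_in: float
    lo_out: float
    hi_out: float

    def rescale(self, value):
        """Map a raw rating onto the model range; rejects out-of-bounds input."""
        arr = np.asarray(value, dtype=float)
        if np.any(arr < self.lo_in) or np.any(arr > self.hi_in):
            raise ValueError(
                f"value {value!r} outside scale {self.name} "
                f"bounds [{self.lo_in}, {self.hi_in}]"
            )
        out = self.lo_out + (arr - self.lo_in) * (self.hi_out - self.lo_out) / (
            self.hi_in - self.lo_in
        )
        return float(out) if np.isscalar(value) else out

    def inverse(self, value):
        """Map a model-range value back onto the raw rating scale."""
        arr = np.asarray(value, dtype=float)
        lo, hi = sorted((self.lo_out, self.hi_out))
        if np.any(arr < lo - 1e-12) or np.any(arr > hi + 1e-12):
            raise ValueError(
                f"value {value!r} outside rescaled range of {self.name}"
            )
        out = self.lo_in + (arr - self.lo_out) * (self.hi_in - self.lo_in) / (
            self.hi_out - self.lo_out
        )
        return float(out) if np.isscalar(value) else out


#: Six-point belief scale -> [-1, 1]:  x -> 2(x-1)/5 - 1.
LIKERT6 = Scale("likert6", 1.0, 6.0, -1.0, 1.0)

#: Six-point importance scale -> [0, 1]:  x -> (x-1)/5.
IMPORTANCE6 = Scale("importance6", 1.0, 6.0, 0.0, 1.0)

#: Bipolar valence scale -> [-1, 1]:  y -> y/4.
SEMANTIC_DIFFERENTIAL = Scale("semantic_differential", -4.0, 4.0, -1.0, 1.0)

#: Seven-point reported-change scale -> [-1, 1]:  c -> (c-4)/3.
CHANGE7 = Scale("change7", 1.0, 7.0, -1.0, 1.0)


def rescale(value, scale: Scale):
    """Map ``value`` from its raw rating scale onto the model range."""
    return scale.rescale(value)


def inverse_rescale(value, scale: Scale):
    """Map a model-range ``value`` back onto its raw rating scale."""
    return scale.inverse(value)
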