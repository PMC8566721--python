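"""Calibration between normalized dequenching signal and fusion cycles.

In a FRET lipid-mixing assay the dye dilution per fusion round is finite, so
the normalized dequenching fraction is, in general, a nonlinear function of
the number of fusion cycles the vesicle population has undergone.  The
conversion depends on dye loading and quenching curve, which are assay
properties rather than model properties; it is therefore kept behind a small
pluggable object shared by the trace generator and the analyzer.

The default is the identity on the early-time regime: one unit of normalized
dequenching equals one fusion-cycle fraction, with unit gain at zero signal.
Alternative quenching curves can be injected by supplying the forward map,
its inverse, and the forward gain at zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["Calibration", "IDENTITY"]


def _identity(x):
    return np.asarray(x, dtype=float)


@dataclass(frozen=True)
class Calibration:
    """Map between fusion-cycle fraction and normalized dequenching.

    Attributes
    ----------
    cycles_to_dequench:
        Forward map applied by the generator (cycle fraction -> normalized
        dequenching in [0, 1]).  Must be monotone with value 0 at 0.
    dequench_to_cycles:
        Inverse map used when converting normalized signals back.
    gain_at_zero:
        d(dequench)/d(cycles) at zero signal; initial slopes in normalized
        dequenching per minute are divided by this gain to obtain fusion
        cycles per minute.
    """

    cycles_to_dequench: Callable = field(default=_identity)
    dequench_to_cycles: Callable = field(default=_identity)
    gain_at_zero: float = 1.0

    def slope_to_cycles(self, slope: float) -> float:
        """Convert an initial slope of normalized dequenching (min^-1) into
        fusion cycles per minute."""
        return slope / self.gain_at_zero


IDENTITY = Calibration()
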