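"""Energy unit conversions.

All quantum-chemical total energies enter the pipeline in hartree and every
derived descriptor is reported in eV, so a single conversion factor is the
only unit bridge needed. The factor lives here, in one place, because the
convention-replication math (softness and electrophilicity evaluated in
atomic units) must share it.
"""

import math

#: Hartree-to-eV conversion factor (CODATA-style). One configuration
#: constant; override per call where a caller needs a different value.
HARTREE_TO_EV: float = 27.211386


def hartree_to_ev(x: float, factor: float = HARTREE_TO_EV) -> float:
    """Convert an energy from hartree to eV.

    Parameters
    ----------
    x : float
        Energy in hartree. Must be finite.
    factor : float
        Conversion factor; defaults to :data:`HARTREE_TO_EV`.
    """
    if not math.isfinite(x):
        raise ValueError(f"energy must be finite, got {x}")
    return x * factor


def ev_to_hartree(x: float, factor: float = HARTREE_TO_EV) -> float:
    """Convert an energy from eV to hartree (inverse of :func:`hartree_to_ev`)."""
    if not math.isfinite(x):
        raise ValueError(f"energy must be finite, got {x}")
    return x / factor
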