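"""Exact, invertible arithmetic between delta-13C values, isotope ratios and
isotope-amount fractions (atom percent) relative to the VPDB standard.

Conventions
-----------
* delta-13C values are ALWAYS expressed in per mil (permil, ‰) at every
  interface of this package and divided by 1000 internally.
* The isotope-amount fraction ``x`` is the dimensionless fraction of 13C
  atoms among all carbon atoms; ``atom percent = 100 * x``.
* The 13C/12C ratio of the Vienna PeeDee Belemnite (VPDB) standard defaults
  to 0.0111802 but is configurable via :class:`IsotopeConstants`.

All functions accept scalars or NumPy arrays and are exact inverses of each
other to floating-point precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from rsil.errors import InvalidMeasurementError

#: 13C/12C isotope ratio of the VPDB reference standard.
VPDB_RATIO: float = 0.0111802


@dataclass(frozen=True)
class IsotopeConstants:
    """Reference constants for isotope conversions.

    Parameters
    ----------
    r_vpdb
        13C/12C ratio of the VPDB standard. Must be strictly positive.
    """

    r_vpdb: float = VPDB_RATIO

    def __post_init__(self) -> None:
        if not self.r_vpdb > 0:
            raise InvalidMeasurementError(
                f"r_vpdb must be > 0, got {self.r_vpdb}"
            )


_DEFAULT = IsotopeConstants()


def delta_to_atom_fraction(delta_permil, constants: IsotopeConstants = _DEFAULT):
    """Convert delta-13C (permil vs VPDB) to the 13C isotope-amount fraction.

    The sample isotope ratio is ``R' = (delta/1000 + 1) * r_vpdb`` and the
    amount fraction is ``x = R' / (1 + R')``.

    Parameters
    ----------
    delta_permil
        delta-13C in permil vs VPDB; scalar or array. Must be >= -1000
        (an isotope ratio cannot be negative).
    constants
        Reference constants; defaults to VPDB.

    Returns
    -------
    float or ndarray
        13C atom fraction in [0, 1).

    Raises
    ------
    InvalidMeasurementError
        If any delta is below -1000 permil.
    """
    delta = np.asarray(delta_permil, dtype=float)
    if np.any(delta < -1000.0):
        raise InvalidMeasurementError(
            f"delta-13C below -1000 permil is non-physical (got {delta_permil})"
        )
    ratio = (delta / 1000.0 + 1.0) * constants.r_vpdb
    x = ratio / (1.0 + ratio)
    return x if x.ndim else float(x)


def atom_fraction_to_delta(x13c, constants: IsotopeConstants = _DEFAULT):
    """Convert a 13C atom fraction back to delta-13C in permil vs VPDB.

    Exact inverse of :func:`delta_to_atom_fraction`.

    Parameters
    ----------
    x13c
        13C atom fraction in [0, 1); scalar or array.
    constants
        Reference constants; defaults to VPDB.

    Returns
    -------
    float or ndarray
        delta-13C in permil (>= -1000).

    Raises
    ------
    InvalidMeasurementError
        If any atom fraction lies outside [0, 1).
    """
    x = np.asarray(x13c, dtype=float)
    if np.any(x < 0.0) or np.any(x >= 1.0):
        raise InvalidMeasurementError(
            f"atom fraction must lie in [0, 1), got {x13c}"
        )
    ratio = x / (1.0 - x)
    delta = (ratio / constants.r_vpdb - 1.0) * 1000.0
    return delta if delta.ndim else float(delta)


def atom_percent(x13c):
    """Express an atom fraction as atom percent (``100 * x``)."""
    x = np.asarray(x13c, dtype=float) * 100.0
    return x if x.ndim else float(x)


def atom_percent_to_fraction(pct):
    """Inverse of :func:`atom_percent`."""
    x = np.asarray(pct, dtype=float) / 100.0
    return x if x.ndim else float(x)
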