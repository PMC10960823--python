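"""Spectral water and vegetation indices.

Four indices drive the compositing strategy:

* ``LTideI`` (low-tide index): contrasts the NIR band against the maximum of
  the blue, green, red and SWIR2 bands,

      LTideI = (rho_NIR - M) / (rho_NIR + M + L) * (1 + L),
      M = max(rho_blue, rho_green, rho_red, rho_SWIR2),

  with a small additive stabiliser ``L`` (default 0.1).  Exposed tidal or
  flooded flats score positive, open water scores negative; the max over the
  visible/SWIR bands guards against atmospheric-correction artefacts that
  push single visible bands negative at high latitude.
* ``mNDWI`` (modified normalised-difference water index, green vs NIR):
  positive over open water.
* ``NDVI`` (red vs NIR) and ``LSWI`` (NIR vs SWIR): vegetation and surface
  moisture.  The ``LSWI`` definition circulates in two forms that differ in
  which SWIR band enters the numerator; both are implemented (see
  :class:`IndexConfig`).

All functions are elementwise over arbitrarily shaped arrays and return
float64.  Zero denominators yield a 0 sentinel (finite features are required
downstream); callers needing to know can request the flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Canonical band order used throughout the package.
BANDS = ("blue", "green", "red", "nir", "swir1", "swir2")
BAND_INDEX = {b: i for i, b in enumerate(BANDS)}


@dataclass(frozen=True)
class IndexConfig:
    """Parameters of the index formulas.

    L
        Additive stabiliser of the low-tide index denominator; must be > 0.
        0.1 is the published recommendation.
    lswi_variant
        ``"swir1_consistent"`` uses SWIR1 in both numerator and denominator
        (the common LSWI definition); ``"paper_printed"`` reproduces the
        mixed-band form (SWIR2 numerator over SWIR1 denominator).
    """

    L: float = 0.1
    lswi_variant: str = "swir1_consistent"

    def __post_init__(self) -> None:
        if not self.L > 0:
            raise ValueError(f"L must be > 0, got {self.L}")
        if self.lswi_variant not in ("swir1_consistent", "paper_printed"):
            raise ValueError(f"unknown lswi_variant {self.lswi_variant!r}")


def _safe_ratio(num, den):
    """num/den with a 0 sentinel where den == 0; returns (ratio, flag)."""
    num = np.asarray(num, dtype=np.float64)
    den = np.asarray(den, dtype=np.float64)
    bad = den == 0
    out = np.divide(num, np.where(bad, 1.0, den))
    out = np.where(bad, 0.0, out)
    return out, bad


def ndvi(red, nir):
    """(NIR - red) / (NIR + red)."""
    r, _ = _safe_ratio(np.asarray(nir, float) - red, np.asarray(nir, float) + red)
    return r


def mndwi(green, nir):
    """(green - NIR) / (green + NIR); positive over open water."""
    r, _ = _safe_ratio(np.asarray(green, float) - nir, np.asarray(green, float) + nir)
    return r


def lswi(nir, swir1, swir2, variant: str = "swir1_consistent"):
    """Land-surface water index; see :class:`IndexConfig` for variants."""
    nir = np.asarray(nir, dtype=np.float64)
    num = nir - (swir1 if variant == "swir1_consistent" else swir2)
    r, _ = _safe_ratio(num, nir + swir1)
    return r


def ltidei(blue, green, red, nir, swir2, L: float = 0.1):
    """Low-tide index; in [-1, 1] for reflectance in [0, 1] and L > 0."""
    m = np.maximum.reduce([np.asarray(b, dtype=np.float64)
                           for b in (blue, green, red, swir2)])
    nir = np.asarray(nir, dtype=np.float64)
    return (nir - m) / (nir + m + L) * (1.0 + L)


def compute_indices(reflectance, config: IndexConfig | None = None,
                    return_flags: bool = False):
    """Compute all four indices from a 6-band reflectance array.

    Parameters
    ----------
    reflectance
        Array whose *first* axis is the band axis in :data:`BANDS` order
        (blue, green, red, nir, swir1, swir2); any trailing shape.
    config
        Index parameters; defaults to :class:`IndexConfig()`.
    return_flags
        If True, also return a dict of boolean zero-denominator flags for
        the three plain normalised-difference indices.

    Returns
    -------
    dict mapping ``{"ndvi", "mndwi", "lswi", "ltidei"}`` to arrays of the
    trailing shape.
    """
    config = config or IndexConfig()
    refl = np.asarray(reflectance, dtype=np.float64)
    if refl.shape[0] != 6:
        raise ValueError(f"expected 6 bands on the first axis, got {refl.shape[0]}")
    b, g, r, n, s1, s2 = refl

    out = {}
    flags = {}
    out["ndvi"], flags["ndvi"] = _safe_ratio(n - r, n + r)
    out["mndwi"], flags["mndwi"] = _safe_ratio(g - n, g + n)
    num = n - (s1 if config.lswi_variant == "swir1_consistent" else s2)
    out["lswi"], flags["lswi"] = _safe_ratio(num, n + s1)
    out["ltidei"] = ltidei(b, g, r, n, s2, L=config.L)
    if return_flags:
        return out, flags
    return out
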