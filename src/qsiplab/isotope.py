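"""Buoyant-density isotope model for 13C qSIP.

The model links the GC content of a taxon's genome to the buoyant density of
its unlabeled ("light") DNA in a CsCl gradient, and converts a labeling-induced
shift in weighted average density (WAD) into the excess atom fraction (EAF) of
13C in that DNA.  Chain of relations:

    W_light = slope_gc_density * G + intercept_density
    M_light = mw_slope * G + mw_intercept            (mean nucleotide mass)
    M_heavymax - M_light = heavy_slope * G + heavy_intercept
    M_lab = (dW / W_light + 1) * M_light
    EAF   = (M_lab - M_light) / (M_heavymax - M_light) * (1 - nat_13c)

M_heavymax is the molecular weight the DNA would have if every carbon atom
were 13C; nat_13c is the natural 13C atom fraction, so the maximum attainable
EAF is 1 - nat_13c.  EAF is left untruncated: sampling noise can produce small
negative density shifts and hence negative point estimates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "IsotopeModelParams",
    "DEFAULT_PARAMS",
    "gc_from_density",
    "molecular_weights",
    "eaf_point",
    "expected_band_center",
]


@dataclass(frozen=True)
class IsotopeModelParams:
    """Constants of the GC/density/molecular-weight model for 13C.

    Units: densities in g ml^-1, molecular weights in g mol^-1 per average
    nucleotide, GC as a fraction in [0, 1].
    """

    slope_gc_density: float = 0.083506
    intercept_density: float = 1.646057
    mw_slope: float = 0.496
    mw_intercept: float = 307.691
    heavy_slope: float = -0.4987282
    heavy_intercept: float = 9.974564
    nat_13c: float = 0.01111233

    @property
    def max_eaf(self) -> float:
        return 1.0 - self.nat_13c


DEFAULT_PARAMS = IsotopeModelParams()


def gc_from_density(w_light, params: IsotopeModelParams = DEFAULT_PARAMS, *, warn: bool = True):
    """GC fraction implied by a light-DNA buoyant density.

    Inverts the linear GC-density relation; values falling outside [0, 1]
    (possible under noisy WADs) are clamped, with a warning.  Accepts scalars
    or arrays.
    """
    w_light = np.asarray(w_light, dtype=float)
    g_raw = (w_light - params.intercept_density) / params.slope_gc_density
    g = np.clip(g_raw, 0.0, 1.0)
    if warn and np.any((g_raw < 0) | (g_raw > 1)):
        warnings.warn(
            "GC estimate outside [0, 1] clamped; check fraction densities",
            stacklevel=2,
        )
    return g if g.ndim else float(g)


def molecular_weights(g, params: IsotopeModelParams = DEFAULT_PARAMS):
    """(M_light, M_heavymax) for GC fraction ``g``.

    M_light is the average nucleotide molecular weight of unlabeled DNA;
    M_heavymax that of DNA in which all carbon is 13C.
    """
    g = np.asarray(g, dtype=float)
    m_light = params.mw_slope * g + params.mw_intercept
    m_heavymax = m_light + (params.heavy_slope * g + params.heavy_intercept)
    if m_light.ndim:
        return m_light, m_heavymax
    return float(m_light), float(m_heavymax)


def eaf_point(w_light, w_lab, params: IsotopeModelParams = DEFAULT_PARAMS, *, warn: bool = False):
    """Excess atom fraction 13C from light and labeled WADs.

    ``w_light`` is the taxon's unlabeled (control) weighted average density,
    ``w_lab`` its density in the labeled incubation.  Vectorized over both
    arguments.  eaf_point(W, W) == 0 exactly; a fully labeled taxon
    (M_lab == M_heavymax) returns 1 - nat_13c.
    """
    w_light = np.asarray(w_light, dtype=float)
    w_lab = np.asarray(w_lab, dtype=float)
    g = gc_from_density(w_light, params, warn=warn)
    m_light, m_heavymax = molecular_weights(g, params)
    m_lab = (((w_lab - w_light) / w_light) + 1.0) * m_light
    a = (m_lab - m_light) / (m_heavymax - m_light) * (1.0 - params.nat_13c)
    return a if np.ndim(a) else float(a)


def expected_band_center(g, a_true, params: IsotopeModelParams = DEFAULT_PARAMS):
    """Buoyant density of DNA with GC fraction ``g`` and true EAF ``a_true``.

    Exact inverse of :func:`eaf_point`: for any G in [0, 1] and A in
    [0, 1 - nat_13c], ``eaf_point(W_light, expected_band_center(G, A)) == A``
    up to floating-point round-off.
    """
    g = np.asarray(g, dtype=float)
    a_true = np.asarray(a_true, dtype=float)
    w_light = params.slope_gc_density * g + params.intercept_density
    m_light, m_heavymax = molecular_weights(g, params)
    dw = w_light * (m_heavymax - m_light) / m_light * a_true / (1.0 - params.nat_13c)
    w = w_light + dw
    return w if np.ndim(w) else float(w)
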