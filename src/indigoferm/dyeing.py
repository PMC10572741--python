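"""Dyeing-intensity metric from CIE L*a*b* colorimetry.

The phenotype of an indigo vat is quantified by dipping cloth and
measuring its colour: the L*a*b* value of a pixel is the Euclidean
magnitude sqrt(L*^2 + a*^2 + b*^2), averaged over pixels, and the dyeing
intensity is that value scaled by 10.

The literal magnitude of any visible cloth is far larger than the
intensities (~0.5-2.4) the phenotype scale actually spans, so a
reference-difference variant (|value - reference| x scale, e.g. against
an undyed cloth) is also provided; the literal formula stays the
default. See the methods note for the discussion.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .errors import InputError


def lab_value(pixels) -> float:
    """Mean over pixels of sqrt(L*^2 + a*^2 + b*^2).

    Parameters
    ----------
    pixels : array-like of shape (n, 3) or DataFrame with columns L, a, b
        Per-pixel CIE L*a*b* measurements.
    """
    if isinstance(pixels, pd.DataFrame):
        arr = pixels[["L", "a", "b"]].to_numpy(dtype=float)
    else:
        arr = np.atleast_2d(np.asarray(pixels, dtype=float))
    if arr.size == 0:
        raise InputError("empty pixel list")
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise InputError(f"expected (n, 3) L*a*b* array, got shape {arr.shape}")
    if not np.isfinite(arr).all():
        raise InputError("non-finite L*a*b* value")
    if (arr[:, 0] < 0).any():
        raise InputError("negative L* (lightness) value")
    return float(np.mean(np.linalg.norm(arr, axis=1)))


def dyeing_intensity(lab: float, scale: float = 10.0,
                     reference: float | None = None) -> float:
    """Scaled dyeing intensity from a L*a*b* magnitude.

    Without a reference this is ``lab * scale`` (the literal definition);
    with a reference it is ``|lab - reference| * scale``, the normalized
    variant for measurements taken against a blank cloth.
    """
    if scale < 0:
        raise InputError("scale must be nonnegative")
    if lab < 0:
        raise InputError("lab_value must be nonnegative")
    if reference is None:
        return float(lab * scale)
    return float(abs(lab - reference) * scale)
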