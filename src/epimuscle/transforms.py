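"""Beta <-> M-value transforms.

The beta-value is the proportion of methylated signal at a CpG (0 = fully
unmethylated, 1 = fully methylated).  The M-value is its log2-odds,
M = log2(beta / (1 - beta)), the scale on which per-probe linear models are
fitted because it is unbounded and closer to homoscedastic.  Both transforms
are strictly monotone, so rank statistics (Spearman correlations) are
identical on either scale.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

DEFAULT_CLAMP_EPS = 1e-6


def _apply(x, fn):
    if isinstance(x, pd.DataFrame):
        return pd.DataFrame(fn(x.to_numpy(dtype=float)), index=x.index, columns=x.columns)
    if isinstance(x, pd.Series):
        return pd.Series(fn(x.to_numpy(dtype=float)), index=x.index)
    arr = np.asarray(x, dtype=float)
    out = fn(arr)
    return float(out) if np.isscalar(x) or arr.ndim == 0 else out


def beta_to_m(beta, clamp_eps: float = DEFAULT_CLAMP_EPS):
    """M = log2(b' / (1 - b')) with b' clamped into [clamp_eps, 1 - clamp_eps].

    Clamping keeps M finite for degenerate betas at exactly 0 or 1 (which can
    arise in simulation but not from intensity ratios).
    """
    def fn(b):
        if np.any((b < 0) | (b > 1) | ~np.isfinite(b)):
            raise ValueError("beta values must lie within [0, 1]")
        b = np.clip(b, clamp_eps, 1.0 - clamp_eps)
        return np.log2(b / (1.0 - b))

    return _apply(beta, fn)


def m_to_beta(m):
    """Inverse transform: beta = 2^M / (2^M + 1), numerically stable for any M."""
    def fn(x):
        if np.any(~np.isfinite(x)):
            raise ValueError("M-values must be finite")
        # logistic in base 2, stable for large |M|
        return 0.5 * (1.0 + np.tanh(0.5 * np.log(2.0) * x))

    return _apply(m, fn)
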