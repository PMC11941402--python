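"""Parameter transforms: dispersions are optimized on the log scale."""

from __future__ import annotations

import numpy as np

from .models import Theta

# SDs and variances live on (0, inf); location/slope parameters on R
_LOG_SCALE = {"sigma1", "sigma2", "sigma2_obs", "tau2"}

__all__ = ["to_unconstrained", "from_unconstrained", "is_log_scale"]


def is_log_scale(name: str) -> bool:
    return name in _LOG_SCALE


def to_unconstrained(theta: Theta, names) -> np.ndarray:
    out = []
    for name in names:
        v = theta[name]
        out.append(np.log(v) if name in _LOG_SCALE else v)
    return np.asarray(out, dtype=float)


def from_unconstrained(z, names, base: Theta) -> Theta:
    updates = {}
    for name, v in zip(names, np.asarray(z, dtype=float)):
        updates[name] = float(np.exp(v)) if name in _LOG_SCALE else float(v)
    return base.replace(**updates)
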