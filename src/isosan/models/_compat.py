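"""Optional numba acceleration for model right-hand sides."""

from __future__ import annotations

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit as _njit

    def maybe_njit(fn):
        return _njit(fn, cache=True, fastmath=False)

    HAVE_NUMBA = True
except Exception:  # pragma: no cover
    def maybe_njit(fn):
        return fn

    HAVE_NUMBA = False
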