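"""SAN cell model registry."""

from __future__ import annotations

from .base import CellModelSpec, UnsupportedActionError
from . import boyett, kurata

__all__ = ["build_model", "MODEL_NAMES", "CellModelSpec", "UnsupportedActionError"]

MODEL_NAMES = (
    "boyett-central",
    "boyett-peripheral",
    "kurata-central",
    "kurata-peripheral",
)


def build_model(name: str) -> CellModelSpec:
    """Build one of the four base cell models by name.

    All four fire spontaneously without any stimulus; the Boyett family
    carries a sustained inward current (``g_st``), the Kurata family does
    not.
    """
    if name not in MODEL_NAMES:
        raise ValueError(
            f"unknown model {name!r}; valid names: {', '.join(MODEL_NAMES)}"
        )
    family, region = name.split("-", 1)
    return (boyett if family == "boyett" else kurata).build(region)
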