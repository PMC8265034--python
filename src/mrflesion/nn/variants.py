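"""The eight network variants: loss function x input/output configuration.

Naming is LOSS-<n_outputs>: five-output networks regress T1, T2*, NAWM-,
GM- and lesion-probability maps jointly from the 35 MRF baseline frames;
one-output networks regress only the lesion probability map.  MSE-2-1 is the
reference network that takes the two reconstructed quantitative maps
(T1, T2*) as input instead of the raw fingerprint frames.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["NetworkVariant", "VARIANTS", "get_variant"]


@dataclass(frozen=True)
class NetworkVariant:
    name: str
    loss: str  # MSE | MAE | LCL | DICE
    n_inputs: int  # 35 (MRF baseline frames) or 2 (T1, T2* maps)
    n_outputs: int  # 5 (T1, T2*, NAWM-, GM-, lesion prob.) or 1 (lesion prob.)


VARIANTS: dict[str, NetworkVariant] = {
    v.name: v
    for v in (
        NetworkVariant("MSE-5", "MSE", 35, 5),
        NetworkVariant("MAE-5", "MAE", 35, 5),
        NetworkVariant("LCL-5", "LCL", 35, 5),
        NetworkVariant("MSE-1", "MSE", 35, 1),
        NetworkVariant("MAE-1", "MAE", 35, 1),
        NetworkVariant("LCL-1", "LCL", 35, 1),
        NetworkVariant("DICE-1", "DICE", 35, 1),
        NetworkVariant("MSE-2-1", "MSE", 2, 1),
    )
}


def get_variant(name: str) -> NetworkVariant:
    try:
        return VARIANTS[name]
    except KeyError:
        raise ValueError(f"unknown variant {name!r}; choose from {sorted(VARIANTS)}") from None
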