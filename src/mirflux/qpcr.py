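"""Relative expression by the 2^-ddCt method."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence


@dataclass(frozen=True)
class QpcrMeasurement:
    sample: str
    condition: str                 # "treated" | "control"
    ct_target: float
    ct_reference: float

    def __post_init__(self):
        for name, ct in (("ct_target", self.ct_target),
                         ("ct_reference", self.ct_reference)):
            if not (ct == ct and abs(ct) != float("inf")):
                raise ValueError(f"{name} must be finite, got {ct}")

    @property
    def dct(self) -> float:
        return self.ct_target - self.ct_reference


def ddct_fold_change(treated: Iterable[QpcrMeasurement],
                     control: Iterable[QpcrMeasurement],
                     ) -> tuple[float, list[float], list[float]]:
    """FC = 2^-(mean dCt(treated) - mean dCt(control)).

    dCt is computed per sample (Ct_target - Ct_reference) and averaged
    within condition.  Returns (FC, treated dCt list, control dCt list).
    """
    dct_t = [m.dct for m in treated]
    dct_c = [m.dct for m in control]
    if not dct_t or not dct_c:
        raise ValueError("each condition needs at least one measurement")
    ddct = sum(dct_t) / len(dct_t) - sum(dct_c) / len(dct_c)
    return 2.0 ** (-ddct), dct_t, dct_c
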