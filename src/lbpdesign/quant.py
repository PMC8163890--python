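"""qPCR quantification math: comparative-Ct composition and ddCt fold change.

Relative template abundance scales as efficiency^(-Ct) (efficiency 2 for a
perfect doubling per cycle).  Community composition normalizes these weights
within a sample; tissue expression uses the comparative 2^-ddCt fold change
against a reference gene and a control condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass
class CtTable:
    """Threshold cycles per target; missing = below the detection limit."""

    sample_id: str
    ct: dict[str, float | None]

    def __post_init__(self):
        bad = {
            t: v
            for t, v in self.ct.items()
            if v is not None and not (math.isfinite(v) and v > 0)
        }
        if bad:
            raise ValueError(f"Ct values must be finite and > 0: {bad}")


@dataclass
class CompositionTable:
    sample_id: str
    fractions: dict[str, float]
    no_detection: bool = False

    def __post_init__(self):
        if any(v < 0 for v in self.fractions.values()):
            raise ValueError("negative abundance fraction")
        total = sum(self.fractions.values())
        if not self.no_detection and abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")


def composition_from_ct(ct: CtTable, efficiency: float = 2.0) -> CompositionTable:
    """Relative abundances by the comparative Ct method (2^-Ct weights).

    Undetected targets get abundance 0; if nothing is detected the row is
    all-zero and flagged ``no_detection``.
    """
    if not ct.ct:
        raise ValueError("Ct table has no targets")
    weights = {
        t: (efficiency ** (-v) if v is not None else 0.0) for t, v in ct.ct.items()
    }
    total = sum(weights.values())
    if total == 0.0:
        return CompositionTable(ct.sample_id, {t: 0.0 for t in weights}, no_detection=True)
    return CompositionTable(ct.sample_id, {t: w / total for t, w in weights.items()})


def fold_change_ddct(
    ct_target_case: float,
    ct_ref_case: float,
    ct_target_ctrl: float,
    ct_ref_ctrl: float,
    efficiency: float = 2.0,
) -> float:
    """Expression fold change by the comparative 2^-ddCt method."""
    values = (ct_target_case, ct_ref_case, ct_target_ctrl, ct_ref_ctrl)
    if any(v is None or not math.isfinite(v) for v in values):
        raise ValueError(f"all four Ct values must be present and finite: {values}")
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return efficiency ** (-ddct)
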