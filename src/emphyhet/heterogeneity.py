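"""Signed emphysema heterogeneity index (HI%).

HI% contrasts the emphysema volume in the upper zone against the lower
zone of a lung (or of the whole lung):

    HI = 100 × (V_upper − V_lower) / (V_upper + V_lower)

where the volumes are LAA volumes in ml (not lobe-normalised percentages).
The right middle lobe counts with the upper zone, so the zones are

* left lung:  LUL  vs  LLL
* right lung: RUL + RML  vs  RLL
* whole lung: LUL + RUL + RML  vs  LLL + RLL

The index ranges from −100% (all emphysema in the lower zone) to +100%
(all upper).  Two rules force HI to zero: when the whole-lung emphysema
extent is below 1% (too little disease to localise), and when the upper
and lower volumes are equal (including both zero).

A subject is classified *upper-dominant* iff HI > 0; HI = 0 falls in the
lower-dominant group.
"""

from __future__ import annotations

from dataclasses import dataclass

from .laa import LobeQuant

#: Whole-lung %LAA below which HI is defined as zero.
MIN_EXTENT_PCT = 1.0

_SCOPE_ZONES = {
    "left": (("LUL",), ("LLL",)),
    "right": (("RUL", "RML"), ("RLL",)),
    "whole": (("LUL", "RUL", "RML"), ("LLL", "RLL")),
}


@dataclass
class HIResult:
    """Heterogeneity index for one scope of one subject."""

    scope: str  # "left" | "right" | "whole"
    v_upper_ml: float
    v_lower_ml: float
    whole_lung_laa_pct: float
    hi: float  # percent, in [-100, 100]

    @property
    def dominance(self) -> str:
        return "upper" if self.hi > 0 else "lower"


def _signed_ratio(v_upper: float, v_lower: float) -> float:
    # Isolated so the index formula lives in exactly one place.
    denom = v_upper + v_lower
    if denom == 0:
        return 0.0
    # ratio before scaling so the ±100 boundary is exact in floating point
    return 100.0 * ((v_upper - v_lower) / denom)


def compute_hi(
    quant: LobeQuant,
    scope: str = "whole",
    min_extent_pct: float = MIN_EXTENT_PCT,
    extent_scope: str = "whole",
) -> HIResult:
    """Compute HI% for one scope from per-lobe LAA tallies.

    The <1% rule uses the **whole-lung** extent for every scope by
    default; pass ``extent_scope="self"`` to gate each scope on its own
    extent instead.

    Raises
    ------
    ValueError
        If ``scope`` is unknown or a required lobe is absent from the
        tallies (zero volume).
    """
    if scope not in _SCOPE_ZONES:
        raise ValueError(f"unknown scope {scope!r}; expected left, right or whole")
    upper_lobes, lower_lobes = _SCOPE_ZONES[scope]
    for name in upper_lobes + lower_lobes:
        if name not in quant.regions or quant.regions[name].empty:
            raise ValueError(f"lobe {name} is missing from the quantification")

    v_upper = sum(quant[name].laa_volume_ml for name in upper_lobes)
    v_lower = sum(quant[name].laa_volume_ml for name in lower_lobes)
    whole_pct = quant["whole"].laa_pct
    if whole_pct is None:
        raise ValueError("whole-lung extent is undefined (empty lung)")
    gate_pct = whole_pct if extent_scope == "whole" else (
        quant[scope if scope != "whole" else "whole"].laa_pct or 0.0
    )

    if gate_pct < min_extent_pct:
        hi = 0.0
    else:
        hi = _signed_ratio(v_upper, v_lower)
    return HIResult(
        scope=scope,
        v_upper_ml=v_upper,
        v_lower_ml=v_lower,
        whole_lung_laa_pct=whole_pct,
        hi=hi,
    )


def classify_dominance(hi: "HIResult | float") -> str:
    """'upper' iff HI > 0, else 'lower' (HI = 0 counts as lower)."""
    value = hi.hi if isinstance(hi, HIResult) else float(hi)
    return "upper" if value > 0 else "lower"


def left_right_hi_difference(left: HIResult, right: HIResult) -> float:
    """HI(left lung) − HI(right lung) for one subject, in percent."""
    if left.scope != "left" or right.scope != "right":
        raise ValueError(
            f"expected scopes (left, right), got ({left.scope}, {right.scope})"
        )
    return left.hi - right.hi
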