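"""ACMG/AMP evidence parsing and five-tier classification.

Evidence tokens follow the clinical shorthand ``<code>[_<modifier>]``:
the code prefix fixes the default strength (PVS very strong, PS strong,
PM moderate, PP supporting; BA stand-alone, BS strong, BP supporting
benign) and an optional modifier overrides it (``_SUP``/``_P``,
``_MOD``/``_M``, ``_STR``/``_S``, ``_VS``).

Two combiners are provided:

* :func:`classify_points` — the point-scale refinement (supporting 1,
  moderate 2, strong 4, very strong 8; benign evidence negative) with
  tier thresholds >=10 pathogenic, 6..9 likely pathogenic, 0..5 uncertain,
  -6..-1 likely benign, <=-7 benign;
* :func:`classify_rules` — the original categorical combining-rule table,
  applied after modifiers are mapped to their effective category.  When
  pathogenic and benign rules fire simultaneously the call is uncertain
  with a conflict flag.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from enum import Enum

__all__ = [
    "Strength",
    "Tier",
    "EvidenceCode",
    "Classification",
    "parse_evidence",
    "parse_evidence_list",
    "points_of",
    "classify_points",
    "classify_rules",
]


class Strength(str, Enum):
    STAND_ALONE = "stand_alone"
    VERY_STRONG = "very_strong"
    STRONG = "strong"
    MODERATE = "moderate"
    SUPPORTING = "supporting"


class Tier(str, Enum):
    PATHOGENIC = "pathogenic"
    LIKELY_PATHOGENIC = "likely_pathogenic"
    UNCERTAIN = "uncertain"
    LIKELY_BENIGN = "likely_benign"
    BENIGN = "benign"


_PREFIX_STRENGTH = {
    "PVS": ("pathogenic", Strength.VERY_STRONG),
    "PS": ("pathogenic", Strength.STRONG),
    "PM": ("pathogenic", Strength.MODERATE),
    "PP": ("pathogenic", Strength.SUPPORTING),
    "BA": ("benign", Strength.STAND_ALONE),
    "BS": ("benign", Strength.STRONG),
    "BP": ("benign", Strength.SUPPORTING),
}

# accepted modifier dialects, normalized
_MODIFIERS = {
    "VS": Strength.VERY_STRONG,
    "STR": Strength.STRONG,
    "S": Strength.STRONG,
    "MOD": Strength.MODERATE,
    "M": Strength.MODERATE,
    "SUP": Strength.SUPPORTING,
    "P": Strength.SUPPORTING,
}

_TOKEN_RE = re.compile(r"^(PVS|PS|PM|PP|BA|BS|BP)(\d+)(?:_([A-Z]+))?$")

_POINTS = {
    Strength.SUPPORTING: 1,
    Strength.MODERATE: 2,
    Strength.STRONG: 4,
    Strength.VERY_STRONG: 8,
    Strength.STAND_ALONE: 8,  # BA1: strongest benign weight
}


@dataclass(frozen=True)
class EvidenceCode:
    label: str
    base_strength: Strength
    modifier: Strength | None
    direction: str  # "pathogenic" | "benign"

    @property
    def effective_strength(self) -> Strength:
        return self.modifier if self.modifier is not None else self.base_strength

    def format(self) -> str:
        if self.modifier is None:
            return self.label
        suffix = {
            Strength.VERY_STRONG: "VS",
            Strength.STRONG: "STR",
            Strength.MODERATE: "MOD",
            Strength.SUPPORTING: "SUP",
        }[self.modifier]
        return f"{self.label}_{suffix}"


@dataclass
class Classification:
    tier: Tier
    points: int
    rule_trace: list[tuple[str, int]] = field(default_factory=list)
    conflict: bool = False


def parse_evidence(token: str) -> EvidenceCode:
    m = _TOKEN_RE.match(token.strip().upper())
    if not m:
        raise ValueError(f"unrecognized ACMG evidence token {token!r}")
    prefix, num, mod = m.groups()
    direction, base = _PREFIX_STRENGTH[prefix]
    modifier = None
    if mod is not None:
        if mod not in _MODIFIERS:
            raise ValueError(f"unknown strength modifier {mod!r} in {token!r}")
        modifier = _MODIFIERS[mod]
    return EvidenceCode(
        label=f"{prefix}{num}", base_strength=base, modifier=modifier,
        direction=direction,
    )


def parse_evidence_list(text: str) -> list[EvidenceCode]:
    """Parse a semicolon-separated evidence string (Table-style input)."""
    tokens = [t for t in (s.strip() for s in text.split(";")) if t]
    if not tokens:
        raise ValueError("empty evidence string")
    return [parse_evidence(t) for t in tokens]


def points_of(code: EvidenceCode) -> int:
    """Signed point value of one evidence code."""
    pts = _POINTS[code.effective_strength]
    return pts if code.direction == "pathogenic" else -pts


def classify_points(codes: list[EvidenceCode]) -> Classification:
    """Point-sum combiner with the published five-tier thresholds."""
    trace = [(c.format(), points_of(c)) for c in codes]
    total = sum(p for _, p in trace)
    if total >= 10:
        tier = Tier.PATHOGENIC
    elif total >= 6:
        tier = Tier.LIKELY_PATHOGENIC
    elif total >= 0:
        tier = Tier.UNCERTAIN
    elif total >= -6:
        tier = Tier.LIKELY_BENIGN
    else:
        tier = Tier.BENIGN
    return Classification(tier=tier, points=total, rule_trace=trace)


def classify_rules(codes: list[EvidenceCode]) -> Classification:
    """Categorical combining-rule table (modifiers applied first)."""
    n = {s: 0 for s in Strength}
    nb = {s: 0 for s in Strength}
    for c in codes:
        (n if c.direction == "pathogenic" else nb)[c.effective_strength] += 1
    pvs = n[Strength.VERY_STRONG]
    ps = n[Strength.STRONG]
    pm = n[Strength.MODERATE]
    pp = n[Strength.SUPPORTING]
    ba = nb[Strength.STAND_ALONE]
    bs = nb[Strength.STRONG]
    bp = nb[Strength.SUPPORTING] + nb[Strength.MODERATE]

    pathogenic = (
        (pvs >= 1 and (ps >= 1 or pm >= 2 or (pm == 1 and pp == 1) or pp >= 2))
        or pvs >= 2
        or ps >= 2
        or (ps == 1 and (pm >= 3 or (pm == 2 and pp >= 2) or (pm == 1 and pp >= 4)))
    )
    likely_pathogenic = (
        (pvs >= 1 and pm == 1)
        or (ps == 1 and 1 <= pm <= 2)
        or (ps == 1 and pp >= 2)
        or pm >= 3
        or (pm == 2 and pp >= 2)
        or (pm == 1 and pp >= 4)
    )
    benign = ba >= 1 or bs >= 2
    likely_benign = (bs == 1 and bp >= 1) or bp >= 2

    trace = [(c.format(), points_of(c)) for c in codes]
    total = sum(p for _, p in trace)

    path_call = pathogenic or likely_pathogenic
    benign_call = benign or likely_benign
    if path_call and benign_call:
        return Classification(tier=Tier.UNCERTAIN, points=total,
                              rule_trace=trace, conflict=True)
    if pathogenic:
        tier = Tier.PATHOGENIC
    elif likely_pathogenic:
        tier = Tier.LIKELY_PATHOGENIC
    elif benign:
        tier = Tier.BENIGN
    elif likely_benign:
        tier = Tier.LIKELY_BENIGN
    else:
        tier = Tier.UNCERTAIN
    return Classification(tier=tier, points=total, rule_trace=trace)
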