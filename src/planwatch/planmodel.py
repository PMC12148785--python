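"""Plan-property detection and name-based structure-to-role matching.

The matching lexicon (English + Italian tokens) ships as editable
configuration: the original tool relies on site-specific structure
naming, so the token table is data, not code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from importlib import resources

from .exceptions import AmbiguityError, ValidationError
from .rtio import PlanInfo, Structure, Technique


class Laterality(str, Enum):
    LEFT = "LEFT"
    RIGHT = "RIGHT"
    BILATERAL = "BILATERAL"


class BreastModifier(str, Enum):
    NONE = "NONE"
    CHESTWALL = "CHESTWALL"
    EXP = "EXP"
    EXP_HS = "EXP_HS"


class PlanTechnique(str, Enum):
    THREE_DCRT = "3DCRT"
    IMRT = "IMRT"
    VMAT = "VMAT"
    HYBRID = "HYBRID"


class Bolus(str, Enum):
    NONE = "NONE"
    ALL = "ALL"
    PARTIAL = "PARTIAL"


#: optional technique modifiers: breath-hold, autoplanned, tangential
TECH_MODIFIERS = frozenset({"BH", "AP", "TANG"})

ROLES = (
    "PTV_BREAST", "PTV_BOOST", "PTV_NODES",
    "LUNG_IPSI", "LUNG_CONTRA", "HEART", "LAD", "BREAST_CONTRA",
    "ESOPHAGUS", "STOMACH", "LIVER", "THYROID", "SKIN",
)

PTV_ROLES = ("PTV_BREAST", "PTV_BOOST", "PTV_NODES")

_LEFT_TOKENS = ("sx", "sin", "left", "lt", "l")
_RIGHT_TOKENS = ("dx", "des", "right", "rt", "r")

#: match priority: specific roles before generic ones (contra-breast owns
#: "breast contra" names before the generic breast PTV can claim them)
_ROLE_ORDER = (
    "PTV_BOOST", "PTV_NODES", "BREAST_CONTRA", "PTV_BREAST",
    "LAD", "HEART",
    "ESOPHAGUS", "STOMACH", "LIVER", "THYROID", "SKIN",
)


@dataclass(frozen=True)
class PlanProperties:
    laterality: Laterality
    has_boost: bool = False
    has_nodes: bool = False
    breast_modifier: BreastModifier = BreastModifier.NONE
    technique: PlanTechnique = PlanTechnique.THREE_DCRT
    technique_modifiers: frozenset[str] = frozenset()
    bolus: Bolus = Bolus.NONE

    def __post_init__(self) -> None:
        bad = set(self.technique_modifiers) - TECH_MODIFIERS
        if bad:
            raise ValidationError(f"unknown technique modifiers: {sorted(bad)}")


@dataclass
class RoleAssignment:
    structure_name: str
    source: str = "AUTO"  # AUTO | USER


@dataclass
class StructureMapping:
    roles: dict[str, RoleAssignment] = field(default_factory=dict)

    def name_for(self, role: str) -> str | None:
        a = self.roles.get(role)
        return a.structure_name if a else None

    def set_override(self, role: str, structure_name: str) -> None:
        if role not in ROLES:
            raise ValidationError(f"unknown structure role {role!r}")
        # a structure maps to at most one role: evict any previous claim
        for r, a in list(self.roles.items()):
            if a.structure_name == structure_name and r != role:
                del self.roles[r]
        self.roles[role] = RoleAssignment(structure_name, source="USER")


# ---------------------------------------------------------------------------
# lexicon

def default_lexicon_text() -> str:
    return (
        resources.files("planwatch.data").joinpath("lexicon.txt").read_text("utf-8")
    )


def parse_lexicon(text: str) -> dict[str, list[str]]:
    """Parse ``ROLE: token1, token2, ...`` lines into a role→tokens table."""
    table: dict[str, list[str]] = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if ":" not in line:
            raise ValidationError(f"lexicon line {lineno}: expected 'ROLE: tokens'")
        role, _, tokens = line.partition(":")
        role = role.strip().upper()
        if role not in ROLES and role != "LUNG":
            raise ValidationError(f"lexicon line {lineno}: unknown role {role!r}")
        table[role] = [t.strip().lower() for t in tokens.split(",") if t.strip()]
    return table


def load_lexicon(path: str | None = None) -> dict[str, list[str]]:
    if path is None:
        return parse_lexicon(default_lexicon_text())
    with open(path, "r", encoding="utf-8") as fh:
        return parse_lexicon(fh.read())


# ---------------------------------------------------------------------------
# detection

def _side_of(name: str) -> Laterality | None:
    words = _split_words(name)
    if any(t in words for t in _LEFT_TOKENS):
        return Laterality.LEFT
    if any(t in words for t in _RIGHT_TOKENS):
        return Laterality.RIGHT
    return None


def _split_words(name: str) -> set[str]:
    out, word = set(), []
    for ch in name.lower():
        if ch.isalnum():
            word.append(ch)
        else:
            if word:
                out.add("".join(word))
            word = []
    if word:
        out.add("".join(word))
    return out


def _normalize_name(name: str) -> str:
    return " ".join("".join(ch if ch.isalnum() else " " for ch in name.lower()).split())


def _token_matches(name: str, token: str) -> bool:
    if len(token) <= 2:
        return token in _split_words(name)  # short tokens must be whole words
    return token in _normalize_name(name)


def detect_technique(plan: PlanInfo) -> PlanTechnique:
    kinds = {b.technique_hint for b in plan.treatment_beams}
    if not kinds:
        return PlanTechnique.THREE_DCRT
    if Technique.STATIC in kinds and kinds & {Technique.ARC, Technique.DYNAMIC_MLC}:
        return PlanTechnique.HYBRID
    if Technique.ARC in kinds:
        return PlanTechnique.VMAT
    if Technique.DYNAMIC_MLC in kinds:
        return PlanTechnique.IMRT
    return PlanTechnique.THREE_DCRT


def detect_properties(
    plan: PlanInfo,
    structures: list[Structure],
    lexicon: dict[str, list[str]] | None = None,
    overrides: dict | None = None,
) -> PlanProperties:
    """Infer laterality, targets and technique; *overrides* win field-wise."""
    if not structures:
        raise ValidationError("cannot detect plan properties without structures")
    lexicon = lexicon or load_lexicon()
    overrides = overrides or {}

    target_tokens = [t for role in PTV_ROLES for t in lexicon.get(role, [])]
    contra_tokens = lexicon.get("BREAST_CONTRA", [])
    target_names = [
        s.name for s in structures
        if any(_token_matches(s.name, t) for t in target_tokens)
        and not any(_token_matches(s.name, t) for t in contra_tokens)
    ]
    sides = {side for n in target_names if (side := _side_of(n)) is not None}
    if "laterality" in overrides:
        laterality = Laterality(overrides["laterality"])
    elif sides == {Laterality.LEFT, Laterality.RIGHT}:
        laterality = Laterality.BILATERAL
    elif len(sides) == 1:
        laterality = next(iter(sides))
    else:
        raise ValidationError(
            "cannot infer laterality from target names "
            f"{target_names or [s.name for s in structures]}; supply an override"
        )

    def has_role(role: str) -> bool:
        return any(
            any(_token_matches(s.name, t) for t in lexicon.get(role, []))
            for s in structures
        )

    props = PlanProperties(
        laterality=laterality,
        has_boost=has_role("PTV_BOOST"),
        has_nodes=has_role("PTV_NODES"),
        breast_modifier=BreastModifier.NONE,
        technique=detect_technique(plan),
        technique_modifiers=frozenset(),
        bolus=Bolus.NONE,
    )
    field_overrides = {
        k: v for k, v in overrides.items()
        if k in PlanProperties.__dataclass_fields__ and k != "laterality"
    }
    if "technique_modifiers" in field_overrides:
        field_overrides["technique_modifiers"] = frozenset(
            field_overrides["technique_modifiers"]
        )
    return replace(props, **field_overrides)


# ---------------------------------------------------------------------------
# matching

def _best_match(
    role_tokens: list[str], candidates: list[str]
) -> tuple[str | None, list[str]]:
    """Return (best candidate, tied candidates). Score = longest matching token."""
    scored: list[tuple[int, str]] = []
    for name in candidates:
        lengths = [len(t) for t in role_tokens if _token_matches(name, t)]
        if lengths:
            scored.append((max(lengths), name))
    if not scored:
        return None, []
    best = max(s for s, _ in scored)
    tied = sorted(name for s, name in scored if s == best)
    return tied[0], tied


def match_structures(
    structures: list[Structure],
    laterality: Laterality,
    lexicon: dict[str, list[str]] | None = None,
    overrides: dict[str, str] | None = None,
) -> StructureMapping:
    """Match structures to protocol roles by name tokens (case-insensitive).

    Ipsi/contra lung resolution uses *laterality*. Exact ties raise
    :class:`AmbiguityError`; ties at the same score but different names are
    broken alphabetically. Unmatched roles stay empty (their constraints
    will be NOT-EVALUATED).
    """
    lexicon = lexicon or load_lexicon()
    mapping = StructureMapping()
    names = [s.name for s in structures]
    if len(set(n.lower() for n in names)) != len(names):
        seen: dict[str, str] = {}
        for n in names:
            if n.lower() in seen:
                raise AmbiguityError(
                    f"duplicate structure names (case-insensitive): {seen[n.lower()]!r} / {n!r}"
                )
            seen[n.lower()] = n
    claimed: set[str] = set()

    # lungs first: shared 'LUNG' tokens + side resolution
    lung_tokens = lexicon.get("LUNG", ["lung", "polmone"])
    lungs = [n for n in names if any(_token_matches(n, t) for t in lung_tokens)]
    if laterality != Laterality.BILATERAL and lungs:
        ipsi_side = laterality
        contra_side = (
            Laterality.LEFT if laterality == Laterality.RIGHT else Laterality.RIGHT
        )
        for role, side in (("LUNG_IPSI", ipsi_side), ("LUNG_CONTRA", contra_side)):
            matches = sorted(n for n in lungs if _side_of(n) == side)
            if len(matches) > 1:
                raise AmbiguityError(f"multiple candidates for {role}: {matches}")
            if matches:
                mapping.roles[role] = RoleAssignment(matches[0])
                claimed.add(matches[0])

    for role in _ROLE_ORDER:
        tokens = lexicon.get(role, [])
        if not tokens:
            continue
        candidates = [n for n in names if n not in claimed]
        best, tied = _best_match(tokens, candidates)
        if best is None:
            continue
        if len(tied) > 1 and len({t.lower() for t in tied}) < len(tied):
            raise AmbiguityError(f"structures tie exactly for role {role}: {tied}")
        mapping.roles[role] = RoleAssignment(best)
        claimed.add(best)

    for role, name in (overrides or {}).items():
        if name not in names:
            raise ValidationError(f"override for {role}: no structure named {name!r}")
        mapping.set_override(role, name)
    return mapping
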