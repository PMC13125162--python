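"""ACMG/AMP 2015 evidence model and combining rules.

The 2015 guideline classifies a variant by tallying applied evidence
criteria (PVS1, PS1-PS4, PM1-PM6, PP1-PP5 on the pathogenic side; BA1,
BS1-BS4, BP1-BP7 on the benign side) and matching the tally against a
published table of qualifying combinations.  Criteria carry a *default*
strength implied by their code prefix, but laboratories may apply a
criterion at a modified strength (e.g. ``PP3_Strong``): this module counts
strengths code-agnostically, so a PP3 applied at Strong fills a
strong-pathogenic slot exactly as PS1 would.

Gap cases the published table leaves open are configurable through
:class:`EngineOptions`; the defaults follow common laboratory practice and
are documented in the methods note.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass, field, replace
from enum import Enum, IntEnum
from typing import Iterable, Iterator, Mapping

__all__ = [
    "EvidenceStrength",
    "Polarity",
    "Classification",
    "EvidenceCriterion",
    "AppliedEvidence",
    "EvidenceProfile",
    "EngineOptions",
    "default_strength",
    "combine",
    "enumerate_rule_table",
    "ALL_CODES",
]


class EvidenceStrength(IntEnum):
    """Evidence weight tiers, totally ordered weakest to strongest."""

    SUPPORTING = 1
    MODERATE = 2
    STRONG = 3
    VERY_STRONG = 4
    STAND_ALONE = 5

    @property
    def token(self) -> str:
        return _STRENGTH_TOKENS[self]


_STRENGTH_TOKENS = {
    EvidenceStrength.SUPPORTING: "Supporting",
    EvidenceStrength.MODERATE: "Moderate",
    EvidenceStrength.STRONG: "Strong",
    EvidenceStrength.VERY_STRONG: "VeryStrong",
    EvidenceStrength.STAND_ALONE: "StandAlone",
}
_TOKEN_STRENGTHS = {v.lower(): k for k, v in _STRENGTH_TOKENS.items()}


class Polarity(Enum):
    PATHOGENIC = "pathogenic"
    BENIGN = "benign"


class Classification(IntEnum):
    """Five-tier call, ordered benign end to pathogenic end."""

    BENIGN = 1
    LIKELY_BENIGN = 2
    VUS = 3
    LIKELY_PATHOGENIC = 4
    PATHOGENIC = 5

    @property
    def label(self) -> str:
        return _CLASS_LABELS[self]

    @classmethod
    def from_label(cls, label: str) -> "Classification":
        key = label.strip().lower().replace(" ", "_").replace("-", "_")
        try:
            return _LABEL_CLASSES[key]
        except KeyError:
            raise ValueError(f"unknown classification label: {label!r}") from None


_CLASS_LABELS = {
    Classification.BENIGN: "Benign",
    Classification.LIKELY_BENIGN: "Likely_Benign",
    Classification.VUS: "VUS",
    Classification.LIKELY_PATHOGENIC: "Likely_Pathogenic",
    Classification.PATHOGENIC: "Pathogenic",
}
_LABEL_CLASSES = {
    "benign": Classification.BENIGN,
    "b": Classification.BENIGN,
    "likely_benign": Classification.LIKELY_BENIGN,
    "lb": Classification.LIKELY_BENIGN,
    "vus": Classification.VUS,
    "uncertain_significance": Classification.VUS,
    "likely_pathogenic": Classification.LIKELY_PATHOGENIC,
    "lp": Classification.LIKELY_PATHOGENIC,
    "pathogenic": Classification.PATHOGENIC,
    "p": Classification.PATHOGENIC,
}

#: The full ACMG 2015 criterion catalogue.
ALL_CODES: tuple[str, ...] = (
    ("PVS1",)
    + tuple(f"PS{i}" for i in range(1, 5))
    + tuple(f"PM{i}" for i in range(1, 7))
    + tuple(f"PP{i}" for i in range(1, 6))
    + ("BA1",)
    + tuple(f"BS{i}" for i in range(1, 5))
    + tuple(f"BP{i}" for i in range(1, 8))
)
_CODE_SET = frozenset(ALL_CODES)

_PREFIX_STRENGTH = {
    "PVS": EvidenceStrength.VERY_STRONG,
    "PS": EvidenceStrength.STRONG,
    "PM": EvidenceStrength.MODERATE,
    "PP": EvidenceStrength.SUPPORTING,
    "BA": EvidenceStrength.STAND_ALONE,
    "BS": EvidenceStrength.STRONG,
    "BP": EvidenceStrength.SUPPORTING,
}


def default_strength(code: str) -> EvidenceStrength:
    """Prefix-determined default strength of an ACMG 2015 code.

    Raises
    ------
    ValueError
        If ``code`` is not in the 2015 catalogue.
    """
    code = code.upper()
    if code not in _CODE_SET:
        raise ValueError(f"unknown ACMG 2015 evidence code: {code!r}")
    for prefix in ("PVS", "PS", "PM", "PP", "BA", "BS", "BP"):
        if code.startswith(prefix):
            return _PREFIX_STRENGTH[prefix]
    raise AssertionError("unreachable")  # pragma: no cover


def polarity_of(code: str) -> Polarity:
    code = code.upper()
    if code not in _CODE_SET:
        raise ValueError(f"unknown ACMG 2015 evidence code: {code!r}")
    return Polarity.PATHOGENIC if code.startswith("P") else Polarity.BENIGN


@dataclass(frozen=True)
class EvidenceCriterion:
    """One catalogue entry: code, polarity and prefix-default strength."""

    code: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "code", self.code.upper())
        if self.code not in _CODE_SET:
            raise ValueError(f"unknown ACMG 2015 evidence code: {self.code!r}")

    @property
    def polarity(self) -> Polarity:
        return polarity_of(self.code)

    @property
    def default_strength(self) -> EvidenceStrength:
        return default_strength(self.code)


@dataclass(frozen=True)
class AppliedEvidence:
    """A criterion applied at an effective (possibly modified) strength."""

    criterion: EvidenceCriterion
    strength: EvidenceStrength

    def __post_init__(self) -> None:
        if (
            self.strength is EvidenceStrength.STAND_ALONE
            and self.criterion.polarity is Polarity.BENIGN
            and self.criterion.code != "BA1"
        ):
            raise ValueError(
                f"{self.criterion.code} may not carry StandAlone strength (BA1 only)"
            )

    @property
    def code(self) -> str:
        return self.criterion.code

    @classmethod
    def make(cls, code: str, strength: EvidenceStrength | None = None) -> "AppliedEvidence":
        crit = EvidenceCriterion(code)
        return cls(crit, crit.default_strength if strength is None else strength)

    @property
    def token(self) -> str:
        """Serialized form, ``CODE`` when at default strength else ``CODE_Strength``."""
        if self.strength is self.criterion.default_strength:
            return self.code
        return f"{self.code}_{self.strength.token}"


class EvidenceProfile:
    """The multiset of evidence applied to one variant, at most one entry per code.

    Adding a code already present replaces its previous strength.
    """

    def __init__(self, items: Iterable[AppliedEvidence] = ()) -> None:
        self._items: dict[str, AppliedEvidence] = {}
        for item in items:
            self.add(item)

    def add(self, item: AppliedEvidence) -> None:
        self._items[item.code] = item

    def remove(self, code: str) -> None:
        self._items.pop(code.upper(), None)

    def get(self, code: str) -> AppliedEvidence | None:
        return self._items.get(code.upper())

    def __contains__(self, code: str) -> bool:
        return code.upper() in self._items

    def __iter__(self) -> Iterator[AppliedEvidence]:
        return iter(self._items.values())

    def __len__(self) -> int:
        return len(self._items)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EvidenceProfile):
            return NotImplemented
        return self._items == other._items

    def __repr__(self) -> str:
        return f"EvidenceProfile({self.serialize()!r})"

    def copy(self) -> "EvidenceProfile":
        return EvidenceProfile(self)

    # -- serialization ---------------------------------------------------

    def serialize(self) -> str:
        """Comma-separated tokens in canonical catalogue order."""
        order = {c: i for i, c in enumerate(ALL_CODES)}
        return ",".join(
            item.token for item in sorted(self, key=lambda it: order[it.code])
        )

    @classmethod
    def parse(cls, text: str) -> "EvidenceProfile":
        """Parse ``PM2,PP3_Strong,BS1``-style token lists (suffix case-insensitive)."""
        profile = cls()
        text = text.strip()
        if not text:
            return profile
        for token in text.split(","):
            token = token.strip()
            if not token:
                continue
            code, _, suffix = token.partition("_")
            code = code.upper()
            if suffix:
                key = suffix.replace("_", "").lower()
                # tolerate e.g. "Very_Strong" / "Stand_Alone" spellings
                key2 = suffix.lower().replace("_", "")
                strength = _TOKEN_STRENGTHS.get(key) or _TOKEN_STRENGTHS.get(key2)
                if strength is None:
                    # the code itself may contain no underscore; suffix was part
                    # of an unknown token
                    raise ValueError(f"unknown strength suffix in token {token!r}")
                profile.add(AppliedEvidence.make(code, strength))
            else:
                profile.add(AppliedEvidence.make(code))
        return profile


@dataclass(frozen=True)
class EngineOptions:
    """Switches for the gap cases the 2015 table leaves open.

    single_bs_is_lb
        A single strong benign criterion alone yields Likely Benign
        (otherwise it matches no rule and falls through to VUS).
    ba1_overrides
        BA1 classifies Benign regardless of pathogenic evidence.
    """

    single_bs_is_lb: bool = True
    ba1_overrides: bool = True

    def replace(self, **kw) -> "EngineOptions":
        return replace(self, **kw)


DEFAULT_OPTIONS = EngineOptions()


def _tally(profile: Iterable[AppliedEvidence]) -> tuple[Counter, Counter]:
    path: Counter = Counter()
    ben: Counter = Counter()
    for item in profile:
        if item.criterion.polarity is Polarity.PATHOGENIC:
            path[item.strength] += 1
        else:
            ben[item.strength] += 1
    return path, ben


def _pathogenic_fires(vs: int, s: int, m: int, p: int) -> bool:
    # Published qualifying combinations for Pathogenic, on strength counts.
    if vs >= 2:  # not covered by the 2015 table; see EngineOptions docs
        return True
    if vs == 1 and (s >= 1 or m >= 2 or (m == 1 and p >= 1) or p >= 2):
        return True
    if s >= 2:
        return True
    if s == 1 and (m >= 3 or (m == 2 and p >= 2) or (m == 1 and p >= 4)):
        return True
    return False


def _likely_pathogenic_fires(vs: int, s: int, m: int, p: int) -> bool:
    if vs == 1 and m == 1:
        return True
    if s == 1 and 1 <= m <= 2:
        return True
    if s == 1 and p >= 2:
        return True
    if m >= 3:
        return True
    if m == 2 and p >= 2:
        return True
    if m == 1 and p >= 4:
        return True
    return False


def combine(
    profile: EvidenceProfile | Iterable[AppliedEvidence],
    options: EngineOptions = DEFAULT_OPTIONS,
) -> Classification:
    """Combine an evidence profile into a five-tier classification.

    Strength counting is code-agnostic: a PP3 applied at Strong fills a
    strong-pathogenic slot exactly as PS1 would, and a criterion raised to
    Very Strong fills the very-strong slot exactly as PVS1 would.  A benign
    criterion at Very Strong fills a strong-benign slot (the 2015 table has
    no benign very-strong slot).  If rules fire on both polarities, or no
    rule fires, the call is VUS.
    """
    path, ben = _tally(profile)

    vs = path[EvidenceStrength.VERY_STRONG]
    s = path[EvidenceStrength.STRONG]
    m = path[EvidenceStrength.MODERATE]
    p = path[EvidenceStrength.SUPPORTING]

    ba = ben[EvidenceStrength.STAND_ALONE]
    # benign Very Strong counts toward the strong-benign tally
    bs = ben[EvidenceStrength.STRONG] + ben[EvidenceStrength.VERY_STRONG]
    bm = ben[EvidenceStrength.MODERATE]
    bp = ben[EvidenceStrength.SUPPORTING]

    if ba >= 1 and options.ba1_overrides:
        return Classification.BENIGN

    pathogenic = _pathogenic_fires(vs, s, m, p)
    likely_pathogenic = pathogenic or _likely_pathogenic_fires(vs, s, m, p)

    benign = ba >= 1 or bs >= 2
    # benign Moderate has no slot of its own in 2015; it counts as supporting
    # toward the likely-benign combinations
    bsup = bp + bm
    likely_benign = (
        benign
        or (bs == 1 and bsup >= 1)
        or bsup >= 2
        or (options.single_bs_is_lb and bs >= 1)
    )

    fired_path = pathogenic or likely_pathogenic
    fired_ben = benign or likely_benign
    # Contradictory evidence falls through to VUS.  Beyond the both-sides-fire
    # case, strong-or-stronger evidence of the opposite polarity vetoes a
    # call: {PS1, BS1} is uncertain, while a lone moderate pathogenic item
    # does not block a benign call (a single BP4 upgrade over a PM2 baseline
    # legitimately reaches Likely Benign).
    if fired_path and fired_ben:
        return Classification.VUS
    if fired_ben and (vs + s) >= 1:
        return Classification.VUS
    if fired_path and bs >= 1:
        return Classification.VUS
    if pathogenic:
        return Classification.PATHOGENIC
    if likely_pathogenic:
        return Classification.LIKELY_PATHOGENIC
    if benign:
        return Classification.BENIGN
    if likely_benign:
        return Classification.LIKELY_BENIGN
    return Classification.VUS


# ---------------------------------------------------------------------------
# rule-table enumeration (test/documentation surface)

_PATHOGENIC_LEVELS = (
    EvidenceStrength.VERY_STRONG,
    EvidenceStrength.STRONG,
    EvidenceStrength.MODERATE,
    EvidenceStrength.SUPPORTING,
)
_BENIGN_LEVELS = (
    EvidenceStrength.STAND_ALONE,
    EvidenceStrength.VERY_STRONG,
    EvidenceStrength.STRONG,
    EvidenceStrength.MODERATE,
    EvidenceStrength.SUPPORTING,
)

#: Criterion codes used to materialize abstract strength multisets as
#: profiles (distinct codes so the one-entry-per-code invariant holds).
_PATH_CODES = ("PVS1", "PS1", "PS2", "PS3", "PS4", "PM1", "PM2", "PM3")
_BENIGN_CODES = ("BS1", "BS2", "BS3", "BS4", "BP1", "BP2", "BP3", "BP5")


def profile_from_multisets(
    pathogenic: Mapping[EvidenceStrength, int] | Iterable[EvidenceStrength],
    benign: Mapping[EvidenceStrength, int] | Iterable[EvidenceStrength] = (),
) -> EvidenceProfile:
    """Build a concrete profile realizing abstract per-polarity strength multisets."""

    def expand(ms) -> list[EvidenceStrength]:
        if isinstance(ms, Mapping):
            return [lvl for lvl, n in ms.items() for _ in range(n)]
        return list(ms)

    profile = EvidenceProfile()
    p_levels = expand(pathogenic)
    b_levels = expand(benign)
    if len(p_levels) > len(_PATH_CODES) or len(b_levels) > len(_BENIGN_CODES):
        raise ValueError("multiset too large to realize with distinct codes")
    for code, lvl in zip(_PATH_CODES, p_levels):
        profile.add(AppliedEvidence.make(code, lvl))
    b_codes = iter(_BENIGN_CODES)
    for lvl in b_levels:
        code = "BA1" if lvl is EvidenceStrength.STAND_ALONE else next(b_codes)
        profile.add(AppliedEvidence.make(code, lvl))
    return profile


def enumerate_rule_table(
    max_items: int,
    *,
    sides: tuple[str, ...] = ("pathogenic", "benign"),
    options: EngineOptions = DEFAULT_OPTIONS,
) -> dict[tuple[tuple[EvidenceStrength, ...], tuple[EvidenceStrength, ...]], Classification]:
    """Enumerate combine() over all strength multisets of size <= max_items per polarity.

    Keys are ``(pathogenic_levels, benign_levels)`` tuples sorted strongest
    first; the stand-alone benign level appears at most once (only BA1 may
    carry it).  Used for exhaustive testing and documentation.
    """
    if max_items < 0:
        raise ValueError("max_items must be >= 0")

    def multisets(levels, max_n, max_standalone=None):
        out = []
        for n in range(max_n + 1):
            for combo in itertools.combinations_with_replacement(levels, n):
                if (
                    max_standalone is not None
                    and combo.count(EvidenceStrength.STAND_ALONE) > max_standalone
                ):
                    continue
                out.append(tuple(sorted(combo, reverse=True)))
        return out

    path_sets = (
        multisets(_PATHOGENIC_LEVELS, max_items) if "pathogenic" in sides else [()]
    )
    ben_sets = (
        multisets(_BENIGN_LEVELS, max_items, max_standalone=1)
        if "benign" in sides
        else [()]
    )

    table = {}
    for ps in path_sets:
        for bs in ben_sets:
            profile = profile_from_multisets(ps, bs)
            table[(ps, bs)] = combine(profile, options)
    return table
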