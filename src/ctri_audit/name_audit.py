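"""Person- and organization-name variant detection and clustering.

Registries record the same principal investigator (and the same sponsor)
under many renderings: middle name present or absent, parts abbreviated to
initials, spelling slips, reordered parts, run-on or extra spacing, case
changes, and extraneous honorifics or degree suffixes.  This module detects
those variants with an explainable matching ladder whose rungs map one-to-one
onto the variation categories:

exact after normalization        -> CAPITALS / SPACING / EXTRANEOUS
same tokens once spaces removed  -> SPACING
same token multiset              -> ORDERING
initial-compatible alignment     -> ABBREVIATION (and MIDDLE_NAME when one
                                    token is absent altogether)
small edit distance              -> SPELLING

Anything the ladder cannot justify is DISTINCT.  Two individuals who truly
share a name are merged — an acknowledged false-positive mode that registry
data cannot resolve without persistent person identifiers (ORCID-style).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence, Union

from ._lexicons import CORPORATE_SUFFIXES, DEGREE_SUFFIXES, HONORIFICS
from ._strdist import damerau_levenshtein, within_edit
from .record_model import TrialRecord, is_missing_token

MIDDLE_NAME = "MIDDLE_NAME"
ABBREVIATION = "ABBREVIATION"
SPELLING = "SPELLING"
ORDERING = "ORDERING"
SPACING = "SPACING"
CAPITALS = "CAPITALS"
EXTRANEOUS = "EXTRANEOUS"
CATEGORIES = (MIDDLE_NAME, ABBREVIATION, SPELLING, ORDERING, SPACING, CAPITALS, EXTRANEOUS)

#: verdict for a pair the ladder cannot justify as the same person
DISTINCT = "DISTINCT"

VariantVerdict = Union[frozenset, str]

_PUNCT = re.compile(r"[^\w\s]|_")
_CAMEL = re.compile(r"(?<=[a-z])(?=[A-Z])")


@dataclass(frozen=True)
class NormalizedName:
    """Canonical token form of a raw name plus what normalization removed."""

    raw: str
    tokens: tuple[str, ...]
    stripped_prefix: tuple[str, ...] = ()
    stripped_suffix: tuple[str, ...] = ()

    @property
    def initials(self) -> tuple[str, ...]:
        return tuple(t[0] for t in self.tokens)

    def render(self) -> str:
        return " ".join(self.tokens)


def _split_tokens(raw: str) -> list[str]:
    text = _PUNCT.sub(" ", raw)
    parts: list[str] = []
    for chunk in text.split():
        # keep known honorific/degree chunks atomic: camel-splitting would
        # mangle mixed-case abbreviations like "PhD" or "MBBS"
        if chunk.lower() in HONORIFICS or chunk.lower() in DEGREE_SUFFIXES:
            parts.append(chunk)
        else:
            parts.extend(p for p in _CAMEL.split(chunk) if p)
    return [p.lower() for p in parts]


def normalize_person_name(raw: str) -> NormalizedName:
    """Case-fold, strip punctuation, split run-on camel-case boundaries, and
    strip (but record) leading honorifics and trailing degree suffixes."""
    if is_missing_token(raw):
        raise ValueError("normalize_person_name requires a non-missing name")
    tokens = _split_tokens(raw)
    prefix: list[str] = []
    suffix: list[str] = []
    while len(tokens) > 1 and tokens[0] in HONORIFICS:
        prefix.append(tokens.pop(0))
    while len(tokens) > 1 and tokens[-1] in DEGREE_SUFFIXES:
        suffix.append(tokens.pop())
    suffix.reverse()
    return NormalizedName(raw, tuple(tokens), tuple(prefix), tuple(suffix))


def normalize_org_name(raw: str) -> NormalizedName:
    """Like person-name normalization, but strips trailing corporate suffix
    runs ("... India Private Limited" -> core name) instead of degrees."""
    if is_missing_token(raw):
        raise ValueError("normalize_org_name requires a non-missing name")
    tokens = _split_tokens(raw)
    suffix: list[str] = []
    while len(tokens) > 1 and tokens[-1] in CORPORATE_SUFFIXES:
        suffix.append(tokens.pop())
    suffix.reverse()
    return NormalizedName(raw, tuple(tokens), (), tuple(suffix))


def _initial_pair(a: str, b: str) -> bool:
    if a == b:
        return False
    return (len(a) == 1 and b.startswith(a)) or (len(b) == 1 and a.startswith(b))


def _compatible(a: Sequence[str], b: Sequence[str]) -> tuple[bool, bool]:
    """(all positions equal-or-initial, any initial pair used)."""
    if len(a) != len(b):
        return False, False
    used_initial = False
    for x, y in zip(a, b):
        if x == y:
            continue
        if _initial_pair(x, y):
            used_initial = True
            continue
        return False, False
    return True, used_initial


def _surface_categories(a: NormalizedName, b: NormalizedName) -> frozenset:
    """Attribute the surface difference of two raws that normalize identically."""
    if a.raw == b.raw:
        return frozenset()
    cats = set()
    if (a.stripped_prefix, a.stripped_suffix) != (b.stripped_prefix, b.stripped_suffix):
        cats.add(EXTRANEOUS)
    ra = " ".join(a.raw.split())
    rb = " ".join(b.raw.split())
    if ra.lower() != rb.lower() and re.sub(r"\s+", "", ra.lower()) == re.sub(r"\s+", "", rb.lower()):
        cats.add(SPACING)
    if ra != rb and ra.lower() == rb.lower():
        cats.add(CAPITALS)
    if not cats:
        # residual: punctuation or a case difference entangled with spacing
        stripped_a = re.sub(r"[\W_]+", "", ra.lower())
        stripped_b = re.sub(r"[\W_]+", "", rb.lower())
        cats.add(CAPITALS if stripped_a == stripped_b and ra.lower() != rb.lower() else EXTRANEOUS)
    return frozenset(cats)


def classify_name_variant(
    a: NormalizedName, b: NormalizedName, max_edit: int = 2
) -> VariantVerdict:
    """Judge whether two normalized names plausibly denote the same person.

    Returns the (possibly empty) set of variation categories explaining the
    difference, or :data:`DISTINCT`.  Symmetric in its arguments; exact raw
    duplicates yield the empty set.
    """
    if max_edit < 0:
        raise ValueError("max_edit must be >= 0")
    if a.tokens == b.tokens:
        return _surface_categories(a, b)
    if "".join(a.tokens) == "".join(b.tokens):
        return frozenset({SPACING})
    if sorted(a.tokens) == sorted(b.tokens):
        return frozenset({ORDERING})
    ok, used_initial = _compatible(a.tokens, b.tokens)
    if ok:
        return frozenset({ABBREVIATION}) if used_initial else frozenset()
    if abs(len(a.tokens) - len(b.tokens)) == 1:
        longer, shorter = (a.tokens, b.tokens) if len(a.tokens) > len(b.tokens) else (b.tokens, a.tokens)
        # only interior tokens may be absent: a missing "middle name" is
        # never the leading given name or the trailing surname (dropping a
        # surname and initial-matching the rest conflates distinct people)
        for i in range(1, len(longer) - 1):
            reduced = longer[:i] + longer[i + 1:]
            ok, used_initial = _compatible(reduced, shorter)
            if ok:
                cats = {MIDDLE_NAME}
                if used_initial:
                    cats.add(ABBREVIATION)
                return frozenset(cats)
    if len(a.tokens) == len(b.tokens):
        if all(within_edit(x, y, max_edit) for x, y in zip(a.tokens, b.tokens)):
            return frozenset({SPELLING})
    if within_edit("".join(a.tokens), "".join(b.tokens), max_edit):
        return frozenset({SPELLING})
    return DISTINCT


@dataclass(frozen=True)
class NameCluster:
    """A connected component of the same-person relation."""

    members: tuple[str, ...]
    representative: str


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _cluster(
    raw_names: Sequence[str], normalized: Sequence[NormalizedName], max_edit: int
) -> list[NameCluster]:
    uf = _UnionFind(len(raw_names))
    for i in range(len(raw_names)):
        for j in range(i + 1, len(raw_names)):
            if uf.find(i) == uf.find(j):
                continue
            if classify_name_variant(normalized[i], normalized[j], max_edit) != DISTINCT:
                uf.union(i, j)
    groups: dict[int, list[int]] = {}
    for i in range(len(raw_names)):
        groups.setdefault(uf.find(i), []).append(i)
    clusters = []
    for root in sorted(groups, key=lambda r: min(groups[r])):
        idx = groups[root]
        members = tuple(raw_names[i] for i in idx)
        representative = max(members, key=lambda m: (len(m), -members.index(m)))
        clusters.append(NameCluster(members, representative))
    return clusters


def cluster_names(names: Sequence[str], max_edit: int = 2) -> list[NameCluster]:
    """Connected components of the same-person relation over raw names.

    The representative is the longest member (ties: first seen).  Output is
    deterministic given the input order.
    """
    if not names:
        raise ValueError("cluster_names requires a non-empty list")
    normalized = [normalize_person_name(n) for n in names]
    return _cluster(list(names), normalized, max_edit)


def sponsor_audit(
    records: Iterable[TrialRecord], max_edit: int = 2
) -> tuple[list[NameCluster], dict[str, frozenset[str]]]:
    """Cluster sponsor names and report classification conflicts.

    Returns the clusters over the distinct non-missing sponsor names in the
    registry, plus a map from a cluster's representative to the set of
    sponsor classifications its member records carry, for every cluster with
    at least two distinct classifications.
    """
    seen: dict[str, set[str]] = {}
    order: list[str] = []
    for record in records:
        name = record.sponsor_name
        if is_missing_token(name):
            continue
        if name not in seen:
            seen[name] = set()
            order.append(name)
        if record.sponsor_classification and record.sponsor_classification.strip():
            seen[name].add(record.sponsor_classification.strip())
    if not order:
        return [], {}
    normalized = [normalize_org_name(n) for n in order]
    clusters = _cluster(order, normalized, max_edit)
    conflicts: dict[str, frozenset[str]] = {}
    for cluster in clusters:
        classes = frozenset().union(*(seen[m] for m in cluster.members))
        if len(classes) >= 2:
            conflicts[cluster.representative] = classes
    return clusters, conflicts
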