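"""ICD-10 hierarchical diagnostic grouping.

Implements a two-level view of ICD-10 chapters V ("F" codes, mental and
behavioral disorders) and VI ("G" codes, diseases of the nervous system):

* a *narrow* diagnostic group is a single second-level code (e.g. ``F32``),
  with decimal subcodes such as ``F32.1`` rolled up to their parent;
* a *broad* diagnostic group is a contiguous first-level range
  (e.g. ``G35-G37``).

Group retention follows a sample-size rule with a single threshold
``min_n``: narrow groups with at least ``min_n`` cases are kept; a broad
range is kept only when none of its narrow members qualifies on its own but
the pooled range does.  Comorbidity accounting and the reduction to a
unique (single-diagnosis) case list operate on the retained groups.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import CodeParseError, ConfigError

_CODE_RE = re.compile(r"^([A-Z])(\d{2})(?:\.(\d+))?$")
_RANGE_RE = re.compile(r"^([A-Z])(\d{2})-([A-Z])(\d{2})$")


@dataclass(frozen=True, order=True)
class Icd10Code:
    """A parsed ICD-10 code: chapter letter, 2-digit number, optional subcode.

    Ordering is lexicographic on ``(letter, number)``, matching how ICD-10
    ranges are defined.
    """

    letter: str
    number: int
    subcode: str | None = field(default=None, compare=False)

    @classmethod
    def parse(cls, text: str, participant_id: str | None = None) -> "Icd10Code":
        m = _CODE_RE.match(text.strip())
        if m is None:
            who = f" (participant {participant_id})" if participant_id else ""
            raise CodeParseError(f"unparseable ICD-10 code {text!r}{who}")
        return cls(m.group(1), int(m.group(2)), m.group(3))

    @property
    def parent(self) -> "Icd10Code":
        """The 2-digit second-level code this code rolls up to."""
        return Icd10Code(self.letter, self.number)

    def __str__(self) -> str:
        base = f"{self.letter}{self.number:02d}"
        return f"{base}.{self.subcode}" if self.subcode else base


def parse_range(label: str) -> tuple[Icd10Code, Icd10Code]:
    """Parse a broad-range label like ``"G35-G37"`` into (low, high) codes."""
    m = _RANGE_RE.match(label.strip())
    if m is None:
        # single-code "range" such as "F99"
        code = Icd10Code.parse(label)
        return code, code
    lo = Icd10Code(m.group(1), int(m.group(2)))
    hi = Icd10Code(m.group(3), int(m.group(4)))
    if lo.letter != hi.letter or lo > hi:
        raise ConfigError(f"invalid ICD-10 range {label!r}")
    return lo, hi


def code_in_range(code: Icd10Code, label: str) -> bool:
    lo, hi = parse_range(label)
    return code.letter == lo.letter and lo.number <= code.number <= hi.number


@dataclass(frozen=True)
class DiagnosticGroup:
    """A retained diagnostic group at broad or narrow level.

    ``label`` is the narrow code ("F32") or the broad range ("G35-G37");
    ``case_ids`` is the set of participant IDs whose code set places them in
    the group.
    """

    label: str
    level: str  # "broad" | "narrow"
    case_ids: frozenset

    def __post_init__(self):
        if self.level not in ("broad", "narrow"):
            raise ConfigError(f"level must be broad|narrow, got {self.level!r}")
        if not self.case_ids:
            raise ConfigError(f"group {self.label} has no cases")

    @property
    def n_cases(self) -> int:
        return len(self.case_ids)


Hierarchy = Sequence[tuple[str, Sequence[str]]]
"""A hierarchy is an ordered list of (broad range label, narrow code list)."""


def default_hierarchy() -> list[tuple[str, list[str]]]:
    """The shipped two-level hierarchy for ICD-10 chapters V and VI.

    Loaded from packaged YAML; each first-level block of chapters V/VI with
    every second-level code it contains.
    """
    text = resources.files("transdx.data").joinpath("icd10_fg_hierarchy.yaml").read_text()
    raw = yaml.safe_load(text)
    return [(entry["range"], list(entry["narrow"])) for entry in raw]


def _validate_hierarchy(hierarchy: Hierarchy) -> None:
    seen: list[tuple[Icd10Code, Icd10Code, str]] = []
    for broad, narrows in hierarchy:
        lo, hi = parse_range(broad)
        for plo, phi, plabel in seen:
            if lo.letter == plo.letter and not (hi.number < plo.number or lo.number > phi.number):
                raise ConfigError(f"hierarchy ranges overlap: {plabel} and {broad}")
        seen.append((lo, hi, broad))
        for code in narrows:
            if not code_in_range(Icd10Code.parse(code), broad):
                raise ConfigError(f"narrow code {code} outside its broad range {broad}")


def _codes_of(row_value) -> list[Icd10Code]:
    if isinstance(row_value, str):
        parts = [p for p in row_value.split(";") if p.strip()]
    elif row_value is None or (isinstance(row_value, float) and np.isnan(row_value)):
        parts = []
    else:
        parts = [str(c) for c in row_value]
    return parts


def assign_members(
    participants: pd.DataFrame, hierarchy: Hierarchy | None = None
) -> dict[str, set]:
    """Map every hierarchy label (broad and narrow) to its member case IDs.

    A participant belongs to a narrow group iff any of their codes rolls up
    to that second-level code, and to a broad group iff any code falls in
    the range.  Labels with no members are included with empty sets so the
    retention rule can inspect all three branches uniformly.

    Parameters
    ----------
    participants
        Table with columns ``id`` and ``icd10`` (semicolon-delimited string
        or iterable of code strings; empty means no diagnoses).
    hierarchy
        ``[(broad_range, [narrow codes...]), ...]``; defaults to the shipped
        chapters V/VI hierarchy.
    """
    if hierarchy is None:
        hierarchy = default_hierarchy()
    _validate_hierarchy(hierarchy)
    membership: dict[str, set] = {}
    for broad, narrows in hierarchy:
        membership[broad] = set()
        for code in narrows:
            membership[code] = set()
    for pid, raw in zip(participants["id"], participants["icd10"]):
        for text in _codes_of(raw):
            code = Icd10Code.parse(text, participant_id=str(pid)).parent
            for broad, narrows in hierarchy:
                if code_in_range(code, broad):
                    membership[broad].add(pid)
                    if str(code) in narrows:
                        membership[str(code)].add(pid)
    return membership


def retain_groups(
    membership: Mapping[str, Iterable],
    hierarchy: Hierarchy | None = None,
    min_n: int = 125,
) -> list[DiagnosticGroup]:
    """Apply the two-level retention rule.

    For each broad range: every narrow group with ``>= min_n`` cases is
    retained at the narrow level.  If no narrow group qualifies but the
    broad range pooled together reaches ``min_n``, the broad group is
    retained instead.  Ranges failing both ways contribute nothing; when a
    narrow sibling qualifies, the under-threshold siblings are dropped, not
    merged into a broad remainder.
    """
    if hierarchy is None:
        hierarchy = default_hierarchy()
    _validate_hierarchy(hierarchy)
    retained: list[DiagnosticGroup] = []
    for broad, narrows in hierarchy:
        narrow_kept = False
        for code in narrows:
            ids = frozenset(membership.get(code, ()))
            if len(ids) >= min_n:
                retained.append(DiagnosticGroup(code, "narrow", ids))
                narrow_kept = True
        if not narrow_kept:
            ids = frozenset(membership.get(broad, ()))
            if len(ids) >= min_n:
                retained.append(DiagnosticGroup(broad, "broad", ids))
    return retained


def comorbidity_stats(
    groups: Sequence[DiagnosticGroup],
) -> tuple[float, pd.DataFrame]:
    """Overall comorbidity rate and pairwise conditional overlap.

    The overall rate is the proportion of diagnosed individuals (members of
    at least one retained group) who belong to more than one.  The overlap
    matrix entry ``[a, b]`` is ``P(member of b | member of a)``; its
    diagonal is 1 by construction.
    """
    if not groups:
        raise ConfigError("comorbidity_stats requires at least one group")
    labels = [g.label for g in groups]
    sets = {g.label: set(g.case_ids) for g in groups}
    counts: dict = {}
    for s in sets.values():
        for pid in s:
            counts[pid] = counts.get(pid, 0) + 1
    n_any = len(counts)
    n_multi = sum(1 for c in counts.values() if c > 1)
    rate = n_multi / n_any if n_any else 0.0
    mat = pd.DataFrame(0.0, index=labels, columns=labels)
    for a in labels:
        for b in labels:
            mat.loc[a, b] = len(sets[a] & sets[b]) / len(sets[a])
    return rate, mat


def unique_case_list(groups: Sequence[DiagnosticGroup]) -> dict[str, set]:
    """Restrict each group to individuals carrying exactly one group label.

    The returned sets are pairwise disjoint; anyone in two or more retained
    groups is excluded everywhere.
    """
    counts: dict = {}
    for g in groups:
        for pid in g.case_ids:
            counts[pid] = counts.get(pid, 0) + 1
    return {g.label: {pid for pid in g.case_ids if counts[pid] == 1} for g in groups}
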