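"""Low-level name analysis: tokenisation, edit distance, pattern detectors.

Everything here is pure text-in/values-out; thresholds (how long a digit run
is "obscure", how close two tokens are "the same word misspelled") live in
the checks layer's configuration, not here.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

#: Characters treated as word-boundary separators inside names.
SEPARATOR_CHARS = " _-."

_SEP_RE = re.compile(r"[ _\-.]+")
_SEP_NO_HYPHEN_RE = re.compile(r"[ _.]+")


@dataclass
class TokenList:
    """Tokens plus the separator runs consumed between (and around) them.

    ``separators`` has ``len(tokens) + 1`` elements: the run before the
    first token, between each pair, and after the last (any may be empty),
    so :meth:`join` reproduces the original name exactly.
    """

    tokens: list[str]
    separators: list[str]

    def join(self) -> str:
        out = [self.separators[0]]
        for tok, sep in zip(self.tokens, self.separators[1:]):
            out.append(tok)
            out.append(sep)
        return "".join(out)


@dataclass
class PatternMatch:
    """A detected substring pattern with its half-open character span."""

    kind: str  # "digit_run" | "date" | "figure_ref"
    span: tuple[int, int]
    text: str


def tokenize(name: str, keep_hyphens: bool = False) -> TokenList:
    """Split a name on runs of space, underscore, hyphen and period.

    Tokens are never empty and re-joining with the recorded separators is
    the identity.  With ``keep_hyphens=True`` hyphens stay inside tokens:
    per the naming convention hyphens mark keywords (``covid-19``), so
    consistency comparisons treat a hyphenated keyword as one unit.
    """
    sep_re = _SEP_NO_HYPHEN_RE if keep_hyphens else _SEP_RE
    tokens: list[str] = []
    separators: list[str] = []
    pos = 0
    pending_sep = ""
    for m in sep_re.finditer(name):
        if m.start() > pos:
            tokens.append(name[pos : m.start()])
            separators.append(pending_sep)
            pending_sep = ""
        pending_sep += m.group(0)
        pos = m.end()
    if pos < len(name):
        tokens.append(name[pos:])
        separators.append(pending_sep)
        pending_sep = ""
    separators.append(pending_sep)
    # leading separator run belongs in slot 0; the loop above already puts
    # it there because the first token's preceding run is accumulated first
    return TokenList(tokens=tokens, separators=separators)


def edit_distance(a: str, b: str) -> int:
    """Unrestricted Damerau–Levenshtein distance.

    Unit-cost substitutions, insertions, deletions and adjacent
    transpositions, with no restriction on later edits touching transposed
    characters (the Lowrance–Wagner formulation).  Unlike the restricted
    variant this is a true metric, which matters when clustering
    near-duplicate names.
    """
    la, lb = len(a), len(b)
    if la == 0:
        return lb
    if lb == 0:
        return la
    inf = la + lb
    # d has a sentinel row/column at index 0 holding `inf`
    d = [[0] * (lb + 2) for _ in range(la + 2)]
    d[0][0] = inf
    for i in range(la + 1):
        d[i + 1][0] = inf
        d[i + 1][1] = i
    for j in range(lb + 1):
        d[0][j + 1] = inf
        d[1][j + 1] = j
    last_row: dict[str, int] = {}
    for i in range(1, la + 1):
        last_col = 0
        for j in range(1, lb + 1):
            k = last_row.get(b[j - 1], 0)
            l = last_col
            if a[i - 1] == b[j - 1]:
                cost = 0
                last_col = j
            else:
                cost = 1
            d[i + 1][j + 1] = min(
                d[i][j] + cost,          # substitute / match
                d[i + 1][j] + 1,         # insert
                d[i][j + 1] + 1,         # delete
                d[k][l] + (i - k - 1) + 1 + (j - l - 1),  # transpose block
            )
        last_row[a[i - 1]] = i
    return d[la + 1][lb + 1]


_DATE_PATTERNS = [
    # (regex, year group, month group, day group)
    (re.compile(r"(?<!\d)(\d{4})-(\d{2})-(\d{2})(?!\d)"), 1, 2, 3),
    (re.compile(r"(?<!\d)(\d{4})_(\d{2})_(\d{2})(?!\d)"), 1, 2, 3),
    (re.compile(r"(?<!\d)(\d{2})-(\d{2})-(\d{4})(?!\d)"), 3, 2, 1),
    (re.compile(r"(?<!\d)(\d{4})(\d{2})(\d{2})(?!\d)"), 1, 2, 3),
]


def _plausible(year: int, month: int, day: int) -> bool:
    return 1900 <= year <= 2099 and 1 <= month <= 12 and 1 <= day <= 31


def detect_dates(name: str) -> list[PatternMatch]:
    """Date-like substrings (YYYYMMDD, YYYY-MM-DD, YYYY_MM_DD, DD-MM-YYYY).

    A loose plausibility filter (year 1900–2099, month 01–12, day 01–31)
    keeps arbitrary 8-digit identifiers from being read as dates.
    """
    matches: list[PatternMatch] = []
    taken: list[tuple[int, int]] = []
    for pattern, gy, gm, gd in _DATE_PATTERNS:
        for m in pattern.finditer(name):
            span = m.span()
            if any(span[0] < e and s < span[1] for s, e in taken):
                continue
            try:
                year, month, day = int(m.group(gy)), int(m.group(gm)), int(m.group(gd))
            except ValueError:  # pragma: no cover - groups are all-digit
                continue
            if _plausible(year, month, day):
                matches.append(PatternMatch("date", span, m.group(0)))
                taken.append(span)
    matches.sort(key=lambda p: p.span)
    return matches


_DIGIT_RUN_RE = re.compile(r"\d+")


def detect_digit_runs(name: str, min_len: int) -> list[PatternMatch]:
    """Maximal decimal-digit runs of length >= ``min_len``.

    Runs that are part of a detected date are excluded — an 8-digit run
    that reads as a plausible date is reported as a date, not as an
    obscure identifier.
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    date_spans = [m.span for m in detect_dates(name)]
    matches = []
    for m in _DIGIT_RUN_RE.finditer(name):
        if m.end() - m.start() < min_len:
            continue
        if any(m.start() < e and s < m.end() for s, e in date_spans):
            continue
        matches.append(PatternMatch("digit_run", m.span(), m.group(0)))
    return matches


_FIGURE_RE = re.compile(
    r"(?<![A-Za-z])(?:figure|fig)(?![A-Za-z])(?:[ _\-.]*\d+)?",
    re.IGNORECASE,
)


def detect_figure_refs(name: str) -> list[PatternMatch]:
    """References to paper figures: ``figure``/``fig``, optionally numbered.

    Word-bounded so that e.g. "configuration" never matches.
    """
    return [PatternMatch("figure_ref", m.span(), m.group(0)) for m in _FIGURE_RE.finditer(name)]
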