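"""The rule registry: every organisation recommendation as a pure check.

Each check is a pure function ``(DatasetTree, CheckConfig) -> [Finding]``.
Severity model: hard limits (path length, forbidden characters, files per
folder) are warnings; stylistic points (letter case, excluded words) are
info; nothing is an error by default — the linter advises on best practice,
it does not block.
"""

from __future__ import annotations

import fnmatch
import math
import re
from dataclasses import dataclass, field, fields as dc_fields
from typing import Callable, Iterable, Optional

import yaml

from . import lexicon
from .tree_model import DatasetTree, TreeEntry

# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

PORTABLE_CHARS = (
    "ABCDEFGHIJKLMNOPQRSTUVWXYZ"
    "abcdefghijklmnopqrstuvwxyz"
    "0123456789._-"
)

#: Extensions that are really one compound suffix; the inner period is fine.
DEFAULT_MULTI_EXTENSIONS = (".tar.gz", ".ome.tiff", ".ome.tif", ".ome.tf2", ".ome.tf8", ".ome.btf")

DEFAULT_OPEN_FORMATS = {
    ".tif": "TIFF",
    ".tiff": "TIFF",
    ".ome.tiff": "OME-TIFF",
    ".ome.tif": "OME-TIFF",
    ".png": "PNG",
    ".mrc": "MRC",
    ".rec": "MRC",
    ".zarr": "OME-NGFF (Zarr)",
    ".h5": "HDF5",
    ".zip": "ZIP archive",
    ".txt": "plain text",
}

DEFAULT_PROPRIETARY_FORMATS = {
    ".czi": "Zeiss CZI",
    ".lif": "Leica LIF",
    ".nd2": "Nikon ND2",
    ".ims": "Imaris IMS",
    ".lsm": "Zeiss LSM",
    ".oib": "Olympus OIB",
    ".oif": "Olympus OIF",
    ".vsi": "Olympus VSI",
    ".mrxs": "3DHISTECH MIRAX",
}


@dataclass
class CheckConfig:
    """All thresholds and vocabularies in one place.

    Defaults follow the published archival recommendations: 50-character
    names, 320-character paths (the legacy IMOD input limit), at most four
    folder levels and at most 10,000 files per folder.  Every bound is
    inclusive: a 50-character name passes, a 51-character one fails.
    """

    max_name_length: int = 50
    max_path_length: int = 320
    max_depth: int = 4
    depth_counts_root: bool = True
    max_files_per_folder: int = 10_000
    portable_chars: str = PORTABLE_CHARS
    forbidden_chars_note: str = "&!? "
    excluded_words: set[str] = field(default_factory=lambda: {"files", "data", "images"})
    exempt_root_excluded_words: bool = True
    multi_extension_whitelist: set[str] = field(
        default_factory=lambda: set(DEFAULT_MULTI_EXTENSIONS)
    )
    min_digit_run: int = 6
    sibling_distance_threshold: int = 1
    repetition_min_token_len: int = 3
    personal_id_blocklist: set[str] = field(default_factory=set)
    open_formats: dict[str, str] = field(default_factory=lambda: dict(DEFAULT_OPEN_FORMATS))
    proprietary_formats: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_PROPRIETARY_FORMATS)
    )
    readme_patterns: set[str] = field(
        default_factory=lambda: {"readme", "readme.txt", "readme.md"}
    )
    checksum_patterns: set[str] = field(
        default_factory=lambda: {"md5*", "sha256*", "sha512*", "*.par2", "*sums.txt", "*hashes.txt"}
    )
    mixed_content_min_files: int = 20
    mixed_content_max_classes: int = 3

    def __post_init__(self) -> None:
        for name in (
            "max_name_length",
            "max_path_length",
            "max_depth",
            "max_files_per_folder",
            "min_digit_run",
            "sibling_distance_threshold",
            "repetition_min_token_len",
            "mixed_content_min_files",
            "mixed_content_max_classes",
        ):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        self.excluded_words = {w.lower() for w in self.excluded_words}

    @classmethod
    def from_dict(cls, data: dict) -> "CheckConfig":
        valid = {f.name for f in dc_fields(cls)}
        unknown = set(data) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = {}
        for f in dc_fields(cls):
            if f.name not in data:
                continue
            value = data[f.name]
            if isinstance(getattr(cls(), f.name, None), set) and isinstance(value, list):
                value = set(value)
            coerced[f.name] = value
        return cls(**coerced)

    @classmethod
    def from_file(cls, path: str) -> "CheckConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path!r} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = {}
        for f in dc_fields(self):
            value = getattr(self, f.name)
            if isinstance(value, set):
                value = sorted(value)
            out[f.name] = value
        return out

    def file_extension(self, name: str) -> str:
        """Extension of a file name, honouring the multi-part whitelist."""
        low = name.lower()
        for ext in sorted(self.multi_extension_whitelist, key=len, reverse=True):
            if low.endswith(ext) and len(low) > len(ext):
                return ext
        idx = low.rfind(".")
        if idx <= 0 or idx == len(low) - 1:
            return ""
        return low[idx:]


SEVERITY_ORDER = {"info": 0, "warning": 1, "error": 2}


@dataclass
class Finding:
    """One detected violation bound to a check, severity and subject paths."""

    check_id: str
    recommendation: str
    severity: str
    paths: list[str]
    message: str
    suggestion: Optional[dict] = None

    def as_dict(self) -> dict:
        return {
            "check_id": self.check_id,
            "recommendation": self.recommendation,
            "severity": self.severity,
            "paths": list(self.paths),
            "message": self.message,
            "suggestion": self.suggestion,
        }


# ---------------------------------------------------------------------------
# Small shared helpers
# ---------------------------------------------------------------------------

_DIGITS_RE = re.compile(r"[0-9]+")
_ALPHA_RE = re.compile(r"[a-z]+")

_EXT_CLASS_ALIASES = {"tif": "tiff", "jpg": "jpeg", "jpeg": "jpeg", "tiff": "tiff"}


def name_skeleton(name: str) -> str:
    """Structural shape of a name: digit runs -> ``#``, letter runs -> ``a``.

    Two names with equal skeletons differ only in which letters/digits fill
    the same slots — e.g. every ``child00`` … ``child99`` shares a skeleton.
    """
    low = name.casefold()
    low = _DIGITS_RE.sub("#", low)
    return _ALPHA_RE.sub("a", low)


def _digits_only_differ(a: str, b: str) -> bool:
    """True when two names differ only inside digit runs (sequence variants)."""
    return a != b and _DIGITS_RE.sub("#", a) == _DIGITS_RE.sub("#", b)


def extension_class(ext: str) -> str:
    stripped = ext.lstrip(".").lower()
    return _EXT_CLASS_ALIASES.get(stripped, stripped)


def _tokens(name: str, keep_hyphens: bool = False) -> list[str]:
    return lexicon.tokenize(name, keep_hyphens=keep_hyphens).tokens


# ---------------------------------------------------------------------------
# Structure checks (top-level folder, sizes, depth, redundancy)
# ---------------------------------------------------------------------------


def check_name_length(tree: DatasetTree, config: CheckConfig) -> list[Finding]:
    findings = []
    for path, entry, _depth in tree.walk():
        if len(entry.name) > config.max_name_length:
            findings.append(
                Finding(
                    check_id="name_length",
                    recommendation="R3a",
                    severity="warning",
                    paths=[path],
                    message=(
                        f"name is {len(entry.name)} characters long "
                        f"(limit {config.max_name_length})"
                    ),
                    suggestion={"shorten_to": config.max_name_length},
                )
            )
    return findings


def check_path_length(tree: DatasetTree, config: CheckConfig) -> list[Finding]:
    findings = []
    for path, _entry, _depth in tree.walk():
        if len(path) > config.max_path_length:
            findings.append(
                Finding(
                    check_id="path_length",
                    recommendation="R3a",
                    severity="warning",
                    paths=[path],
                    message=(
                        f"path is {len(path)} characters long "
                        f"(limit {config.max_path_length}; legacy software such as "
                        f"IMOD rejects longer input paths)"
                    ),
                )
            )
    return findings


def check_depth(tree: DatasetTree, config: CheckConfig) -> list[Finding]:
    """Folders nested deeper than the configured maximum number of levels.

    With ``depth_counts_root`` (the default) the top-level folder is level 1.
    """
    findings = []
    offset = 0 if config.depth_counts_root else 1
    for path, entry, depth in tree.walk():
        if entry.is_folder and depth - offset > config.max_depth:
            findings.append(
                Finding(
                    check_id="depth",
                    recommendation="R3b",
                    severity="warning",
                    paths=[path],
                    message=(
                        f"folder is at level {depth - offset} "
                        f"(limit {config.max_depth}); deep nesting makes navigation hard"
                    ),
                )
            )
    return findings


def check_files_per_folder(tree: DatasetTree, config: CheckConfig) -> list[Finding]:
    findings = []
    cap = config.max_files_per_folder
    for path, entry, _depth in tree.walk():
        if not entry.is_folder:
            continue
        n = sum(1 for c in entry.children if c.is_file)
        if n > cap:
            n_sub = math.ceil(n / cap)
            width = max(2, len(str(n_sub - 1)))
            findings.append(
                Finding(
                    check_id="files_per_folder",
                    recommendation="R3d",
                    severity="warning",
                    paths=[path],
                    message=(
                        f"folder holds {n} files (limit {cap}); split into "
                        f"{n_sub} sub-folders (child{'0' * width} to "
                        f"child{str(n_sub - 1).zfill(width)})"
                    ),
                    suggestion={"split": {"n_subfolders": n_sub, "cap": cap, "width": width}},
                )
            )
    return findings


def _iter_chains(tree: DatasetTree):
    """Yield maximal runs of folders whose only child is a folder."""
    for path, entry, _depth, ancestors in tree.walk_with_ancestors():
        if not entry.is_folder:
            continue
        is_link = len(entry.children) == 1 and entry.children[0].is_folder
        if not is_link:
            continue
        parent = ancestors[-1] if ancestors else None
        parent_is_link = (
            parent is not None
            and len(parent.children) == 1
            and parent.children[0].is_folder
        )
        if parent_is_link:
            continue  # not the head of a maximal chain
        chain = [path]
        node = entry.children[0]
        node_path = f"{path}/{node.name}"
        while len(node.children) == 1 and node.children[0].is_folder:
            chain.append(node_path)
            node = node.children[0]
            node_path = f"{node_path}/{node.name}"
        yield chain, node_path


def check_redundant_folders(tree: DatasetTree, config: CheckConfig) -> list[Finding]:
    """Single-child folder chains, and folders named after their only format.

    A folder named e.g. ``tiff`` that holds nothing but TIFF files adds no
    information — unless a sibling folder holds a different format, in which
    case the per-format split is meaningful.
    """
    findings = []
    for chain, terminal in _iter_chains(tree):
        findings.append(
            Finding(
                check_id="redundant_folders",
                recommendation="R3c",
                severity="warning",
                paths=list(chain),
                message=(
                    f"{len(chain)} folder(s) each contain only a single folder; "
                    f"the data only starts at {terminal!r}"
                ),
                suggestion={"collapse_to": terminal},
            )
        )
    # format-named folders
    for path, entry, _depth in tree.walk():
        if not entry.is_folder:
            continue
        folder_children = [c for c in entry.children if c.is_folder]
        for sub in folder_children:
            if not sub.children or not all(c.is_file for c in sub.children):
                continue
            classes = {extension_class(config.file_extension(c.name)) for c in sub.children}
            if len(classes) != 1:
                continue
            cls = classes.pop()
            raw_exts = {
                config.file_extension(c.name).lstrip(".") for c in sub.children
            }
            if not cls or sub.name.lower() not in raw_exts | {cls}:
                continue
            # exception: siblings split by format are meaningful
            sibling_classes = set()
            for other in folder_children:
                if other is sub or not other.children:
                    continue
                if all(c.is_file for c in other.children):
                    oc = {
                        extension_class(config.file_extension(c.name))
                        for c in other.children
                    }
                    if len(oc) == 1:
                        sibling_classes |= oc
            if sibling_classes - {cls}:
                continue
            findings.append(
                Finding(
                    check_id="redundant_folders",
                    recommendation="R3c",
                    severity="warning",
                    paths=[f"{path}/{sub.name}"],
                    message=(
                        f"folder {sub.name!r} only restates the format of the "
                        f"{cls} files it holds"
                    ),
                    suggestion={"collapse_to": path},
                )
            )
    return findings


# ---------------------------------------------------------------------------
# Character-level naming checks
# ---------------------------------------------------------------------------


def check_characters(tree: DatasetTree, config: CheckConfig) -> list[Finding]:
    """Characters outside the POSIX portable set, plus a case advisory."""
    findings = []
    portable = set(config.portable_chars)
    noted = set(config.forbidden_chars_note)
    for path, entry, _depth in tree.walk():
        seen: set[str] = set()
        for ch in entry.name:
            if ch in portable or ch in seen:
                continue
            seen.add(ch)
            if ch == " ":
                msg = "name contains spaces"
            elif ch in noted:
                msg = f"name contains the problematic character {ch!r}"
            elif ord(ch) > 127:
                msg = f"name contains the non-ASCII character {ch!r} (U+{ord(ch):04X})"
            else:
                msg = f"name contains the non-portable character {ch!r}"
            findings.append(
                Finding(
                    check_id="characters",
                    recommendation="R6b",
                    severity="warning",
                    paths=[path],
                    message=msg,
                    suggestion={"character": ch},
                )
            )
        if any("A" <= ch <= "Z" for ch in entry.name):
            findings.append(
                Finding(
                    check_id="characters",
                    recommendation="R6a",
                    severity="info",
                    paths=[path],
                    message="name contains uppercase letters; prefer all-lowercase names",
                    suggestion={"case": "lower"},
                )
            )
    return findings


def check_periods(tree: DatasetTree, config: CheckConfig) -> list[Finding]:
    """Periods outside a (possibly multi-part) file extension."""
    findings = []
    for path, entry, _depth in tree.walk():
        if entry.is_file:
            ext = config.file_extension(entry.name)
            stem = entry.name[: len(entry.name) - len(ext)] if ext else entry.name
        else:
            stem = entry.name
        n_periods = stem.count(".")
        if n_periods:
            where = "folder name" if entry.is_folder else "file name stem"
            findings.append(
                Finding(
                    check_id="periods",
                    recommendation="R6c",
                    severity="warning",
                    paths=[path],
                    message=(
                        f"{where} contains {n_periods} period(s); periods should "
                        f"only separate a file extension"
                    ),
                )
            )
    return findings


def check_excluded_words(tree: DatasetTree, config: CheckConfig) -> list[Finding]:
    """Names containing filler words ('files', 'data', 'images', ...).

    The single top-level folder is exempt: a generic root such as ``data/``
    is conventional and carries the dataset context itself.
    """
    findings = []
    root_paths = {r.name for r in tree.roots} if config.exempt_root_excluded_words else set()
    for path, entry, _depth in tree.walk():
        if path in root_paths:
            continue
        hits = sorted(
            {t.lower() for t in _tokens(entry.name) if t.lower() in config.excluded_words}
        )
        for word in hits:
            findings.append(
                Finding(
                    check_id="excluded_words",
                    recommendation="R7c",
                    severity="info",
                    paths=[path],
                    message=f"name contains the uninformative word {word!r}",
                    suggestion={"drop_token": word},
                )
            )
    return findings


def check_path_repetition(tree: DatasetTree, config: CheckConfig) -> list[Finding]:
    """Tokens repeated from an ancestor folder's name.

    A folder name applies to everything below it; repeating its tokens in
    descendants wastes name space.  Only tokens of at least
    ``repetition_min_token_len`` characters count, so short connectives
    never fire.
    """
    findings = []
    min_len = config.repetition_min_token_len
    for path, entry, _depth, ancestors in tree.walk_with_ancestors():
        if not ancestors:
            continue
        ancestor_tokens = {
            t.lower()
            for anc in ancestors
            for t in _tokens(anc.name)
            if len(t) >= min_len
        }
        seen: set[str] = set()
        for tok in _tokens(entry.name):
            low = tok.lower()
            if len(tok) >= min_len and low in ancestor_tokens and low not in seen:
                seen.add(low)
                findings.append(
                    Finding(
                        check_id="path_repetition",
                        recommendation="R7d",
                        severity="warning",
                        paths=[path],
                        message=(
                            f"token {tok!r} already appears in an ancestor "
                            f"folder name"
                        ),
                        suggestion={"drop_token": tok},
                    )
                )
    return findings


# ---------------------------------------------------------------------------
# Consistency checks (near-duplicates, cohorts)
# ---------------------------------------------------------------------------

_STRIP_SEPS_RE = re.compile(r"[ _\-.]+")

#: pairwise comparison is quadratic; above this many names/tokens the
#: distance and prefix rules are skipped (grouping rules still apply)
_PAIRWISE_CAP = 400


def _classify_pair(a: str, b: str, threshold: int) -> Optional[str]:
    """How two names/tokens relate: case, separator, prefix or typo variant.

    Pairs that differ only inside digit runs are deliberately ignored —
    sequential siblings (``child00``/``child01``) are expected, not typos.
    """
    if a == b:
        return None
    af, bf = a.casefold(), b.casefold()
    if af == bf:
        return "case"
    sa, sb = _STRIP_SEPS_RE.sub("", af), _STRIP_SEPS_RE.sub("", bf)
    if sa and sa == sb:
        return "separator"
    if _digits_only_differ(af, bf):
        return None
    if af.isalpha() and bf.isalpha() and (af.startswith(bf) or bf.startswith(af)):
        return "prefix"
    if abs(len(af) - len(bf)) <= threshold and lexicon.edit_distance(af, bf) <= threshold:
        return "typo"
    return None


_VARIANT_MESSAGES = {
    "case": "differ only in letter case",
    "separator": "differ only in separator characters",
    "prefix": "one is a truncation of the other",
    "typo": "differ by a subtle spelling change",
}


def check_sibling_near_duplicates(tree: DatasetTree, config: CheckConfig) -> list[Finding]:
    """Name/token pairs that are suspiciously alike.

    Two modes: full sibling names within each folder, and name tokens across
    the whole tree.  Flags case variants ('Topology'/'topology'), separator
    variants ('Tr1-323'/'Tr1323'), truncations ('tomo'/'tomogram') and
    spelling slips within the configured edit distance
    ('Treatment'/'Treatement').  Each pair is reported once.
    """
    threshold = config.sibling_distance_threshold
    findings = []
    reported: set[frozenset[str]] = set()

    def report(a: str, b: str, variant: str, path_a: str, path_b: str) -> None:
        key = frozenset((a, b))
        if key in reported:
            return
        reported.add(key)
        paths = sorted({path_a, path_b})
        findings.append(
            Finding(
                check_id="sibling_near_duplicates",
                recommendation="R7a",
                severity="warning",
                paths=paths,
                message=f"{a!r} and {b!r} {_VARIANT_MESSAGES[variant]}",
                suggestion={"variant": variant, "a": a, "b": b},
            )
        )

    # mode 1: sibling names within each folder
    for path, entry, _depth in tree.walk():
        if not entry.is_folder or len(entry.children) > _PAIRWISE_CAP:
            continue
        kids = entry.children
        for i in range(len(kids)):
            for j in range(i + 1, len(kids)):
                variant = _classify_pair(kids[i].name, kids[j].name, threshold)
                if variant:
                    report(
                        kids[i].name,
                        kids[j].name,
                        variant,
                        f"{path}/{kids[i].name}",
                        f"{path}/{kids[j].name}",
                    )

    # mode 2: tokens across the whole tree
    token_paths: dict[str, str] = {}
    for path, entry, _depth in tree.walk():
        for tok in _tokens(entry.name, keep_hyphens=True):
            if len(tok) < 3 or tok.isdigit():
                continue
            token_paths.setdefault(tok, path)
    tokens = sorted(token_paths)
    if len(tokens) <= _PAIRWISE_CAP:
        for i in range(len(tokens)):
            for j in range(i + 1, len(tokens)):
                variant = _classify_pair(tokens[i], tokens[j], threshold)
                if variant:
                    report(
                        tokens[i],
                        tokens[j],
                        variant,
                        token_paths[tokens[i]],
                        token_paths[tokens[j]],
                    )
    else:
        by_fold: dict[str, list[str]] = {}
        for tok in tokens:
            by_fold.setdefault(_STRIP_SEPS_RE.sub("", tok.casefold()), []).append(tok)
        for group in by_fold.values():
            for i in range(len(group)):
                for j in range(i + 1, len(group)):
                    variant = _classify_pair(group[i], group[j], threshold)
                    if variant:
                        report(
                            group[i],
                            group[j],
                            variant,
                            token_paths[group[i]],
                            token_paths[group[j]],
                        )
    return findings


def _subtree_depth(entry: TreeEntry) -> int:
    if not entry.children:
        return 0
    return 1 + max(_subtree_depth(c) for c in entry.children)


def _shape_signature(entry: TreeEntry) -> tuple:
    children = tuple(sorted((c.kind, name_skeleton(c.name)) for c in entry.children))
    return (_subtree_depth(entry), children)


def check_cohort_structure(tree: DatasetTree, config: CheckConfig) -> list[Finding]:
    """Sibling folders that should look alike but don't.

    Sibling folders sharing a word (e.g. four ``... Tissue`` treatment
    folders) form a cohort; when at least three members exist and a clear
    majority share a subtree shape, the odd ones out are flagged.  The
    shape signature uses name skeletons, so an extra child level breaks the
    pattern while differing indices or spellings do not.
    """
    findings = []
    flagged: set[str] = set()
    for path, entry, _depth in tree.walk():
        if not entry.is_folder:
            continue
        folder_children = [c for c in entry.children if c.is_folder]
        if len(folder_children) < 3:
            continue
        by_token: dict[str, list[TreeEntry]] = {}
        for sub in folder_children:
            for tok in _tokens(sub.name):
                low = tok.lower()
                if len(low) >= 3 and not low.isdigit():
                    by_token.setdefault(low, []).append(sub)
        for token, members in by_token.items():
            if len(members) < 3:
                continue
            sigs = {m.name: _shape_signature(m) for m in members}
            counts: dict[tuple, int] = {}
            for sig in sigs.values():
                counts[sig] = counts.get(sig, 0) + 1
            majority = max(counts, key=lambda s: counts[s])
            if counts[majority] * 2 <= len(members):
                continue  # no clear majority, nothing to compare against
            for m in members:
                mpath = f"{path}/{m.name}"
                if sigs[m.name] != majority and mpath not in flagged:
                    flagged.add(mpath)
                    findings.append(
                        Finding(
                            check_id="cohort_structure",
                            recommendation="R7a",
                            severity="info",
                            paths=[mpath],
                            message=(
                                f"folder breaks the structural pattern of its "
                                f"{len(members)} {token!r} siblings"
                            ),
                        )
                    )
    return findings


# ---------------------------------------------------------------------------
# Meaningfulness checks (obscure ids, external refs, dates, personal ids)
# ---------------------------------------------------------------------------


def check_obscure_and_external(tree: DatasetTree, config: CheckConfig) -> list[Finding]:
    """Obscure numeric identifiers, dates, figure references, personal names.

    Long digit runs convey nothing to a dataset user; figure numbers point
    at external (possibly paywalled) articles; dates in folder names make
    mass renames painful; personal identifiers should not be published.
    """
    findings = []
    blocklist = {b.casefold() for b in config.personal_id_blocklist}
    for path, entry, _depth in tree.walk():
        name = entry.name
        for m in lexicon.detect_digit_runs(name, config.min_digit_run):
            findings.append(
                Finding(
                    check_id="obscure_and_external",
                    recommendation="R5a",
                    severity="warning",
                    paths=[path],
                    message=(
                        f"numeric identifier {m.text!r} has no obvious meaning "
                        f"in the context of the dataset"
                    ),
                    suggestion={"pattern": "digit_run", "text": m.text},
                )
            )
        for m in lexicon.detect_dates(name):
            findings.append(
                Finding(
                    check_id="obscure_and_external",
                    recommendation="R5b",
                    severity="warning" if entry.is_folder else "info",
                    paths=[path],
                    message=f"name contains the date-like attribute {m.text!r}",
                    suggestion={"pattern": "date", "text": m.text},
                )
            )
        for m in lexicon.detect_figure_refs(name):
            findings.append(
                Finding(
                    check_id="obscure_and_external",
                    recommendation="R5a",
                    severity="warning",
                    paths=[path],
                    message=(
                        f"{m.text!r} looks like a reference to a figure in an "
                        f"external article"
                    ),
                    suggestion={"pattern": "figure_ref", "text": m.text},
                )
            )
        low_tokens = [t.casefold() for t in _tokens(name)]
        personal = None
        for item in blocklist:
            if item and item in name.casefold():
                personal = item
                break
        if personal is None:
            for k in range(len(low_tokens) - 1):
                if low_tokens[k] == "et" and low_tokens[k + 1] == "al":
                    personal = "et al"
                    break
        if personal is not None:
            findings.append(
                Finding(
                    check_id="obscure_and_external",
                    recommendation="R7b",
                    severity="warning",
                    paths=[path],
                    message=f"name appears to contain a personal identifier ({personal!r})",
                    suggestion={"pattern": "personal_id", "text": personal},
                )
            )
    return findings


# ---------------------------------------------------------------------------
# Padding check
# ---------------------------------------------------------------------------

_TRAILING_DIGITS_RE = re.compile(r"(\d+)$")

#: minimum number of files sharing (prefix, extension) to call it a sequence
PADDING_MIN_GROUP = 3


def padding_groups(entry: TreeEntry, config: CheckConfig) -> list[dict]:
    """Group a folder's files into zero-padding groups.

    Files whose stem ends in a decimal run and that share the remaining
    (prefix, extension) form a group once at least ``PADDING_MIN_GROUP``
    members exist.
    """
    groups: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for c in entry.children:
        if not c.is_file:
            continue
        ext = config.file_extension(c.name)
        stem = c.name[: len(c.name) - len(ext)] if ext else c.name
        m = _TRAILING_DIGITS_RE.search(stem)
        if not m:
            continue
        prefix = stem[: m.start()]
        groups.setdefault((prefix, ext), []).append((c.name, m.group(1)))
    out = []
    for (prefix, ext), members in sorted(groups.items()):
        if len(members) < PADDING_MIN_GROUP:
            continue
        out.append(
            {
                "prefix": prefix,
                "extension": ext,
                "files": sorted(members),
            }
        )
    return out


def check_padding(tree: DatasetTree, config: CheckConfig) -> list[Finding]:
    """Slice/file sequences whose numeric field is not zero-padded.

    Unpadded indices sort lexicographically out of numeric order
    (``x-10`` before ``x-2``), which silently shuffles slices in any tool
    that processes files in name order.
    """
    findings = []
    for path, entry, _depth in tree.walk():
        if not entry.is_folder:
            continue
        for group in padding_groups(entry, config):
            widths = {len(digits) for _name, digits in group["files"]}
            max_index = max(int(digits) for _name, digits in group["files"])
            want = len(str(max_index))
            inconsistent = len(widths) > 1
            underpadded = not inconsistent and next(iter(widths)) < want
            if not (inconsistent or underpadded):
                continue
            file_paths = sorted(f"{path}/{name}" for name, _d in group["files"])
            reason = (
                "indices use inconsistent widths"
                if inconsistent
                else f"indices are narrower than the largest index {max_index}"
            )
            findings.append(
                Finding(
                    check_id="padding",
                    recommendation="R7e",
                    severity="warning",
                    paths=file_paths,
                    message=(
                        f"sequence {group['prefix']!r}*{group['extension']} "
                        f"is not uniformly zero-padded ({reason}); pad to "
                        f"{want} digits so lexicographic order matches slice order"
                    ),
                    suggestion={
                        "width": want,
                        "prefix": group["prefix"],
                        "extension": group["extension"],
                    },
                )
            )
    return findings


# ---------------------------------------------------------------------------
# Root hygiene and formats
# ---------------------------------------------------------------------------


def _matches_any(name: str, patterns: Iterable[str]) -> bool:
    low = name.lower()
    return any(fnmatch.fnmatchcase(low, pat.lower()) for pat in patterns)


def check_root_hygiene(tree: DatasetTree, config: CheckConfig) -> list[Finding]:
    """One top-level folder, with a README and a checksum manifest inside."""
    findings = []
    folder_roots = [r for r in tree.roots if r.is_folder]
    if len(tree.roots) != 1 or len(folder_roots) != 1:
        paths = [r.name for r in tree.roots] or ["."]
        findings.append(
            Finding(
                check_id="root_hygiene",
                recommendation="R2",
                severity="warning",
                paths=paths,
                message=(
                    f"dataset should have exactly one top-level folder "
                    f"(found {len(folder_roots)} folder root(s) and "
                    f"{len(tree.roots) - len(folder_roots)} file root(s))"
                ),
            )
        )
    root = folder_roots[0] if len(folder_roots) == 1 else None
    top_files = [c.name for c in root.children if c.is_file] if root else []
    top_path = root.name if root else "."
    if not any(n.lower() in config.readme_patterns for n in top_files):
        findings.append(
            Finding(
                check_id="root_hygiene",
                recommendation="R9a",
                severity="warning",
                paths=[top_path],
                message="no README file at the top level describing the organisation",
            )
        )
    if not any(_matches_any(n, config.checksum_patterns) for n in top_files):
        findings.append(
            Finding(
                check_id="root_hygiene",
                recommendation="R10",
                severity="warning",
                paths=[top_path],
                message=(
                    "no checksum/parity file (e.g. md5-sums.txt, sha512-hashes.txt "
                    "or a .par2 file) at the top level"
                ),
            )
        )
    return findings


def check_formats(tree: DatasetTree, config: CheckConfig) -> list[Finding]:
    """Proprietary formats, and folders mixing many unrelated file types."""
    findings = []
    for path, entry, _depth in tree.walk():
        if entry.is_file:
            ext = config.file_extension(entry.name)
            if ext in config.proprietary_formats:
                label = config.proprietary_formats[ext]
                findings.append(
                    Finding(
                        check_id="formats",
                        recommendation="R8b",
                        severity="info",
                        paths=[path],
                        message=(
                            f"{ext!r} is a proprietary format ({label}); prefer open "
                            f"formats such as OME-TIFF or OME-NGFF"
                        ),
                        suggestion={"open_alternatives": ["OME-TIFF", "OME-NGFF"]},
                    )
                )
            continue
        file_children = [c for c in entry.children if c.is_file]
        if len(file_children) < config.mixed_content_min_files:
            continue
        classes = {
            extension_class(config.file_extension(c.name)) for c in file_children
        }
        if len(classes) > config.mixed_content_max_classes:
            findings.append(
                Finding(
                    check_id="formats",
                    recommendation="R4a",
                    severity="warning",
                    paths=[path],
                    message=(
                        f"folder mixes {len(file_children)} files across "
                        f"{len(classes)} format classes; group related files "
                        f"into sub-folders"
                    ),
                )
            )
    return findings


# ---------------------------------------------------------------------------
# Engine
# ---------------------------------------------------------------------------

CheckFunc = Callable[[DatasetTree, CheckConfig], list[Finding]]

CHECKS: dict[str, CheckFunc] = {
    "root_hygiene": check_root_hygiene,
    "name_length": check_name_length,
    "path_length": check_path_length,
    "depth": check_depth,
    "files_per_folder": check_files_per_folder,
    "redundant_folders": check_redundant_folders,
    "characters": check_characters,
    "periods": check_periods,
    "excluded_words": check_excluded_words,
    "path_repetition": check_path_repetition,
    "sibling_near_duplicates": check_sibling_near_duplicates,
    "cohort_structure": check_cohort_structure,
    "obscure_and_external": check_obscure_and_external,
    "padding": check_padding,
    "formats": check_formats,
}

#: checks about what things are called (vs. how the tree is shaped)
NAMING_CHECK_IDS = frozenset(
    {
        "name_length",
        "path_length",
        "characters",
        "periods",
        "excluded_words",
        "path_repetition",
        "sibling_near_duplicates",
    }
)

STRUCTURE_CHECK_IDS = frozenset(
    {"depth", "files_per_folder", "redundant_folders", "cohort_structure", "root_hygiene"}
)

#: naming defects a rename plan can always fix without human judgement
MECHANICAL_NAMING_CHECK_IDS = frozenset({"characters", "periods", "path_repetition"})


def run_checks(
    tree: DatasetTree,
    config: Optional[CheckConfig] = None,
    enabled: Optional[Iterable[str]] = None,
) -> list[Finding]:
    """Run the enabled checks and return findings sorted by (path, check).

    Pure: identical inputs always give identical output.  Unknown check ids
    raise ``ValueError`` listing the valid ones.
    """
    config = config or CheckConfig()
    if enabled is None:
        ids = list(CHECKS)
    else:
        ids = list(enabled)
        unknown = [i for i in ids if i not in CHECKS]
        if unknown:
            raise ValueError(
                f"unknown check id(s) {unknown}; valid ids: {sorted(CHECKS)}"
            )
    findings: list[Finding] = []
    for check_id in ids:
        findings.extend(CHECKS[check_id](tree, config))
    findings.sort(key=lambda f: (f.paths[0] if f.paths else "", f.check_id, f.message))
    return findings
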