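"""Mechanical fix planning: normalisation, chain collapse, splits, padding.

Everything here is *mechanical*: lowercasing, transliterating, collapsing
redundant levels, de-duplicating repeated tokens, zero-padding sequences and
splitting oversized folders.  Choosing a *meaningful* replacement for an
obscure name is human judgement and stays out of scope — the lint report
tells the user where that judgement is still needed.
"""

from __future__ import annotations

import json
import math
import os
import re
import shutil
import unicodedata
from dataclasses import dataclass, field

from . import lexicon
from .checks import CheckConfig
from .tree_model import DatasetTree, TreeEntry


# ---------------------------------------------------------------------------
# Name normalisation
# ---------------------------------------------------------------------------

_SEP_RUN_RE = re.compile(r"[ _\-]+")


def _normalise_stem(stem: str, config: CheckConfig) -> str:
    # transliterate accented letters to their base letter, drop the rest
    decomposed = unicodedata.normalize("NFKD", stem)
    ascii_stem = decomposed.encode("ascii", "ignore").decode("ascii")
    ascii_stem = ascii_stem.lower()
    # periods inside a stem are word boundaries once the extension is split off
    ascii_stem = ascii_stem.replace(".", "_")
    # keep word characters and separators, drop everything else
    ascii_stem = re.sub(r"[^a-z0-9 _\-]", "", ascii_stem)

    # collapse each separator run: hyphens mark keywords, so a run containing
    # a hyphen collapses to '-', any other run to '_'
    def collapse(m: re.Match) -> str:
        return "-" if "-" in m.group(0) else "_"

    ascii_stem = _SEP_RUN_RE.sub(collapse, ascii_stem)
    return ascii_stem.strip("_-")


_CLEAN_EXT_RE = re.compile(r"^\.[a-z0-9]+$")


def normalise_name(
    name: str, config: CheckConfig | None = None, is_file: bool = True
) -> str:
    """Normalise one path component to the archival naming convention.

    Lowercases, transliterates accented letters ('ö' -> 'o'), turns spaces
    into underscores, drops forbidden characters, preserves hyphens (keyword
    markers) and — for files — the final or whitelisted multi-part
    extension, collapses separator runs and strips leading/trailing
    separators.  Idempotent.

    Raises ``ValueError`` if no stem survives; the caller must then supply
    a fallback name.
    """
    config = config or CheckConfig()
    ext = config.file_extension(name) if is_file else ""
    if ext and ext.lower() not in config.multi_extension_whitelist and not _CLEAN_EXT_RE.match(ext.lower()):
        ext = ""  # a non-alphanumeric suffix is a defect, not an extension
    stem = name[: len(name) - len(ext)] if ext else name
    out = _normalise_stem(stem, config)
    if not out:
        raise ValueError(f"nothing left of {name!r} after normalisation")
    return out + ext.lower() if ext else out


# ---------------------------------------------------------------------------
# Token de-duplication along a path
# ---------------------------------------------------------------------------


def _is_short_numeric(token: str) -> bool:
    return token.isdigit() and len(token) < 3


def _dedupe_component(name: str, ancestor_tokens: set[str], protect_ext: str = "") -> str:
    """Drop tokens of one component that repeat ancestor tokens.

    Short numeric tokens (indices like '1') are kept even when repeated; a
    component is never emptied — if everything repeats, the last token stays.
    """
    stem = name[: len(name) - len(protect_ext)] if protect_ext else name
    tl = lexicon.tokenize(stem)
    if not tl.tokens:
        return name
    keep = [
        not (tok.lower() in ancestor_tokens and not _is_short_numeric(tok))
        for tok in tl.tokens
    ]
    if not any(keep):
        keep[-1] = True
    parts: list[str] = []
    first = True
    for tok, kept, sep_before in zip(tl.tokens, keep, tl.separators):
        if not kept:
            continue
        if not first:
            parts.append(sep_before)
        parts.append(tok)
        first = False
    return "".join(parts) + protect_ext


def dedupe_path_tokens(path: str) -> str:
    """Remove tokens repeated from ancestor components along a path.

    Token sets accumulate from the original component spellings, matched
    case-insensitively.
    """
    components = path.split("/")
    seen: set[str] = set()
    out: list[str] = []
    for i, comp in enumerate(components):
        if i == 0:
            out.append(comp)
        else:
            out.append(_dedupe_component(comp, seen))
        seen |= {t.lower() for t in lexicon.tokenize(comp).tokens}
    return "/".join(out)


# ---------------------------------------------------------------------------
# Split plans for oversized folders
# ---------------------------------------------------------------------------


@dataclass
class SplitPlan:
    """Partition of an oversized folder into capped child folders.

    Children are named ``child00``, ``child01``, ... (width grows with the
    number of children, minimum two digits) and each receives a contiguous
    index range of at most ``cap`` files.
    """

    folder: str
    n_files: int
    cap: int
    n_subfolders: int
    child_name_width: int
    assignment: list[tuple[str, int, int]]  # (child name, first index, last index)

    def child_names(self) -> list[str]:
        return [name for name, _a, _b in self.assignment]


def make_split_plan(n_files: int, cap: int, folder: str = "parent_folder") -> SplitPlan:
    """Plan the split of ``n_files`` files into sub-folders of at most ``cap``."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if n_files <= cap:
        raise ValueError(f"{n_files} files fit under the cap {cap}; no split needed")
    n_sub = math.ceil(n_files / cap)
    width = max(2, len(str(n_sub - 1)))
    assignment = []
    start = 1
    for i in range(n_sub):
        end = min(start + cap - 1, n_files)
        assignment.append((f"child{str(i).zfill(width)}", start, end))
        start = end + 1
    return SplitPlan(
        folder=folder,
        n_files=n_files,
        cap=cap,
        n_subfolders=n_sub,
        child_name_width=width,
        assignment=assignment,
    )


# ---------------------------------------------------------------------------
# Padding plans for numeric file sequences
# ---------------------------------------------------------------------------


@dataclass
class PaddingGroup:
    """Sibling files sharing a prefix/extension around a decimal index."""

    prefix: str
    extension: str
    files: list[tuple[str, int]]  # (file name, numeric index)


@dataclass
class PaddingPlan:
    prefix: str
    extension: str
    width: int
    renames: list[tuple[str, str]]  # (old name, new name)


def make_padding_plan(group: PaddingGroup) -> PaddingPlan:
    """Zero-pad a sequence so lexicographic order equals numeric order.

    The width is the digit count of the maximum index.  Two files claiming
    the same index make the sequence ambiguous and raise ``ValueError``.
    """
    if not group.files:
        raise ValueError("padding group is empty")
    indices = [idx for _n, idx in group.files]
    if len(indices) != len(set(indices)):
        dupes = sorted({i for i in indices if indices.count(i) > 1})
        raise ValueError(f"ambiguous sequence: duplicate indices {dupes}")
    width = len(str(max(indices)))
    renames = [
        (old, f"{group.prefix}{str(idx).zfill(width)}{group.extension}")
        for old, idx in sorted(group.files, key=lambda f: f[1])
    ]
    return PaddingPlan(
        prefix=group.prefix, extension=group.extension, width=width, renames=renames
    )


# ---------------------------------------------------------------------------
# Whole-tree rename plans
# ---------------------------------------------------------------------------


@dataclass
class RenamePlan:
    """Injective old-path -> new-path mapping, applied deepest-first."""

    steps: list[tuple[str, str]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)

    def to_json(self) -> str:
        return json.dumps(
            [{"source": s, "target": t} for s, t in self.steps], indent=2
        )

    def to_tsv(self) -> str:
        return "".join(f"{s}\t{t}\n" for s, t in self.steps)

    @classmethod
    def from_json(cls, text: str) -> "RenamePlan":
        data = json.loads(text)
        return cls(steps=[(d["source"], d["target"]) for d in data])


@dataclass
class _Node:
    entry: TreeEntry
    orig_path: str
    children: list["_Node"] = field(default_factory=list)
    new_name: str = ""


def _build_nodes(entry: TreeEntry, path: str) -> _Node:
    node = _Node(entry=entry, orig_path=path)
    for c in entry.children:
        node.children.append(_build_nodes(c, f"{path}/{c.name}"))
    return node


def _collapse_children(children: list[_Node]) -> None:
    """Replace every single-folder chain member by its promoted child."""
    changed = True
    while changed:
        changed = False
        for i, c in enumerate(children):
            if (
                c.entry.is_folder
                and len(c.children) == 1
                and c.children[0].entry.is_folder
            ):
                children[i] = c.children[0]
                changed = True
    for c in children:
        if c.entry.is_folder:
            _collapse_children(c.children)


def _suffix_collision(name: str, ext: str, taken: set[str]) -> str:
    if name not in taken:
        return name
    stem = name[: len(name) - len(ext)] if ext else name
    k = 2
    while f"{stem}-{k}{ext}" in taken:
        k += 1
    return f"{stem}-{k}{ext}"


def _plan_nodes(
    tree: DatasetTree, config: CheckConfig, rename: bool
) -> tuple[list[_Node], list[tuple[str, str]]]:
    """Collapse chains and assign final names; return roots plus all steps.

    With ``rename`` the per-component pipeline (token de-duplication then
    normalisation) runs; without it original names are kept (pure collapse).
    Collisions get a deterministic ``-2``/``-3`` suffix on the entry with
    the byte-wise larger source path (children are visited in source order).
    """
    roots = [_build_nodes(r, r.name) for r in tree.roots]
    for root in roots:
        _collapse_children(root.children)
    steps: list[tuple[str, str]] = []

    def assign(
        node: _Node, parent_path: str, ancestor_tokens: set[str], taken: set[str]
    ) -> None:
        ext = config.file_extension(node.entry.name) if node.entry.is_file else ""
        if rename:
            deduped = _dedupe_component(
                node.entry.name, ancestor_tokens, protect_ext=ext
            )
            try:
                name = normalise_name(deduped, config, is_file=node.entry.is_file)
            except ValueError:
                name = "unnamed" + ext.lower()
        else:
            name = node.entry.name
        name = _suffix_collision(name, config.file_extension(name) if node.entry.is_file else "", taken)
        taken.add(name)
        node.new_name = name
        new_path = f"{parent_path}/{name}" if parent_path else name
        if new_path != node.orig_path:
            steps.append((node.orig_path, new_path))
        child_tokens = ancestor_tokens | {
            t.lower() for t in lexicon.tokenize(name).tokens
        }
        child_taken: set[str] = set()
        for c in sorted(
            node.children, key=lambda n: n.orig_path.encode("utf-8", "surrogateescape")
        ):
            assign(c, new_path, child_tokens, child_taken)

    root_taken: set[str] = set()
    for root in roots:
        assign(root, "", set(), root_taken)
    steps.sort(key=lambda st: (-st[0].count("/"), st[0]))
    return roots, steps


def collapse_chains(tree: DatasetTree) -> list[tuple[str, str]]:
    """Plan fragment removing redundant single-folder chains below the root.

    Each maximal chain is replaced by the first folder that actually holds
    content, reparented to the chain's parent; the top-level folder itself
    is never collapsed.  Only moved subtree roots are listed (descendants
    travel with them); a promotion colliding with an existing sibling name
    gets a deterministic ``-2`` suffix.
    """
    _roots, steps = _plan_nodes(tree, CheckConfig(), rename=False)
    moved_roots = [
        (s, t)
        for s, t in steps
        if not any(s != s2 and s.startswith(s2 + "/") for s2, _t2 in steps)
    ]
    return moved_roots


def build_rename_plan(tree: DatasetTree, config: CheckConfig | None = None) -> RenamePlan:
    """Compose chain collapse, token de-duplication and name normalisation.

    Produces an injective source-to-target mapping covering every entry
    whose path changes, ordered deepest-first so children move before their
    parents.  Obscure identifiers are normalised but not invented away, and
    over-long names are not truncated — those renames need human semantics
    and are left to the lint report.
    """
    config = config or CheckConfig()
    _roots, steps = _plan_nodes(tree, config, rename=True)
    return RenamePlan(steps=steps)


def planned_tree(tree: DatasetTree, config: CheckConfig | None = None) -> DatasetTree:
    """The tree as it would look after applying :func:`build_rename_plan`."""
    config = config or CheckConfig()
    roots, _steps = _plan_nodes(tree, config, rename=True)

    def rebuild(node: _Node) -> TreeEntry:
        entry = TreeEntry(
            name=node.new_name, kind=node.entry.kind, size_bytes=node.entry.size_bytes
        )
        entry.children = [rebuild(c) for c in node.children]
        return entry

    out = DatasetTree(roots=[rebuild(r) for r in roots], source=tree.source)
    out.sort()
    return out


def apply_plan(
    plan: RenamePlan,
    base_dir: str,
    dry_run: bool = True,
    journal_path: str | None = None,
) -> list[tuple[str, str]]:
    """Apply a rename plan to entries on disk, deepest-first.

    ``base_dir`` is the directory *containing* the dataset's top-level
    folder (plan paths are relative to it).  With ``dry_run`` (the default)
    nothing is touched; the would-be operations are returned either way.
    Executed moves are appended to a JSON-lines journal so they can be
    reversed by hand if needed.
    """
    ops: list[tuple[str, str]] = []
    steps = sorted(plan.steps, key=lambda st: (-st[0].count("/"), st[0]))
    for src, tgt in steps:
        src_abs = os.path.join(base_dir, *src.split("/"))
        tgt_abs = os.path.join(base_dir, *tgt.split("/"))
        if not os.path.lexists(src_abs):
            continue  # moved along with a parent, or never materialised
        ops.append((src, tgt))
        if dry_run:
            continue
        os.makedirs(os.path.dirname(tgt_abs) or ".", exist_ok=True)
        if os.path.isdir(src_abs) and os.path.isdir(tgt_abs):
            # merge into the already-created target, then drop the husk
            for child in os.listdir(src_abs):
                shutil.move(os.path.join(src_abs, child), os.path.join(tgt_abs, child))
            os.rmdir(src_abs)
        else:
            os.rename(src_abs, tgt_abs)
    if not dry_run:
        # chain collapse leaves empty husk directories behind; prune them
        for root, _dirs, _files in os.walk(base_dir, topdown=False):
            if root != base_dir and not os.listdir(root):
                os.rmdir(root)
        if journal_path:
            with open(journal_path, "a", encoding="utf-8") as fh:
                for src, tgt in ops:
                    fh.write(json.dumps({"source": src, "target": tgt}) + "\n")
    return ops
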