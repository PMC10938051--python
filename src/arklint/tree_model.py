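"""In-memory model of a dataset's file/folder hierarchy.

A dataset prepared for archival is, organisationally, nothing more than a
rooted tree of named entries.  This module represents that tree, ingests it
either from a live filesystem walk or from a plain-text path manifest (so a
tree can be linted without the data present), and computes the summary
statistics that the structural checks consume.

Names are preserved byte-for-byte at ingest: every organisational defect
(non-ASCII characters, spaces, over-long names, ...) must reach the linter
unaltered, so ingest never normalises, and malformed *content* of a name is
never an ingest error — only malformed manifest *syntax* is.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

FILE = "file"
FOLDER = "folder"


class ManifestError(ValueError):
    """Raised for a syntactically invalid or self-contradictory manifest."""

    def __init__(self, message: str, line_no: Optional[int] = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


@dataclass
class TreeEntry:
    """One named node: a file or a folder.

    ``name`` is a single path component (never contains ``/``); ``children``
    is non-empty only for folders; ``size_bytes`` is known only for files
    ingested from a filesystem walk.
    """

    name: str
    kind: str  # FILE or FOLDER
    children: list["TreeEntry"] = field(default_factory=list)
    size_bytes: Optional[int] = None

    @property
    def is_file(self) -> bool:
        return self.kind == FILE

    @property
    def is_folder(self) -> bool:
        return self.kind == FOLDER

    def child(self, name: str) -> Optional["TreeEntry"]:
        for c in self.children:
            if c.name == name:
                return c
        return None

    def sort(self) -> None:
        """Recursively fix child order to byte-wise lexicographic."""
        self.children.sort(key=lambda e: e.name.encode("utf-8", "surrogateescape"))
        for c in self.children:
            c.sort()


@dataclass
class DatasetTree:
    """A forest of root entries plus where it came from.

    A well-organised dataset has exactly one root folder; trees with zero or
    several roots are representable (the root-hygiene check reports them).
    """

    roots: list[TreeEntry] = field(default_factory=list)
    source: str = "manifest"  # "walk" or "manifest"
    warnings: list[str] = field(default_factory=list)

    def sort(self) -> None:
        self.roots.sort(key=lambda e: e.name.encode("utf-8", "surrogateescape"))
        for r in self.roots:
            r.sort()

    def walk(self) -> Iterator[tuple[str, TreeEntry, int]]:
        """Yield ``(path, entry, depth)`` in depth-first preorder.

        Depth convention: a root entry has depth 1, so a file directly
        inside the single top-level folder has depth 2.  Paths are relative
        POSIX paths with no leading slash.
        """
        for path, entry, depth, _ancestors in self.walk_with_ancestors():
            yield path, entry, depth

    def walk_with_ancestors(
        self,
    ) -> Iterator[tuple[str, TreeEntry, int, tuple[TreeEntry, ...]]]:
        stack: list[tuple[str, TreeEntry, int, tuple[TreeEntry, ...]]] = []
        for root in reversed(self.roots):
            stack.append((root.name, root, 1, ()))
        while stack:
            path, entry, depth, ancestors = stack.pop()
            yield path, entry, depth, ancestors
            if entry.is_folder:
                for c in reversed(entry.children):
                    stack.append((f"{path}/{c.name}", c, depth + 1, ancestors + (entry,)))

    def paths(self) -> set[str]:
        return {p for p, _e, _d in self.walk()}

    def find(self, path: str) -> Optional[TreeEntry]:
        parts = path.split("/")
        node: Optional[TreeEntry] = None
        for r in self.roots:
            if r.name == parts[0]:
                node = r
                break
        if node is None:
            return None
        for part in parts[1:]:
            if not node.is_folder:
                return None
            node = node.child(part)
            if node is None:
                return None
        return node


@dataclass
class TreeStats:
    """Summary statistics backing the size/depth/length limit checks."""

    n_files: int = 0
    n_folders: int = 0
    max_depth: int = 0
    max_files_in_one_folder: int = 0
    max_path_length: int = 0
    max_name_length: int = 0
    extension_histogram: dict[str, int] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "n_files": self.n_files,
            "n_folders": self.n_folders,
            "max_depth": self.max_depth,
            "max_files_in_one_folder": self.max_files_in_one_folder,
            "max_path_length": self.max_path_length,
            "max_name_length": self.max_name_length,
            "extension_histogram": dict(sorted(self.extension_histogram.items())),
        }


def read_manifest(lines: Iterable[str]) -> DatasetTree:
    """Build a tree from a path manifest.

    One relative ``/``-separated path per line; blank lines and ``#``
    comments are ignored; a trailing ``/`` declares a folder, otherwise the
    last component is a file (ancestors are implied folders).  Duplicate
    declarations merge; a path declared both as file and folder is a
    conflict.  Component text is preserved byte-for-byte.
    """
    tree = DatasetTree(roots=[], source="manifest")
    index: dict[str, TreeEntry] = {}  # path -> entry

    def ensure(path_parts: list[str], kind: str, line_no: int) -> None:
        parent_children = tree.roots
        so_far = ""
        for i, part in enumerate(path_parts):
            so_far = part if i == 0 else f"{so_far}/{part}"
            want = kind if i == len(path_parts) - 1 else FOLDER
            node = index.get(so_far)
            if node is None:
                node = TreeEntry(name=part, kind=want)
                index[so_far] = node
                parent_children.append(node)
            elif node.kind != want:
                raise ManifestError(
                    f"{so_far!r} declared both as {node.kind} and as {want}",
                    line_no,
                )
            parent_children = node.children

    for line_no, raw in enumerate(lines, start=1):
        line = raw.rstrip("\n").rstrip("\r")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        if line.startswith("/"):
            raise ManifestError("absolute paths are not allowed", line_no)
        is_folder = line.endswith("/")
        body = line.rstrip("/") if is_folder else line
        if not body:
            raise ManifestError("empty path", line_no)
        parts = body.split("/")
        if any(p == "" for p in parts):
            raise ManifestError("empty path component ('//')", line_no)
        ensure(parts, FOLDER if is_folder else FILE, line_no)

    tree.sort()
    return tree


def to_manifest(tree: DatasetTree) -> list[str]:
    """Serialise a tree back to manifest lines (sorted, folders with ``/``).

    Folders that contain entries are implied by their descendants' lines and
    are emitted only when empty, so ``read_manifest(to_manifest(t))``
    round-trips the entry set exactly.
    """
    lines: list[str] = []
    for path, entry, _depth in tree.walk():
        if entry.is_file:
            lines.append(path)
        elif not entry.children:
            lines.append(path + "/")
    return sorted(lines)


def walk_directory(root: str | os.PathLike) -> DatasetTree:
    """Mirror an on-disk directory as a tree.

    The directory itself becomes the single root folder.  Symbolic links are
    recorded as files and never followed; hidden entries are included; child
    order is byte-wise lexicographic.  An unreadable subfolder is recorded
    as a warning on the tree and the walk continues.
    """
    root = os.fspath(root)
    if not os.path.isdir(root):
        raise FileNotFoundError(f"not a readable directory: {root!r}")
    root_name = os.path.basename(os.path.abspath(root))
    tree = DatasetTree(roots=[], source="walk")

    def build(dir_path: str, name: str) -> TreeEntry:
        entry = TreeEntry(name=name, kind=FOLDER)
        try:
            with os.scandir(dir_path) as it:
                dirents = sorted(
                    it, key=lambda d: d.name.encode("utf-8", "surrogateescape")
                )
        except OSError as exc:
            tree.warnings.append(f"unreadable folder {dir_path!r}: {exc}")
            return entry
        for d in dirents:
            if d.is_symlink() or not d.is_dir(follow_symlinks=False):
                try:
                    size = d.stat(follow_symlinks=False).st_size
                except OSError:
                    size = None
                entry.children.append(TreeEntry(name=d.name, kind=FILE, size_bytes=size))
            else:
                entry.children.append(build(os.path.join(dir_path, d.name), d.name))
        return entry

    tree.roots.append(build(root, root_name))
    return tree


def name_extension(name: str) -> str:
    """Last dotted suffix of a file name, lowercased (``".tif"``), or ``""``.

    A purely leading dot (hidden file) does not count as an extension.
    Multi-part extension awareness lives in the checks layer where the
    whitelist is configured; the histogram uses the plain last suffix.
    """
    idx = name.rfind(".")
    if idx <= 0 or idx == len(name) - 1:
        return ""
    return name[idx:].lower()


def tree_stats(tree: DatasetTree) -> TreeStats:
    stats = TreeStats()
    for path, entry, depth in tree.walk():
        stats.max_depth = max(stats.max_depth, depth)
        stats.max_path_length = max(stats.max_path_length, len(path))
        stats.max_name_length = max(stats.max_name_length, len(entry.name))
        if entry.is_file:
            stats.n_files += 1
            ext = name_extension(entry.name)
            stats.extension_histogram[ext] = stats.extension_histogram.get(ext, 0) + 1
        else:
            stats.n_folders += 1
            n_file_children = sum(1 for c in entry.children if c.is_file)
            stats.max_files_in_one_folder = max(
                stats.max_files_in_one_folder, n_file_children
            )
    return stats
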